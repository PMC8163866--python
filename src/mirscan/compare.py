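"""Cross-modality comparison: resampling, SSIM/MSE, label concordance, throughput.

The discrete-band scanner and the hyperspectral imager observe the same
specimen on different grids and axes; this module maps matched channels onto a
common grid, scores their structural similarity (windowed SSIM) and mean
squared error, quantifies segmentation concordance (optimal label matching →
per-class Dice plus a chance-adjusted agreement index), and accounts for the
scan-time / data-load trade-off between the two instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import linear_sum_assignment
from skimage.metrics import structural_similarity
from sklearn.metrics import adjusted_rand_score

from mirscan.acquisition import FtirConfig, HyperCube, ScannerConfig, pixel_grid
from mirscan.errors import ConfigurationError, DataError, GeometryError
from mirscan.preprocess import AbsorbanceImage, normalize_image, tv_denoise_adaptive
from mirscan.segment import LabelMap


@dataclass
class SimilarityReport:
    """Per-channel SSIM and MSE between matched MIR and FT-IR channels."""

    per_channel_ssim: dict[float, float]
    per_channel_mse: dict[float, float]
    roi: tuple[int, int, int, int] | None = None

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(list(self.per_channel_ssim.values())))


@dataclass
class ThroughputRecord:
    """Pixel / channel / value counts and scan time for one modality."""

    name: str
    pixels: int
    channels: int
    scan_time: float

    @property
    def values_total(self) -> int:
        return self.pixels * self.channels


def resample_to_grid(
    image: np.ndarray, src_pitch: float, dst_pitch: float
) -> np.ndarray:
    """Bilinearly resample a raster onto a new pixel pitch over the same extent.

    Pixel centres sit at (i + ½)·pitch; destination centres outside the source
    centre hull are linearly extrapolated so affine fields resample exactly.
    """
    if src_pitch <= 0 or dst_pitch <= 0:
        raise ConfigurationError("pixel pitches must be > 0")
    image = np.asarray(image, dtype=float)
    if src_pitch == dst_pitch:
        return image.copy()
    rows, cols = image.shape
    extent_r, extent_c = rows * src_pitch, cols * src_pitch
    n_r = int(np.floor(extent_r / dst_pitch + 1e-9))
    n_c = int(np.floor(extent_c / dst_pitch + 1e-9))
    if n_r < 1 or n_c < 1:
        raise GeometryError("destination grid has no pixels within the shared extent")
    src_r = (np.arange(rows) + 0.5) * src_pitch
    src_c = (np.arange(cols) + 0.5) * src_pitch
    interp = RegularGridInterpolator(
        (src_r, src_c), image, method="linear", bounds_error=False, fill_value=None
    )
    dst_r = (np.arange(n_r) + 0.5) * dst_pitch
    dst_c = (np.arange(n_c) + 0.5) * dst_pitch
    rr, cc = np.meshgrid(dst_r, dst_c, indexing="ij")
    return interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(n_r, n_c)


def ssim(a: np.ndarray, b: np.ndarray, window: int = 7, data_range: float = 1.0) -> float:
    """Mean windowed structural similarity (standard constants, uniform window)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"shapes differ: {a.shape} vs {b.shape}")
    if data_range <= 0:
        raise ConfigurationError("data_range must be > 0")
    if window > min(a.shape) or window % 2 == 0 or window < 3:
        raise ConfigurationError(
            f"window {window} must be odd, >= 3 and no larger than the image"
        )
    return float(
        structural_similarity(
            a, b, win_size=window, data_range=data_range, gaussian_weights=False
        )
    )


def mse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _crop_roi(img: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    r0, c0, h, w = roi
    if h < 1 or w < 1 or r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
        raise ConfigurationError(f"ROI {roi} does not fit the {img.shape} grid")
    return img[r0 : r0 + h, c0 : c0 + w]


def channel_similarity(
    mir: Mapping[float, AbsorbanceImage] | Sequence[AbsorbanceImage],
    ftir: HyperCube,
    wavenumbers: Sequence[float],
    roi: tuple[int, int, int, int] | None = None,
    window: int = 7,
    denoise_strength: float = 0.0,
) -> SimilarityReport:
    """Score matched MIR and FT-IR channels on a common grid.

    Per requested wavenumber: take the MIR absorbance image, extract the
    nearest FT-IR channel (the gap must not exceed the cube's spectral
    spacing), resample the FT-IR channel onto the MIR grid, optionally apply
    the same TV denoising to both, normalise both identically, then compute
    SSIM and MSE (optionally inside an ROI given as (row0, col0, h, w) on the
    destination grid).
    """
    if isinstance(mir, Mapping):
        mir_map = dict(mir)
    else:
        mir_map = {im.wavenumber: im for im in mir}
    spacing = float(np.median(np.abs(np.diff(ftir.wavenumbers)))) if ftir.wavenumbers.size > 1 else np.inf
    ssim_per: dict[float, float] = {}
    mse_per: dict[float, float] = {}
    for nu in wavenumbers:
        if nu not in mir_map:
            raise DataError(f"no MIR image at {nu} cm^-1")
        mir_img = mir_map[nu]
        idx = ftir.channel_index(nu)
        gap = abs(ftir.wavenumbers[idx] - nu)
        if gap > spacing:
            raise DataError(
                f"nearest FT-IR channel to {nu} cm^-1 is {gap:.1f} cm^-1 away "
                f"(> spacing {spacing:.1f})"
            )
        ft = resample_to_grid(ftir.data[:, :, idx], ftir.pixel_pitch, mir_img.pixel_pitch)
        a = mir_img.values
        if ft.shape != a.shape:
            h = min(ft.shape[0], a.shape[0])
            w = min(ft.shape[1], a.shape[1])
            if h < 1 or w < 1:
                raise GeometryError("MIR and FT-IR extents do not overlap")
            ft, a = ft[:h, :w], a[:h, :w]
        pitch = mir_img.pixel_pitch
        a_img = AbsorbanceImage(a, nu, pitch)
        f_img = AbsorbanceImage(ft, nu, pitch)
        if denoise_strength > 0:
            a_img = tv_denoise_adaptive(a_img, strength=denoise_strength)
            f_img = tv_denoise_adaptive(f_img, strength=denoise_strength)
        a_n = normalize_image(a_img, 1.0, 99.0).values
        f_n = normalize_image(f_img, 1.0, 99.0).values
        if roi is not None:
            a_n = _crop_roi(a_n, roi)
            f_n = _crop_roi(f_n, roi)
        ssim_per[float(nu)] = ssim(a_n, f_n, window=window, data_range=1.0)
        mse_per[float(nu)] = mse(a_n, f_n)
    return SimilarityReport(per_channel_ssim=ssim_per, per_channel_mse=mse_per, roi=roi)


def label_concordance(a: LabelMap, b: LabelMap) -> tuple[dict[int, float], float]:
    """Concordance between two segmentations on one grid.

    Kept clusters are matched one-to-one by maximising total overlap
    (assignment problem); returns per-matched-class Dice keyed by the first
    map's cluster id, plus the adjusted Rand index over all pixels (rejected
    background counts as its own label) as a chance-adjusted agreement score.
    """
    la, lb = a.labels, b.labels
    if la.shape != lb.shape:
        raise DataError("label maps must share one grid; resample first")
    ids_a = a.kept_ids()
    ids_b = b.kept_ids()
    if not ids_a or not ids_b:
        raise DataError("label concordance needs at least one kept cluster per map")
    overlap = np.zeros((len(ids_a), len(ids_b)))
    for i, ca in enumerate(ids_a):
        ma = la == ca
        for j, cb in enumerate(ids_b):
            overlap[i, j] = np.logical_and(ma, lb == cb).sum()
    rows, cols = linear_sum_assignment(-overlap)
    dice: dict[int, float] = {}
    for i, j in zip(rows, cols):
        na = (la == ids_a[i]).sum()
        nb = (lb == ids_b[j]).sum()
        denom = na + nb
        dice[ids_a[i]] = float(2.0 * overlap[i, j] / denom) if denom else 0.0
    ari = float(adjusted_rand_score(la.ravel(), lb.ravel()))
    return dice, ari


def _boundary(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    mask = np.asarray(mask, dtype=bool)
    return mask & ~binary_erosion(mask, border_value=0)


def boundary_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance (pixels) between two masks' boundaries."""
    from scipy.spatial.distance import directed_hausdorff

    pa = np.argwhere(_boundary(a))
    pb = np.argwhere(_boundary(b))
    if pa.size == 0 or pb.size == 0:
        raise DataError("empty boundary: cannot compute Hausdorff distance")
    return float(
        max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    )


def throughput_report(
    mir_config: ScannerConfig,
    mir_scan_time: float,
    ftir_config: FtirConfig,
    ftir_scan_time: float,
    field_mm: tuple[float, float],
    ftir_channels: int | None = None,
) -> tuple[ThroughputRecord, ThroughputRecord, float, float]:
    """Scan-time and data-load accounting for one field, both modalities.

    Scan times are supplied measurements, never derived (the instrument's line
    duty cycle is not modelled).  ``ftir_channels`` should be the restricted
    (clustered) channel count; it defaults to the full configured axis.
    Returns (mir_record, ftir_record, time_ratio, data_ratio) with ratios
    FT-IR / MIR.
    """
    if mir_scan_time <= 0 or ftir_scan_time <= 0:
        raise DataError("scan times must be > 0")
    _, _, mir_px = pixel_grid(field_mm, mir_config.spatial_resolution)
    _, _, ft_px = pixel_grid(field_mm, ftir_config.pixel_pitch)
    n_ft = int(ftir_channels) if ftir_channels is not None else ftir_config.axis().size
    mir_rec = ThroughputRecord(
        name="MIR scanner", pixels=mir_px, channels=len(mir_config.lasers),
        scan_time=mir_scan_time,
    )
    ft_rec = ThroughputRecord(
        name="FT-IR imager", pixels=ft_px, channels=n_ft, scan_time=ftir_scan_time,
    )
    time_ratio = ftir_scan_time / mir_scan_time
    data_ratio = ft_rec.values_total / mir_rec.values_total
    return mir_rec, ft_rec, time_ratio, data_ratio
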