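"""Pre-processing chains for both modalities.

MIR rasters: background-referenced absorbance → alignment → threshold
adjustment (weak-signal amplification) → locally adaptive total-variation
denoising → robust normalisation.

FT-IR cubes: spectral moving-average smoothing → per-pixel vector (unit-norm)
normalisation → restriction to the fingerprint and functional-group ranges.

All operations are deterministic and shape-preserving (the cube restriction
changes only the spectral axis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter, uniform_filter1d, affine_transform, shift as nd_shift
from skimage.registration import phase_cross_correlation

from mirscan.acquisition import HyperCube
from mirscan.errors import AlignmentError, ConfigurationError, DataError

#: Default spectral ranges kept for clustering: fingerprint region and the
#: functional-group region (C–H, N–H, O–H stretches).
DEFAULT_RANGES: tuple[tuple[float, float], ...] = ((750.0, 1500.0), (2500.0, 4000.0))


@dataclass
class AbsorbanceImage:
    """A single-wavenumber absorbance raster on a physical grid."""

    values: np.ndarray
    wavenumber: float
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("absorbance raster must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise DataError("absorbance raster contains non-finite values")


def to_absorbance(
    intensity: np.ndarray,
    background: np.ndarray,
    floor: float = 0.0,
    wavenumber: float = 0.0,
    pixel_pitch: float = 0.0,
) -> AbsorbanceImage:
    """Background-referenced absorbance A = −log10(I / I_bg), floored.

    Noise can push I above I_bg giving slightly negative A; values below
    ``floor`` are clipped to it so downstream clustering features stay
    nonnegative with the default floor of 0.
    """
    intensity = np.asarray(intensity, dtype=float)
    background = np.asarray(background, dtype=float)
    if intensity.shape != background.shape:
        raise DataError(
            f"intensity {intensity.shape} and background {background.shape} shapes differ"
        )
    bad = background <= 0
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DataError(f"nonpositive background at pixel {idx}")
    a = -np.log10(intensity / background)
    return AbsorbanceImage(
        values=np.maximum(a, floor), wavenumber=wavenumber, pixel_pitch=pixel_pitch
    )


def threshold_adjust(
    image: AbsorbanceImage,
    low_percentile: float = 25.0,
    gain: float = 1.5,
    threshold: float | None = None,
) -> AbsorbanceImage:
    """Amplify particularly weak signals with a continuous monotone transfer.

    Pixels below the ``low_percentile`` level t are scaled toward it:
    the transfer is gain·x up to the knot x₀ = t / (gain + 1), then linear
    (slope 1/gain) up to (t, t), identity above.  ``gain = 1`` is the
    identity; ``threshold`` overrides the percentile level directly.
    """
    if not 0.0 <= low_percentile < 100.0:
        raise ConfigurationError("low_percentile must be in [0, 100)")
    if gain < 1.0:
        raise ConfigurationError("gain must be >= 1")
    x = image.values
    t = float(np.percentile(x, low_percentile)) if threshold is None else float(threshold)
    if gain == 1.0 or t <= 0:
        return replace(image, values=x.copy())
    x0 = t / (gain + 1.0)
    out = np.where(
        x >= t,
        x,
        np.where(x <= x0, gain * x, t - (t - x) / gain),
    )
    return replace(image, values=out)


def _adaptive_weight(f: np.ndarray, strength: float, window: int) -> np.ndarray:
    """Per-pixel TV weight: full strength in flat windows, reduced on edges.

    Edginess is measured by the local variance of the gradient magnitude in
    ``window``-sized neighbourhoods, referenced to its image median so the
    (noise-dominated) flat background keeps the nominal strength.
    """
    gy, gx = np.gradient(f)
    g = np.hypot(gx, gy)
    m = uniform_filter(g, window)
    v = uniform_filter(g * g, window) - m * m
    v = np.maximum(v, 0.0)
    ref = float(np.median(v))
    if ref <= 0:
        return np.full_like(f, strength)
    return strength * np.clip(2.0 * ref / (ref + v), 0.0, 1.0)


def _grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy = np.zeros_like(u)
    gx = np.zeros_like(u)
    gy[:-1, :] = u[1:, :] - u[:-1, :]
    gx[:, :-1] = u[:, 1:] - u[:, :-1]
    return gy, gx


def _div(py: np.ndarray, px: np.ndarray) -> np.ndarray:
    d = np.zeros_like(py)
    d[0, :] += py[0, :]
    d[1:-1, :] += py[1:-1, :] - py[:-2, :]
    d[-1, :] += -py[-2, :]
    d[:, 0] += px[:, 0]
    d[:, 1:-1] += px[:, 1:-1] - px[:, :-2]
    d[:, -1] += -px[:, -2]
    return d


def tv_denoise_adaptive(
    image: AbsorbanceImage,
    strength: float = 0.3,
    adapt_window: int = 7,
    iterations: int = 120,
) -> AbsorbanceImage:
    """Locally adaptive total-variation (ROF) denoising.

    Minimises Σ w(x)·|∇u(x)| + ½‖u − f‖² by the Chambolle–Pock primal–dual
    scheme, where the per-pixel weight w(x) equals ``strength`` in flat
    windows and is scaled down where the local gradient variance is high
    (edge preservation).  The output is clamped to the input's value range.
    """
    if strength < 0:
        raise ConfigurationError("strength must be >= 0")
    if adapt_window < 3 or adapt_window % 2 == 0:
        raise ConfigurationError("adapt_window must be odd and >= 3")
    f = image.values
    if strength == 0 or f.size == 0 or np.ptp(f) == 0:
        return replace(image, values=f.copy())

    w = _adaptive_weight(f, strength, adapt_window)

    # Chambolle–Pock with ||∇||² <= 8: sigma = tau = 1/sqrt(8) is admissible.
    sigma = tau = 1.0 / np.sqrt(8.0)
    u = f.copy()
    u_bar = f.copy()
    py = np.zeros_like(f)
    px = np.zeros_like(f)
    for _ in range(int(iterations)):
        gy, gx = _grad(u_bar)
        py += sigma * gy
        px += sigma * gx
        mag = np.hypot(py, px)
        scale = np.maximum(1.0, np.divide(mag, w, out=np.full_like(mag, np.inf), where=w > 0))
        py /= scale
        px /= scale
        u_prev = u
        u = (u + tau * (_div(py, px) + f)) / (1.0 + tau)
        u_bar = 2.0 * u - u_prev
    return replace(image, values=np.clip(u, f.min(), f.max()))


def normalize_image(
    image: AbsorbanceImage, p_low: float = 1.0, p_high: float = 99.0
) -> AbsorbanceImage:
    """Robust linear rescale: percentile p_low → 0, p_high → 1, clipped to [0, 1]."""
    if p_low >= p_high:
        raise ConfigurationError("p_low must be < p_high")
    lo, hi = np.percentile(image.values, [p_low, p_high])
    if hi <= lo:
        raise DataError("degenerate image: normalisation percentiles coincide")
    out = np.clip((image.values - lo) / (hi - lo), 0.0, 1.0)
    return replace(image, values=out)


def smooth_cube(cube: HyperCube, window: int) -> HyperCube:
    """Moving-average smoothing of every pixel spectrum (odd ``window``)."""
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("smoothing window must be odd and >= 1")
    data = cube.data.astype(float)
    if window > 1:
        data = uniform_filter1d(data, window, axis=2, mode="nearest")
    return HyperCube(data=data, wavenumbers=cube.wavenumbers.copy(), pixel_pitch=cube.pixel_pitch)


def preprocess_cube(
    cube: HyperCube,
    smooth_window: int = 9,
    ranges: Sequence[tuple[float, float]] = DEFAULT_RANGES,
    norm_floor_fraction: float = 0.0,
) -> HyperCube:
    """FT-IR spectral chain: smoothing → unit-norm scaling → range restriction.

    A moving average of odd width ``smooth_window`` runs along the spectral
    axis of every pixel, each pixel spectrum is scaled to unit Euclidean norm
    (vector normalisation), and the channel set is restricted to the union of
    the given wavenumber intervals.

    ``norm_floor_fraction`` stabilises the vector normalisation on bare-slide
    pixels: spectra whose norm is below that fraction of the median spectral
    norm are zeroed instead of normalised, since their direction is pure
    noise.  0 (default) disables the floor.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ConfigurationError("smooth_window must be odd and >= 1")
    data = cube.data.astype(float)
    if smooth_window > 1:
        data = uniform_filter1d(data, smooth_window, axis=2, mode="nearest")
    norms = np.linalg.norm(data, axis=2, keepdims=True)
    floor = norm_floor_fraction * float(np.median(norms))
    valid = norms > max(floor, 0.0)
    data = np.divide(data, norms, out=np.zeros_like(data), where=valid)
    data[~np.broadcast_to(valid, data.shape)] = 0.0

    keep = np.zeros(cube.wavenumbers.size, dtype=bool)
    for lo, hi in ranges:
        keep |= (cube.wavenumbers >= lo) & (cube.wavenumbers <= hi)
    if not keep.any():
        raise ConfigurationError("spectral restriction removed every channel")
    return HyperCube(
        data=data[:, :, keep],
        wavenumbers=cube.wavenumbers[keep],
        pixel_pitch=cube.pixel_pitch,
    )


_TV_NOISE_FACTOR = 8.0  # auto TV weight = factor x estimated noise sd


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust pixel-noise estimate from horizontal first differences.

    Uses the median absolute deviation of neighbour differences (scaled to a
    Gaussian sigma, /0.6745/√2); structure edges are sparse in the difference
    image, so the MAD tracks the noise floor.
    """
    d = np.diff(np.asarray(values, dtype=float), axis=1)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0))


@dataclass
class AlignmentResult:
    """Aligned rasters plus the shifts applied and per-image success flags."""

    images: list[np.ndarray]
    shifts: list[tuple[float, float]]
    ok: list[bool]


def align_images(
    images: Sequence[np.ndarray],
    transform: np.ndarray | None = None,
    max_shift_fraction: float = 0.1,
) -> AlignmentResult:
    """Co-register rasters onto the first image's grid.

    With ``transform`` given (2x3 affine matrix), it is applied to every image
    after the first (bilinear).  Otherwise an integer-pixel shift is estimated
    per image by cross-correlation against the first; an estimated shift
    exceeding ``max_shift_fraction`` of the image extent marks that image as
    failed and leaves it unmodified.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    if len({im.shape for im in images}) != 1:
        raise DataError("all images must share one shape")
    out: list[np.ndarray] = [images[0].copy()]
    shifts: list[tuple[float, float]] = [(0.0, 0.0)]
    ok: list[bool] = [True]
    for im in images[1:]:
        if transform is not None:
            t = np.asarray(transform, dtype=float)
            if t.shape != (2, 3):
                raise ConfigurationError("transform must be a 2x3 affine matrix")
            out.append(affine_transform(im, t[:, :2], offset=t[:, 2], order=1))
            shifts.append((float(t[0, 2]), float(t[1, 2])))
            ok.append(True)
            continue
        est, _, _ = phase_cross_correlation(images[0], im, upsample_factor=1)
        limit = max_shift_fraction * np.array(im.shape)
        if np.any(np.abs(est) > limit):
            out.append(im.copy())
            shifts.append((float(est[0]), float(est[1])))
            ok.append(False)
        else:
            out.append(nd_shift(im, est, order=1, mode="nearest"))
            shifts.append((float(est[0]), float(est[1])))
            ok.append(True)
    return AlignmentResult(images=out, shifts=shifts, ok=ok)


def mir_preprocess(
    scanset,
    floor: float = 0.0,
    low_percentile: float = 25.0,
    gain: float = 1.0,
    tv_strength: float | None = None,
    tv_window: int = 7,
    tv_iterations: int = 120,
    p_low: float = 1.0,
    p_high: float = 99.0,
) -> dict[int, AbsorbanceImage]:
    """Run the fixed MIR chain on every laser of a scan set.

    Order: absorbance → align → threshold adjustment → TV denoising →
    normalisation.  Returns one normalised AbsorbanceImage per laser id.

    ``tv_strength = None`` (default) picks the TV weight per channel as
    8 × the robust noise estimate of that channel, so a noiseless scan
    passes through unchanged and noisy scans are smoothed in proportion.
    """
    lasers = list(scanset.config.lasers)
    abso = {
        l.id: to_absorbance(
            scanset.images[l.id],
            scanset.background[l.id],
            floor=floor,
            wavenumber=l.wavenumber,
            pixel_pitch=scanset.config.spatial_resolution,
        )
        for l in lasers
    }
    aligned = align_images([abso[l.id].values for l in lasers])
    out: dict[int, AbsorbanceImage] = {}
    for l, vals in zip(lasers, aligned.images):
        img = replace(abso[l.id], values=vals)
        img = threshold_adjust(img, low_percentile=low_percentile, gain=gain)
        strength = (
            _TV_NOISE_FACTOR * estimate_noise_sd(img.values)
            if tv_strength is None
            else tv_strength
        )
        img = tv_denoise_adaptive(
            img, strength=strength, adapt_window=tv_window, iterations=tv_iterations
        )
        out[l.id] = normalize_image(img, p_low=p_low, p_high=p_high)
    return out
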