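"""Virtual instruments: the 4-laser flying-spot MIR scanner and an FT-IR imager.

The MIR scanner sweeps a focused laser spot along lines (agile mirror, velocity
``mirror_velocity``) while a translation stage advances orthogonally.  Raw
detector samples are acquired at ``oversampling`` samples per spatial pixel and
averaged; a bare-slide background raster is recorded per laser for absorbance
referencing.  Transflection (double pass through the section, reflection off
the silvered slide) is folded into the effective absorbance of the phantom
profiles, since only the ratio to the slide background is observable.

The FT-IR imager records a full absorbance spectrum per pixel on a descending
wavenumber axis, averaged over ``accumulations`` independent noisy draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from mirscan.errors import ConfigurationError, GeometryError
from mirscan.phantom import TissuePhantom


@dataclass(frozen=True)
class LaserChannel:
    """One DFB laser of the scanner."""

    id: int
    wavenumber: float
    role: str

    _ROLES = ("target-lipid", "reference-lipid", "target-protein", "reference-protein")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ConfigurationError(f"unknown laser role {self.role!r}")
        if self.wavenumber <= 0:
            raise ConfigurationError("laser wavenumber must be > 0")


#: The scanner's stock laser set: reference/target pairs for lipids (C–H) and
#: proteins (amide A, N–H).
DEFAULT_LASERS: tuple[LaserChannel, ...] = (
    LaserChannel(1, 2790.0, "reference-lipid"),
    LaserChannel(2, 2926.0, "target-lipid"),
    LaserChannel(3, 3350.0, "target-protein"),
    LaserChannel(4, 3700.0, "reference-protein"),
)


@dataclass
class ScannerConfig:
    """Geometry, timing and noise settings of the flying-spot MIR scanner.

    Attributes
    ----------
    mirror_velocity : float
        Line-scan velocity of the agile mirror in m/s.
    spatial_resolution : float
        Pixel pitch on the sample in µm.
    oversampling : int
        Raw detector samples per spatial pixel (aggregated by mean).
    line_length : float
        Measured line length in cm.
    line_offset : float
        Acceleration offset at each line end in cm (discarded samples; enters
        timing accounting only).
    noise_sd : float
        Relative intensity noise per raw sample (multiplicative Gaussian).
    slide_reflectance : float
        Effective reflectance of the bare slide, in (0, 1].
    """

    lasers: tuple[LaserChannel, ...] = DEFAULT_LASERS
    mirror_velocity: float = 5.3
    spatial_resolution: float = 20.0
    oversampling: int = 10
    line_length: float = 1.0
    line_offset: float = 0.5
    field_mm: tuple[float, float] | None = None
    noise_sd: float = 0.0
    slide_reflectance: float = 1.0

    def __post_init__(self) -> None:
        if self.spatial_resolution <= 0:
            raise ConfigurationError("spatial_resolution must be > 0")
        if self.oversampling < 1:
            raise ConfigurationError("oversampling must be >= 1")
        if self.line_offset < 0:
            raise ConfigurationError("line_offset must be >= 0")

    def wavenumbers(self) -> np.ndarray:
        return np.array([l.wavenumber for l in self.lasers], dtype=float)


@dataclass
class FtirConfig:
    """Settings of the simulated FT-IR hyperspectral imager."""

    wavenumber_max: float = 4000.0
    wavenumber_min: float = 750.0
    spectral_spacing: float = 8.0
    pixel_pitch: float = 25.0
    accumulations: int = 2
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.wavenumber_max <= self.wavenumber_min:
            raise ConfigurationError("wavenumber_max must exceed wavenumber_min")
        if self.spectral_spacing <= 0:
            raise ConfigurationError("spectral_spacing must be > 0")
        if self.accumulations < 1:
            raise ConfigurationError("accumulations must be >= 1")

    def axis(self) -> np.ndarray:
        """Descending wavenumber axis: ν_max, ν_max − Δ, … down to ≥ ν_min."""
        n = int(np.floor((self.wavenumber_max - self.wavenumber_min) / self.spectral_spacing)) + 1
        return self.wavenumber_max - self.spectral_spacing * np.arange(n)


@dataclass
class MirScanSet:
    """Per-laser intensity rasters plus bare-slide background rasters."""

    images: Mapping[int, np.ndarray]
    background: Mapping[int, np.ndarray]
    config: ScannerConfig
    seed: int | None = None

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images.values()}
        shapes |= {im.shape for im in self.background.values()}
        if len(shapes) != 1:
            raise ConfigurationError("all rasters of a scan set must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape  # type: ignore[return-value]


@dataclass
class HyperCube:
    """Band-sequential cube with an explicit descending wavenumber axis."""

    data: np.ndarray  # (rows, cols, bands)
    wavenumbers: np.ndarray  # cm⁻¹, strictly monotone (descending by convention)
    pixel_pitch: float  # µm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavenumbers.size:
            raise ConfigurationError("band count must match wavenumber axis length")
        d = np.diff(self.wavenumbers)
        if self.wavenumbers.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ConfigurationError("wavenumber axis must be strictly monotone")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def channel_index(self, wavenumber: float) -> int:
        """Index of the channel nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def channel(self, wavenumber: float) -> np.ndarray:
        return self.data[:, :, self.channel_index(wavenumber)]


# ---------------------------------------------------------------------------
# Sampling arithmetic
# ---------------------------------------------------------------------------


def _exact_ratio(num: float, den: float, what: str) -> int:
    n = num / den
    if abs(n - round(n)) > 1e-9 or round(n) < 1:
        raise ConfigurationError(f"{what}: {num} is not an integer multiple of {den}")
    return int(round(n))


def samples_per_line(line_length: float, spatial_resolution: float, oversampling: int) -> int:
    """Raw samples per measured line.

    Parameters: line length in cm, resolution in µm, integer oversampling.
    The geometry must divide exactly; no silent rounding.
    """
    if line_length <= 0 or spatial_resolution <= 0 or oversampling < 1:
        raise ConfigurationError("all sampling parameters must be positive")
    pixels = _exact_ratio(line_length * 1e4, spatial_resolution, "line length (um)")
    return pixels * int(oversampling)


def implied_sample_rate(
    mirror_velocity: float, spatial_resolution: float, oversampling: int
) -> float:
    """Raw detector sample rate in MS/s implied by mirror velocity and pitch.

    rate = v_mirror / Δx × f; e.g. 5.3 m/s at 20 µm with 10× oversampling
    gives 2.65 MS/s.
    """
    if mirror_velocity <= 0 or spatial_resolution <= 0 or oversampling < 1:
        raise ConfigurationError("all sampling parameters must be positive")
    return mirror_velocity / (spatial_resolution * 1e-6) * oversampling / 1e6


def pixel_grid(
    field_mm: tuple[float, float], spatial_resolution: float
) -> tuple[int, int, int]:
    """(rows, cols, total pixels) for a physical field at a given pitch.

    ``field_mm`` is (rows extent, cols extent) in mm, resolution in µm; the
    field must be an exact integer multiple of the resolution per axis.
    """
    rows = _exact_ratio(field_mm[0] * 1e3, spatial_resolution, "field rows (um)")
    cols = _exact_ratio(field_mm[1] * 1e3, spatial_resolution, "field cols (um)")
    return rows, cols, rows * cols


def wavenumber_to_wavelength(wavenumber: float) -> float:
    """Vacuum wavelength in µm for a wavenumber in cm⁻¹ (λ = 10⁴ / ν̃)."""
    if np.any(np.asarray(wavenumber) <= 0):
        raise ConfigurationError("wavenumber must be > 0")
    return 1e4 / wavenumber


def line_traversal_time(line_length: float, mirror_velocity: float) -> float:
    """Seconds to traverse one measured line (offsets excluded)."""
    return line_length * 1e-2 / mirror_velocity


def stage_speed(config: ScannerConfig) -> float:
    """Translation-stage speed (mm/s) implied by the configured line geometry.

    One line advance (= one pixel pitch) happens per traversal of the measured
    line plus both acceleration offsets.  This is derived from config; the
    line duty cycle of the physical instrument is not otherwise modelled.
    """
    swept = (config.line_length + 2 * config.line_offset) * 1e-2  # m
    t_line = swept / config.mirror_velocity
    return config.spatial_resolution * 1e-3 / t_line  # mm per line / s


def scan_time(config: ScannerConfig, field_mm: tuple[float, float]) -> float:
    """Nominal single-laser scan time (s) for a field, from the line timing."""
    rows, _, _ = pixel_grid(field_mm, config.spatial_resolution)
    swept = (config.line_length + 2 * config.line_offset) * 1e-2
    return rows * swept / config.mirror_velocity


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

#: Nominal incident intensity at the detector for a perfectly reflective slide.
I0 = 1.0


def _scan_geometry(
    phantom: TissuePhantom, resolution_um: float, field_mm: tuple[float, float] | None
) -> tuple[int, int, int]:
    """Validate phantom/scan geometry; return (rows, cols, block ratio)."""
    ratio = resolution_um / phantom.pixel_pitch
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise GeometryError(
            f"scan resolution {resolution_um} um must be an integer multiple of "
            f"the phantom pitch {phantom.pixel_pitch} um"
        )
    ratio = int(round(ratio))
    if field_mm is not None:
        pr, pc = phantom.field_mm
        if field_mm[0] > pr + 1e-9 or field_mm[1] > pc + 1e-9:
            raise GeometryError("scan field exceeds the phantom extent")
        rows, cols, _ = pixel_grid(field_mm, resolution_um)
    else:
        rows = phantom.shape[0] // ratio
        cols = phantom.shape[1] // ratio
        if rows * ratio != phantom.shape[0] or cols * ratio != phantom.shape[1]:
            raise GeometryError("phantom raster does not tile the scan grid")
    return rows, cols, ratio


def _block_mean(arr: np.ndarray, ratio: int, rows: int, cols: int) -> np.ndarray:
    sub = arr[: rows * ratio, : cols * ratio]
    return sub.reshape(rows, ratio, cols, ratio).mean(axis=(1, 3))


def simulate_mir_scan(
    phantom: TissuePhantom, config: ScannerConfig, seed: int = 0
) -> MirScanSet:
    """Simulate a sequential 4-laser scan plus bare-slide background rasters.

    Per laser, each raw sample is I₀ · R_slide · 10^(−A(ν̃)) · (1 + ε) with
    ε ~ N(0, noise_sd); the pixel value is the mean of its ``oversampling``
    samples.  The background raster is generated identically with A ≡ 0.
    Lasers are simulated sequentially with independent noise streams;
    everything is deterministic for a fixed seed.
    """
    rows, cols, ratio = _scan_geometry(phantom, config.spatial_resolution, config.field_mm)
    f = int(config.oversampling)
    streams = np.random.SeedSequence(seed).spawn(len(config.lasers))

    images: dict[int, np.ndarray] = {}
    background: dict[int, np.ndarray] = {}
    for laser, ss in zip(config.lasers, streams):
        rng = np.random.default_rng(ss)
        a_map = phantom.absorbance_map(laser.wavenumber)
        clean = I0 * config.slide_reflectance * 10.0 ** (-_block_mean(a_map, ratio, rows, cols))
        bg_clean = I0 * config.slide_reflectance
        if config.noise_sd > 0:
            eps = rng.standard_normal((rows, cols, f)).mean(axis=2)
            eps_bg = rng.standard_normal((rows, cols, f)).mean(axis=2)
            images[laser.id] = clean * (1.0 + config.noise_sd * eps)
            background[laser.id] = bg_clean * (1.0 + config.noise_sd * eps_bg)
        else:
            images[laser.id] = clean.copy()
            background[laser.id] = np.full((rows, cols), bg_clean)
    return MirScanSet(images=images, background=background, config=config, seed=seed)


def simulate_ftir(phantom: TissuePhantom, config: FtirConfig, seed: int = 0) -> HyperCube:
    """Simulate an FT-IR hyperspectral acquisition of a phantom.

    Per pixel, the class absorbance spectrum plus additive Gaussian noise of
    sd ``noise_sd`` is averaged over ``accumulations`` independent draws.
    Scan pixels coarser than the phantom raster average the underlying class
    spectra (partial-volume mixing at class boundaries).
    """
    rows, cols, ratio = _scan_geometry(phantom, config.pixel_pitch, None)
    axis = config.axis()
    table = phantom.class_absorbance(axis)  # (n_classes, n_bands)

    # Per-scan-pixel class fractions -> mixed clean spectra.
    n_classes = table.shape[0]
    fractions = np.empty((rows, cols, n_classes))
    for cid in range(n_classes):
        fractions[:, :, cid] = _block_mean(
            (phantom.labels == cid).astype(float), ratio, rows, cols
        )
    cube = fractions @ table  # (rows, cols, n_bands)

    if config.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        acc = np.zeros_like(cube)
        for _ in range(config.accumulations):
            acc += cube + config.noise_sd * rng.standard_normal(cube.shape)
        cube = acc / config.accumulations
    return HyperCube(data=cube, wavenumbers=axis, pixel_pitch=config.pixel_pitch)
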