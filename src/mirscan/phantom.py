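"""Synthetic tissue phantoms: class-label maps plus per-class absorbance models.

A phantom stands in for a dried cryosection on a reflective slide.  Each tissue
class carries a :class:`SpectralProfile` — a sum of Gaussian absorbance bands on
a constant scattering baseline — chosen so that the functional-group region
(~2500–4000 cm⁻¹) shows the canonical bands: the lipid C–H stretch near
2926 cm⁻¹, the amide-A N–H stretch near 3350 cm⁻¹, and low-absorbance wings
near 2790 and 3700 cm⁻¹ where reference lasers sit.  Residual water is modelled
as a broad O–H band added to every class and scaled by ``water_fraction``;
``water_fraction = 0`` is the fully dried condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from mirscan.errors import ConfigurationError, RangeError

#: Valid wavenumber range for absorbance evaluation (cm⁻¹).
WAVENUMBER_MIN = 700.0
WAVENUMBER_MAX = 4100.0

#: Broad O–H stretch of residual water; amplitude is the value at
#: ``water_fraction = 1``.
WATER_BAND_CENTER = 3400.0
WATER_BAND_SIGMA = 180.0
WATER_BAND_AMPLITUDE = 0.50


@dataclass(frozen=True)
class SpectralBand:
    """One Gaussian absorbance band.

    Parameters
    ----------
    center : float
        Band centre in cm⁻¹.
    width : float
        Gaussian sigma in cm⁻¹.
    amplitude : float
        Peak absorbance (dimensionless absorbance units).
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.center > 0:
            raise ConfigurationError(f"band center must be > 0, got {self.center}")
        if not self.width > 0:
            raise ConfigurationError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ConfigurationError(f"band amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class SpectralProfile:
    """Absorbance-versus-wavenumber model of one tissue class.

    The absorbance is a constant scattering ``baseline`` plus a sum of Gaussian
    bands; evaluation is deterministic and linear in the band amplitudes.
    """

    bands: tuple[SpectralBand, ...]
    baseline: float
    label: str

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ConfigurationError(f"baseline must be >= 0, got {self.baseline}")
        object.__setattr__(self, "bands", tuple(self.bands))


def evaluate_absorbance(
    profile: SpectralProfile, wavenumbers: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Evaluate a profile's absorbance A(ν̃) at the given wavenumbers.

    A(ν̃) = baseline + Σ_b amplitude_b · exp(−(ν̃ − center_b)² / (2 width_b²)).

    Parameters
    ----------
    profile : SpectralProfile
    wavenumbers : array-like of float
        Wavenumbers in cm⁻¹, each within [700, 4100].

    Returns
    -------
    ndarray of float, same length as ``wavenumbers``.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    if np.any(nu < WAVENUMBER_MIN) or np.any(nu > WAVENUMBER_MAX):
        raise RangeError(
            f"wavenumbers must lie in [{WAVENUMBER_MIN}, {WAVENUMBER_MAX}] cm^-1"
        )
    out = np.full(nu.shape, profile.baseline, dtype=float)
    for band in profile.bands:
        out += band.amplitude * np.exp(-((nu - band.center) ** 2) / (2.0 * band.width**2))
    return out


def _water_absorbance(wavenumbers: np.ndarray, water_fraction: float) -> np.ndarray:
    nu = np.asarray(wavenumbers, dtype=float)
    return (
        water_fraction
        * WATER_BAND_AMPLITUDE
        * np.exp(-((nu - WATER_BAND_CENTER) ** 2) / (2.0 * WATER_BAND_SIGMA**2))
    )


@dataclass
class TissuePhantom:
    """A 2D tissue phantom: label raster on a physical grid plus class spectra.

    Attributes
    ----------
    labels : ndarray of int, shape (rows, cols)
        0 = bare slide / background, 1..C = tissue classes.
    pixel_pitch : float
        Pixel pitch in µm.
    profiles : mapping int -> SpectralProfile
        One profile per nonzero label.
    water_fraction : float
        In [0, 1]; scales the shared O–H water band added to every tissue class.
    """

    labels: np.ndarray
    pixel_pitch: float
    profiles: Mapping[int, SpectralProfile]
    water_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ConfigurationError("labels must be a 2D raster")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ConfigurationError("water_fraction must be in [0, 1]")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.profiles)
        if missing:
            raise ConfigurationError(f"labels without a profile: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def field_mm(self) -> tuple[float, float]:
        """Physical field size (rows, cols) in mm."""
        r, c = self.labels.shape
        return (r * self.pixel_pitch / 1000.0, c * self.pixel_pitch / 1000.0)

    def tissue_mask(self) -> np.ndarray:
        """Boolean raster: True on tissue, False on bare slide."""
        return self.labels > 0

    def class_absorbance(self, wavenumbers: Sequence[float] | np.ndarray) -> np.ndarray:
        """Absorbance table, shape (max_label + 1, n_wavenumbers); row 0 is zero."""
        nu = np.asarray(wavenumbers, dtype=float)
        n_classes = int(self.labels.max()) + 1
        table = np.zeros((n_classes, nu.size), dtype=float)
        water = _water_absorbance(nu, self.water_fraction)
        for cid, prof in self.profiles.items():
            table[cid] = evaluate_absorbance(prof, nu) + water
        return table

    def absorbance_map(self, wavenumber: float) -> np.ndarray:
        """Per-pixel absorbance raster at one wavenumber (0 on background)."""
        table = self.class_absorbance([wavenumber])[:, 0]
        return table[self.labels]


# ---------------------------------------------------------------------------
# Default class profiles.
#
# Absolute per-class absorbances are free parameters (the instrument papers
# report only band positions and orderings); the defaults fix the orderings the
# measurements rely on: at 2926 cm⁻¹ white matter > hippocampal band > grey
# matter, and the tumour differs from healthy liver mainly in the C–H band.
# ---------------------------------------------------------------------------

LIPID_CH = (2926.0, 60.0)
AMIDE_A = (3350.0, 90.0)


def _profile(label: str, lipid_amp: float, amide_amp: float, baseline: float) -> SpectralProfile:
    return SpectralProfile(
        bands=(
            SpectralBand(*LIPID_CH, lipid_amp),
            SpectralBand(*AMIDE_A, amide_amp),
        ),
        baseline=baseline,
        label=label,
    )


def default_brain_profiles() -> dict[int, SpectralProfile]:
    """Grey matter (1), white matter (2), hippocampal band (3)."""
    return {
        1: _profile("grey_matter", lipid_amp=0.35, amide_amp=0.55, baseline=0.05),
        2: _profile("white_matter", lipid_amp=0.80, amide_amp=0.45, baseline=0.06),
        3: _profile("hippocampus", lipid_amp=0.50, amide_amp=0.70, baseline=0.04),
    }


def default_liver_profiles() -> dict[int, SpectralProfile]:
    """Healthy liver (1) and tumour (2); contrast mainly in the C–H band."""
    return {
        1: _profile("healthy_liver", lipid_amp=0.45, amide_amp=0.60, baseline=0.05),
        2: _profile("tumour", lipid_amp=0.75, amide_amp=0.62, baseline=0.05),
    }


def _grid_shape(field_mm: tuple[float, float], pixel_pitch_um: float) -> tuple[int, int]:
    shape = []
    for f in field_mm:
        n = f * 1000.0 / pixel_pitch_um
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"field {f} mm is not an integer multiple of pitch {pixel_pitch_um} um"
            )
        shape.append(int(round(n)))
    return tuple(shape)  # type: ignore[return-value]


def _check_pitch(pixel_pitch_um: float) -> None:
    if not 5.0 <= pixel_pitch_um <= 100.0:
        raise ConfigurationError(f"pixel pitch must be in [5, 100] um, got {pixel_pitch_um}")


def make_brain_phantom(
    field_mm: tuple[float, float] = (10.0, 10.0),
    pixel_pitch_um: float = 20.0,
    seed: int = 0,
    water_fraction: float = 0.0,
    profiles: Mapping[int, SpectralProfile] | None = None,
) -> TissuePhantom:
    """Coronal-brain-like phantom: grey matter, white-matter arc, hippocampal band.

    The geometry is schematic, not atlas-derived: an elliptical grey-matter
    section inside a bare-slide margin, a thick white-matter arc (corpus
    callosum analogue) in the dorsal half, and a thinner curved hippocampal
    band nested beneath it.  A fixed seed gives a deterministic raster; the
    seed jitters centre, orientation and band radii slightly so distinct seeds
    give distinct but statistically equivalent sections.
    """
    _check_pitch(pixel_pitch_um)
    if field_mm[0] < 2.0 or field_mm[1] < 2.0:
        raise ConfigurationError("brain phantom needs a field of at least 2 x 2 mm")
    rows, cols = _grid_shape(field_mm, pixel_pitch_um)
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy = rows / 2.0 + rng.uniform(-0.01, 0.01) * rows
    cx = cols / 2.0 + rng.uniform(-0.01, 0.01) * cols
    # Section semi-axes leave a bare-slide margin on all sides.
    a_r = 0.40 * rows * (1 + rng.uniform(-0.02, 0.02))
    a_c = 0.44 * cols * (1 + rng.uniform(-0.02, 0.02))

    u = (yy - cy) / a_r
    v = (xx - cx) / a_c
    section = u * u + v * v <= 1.0

    labels = np.zeros((rows, cols), dtype=np.int32)
    labels[section] = 1  # grey matter

    # Normalised elliptical radius and angle (0 = dorsal / up, ±pi lateral).
    rad = np.sqrt(u * u + v * v)
    ang = np.arctan2(v, -u)  # -u: angle 0 points toward low row indices

    tilt = rng.uniform(-0.08, 0.08)
    jr = 1 + rng.uniform(-0.02, 0.02)
    # White-matter arc: dorsal annulus sector.
    wm = (
        section
        & (rad >= 0.55 * jr)
        & (rad <= 0.70 * jr)
        & (np.abs(ang - tilt) <= np.deg2rad(60))
    )
    labels[wm] = 2
    # Hippocampal band: thinner curved band nested under the arc.
    hc = (
        section
        & (rad >= 0.38 * jr)
        & (rad <= 0.50 * jr)
        & (np.abs(ang - tilt) <= np.deg2rad(50))
    )
    labels[hc] = 3

    if not (labels == 2).any() or not (labels == 3).any():
        raise ConfigurationError("field too small to carry the internal structures")

    return TissuePhantom(
        labels=labels,
        pixel_pitch=pixel_pitch_um,
        profiles=dict(profiles) if profiles is not None else default_brain_profiles(),
        water_fraction=water_fraction,
    )


def make_liver_phantom(
    field_mm: tuple[float, float] = (8.0, 8.0),
    pixel_pitch_um: float = 20.0,
    nodule_diameter_mm: float = 3.0,
    margin_irregularity: float = 0.3,
    seed: int = 0,
    water_fraction: float = 0.0,
    infiltration_mm: float = 0.0,
    profiles: Mapping[int, SpectralProfile] | None = None,
) -> TissuePhantom:
    """Liver-like phantom: homogeneous healthy tissue with an infiltrating nodule.

    The tumour is a disc of the requested diameter whose boundary radius is
    perturbed by seeded low-frequency harmonics with relative amplitude
    proportional to ``margin_irregularity`` (0 → exact disc), emulating the
    heterogeneous margin of a naturally grown nodule.

    ``infiltration_mm`` > 0 additionally interdigitates tumour and healthy
    pixels at the raster scale within a band of that width around the
    boundary, with tumour density graded from 1 (inside) to 0 (outside) —
    microscopic infiltration that block-averages into a graded margin when
    scanned at coarser pitch.  0 (default) keeps the boundary sharp.
    """
    _check_pitch(pixel_pitch_um)
    if not 0.0 <= margin_irregularity <= 1.0:
        raise ConfigurationError("margin_irregularity must be in [0, 1]")
    rows, cols = _grid_shape(field_mm, pixel_pitch_um)
    rng = np.random.default_rng(seed)

    r_nod = nodule_diameter_mm * 1000.0 / pixel_pitch_um / 2.0
    if 2 * r_nod >= min(rows, cols) * 0.8:
        raise ConfigurationError(
            f"nodule of {nodule_diameter_mm} mm does not fit inside the "
            f"{field_mm[0]} x {field_mm[1]} mm field"
        )

    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = rows / 2.0, cols / 2.0
    a_r, a_c = 0.45 * rows, 0.45 * cols
    section = ((yy - cy) / a_r) ** 2 + ((xx - cx) / a_c) ** 2 <= 1.0

    labels = np.zeros((rows, cols), dtype=np.int32)
    labels[section] = 1  # healthy liver

    # Nodule centre offset toward one lobe but kept inside the section.
    ny = cy + 0.05 * rows * rng.uniform(-1, 1)
    nx = cx - 0.18 * cols + 0.03 * cols * rng.uniform(-1, 1)

    dy, dx = yy - ny, xx - nx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # Radial perturbation: low-order harmonics deform the nodule shape, a
    # 1/m-decaying tail of higher orders textures the infiltrating margin.
    pert = np.zeros_like(theta)
    var = 0.0
    for m in range(2, 33):
        w = 1.0 if m <= 6 else 6.0 / m
        amp = w * rng.normal(0.0, 1.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        pert += amp * np.cos(m * theta + phase)
        var += w * w
    pert *= 0.12 / np.sqrt(var)  # unit-irregularity relative amplitude ~12% rms
    boundary = r_nod * (1.0 + margin_irregularity * pert)
    if infiltration_mm > 0:
        g = infiltration_mm * 1000.0 / pixel_pitch_um
        density = np.clip(0.5 - (dist - boundary) / g, 0.0, 1.0)
        nodule = section & (rng.random(density.shape) < density)
    else:
        nodule = section & (dist <= boundary)
    labels[nodule] = 2

    return TissuePhantom(
        labels=labels,
        pixel_pitch=pixel_pitch_um,
        profiles=dict(profiles) if profiles is not None else default_liver_profiles(),
        water_fraction=water_fraction,
    )
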