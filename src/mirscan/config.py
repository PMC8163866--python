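"""Run configuration: one YAML document driving the whole pipeline.

Every stage reads its parameters from a section of :class:`RunConfig`;
unknown keys are rejected by name so a typo never silently falls back to a
default.  All defaults are documented here and mirror the instrument settings
the package simulates (20 µm MIR pitch, 10× oversampling, 5.3 m/s mirror,
4000–750 cm⁻¹ FT-IR axis at 8 cm⁻¹, two accumulations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from mirscan.acquisition import FtirConfig, ScannerConfig
from mirscan.errors import ConfigurationError
from mirscan.phantom import TissuePhantom, make_brain_phantom, make_liver_phantom

_DEFAULTS: dict[str, dict[str, Any]] = {
    "phantom": {
        "type": "brain",  # brain | liver
        "field_mm": [6.0, 6.0],
        "pixel_pitch_um": 20.0,
        "seed": 0,
        "water_fraction": 0.0,
        "nodule_diameter_mm": 3.0,  # liver only
        "margin_irregularity": 0.3,  # liver only
        "infiltration_mm": 0.0,  # liver only
    },
    "scanner": {
        "spatial_resolution_um": 20.0,
        "mirror_velocity_m_s": 5.3,
        "oversampling": 10,
        "line_length_cm": 1.0,
        "line_offset_cm": 0.5,
        "noise_sd": 0.05,
        "slide_reflectance": 1.0,
    },
    "ftir": {
        "enabled": True,
        "wavenumber_max": 4000.0,
        "wavenumber_min": 750.0,
        "spectral_spacing": 8.0,
        "pixel_pitch_um": 20.0,
        "accumulations": 2,
        "noise_sd": 0.05,
    },
    "preprocess": {
        "floor": 0.0,
        "low_percentile": 25.0,
        "gain": 1.0,
        "tv_strength": None,  # None -> noise-adaptive
        "tv_window": 7,
        "tv_iterations": 120,
        "p_low": 1.0,
        "p_high": 99.0,
        "smooth_window": 9,
    },
    "segment": {
        "k": 4,
        "seed": 0,
        "restarts": 10,
        "majority": 0.5,
    },
    "compare": {
        "wavenumbers": [2790.0, 2926.0, 3350.0],
        "roi": None,  # (row0, col0, height, width) or None
        "denoise_strength": 0.3,
        "mir_scan_time_s": 3.0,
        "ftir_scan_time_s": 675.0,
    },
}


def _merge_section(name: str, user: Mapping[str, Any]) -> dict[str, Any]:
    merged = dict(_DEFAULTS[name])
    for key, value in user.items():
        if key not in merged:
            raise ConfigurationError(f"unknown key {name}.{key!r} in run config")
        merged[key] = value
    return merged


@dataclass
class RunConfig:
    phantom: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["phantom"]))
    scanner: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["scanner"]))
    ftir: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["ftir"]))
    preprocess: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["preprocess"]))
    segment: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["segment"]))
    compare: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["compare"]))

    @classmethod
    def from_mapping(cls, doc: Mapping[str, Any]) -> "RunConfig":
        unknown = set(doc) - set(_DEFAULTS)
        if unknown:
            raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
        return cls(
            **{name: _merge_section(name, doc.get(name, {}) or {}) for name in _DEFAULTS}
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, Mapping):
            raise ConfigurationError(f"{path} does not contain a mapping")
        return cls.from_mapping(doc)

    def to_dict(self) -> dict[str, Any]:
        return {
            "phantom": dict(self.phantom),
            "scanner": dict(self.scanner),
            "ftir": dict(self.ftir),
            "preprocess": dict(self.preprocess),
            "segment": dict(self.segment),
            "compare": dict(self.compare),
        }

    # -- constructors for the domain objects ------------------------------

    def make_phantom(self) -> TissuePhantom:
        p = self.phantom
        kind = p["type"]
        common = dict(
            field_mm=tuple(p["field_mm"]),
            pixel_pitch_um=float(p["pixel_pitch_um"]),
            seed=int(p["seed"]),
            water_fraction=float(p["water_fraction"]),
        )
        if kind == "brain":
            return make_brain_phantom(**common)
        if kind == "liver":
            return make_liver_phantom(
                nodule_diameter_mm=float(p["nodule_diameter_mm"]),
                margin_irregularity=float(p["margin_irregularity"]),
                infiltration_mm=float(p["infiltration_mm"]),
                **common,
            )
        raise ConfigurationError(f"unknown phantom.type {kind!r} (use 'brain' or 'liver')")

    def make_scanner_config(self) -> ScannerConfig:
        s = self.scanner
        return ScannerConfig(
            mirror_velocity=float(s["mirror_velocity_m_s"]),
            spatial_resolution=float(s["spatial_resolution_um"]),
            oversampling=int(s["oversampling"]),
            line_length=float(s["line_length_cm"]),
            line_offset=float(s["line_offset_cm"]),
            noise_sd=float(s["noise_sd"]),
            slide_reflectance=float(s["slide_reflectance"]),
        )

    def make_ftir_config(self) -> FtirConfig:
        f = self.ftir
        return FtirConfig(
            wavenumber_max=float(f["wavenumber_max"]),
            wavenumber_min=float(f["wavenumber_min"]),
            spectral_spacing=float(f["spectral_spacing"]),
            pixel_pitch=float(f["pixel_pitch_um"]),
            accumulations=int(f["accumulations"]),
            noise_sd=float(f["noise_sd"]),
        )
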