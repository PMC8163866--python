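"""On-disk formats: ENVI-style cubes, TIFF rasters, CSV tables, YAML sidecars.

2D rasters travel as single-channel TIFF, hyperspectral cubes as band-
sequential raw binary with an ENVI-style text header (bit-exact round trip),
tables as CSV and configuration/sidecar metadata as YAML.  All physical
quantities carry units in headers (µm, cm⁻¹, s).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from mirscan.acquisition import HyperCube, LaserChannel, MirScanSet, ScannerConfig
from mirscan.compare import SimilarityReport, ThroughputRecord
from mirscan.errors import FormatError
from mirscan.phantom import SpectralBand, SpectralProfile, TissuePhantom
from mirscan.segment import LabelMap

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _cube_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in {".hdr", ".raw"}:
        base = base.with_suffix("")
    return base.with_suffix(".hdr"), base.with_suffix(".raw")


def write_cube(cube: HyperCube, path: str | Path) -> None:
    """Write a cube as BSQ raw binary plus an ENVI-style text header."""
    hdr_path, raw_path = _cube_paths(path)
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _ENVI_CODES:
        raise FormatError(f"unsupported cube dtype {dtype}")
    rows, cols, bands = cube.data.shape
    wl = ", ".join(repr(float(w)) for w in cube.wavenumbers)
    header = (
        "ENVI\n"
        "description = {mirscan hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"pixel pitch um = {cube.pixel_pitch!r}\n"
        "wavelength units = cm-1\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr_path.write_text(header)
    bsq = np.ascontiguousarray(np.transpose(cube.data, (2, 0, 1)))
    if np.little_endian is False:  # byte order 0 = little endian on disk
        bsq = bsq.astype(dtype.newbyteorder("<"))
    bsq.tofile(raw_path)


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    for line in text.splitlines():
        if key is not None:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                key, buf = None, []
            continue
        if "=" not in line:
            continue
        k, v = line.split("=", 1)
        k, v = k.strip().lower(), v.strip()
        if v.startswith("{") and "}" not in v:
            key, buf = k, [v]
        else:
            fields[k] = v
    return fields


def read_cube(path: str | Path) -> HyperCube:
    """Read a cube written by :func:`write_cube` (bit-exact)."""
    hdr_path, raw_path = _cube_paths(path)
    if not hdr_path.exists():
        raise FormatError(f"missing header file {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"header {hdr_path} lacks required field {exc}") from exc
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    expected = rows * cols * bands * dtype.itemsize
    actual = os.path.getsize(raw_path)
    if actual != expected:
        raise FormatError(
            f"{raw_path}: expected {expected} bytes "
            f"({rows}x{cols}x{bands} of {dtype}), found {actual}"
        )
    bsq = np.fromfile(raw_path, dtype=dtype).reshape(bands, rows, cols)
    wl_text = fields.get("wavelength", "{}").strip()
    wl = np.array(
        [float(tok) for tok in wl_text.strip("{} ").split(",") if tok.strip()], dtype=float
    )
    pitch = float(fields.get("pixel pitch um", 0.0))
    return HyperCube(
        data=np.ascontiguousarray(np.transpose(bsq, (1, 2, 0))),
        wavenumbers=wl,
        pixel_pitch=pitch,
    )


# ---------------------------------------------------------------------------
# MIR scan sets
# ---------------------------------------------------------------------------


def write_scanset(scanset: MirScanSet, directory: str | Path) -> None:
    """One TIFF per laser + per-laser background TIFFs + a YAML sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for lid, im in scanset.images.items():
        tifffile.imwrite(d / f"laser{lid}.tif", np.asarray(im))
        tifffile.imwrite(d / f"laser{lid}_background.tif", np.asarray(scanset.background[lid]))
    cfg = scanset.config
    sidecar = {
        "lasers": [
            {"id": l.id, "wavenumber_cm-1": l.wavenumber, "role": l.role} for l in cfg.lasers
        ],
        "mirror_velocity_m_s": cfg.mirror_velocity,
        "spatial_resolution_um": cfg.spatial_resolution,
        "oversampling": cfg.oversampling,
        "line_length_cm": cfg.line_length,
        "line_offset_cm": cfg.line_offset,
        "noise_sd": cfg.noise_sd,
        "slide_reflectance": cfg.slide_reflectance,
        "seed": scanset.seed,
    }
    (d / "scan.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_scanset(directory: str | Path) -> MirScanSet:
    d = Path(directory)
    sidecar = yaml.safe_load((d / "scan.yaml").read_text())
    lasers = tuple(
        LaserChannel(int(l["id"]), float(l["wavenumber_cm-1"]), str(l["role"]))
        for l in sidecar["lasers"]
    )
    cfg = ScannerConfig(
        lasers=lasers,
        mirror_velocity=float(sidecar["mirror_velocity_m_s"]),
        spatial_resolution=float(sidecar["spatial_resolution_um"]),
        oversampling=int(sidecar["oversampling"]),
        line_length=float(sidecar["line_length_cm"]),
        line_offset=float(sidecar["line_offset_cm"]),
        noise_sd=float(sidecar["noise_sd"]),
        slide_reflectance=float(sidecar["slide_reflectance"]),
    )
    images = {l.id: tifffile.imread(d / f"laser{l.id}.tif") for l in lasers}
    background = {
        l.id: tifffile.imread(d / f"laser{l.id}_background.tif") for l in lasers
    }
    return MirScanSet(images=images, background=background, config=cfg, seed=sidecar.get("seed"))


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


def save_phantom(phantom: TissuePhantom, directory: str | Path) -> None:
    """Labels as TIFF, profile table as CSV, geometry as YAML."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "labels.tif", phantom.labels.astype(np.int32))
    rows = []
    for cid, prof in sorted(phantom.profiles.items()):
        for band in prof.bands:
            rows.append(
                {
                    "class_id": cid,
                    "class_label": prof.label,
                    "band_center": band.center,
                    "band_sigma": band.width,
                    "band_amplitude": band.amplitude,
                    "baseline": prof.baseline,
                }
            )
    pd.DataFrame(rows).to_csv(d / "profiles.csv", index=False)
    meta = {
        "pixel_pitch_um": phantom.pixel_pitch,
        "water_fraction": phantom.water_fraction,
        "shape": list(phantom.shape),
    }
    (d / "phantom.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_phantom(directory: str | Path) -> TissuePhantom:
    d = Path(directory)
    labels = tifffile.imread(d / "labels.tif")
    meta = yaml.safe_load((d / "phantom.yaml").read_text())
    table = pd.read_csv(d / "profiles.csv")
    profiles: dict[int, SpectralProfile] = {}
    for cid, group in table.groupby("class_id"):
        bands = tuple(
            SpectralBand(r.band_center, r.band_sigma, r.band_amplitude)
            for r in group.itertuples()
        )
        profiles[int(cid)] = SpectralProfile(
            bands=bands,
            baseline=float(group["baseline"].iloc[0]),
            label=str(group["class_label"].iloc[0]),
        )
    return TissuePhantom(
        labels=labels,
        pixel_pitch=float(meta["pixel_pitch_um"]),
        profiles=profiles,
        water_fraction=float(meta["water_fraction"]),
    )


# ---------------------------------------------------------------------------
# Label maps and reports
# ---------------------------------------------------------------------------


def write_labelmap(label_map: LabelMap, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "labels.tif", label_map.labels.astype(np.int32))
    pd.DataFrame(label_map.centroids).to_csv(d / "centroids.csv", index=False)
    meta = {
        "k": label_map.k,
        "seed": label_map.seed,
        "rejected_clusters": sorted(int(i) for i in label_map.rejected),
    }
    (d / "labelmap.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_labelmap(directory: str | Path) -> LabelMap:
    d = Path(directory)
    meta = yaml.safe_load((d / "labelmap.yaml").read_text())
    return LabelMap(
        labels=tifffile.imread(d / "labels.tif"),
        k=int(meta["k"]),
        centroids=pd.read_csv(d / "centroids.csv").to_numpy(),
        seed=int(meta["seed"]),
        rejected=frozenset(meta["rejected_clusters"]),
    )


def write_similarity_report(report: SimilarityReport, path: str | Path) -> None:
    """CSV (one row per channel) plus a short human-readable text block."""
    base = Path(path)
    rows = [
        {
            "wavenumber_cm-1": nu,
            "ssim": report.per_channel_ssim[nu],
            "mse": report.per_channel_mse[nu],
        }
        for nu in report.per_channel_ssim
    ]
    pd.DataFrame(rows).to_csv(base.with_suffix(".csv"), index=False)
    lines = ["Cross-modality channel similarity (MIR vs FT-IR)"]
    if report.roi is not None:
        lines.append(f"ROI (row0, col0, h, w): {report.roi}")
    for r in rows:
        lines.append(
            f"  {r['wavenumber_cm-1']:7.1f} cm-1   SSIM {r['ssim']:+.4f}   MSE {r['mse']:.6f}"
        )
    lines.append(f"  mean SSIM {report.mean_ssim:+.4f}")
    base.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def write_throughput_report(
    mir: ThroughputRecord,
    ftir: ThroughputRecord,
    time_ratio: float,
    data_ratio: float,
    path: str | Path,
) -> None:
    base = Path(path)
    df = pd.DataFrame(
        [
            {
                "modality": rec.name,
                "pixels": rec.pixels,
                "channels": rec.channels,
                "values_total": rec.values_total,
                "scan_time_s": rec.scan_time,
            }
            for rec in (mir, ftir)
        ]
    )
    df.to_csv(base.with_suffix(".csv"), index=False)
    text = (
        "Scan-time and data-load comparison\n"
        f"  {mir.name}: {mir.pixels} px x {mir.channels} channels = "
        f"{mir.values_total} values in {mir.scan_time} s\n"
        f"  {ftir.name}: {ftir.pixels} px x {ftir.channels} channels = "
        f"{ftir.values_total} values in {ftir.scan_time} s\n"
        f"  time ratio (FT-IR / MIR): {time_ratio:.1f}\n"
        f"  data ratio (FT-IR / MIR): {data_ratio:.1f}\n"
    )
    base.with_suffix(".txt").write_text(text)
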