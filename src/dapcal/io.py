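"""File I/O for the formats the CLI exchanges.

Dose maps and film scans travel as TIFF with a JSON sidecar carrying
the grid metadata (pitch, beam centre, dpi, fiducial marks); profiles
as CSV with columns ``r_cm,value`` (one file per half-profile, or a
``label`` column); chamber readings and budgets as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import PV_FULL_SCALE, CalibrationCurve, ChamberReading, DoseMap2D, FilmScan, RadialProfile, VoxelVolume

__all__ = [
    "save_dose_map", "load_dose_map",
    "save_film_scan", "load_film_scan",
    "save_profiles", "load_profiles",
    "save_readings", "load_readings",
    "save_curve", "load_curve",
    "save_volume", "load_volume",
]


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def save_dose_map(path, dose: DoseMap2D) -> None:
    tifffile.imwrite(path, dose.values.astype(np.float32))
    _sidecar(path).write_text(json.dumps(
        {"pitch_mm": dose.pitch, "origin": list(dose.origin)}, indent=2))


def load_dose_map(path) -> DoseMap2D:
    values = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return DoseMap2D(values, meta["pitch_mm"], tuple(meta["origin"]))


def save_film_scan(path, scan: FilmScan) -> None:
    # 16-bit container: full-scale 2**16 clips to the uint16 maximum
    pv = np.clip(np.round(scan.pv), 1, PV_FULL_SCALE - 1).astype(np.uint16)
    tifffile.imwrite(path, pv)
    _sidecar(path).write_text(json.dumps(
        {"dpi": scan.dpi, "marks": scan.marks.tolist()}, indent=2))


def load_film_scan(path) -> FilmScan:
    pv = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return FilmScan(pv, meta["dpi"], np.asarray(meta["marks"]))


def save_profiles(path, profiles) -> None:
    frames = [
        pd.DataFrame({"r_cm": p.r, "value": p.value, "label": p.label})
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_profiles(path) -> list[RadialProfile]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        df["label"] = ""
    return [
        RadialProfile(g["r_cm"].to_numpy(), g["value"].to_numpy(), label=str(lab))
        for lab, g in df.groupby("label", sort=False)
    ]


def save_readings(path, readings) -> None:
    payload = [
        {
            "charge_nc": r.charge, "mu": r.mu, "bias_v": r.bias,
            "polarity": r.polarity, "temperature_c": r.temperature,
            "pressure_kpa": r.pressure,
        }
        for r in readings
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_readings(path) -> list[ChamberReading]:
    payload = json.loads(Path(path).read_text())
    return [
        ChamberReading(
            charge=r["charge_nc"], mu=r["mu"], bias=r.get("bias_v", 400.0),
            polarity=r.get("polarity", "pos"),
            temperature=r.get("temperature_c", 20.0),
            pressure=r.get("pressure_kpa", 101.325),
        )
        for r in payload
    ]


def save_curve(path, curve: CalibrationCurve) -> None:
    Path(path).write_text(json.dumps({
        "coefficients": curve.coefficients.tolist(),
        "valid_dose_range_gy": list(curve.valid_dose_range),
    }, indent=2))


def load_curve(path) -> CalibrationCurve:
    meta = json.loads(Path(path).read_text())
    return CalibrationCurve(meta["coefficients"],
                            tuple(meta["valid_dose_range_gy"]))


def save_volume(path, vol: VoxelVolume) -> None:
    tifffile.imwrite(path, vol.values.astype(np.float32))
    _sidecar(path).write_text(json.dumps({"voxel_size_mm": vol.voxel_size}))


def load_volume(path, voxel_size: float | None = None) -> VoxelVolume:
    values = tifffile.imread(path).astype(float)
    if voxel_size is None:
        voxel_size = json.loads(_sidecar(path).read_text())["voxel_size_mm"]
    return VoxelVolume(values, voxel_size)
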