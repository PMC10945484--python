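"""Readers and writers for the on-disk formats.

* Trajectory CSV: columns ``time_s, R1_um, R2_um, rc_um`` (header mandatory).
* Thermogram CSV: ``temp_C, heatflow_mW`` with a JSON sidecar holding
  ``scan_rate_C_per_min`` and ``sample_moles``.
* Spectrum CSV: ``wavenumber_cm1, intensity``.
* Image stacks: multi-page TIFF (or a directory of numbered PNGs) with a
  JSON sidecar carrying pixel size, timestamps, and generator ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .droplet_geometry import ImageFrame, Trajectory
from .dsc import Thermogram
from .raman import RamanSpectrum

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_thermogram_csv",
    "write_thermogram_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_image_stack",
    "write_image_stack",
]

TRAJECTORY_COLUMNS = ["time_s", "R1_um", "R2_um", "rc_um"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": traj.time_s,
            "R1_um": traj.R1_um,
            "R2_um": traj.R2_um,
            "rc_um": traj.rc_um,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV {path} missing columns {missing}")
    return Trajectory(
        df["time_s"].to_numpy(),
        df["R1_um"].to_numpy(),
        df["R2_um"].to_numpy(),
        df["rc_um"].to_numpy(),
    )


def write_thermogram_csv(tg: Thermogram, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"temp_C": tg.temperature_C, "heatflow_mW": tg.heatflow_mW}
    ).to_csv(path, index=False)
    sidecar = {
        "scan_rate_C_per_min": tg.scan_rate,
        "sample_moles": tg.sample_moles,
    }
    for k, v in tg.meta.items():
        if isinstance(v, (int, float, str, bool)) or v is None:
            sidecar[k] = v
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_thermogram_csv(path: str | Path, sidecar: str | Path | None = None) -> Thermogram:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("temp_C", "heatflow_mW"):
        if col not in df.columns:
            raise ValueError(f"thermogram CSV {path} missing column {col!r}")
    side_path = Path(sidecar) if sidecar else _sidecar_path(path)
    meta = json.loads(side_path.read_text())
    return Thermogram(
        df["temp_C"].to_numpy(),
        df["heatflow_mW"].to_numpy(),
        scan_rate=float(meta["scan_rate_C_per_min"]),
        sample_moles=float(meta["sample_moles"]),
        meta=meta,
    )


def write_spectrum_csv(spec: RamanSpectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavenumber_cm1": spec.wavenumber, "intensity": spec.intensity}
    ).to_csv(path, index=False)
    return path


def read_spectrum_csv(path: str | Path) -> RamanSpectrum:
    df = pd.read_csv(path)
    for col in ("wavenumber_cm1", "intensity"):
        if col not in df.columns:
            raise ValueError(f"spectrum CSV {path} missing column {col!r}")
    return RamanSpectrum(df["wavenumber_cm1"].to_numpy(), df["intensity"].to_numpy())


def write_image_stack(frames: Sequence[ImageFrame], path: str | Path) -> Path:
    """Write frames to a multi-page TIFF plus a JSON sidecar with pixel size,
    timestamps and any generator ground truth."""
    import tifffile

    path = Path(path)
    stack = np.stack([f.intensity.astype(np.float32) for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "pixel_size_um": frames[0].pixel_size,
        "timestamps_s": [f.timestamp for f in frames],
        "truth": [f.truth for f in frames],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image_stack(path: str | Path) -> list[ImageFrame]:
    """Read a multi-page TIFF, or a directory of numbered PNGs, with its
    JSON sidecar."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        pngs = sorted(path.glob("*.png"))
        if not pngs:
            raise FileNotFoundError(f"no PNG frames in {path}")
        images = [np.asarray(iio.imread(p), dtype=float) for p in pngs]
        side_path = path / "stack.json"
    else:
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        images = [np.asarray(a, dtype=float) for a in arr]
        side_path = _sidecar_path(path)
    meta = json.loads(side_path.read_text())
    px = float(meta["pixel_size_um"])
    times = meta.get("timestamps_s") or list(range(len(images)))
    truths = meta.get("truth") or [None] * len(images)
    return [
        ImageFrame(img, px, timestamp=float(t), truth=tr)
        for img, t, tr in zip(images, times, truths)
    ]
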