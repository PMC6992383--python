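"""File I/O for the standard interchange formats.

Kymographs travel as single-channel 32-bit float TIFF (or a CSV grid with a
JSON calibration sidecar); traces and profiles as CSV with header row and
"." decimal; fit results and parameters as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import FrapTrace, IntensityProfile, Kymograph
from .results import FitResult

__all__ = [
    "save_kymograph",
    "load_kymograph",
    "save_trace",
    "load_trace",
    "save_profile",
    "load_profile",
    "save_fit_result",
]


def save_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Write a kymograph as float32 TIFF or CSV grid (by extension).

    Calibration goes into the TIFF description tag, or a ``.json`` sidecar
    next to a CSV grid.
    """
    path = Path(path)
    meta = {"pixel_size_um": kymo.pixel_size,
            "frame_interval_s": kymo.frame_interval}
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, kymo.grid.astype(np.float32),
                         description=json.dumps(meta))
    else:
        np.savetxt(path, kymo.grid, delimiter=",")
        path.with_suffix(".json").write_text(json.dumps(meta))


def load_kymograph(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> Kymograph:
    """Read a TIFF or CSV kymograph; explicit calibration overrides stored."""
    path = Path(path)
    meta: dict = {}
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            grid = tif.asarray().astype(float)
            desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    else:
        grid = np.loadtxt(path, delimiter=",")
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
    return Kymograph(
        grid=grid,
        pixel_size=pixel_size or meta.get("pixel_size_um", 0.1),
        frame_interval=frame_interval or meta.get("frame_interval_s", 1 / 13),
    )


def save_trace(trace: FrapTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity}).to_csv(
        path, index=False)
    Path(path).with_suffix(".meta.json").write_text(json.dumps({
        "region_label": trace.region_label,
        "strip_width_um": trace.strip_width,
        "prebleach_intensity": trace.prebleach_intensity,
    }))


def load_trace(path: str | Path, strip_width: float | None = None,
               region_label: str = "") -> FrapTrace:
    """Read a trace CSV (columns time_s, intensity[, background, reference]).

    If background/reference columns are present they are returned untouched
    in the trace's raw form — apply :func:`flaglen.frap.correct_trace` to
    use them.
    """
    df = pd.read_csv(path)
    meta_path = Path(path).with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FrapTrace(
        time=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        region_label=region_label or meta.get("region_label", ""),
        strip_width=strip_width or meta.get("strip_width_um", 2.0),
        prebleach_intensity=meta.get("prebleach_intensity", 1.0),
    )


def save_profile(profile: IntensityProfile, path: str | Path) -> None:
    pd.DataFrame({"x_um": profile.x, "intensity": profile.intensity,
                  "origin": profile.origin}).to_csv(path, index=False)


def load_profile(path: str | Path) -> IntensityProfile:
    df = pd.read_csv(path)
    origin = str(df["origin"].iloc[0]) if "origin" in df else "tip"
    return IntensityProfile(x=df["x_um"].to_numpy(),
                            intensity=df["intensity"].to_numpy(),
                            origin=origin)


def save_fit_result(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2, default=float))
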