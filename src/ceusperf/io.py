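"""Readers and writers: TIC CSV, cohort panel CSV, TIFF/DICOM cines,
JSON reports and YAML configs.

All text formats are UTF-8 with '.' decimals; floats are written at 15
significant digits so CSV/JSON round trips are lossless for practical
purposes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .models import CineLoop, TimeIntensityCurve, UnitsFlag

__all__ = [
    "read_tic_csv",
    "write_tic_csv",
    "read_panel_csv",
    "write_panel_csv",
    "read_cine_tiff",
    "write_cine_tiff",
    "read_cine_dicom",
    "write_json_report",
    "load_config",
]

TIC_HEADER = "time_s,intensity"


class TICParseError(ValueError):
    """Malformed TIC CSV; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_tic_csv(path: Union[str, Path], units_flag: UnitsFlag = "dB") -> TimeIntensityCurve:
    """Parse a two-column TIC CSV with header ``time_s,intensity``.

    Raises TICParseError with the line number on a malformed header or
    row, and ValueError if times are not strictly increasing.
    """
    path = Path(path)
    times, vals = [], []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != TIC_HEADER:
            raise TICParseError(f"expected header {TIC_HEADER!r}, got {header!r}", 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise TICParseError(f"expected 2 fields, got {len(parts)}", lineno)
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise TICParseError(str(exc), lineno) from exc
            times.append(t)
            vals.append(v)
    t_arr = np.asarray(times)
    if t_arr.size > 1 and not np.all(np.diff(t_arr) > 0):
        raise ValueError(f"{path}: times are not strictly increasing")
    return TimeIntensityCurve(times=t_arr, intensities=np.asarray(vals), units_flag=units_flag)


def write_tic_csv(tic: TimeIntensityCurve, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(TIC_HEADER + "\n")
        for t, v in zip(tic.times, tic.intensities):
            fh.write(f"{t:.15g},{v:.15g}\n")


def read_panel_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort panel CSV (wide: subject,week,A,alpha,AUC,DPI,TTP
    — or long: subject,week,index,value)."""
    df = pd.read_csv(path)
    if not {"subject", "week"} <= set(df.columns):
        raise ValueError(f"{path}: panel needs 'subject' and 'week' columns")
    return df


def write_panel_csv(panel: pd.DataFrame, path: Union[str, Path]) -> None:
    panel.to_csv(path, index=False, float_format="%.15g")


def write_cine_tiff(cine: CineLoop, path: Union[str, Path]) -> None:
    """Write a cine as a multi-page float32 TIFF (page order = time)."""
    import tifffile

    tifffile.imwrite(
        str(path),
        cine.frames.astype(np.float32),
        metadata={
            "axes": "TYX",
            "frame_rate_hz": _frame_rate(cine.frame_times),
            "pixel_spacing_mm": list(cine.pixel_spacing),
            "units_flag": cine.units_flag,
        },
    )


def _frame_rate(times: np.ndarray) -> float:
    if times.size < 2:
        return 1.0
    return 1.0 / float(np.median(np.diff(times)))


def read_cine_tiff(
    path: Union[str, Path],
    frame_rate: Optional[float] = None,
    pixel_spacing: Optional[tuple] = None,
    units_flag: UnitsFlag = "dB",
) -> CineLoop:
    """Read a multi-page TIFF cine; page order is time.

    Frame rate and pixel spacing come from the embedded metadata when
    present, else from the arguments (frame rate defaults to 10 Hz,
    spacing to 0.5 mm/px — typical exported-cine values).
    """
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        frames = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    fr = frame_rate or float(meta.get("frame_rate_hz", 10.0))
    sp = pixel_spacing or tuple(meta.get("pixel_spacing_mm", (0.5, 0.5)))
    uf = meta.get("units_flag", units_flag)
    times = np.arange(frames.shape[0]) / fr
    return CineLoop(frames=frames, frame_times=times, pixel_spacing=tuple(sp), units_flag=uf)


def read_cine_dicom(
    path: Union[str, Path],
    frame_rate: Optional[float] = None,
    pixel_spacing: Optional[tuple] = None,
    units_flag: UnitsFlag = "dB",
) -> CineLoop:
    """Read an uncompressed multi-frame grayscale DICOM cine.

    FrameTime (ms per frame) and PixelSpacing are honoured when present;
    otherwise the arguments (or 10 Hz / 0.5 mm defaults) apply.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    frames = ds.pixel_array.astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    if frame_rate is not None:
        fr = frame_rate
    elif getattr(ds, "FrameTime", None):
        fr = 1000.0 / float(ds.FrameTime)
    else:
        fr = 10.0
    if pixel_spacing is not None:
        sp = tuple(pixel_spacing)
    elif getattr(ds, "PixelSpacing", None):
        sp = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    else:
        sp = (0.5, 0.5)
    times = np.arange(frames.shape[0]) / fr
    return CineLoop(frames=frames, frame_times=times, pixel_spacing=sp, units_flag=units_flag)


def write_json_report(obj: dict, path: Union[str, Path]) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting, no
    timestamps — reruns with the same seed are byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _clean(x):
        if isinstance(x, dict):
            return {k: _clean(v) for k, v in sorted(x.items())}
        if isinstance(x, (list, tuple)):
            return [_clean(v) for v in x]
        if isinstance(x, (np.floating, float)):
            v = float(x)
            return v if np.isfinite(v) else None
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, np.bool_):
            return bool(x)
        return x

    with path.open("w", encoding="utf-8") as fh:
        json.dump(_clean(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path: Union[str, Path]) -> dict:
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
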