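"""Mask I/O and the image-selection (gating) rule.

A frame enters vessel analysis only if the optic-disc center — the center
of the minimum enclosing circle of the OD mask — lies within a circle drawn
at the image center with one-quarter of the image width as its radius.
Frames that fail are recorded with ``passed=False`` rather than dropped, so
the QC table accounts for every input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .roi import mec_of_mask

__all__ = ["FundusFrame", "QcResult", "load_frame", "write_mask", "gate_frame",
           "read_manifest", "qc_table"]


@dataclass
class FundusFrame:
    """One eye's input: vessel mask + OD mask sharing the same raster frame."""

    eye_id: str
    group_label: str
    vessel_mask: np.ndarray
    od_mask: np.ndarray

    @property
    def width(self) -> int:
        return self.vessel_mask.shape[1]

    @property
    def height(self) -> int:
        return self.vessel_mask.shape[0]

    @property
    def analyzable(self) -> bool:
        return bool(self.od_mask.any())


@dataclass(frozen=True)
class QcResult:
    eye_id: str
    od_center: tuple[float, float]   # (nan, nan) when the OD mask is empty
    gating_radius: float
    passed: bool
    reason: str


def _read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any channel axis; nonzero anywhere = foreground
        arr = arr.max(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D raster")
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit single-channel PNG (0/255)."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_frame(vessel_path: str | Path, od_path: str | Path,
               eye_id: str, group_label: str) -> FundusFrame:
    """Load one eye's mask pair; any nonzero pixel is foreground.

    Raises ``FileNotFoundError`` for missing files and ``ValueError`` when
    the two masks disagree in shape.  An empty OD mask is not an error here
    — the frame loads but reports ``analyzable == False`` and is flagged by
    :func:`gate_frame`.
    """
    for p in (vessel_path, od_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    vessel = _read_mask(vessel_path)
    od = _read_mask(od_path)
    if vessel.shape != od.shape:
        raise ValueError(
            f"{eye_id}: vessel mask {vessel.shape[::-1]} and OD mask "
            f"{od.shape[::-1]} have different dimensions")
    return FundusFrame(eye_id, group_label, vessel, od)


def gate_frame(frame: FundusFrame) -> QcResult:
    """Apply the OD-centering selection rule.

    The gate passes when the OD minimum-enclosing-circle center lies within
    (inclusively) one-quarter of the image width of the image center.  The
    image center of a W x H raster is ((W-1)/2, (H-1)/2) in pixel-center
    coordinates.
    """
    radius = frame.width / 4.0
    if not frame.analyzable:
        return QcResult(frame.eye_id, (math.nan, math.nan), radius, False,
                        "empty OD mask")
    center = mec_of_mask(frame.od_mask).center
    icx, icy = (frame.width - 1) / 2.0, (frame.height - 1) / 2.0
    dist = math.hypot(center[0] - icx, center[1] - icy)
    passed = dist <= radius
    reason = "" if passed else (
        f"OD center {dist:.1f} px from image center exceeds gating radius "
        f"{radius:.1f} px")
    return QcResult(frame.eye_id, center, radius, passed, reason)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (eye_id, group, vessel_path, od_path).

    Relative mask paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"eye_id", "group", "vessel_path", "od_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    for col in ("vessel_path", "od_path"):
        df[col] = df[col].map(lambda p: str((path.parent / p)) if not Path(p).is_absolute() else p)
    return df


def qc_table(results: list[QcResult]) -> pd.DataFrame:
    """One QcResult per row, in input order."""
    return pd.DataFrame([
        {"eye_id": r.eye_id, "od_cx": r.od_center[0], "od_cy": r.od_center[1],
         "gating_radius": r.gating_radius, "passed": r.passed, "reason": r.reason}
        for r in results])
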