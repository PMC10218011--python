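"""Head-motion quality control.

Framewise displacement (FD) summarises frame-to-frame head movement as the
sum of the three absolute translation increments plus the three rotation
increments converted to arc length at a configurable head radius (50 mm by
default, roughly the distance from head centre to occipital cortex in an
infant).  Runs are screened against absolute displacement limits and, when
movement and stillness coexist, segmented into independent still intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MotionTrace

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
TRANSLATION_LIMIT_MM = 4.0
ROTATION_LIMIT_MM = 5.0
#: shortest retained segment: two full stimulus periods at the default
#: schedule, so period averaging stays possible on every segment.
MIN_SEGMENT_TR = 28


@dataclass
class FdSeries:
    """Per-time-point framewise displacement in millimetres.

    ``values[0]`` is 0 by convention (FD is undefined at the first frame).
    """

    values: np.ndarray
    radius_mm: float
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM

    @property
    def suprathreshold_count(self) -> int:
        return count_suprathreshold(self, self.threshold_mm)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0


def framewise_displacement(
    trace: MotionTrace, radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> FdSeries:
    """FD(t) = |Δdx| + |Δdy| + |Δdz| + r·(|Δα| + |Δβ| + |Δγ|), in mm.

    Rotation increments are converted from degrees to radians before the
    radius multiplication, so each rotation term is an arc length in mm.
    """
    if trace.n_timepoints < 2:
        raise ValueError("FD needs a trace with at least 2 time points")
    d_trans = np.abs(np.diff(trace.translations_mm, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(np.deg2rad(trace.rotations_deg), axis=0)).sum(axis=1)
    fd = np.r_[0.0, d_trans + radius_mm * d_rot]
    return FdSeries(values=fd, radius_mm=radius_mm)


def count_suprathreshold(
    fd_series: FdSeries | np.ndarray, threshold_mm: float = DEFAULT_FD_THRESHOLD_MM
) -> int:
    """Number of time points with FD strictly above the threshold."""
    values = fd_series.values if isinstance(fd_series, FdSeries) else np.asarray(fd_series)
    return int(np.sum(values > threshold_mm))


@dataclass
class ScreenResult:
    """Outcome of motion screening for one run."""

    verdict: str  # "keep", "segment" or "exclude"
    intervals: list[tuple[int, int]] = field(default_factory=list)  # half-open
    reason: str = ""

    @property
    def retained_index(self) -> np.ndarray:
        if not self.intervals:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(a, b) for a, b in self.intervals])

    def covers(self, n: int) -> bool:
        return self.retained_index.size == n


def _still_intervals(bad: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of still (not bad) time points of at least ``min_len``."""
    intervals: list[tuple[int, int]] = []
    n = bad.size
    start = None
    for i in range(n + 1):
        quiet = i < n and not bad[i]
        if quiet and start is None:
            start = i
        elif not quiet and start is not None:
            if i - start >= min_len:
                intervals.append((start, i))
            start = None
    return intervals


def screen_run(
    trace: MotionTrace,
    translation_limit_mm: float = TRANSLATION_LIMIT_MM,
    rotation_limit_mm: float = ROTATION_LIMIT_MM,
    radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    min_segment_tr: int = MIN_SEGMENT_TR,
) -> ScreenResult:
    """Apply the exclusion/segmentation rules to one motion trace.

    A run is excluded outright when the range (max - min) of any cumulative
    translation axis exceeds ``translation_limit_mm``, or the rotational arc
    length range at ``radius_mm`` exceeds ``rotation_limit_mm``.  Otherwise
    time points whose FD exceeds ``fd_threshold_mm`` mark movement spans and
    the still spans between them are retained as independent segments, the
    shortest admissible segment being ``min_segment_tr`` TRs.
    """
    n = trace.n_timepoints
    t_range = np.ptp(trace.translations_mm, axis=0)
    if np.any(t_range > translation_limit_mm):
        return ScreenResult(
            "exclude", [],
            f"translation range {t_range.max():.2f} mm exceeds "
            f"{translation_limit_mm} mm",
        )
    arc_range = np.ptp(np.deg2rad(trace.rotations_deg), axis=0) * radius_mm
    if np.any(arc_range > rotation_limit_mm):
        return ScreenResult(
            "exclude", [],
            f"rotation arc range {arc_range.max():.2f} mm exceeds "
            f"{rotation_limit_mm} mm",
        )

    fd = framewise_displacement(trace, radius_mm)
    bad = fd.values > fd_threshold_mm
    if not bad.any():
        return ScreenResult("keep", [(0, n)], "no suprathreshold motion")

    intervals = _still_intervals(bad, min_segment_tr)
    if not intervals:
        return ScreenResult(
            "exclude", [],
            f"no still segment of >= {min_segment_tr} time points",
        )
    return ScreenResult(
        "segment", intervals,
        f"{int(bad.sum())} suprathreshold time points; "
        f"{len(intervals)} still segment(s) retained",
    )


def summarize_motion(
    traces_by_group: dict[str, list[MotionTrace]],
    radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
) -> pd.DataFrame:
    """Group summary table of head movement, one row per group.

    Columns mirror the conventional motion-QC table: mean and across-subject
    SD for each of the six rigid-body directions, FD mean/SD, and the mean
    number of time points with FD above the threshold.
    """
    cols = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
            "rot_x_deg", "rot_y_deg", "rot_z_deg"]
    rows = []
    for group, traces in traces_by_group.items():
        if not traces:
            raise ValueError(f"group {group!r} has no traces")
        subj_means = np.array([t.params.mean(axis=0) for t in traces])
        fds = [framewise_displacement(t, radius_mm) for t in traces]
        fd_means = np.array([f.mean for f in fds])
        counts = np.array([count_suprathreshold(f, threshold_mm) for f in fds])
        row: dict[str, float | str | int] = {"group": group, "n_subjects": len(traces)}
        for j, c in enumerate(cols):
            row[f"{c}_mean"] = subj_means[:, j].mean()
            row[f"{c}_sd"] = subj_means[:, j].std(ddof=1) if len(traces) > 1 else 0.0
        row["fd_mean"] = fd_means.mean()
        row["fd_sd"] = fd_means.std(ddof=1) if len(traces) > 1 else 0.0
        row["n_suprathreshold"] = counts.mean()
        rows.append(row)
    return pd.DataFrame(rows)
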