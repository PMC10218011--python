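"""Core data containers shared across the analysis stages.

The experiment alternates two stimulus conditions (C1, C2) in equal-duration
blocks, sampled at a fixed TR, with a few dummy volumes at the start of each
run while the longitudinal magnetisation reaches steady state.  Everything
downstream (design matrices, period averaging, spectral analysis) is driven
by the :class:`ConditionSchedule` attached to a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed ROI ordering used for connectivity matrices.
ROI_ORDER: tuple[str, ...] = (
    "MT+ R", "MT+ L", "V1", "V6 R", "V6 L", "PIVC R", "PIVC L",
)


@dataclass(frozen=True)
class ConditionSchedule:
    """Block-design timing for one functional series.

    Parameters
    ----------
    tr_s : repetition time in seconds.
    block_s : duration of a single condition block in seconds.
    n_periods : number of complete C1+C2 alternation periods.
    n_dummy : number of initial dummy volumes (discarded before analysis).
    """

    tr_s: float
    block_s: float
    n_periods: int
    n_dummy: int

    def __post_init__(self) -> None:
        ratio = self.block_s / self.tr_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"block duration {self.block_s} s is not a whole number of "
                f"TRs (TR = {self.tr_s} s)"
            )
        if self.n_periods < 1:
            raise ValueError("need at least one stimulation period")
        if self.n_dummy < 0:
            raise ValueError("dummy count must be non-negative")

    @property
    def block_tr(self) -> int:
        """Block length in TRs."""
        return round(self.block_s / self.tr_s)

    @property
    def period_tr(self) -> int:
        """Length of one full C1+C2 period in TRs."""
        return 2 * self.block_tr

    @property
    def period_s(self) -> float:
        return 2 * self.block_s

    @property
    def n_retained(self) -> int:
        """Number of analysed time points after dummy removal."""
        return self.n_periods * self.period_tr

    @property
    def n_total(self) -> int:
        """Acquired time points including dummies."""
        return self.n_retained + self.n_dummy

    @property
    def fundamental(self) -> int:
        """Fundamental stimulus frequency in cycles per retained run."""
        return self.n_periods

    def boxcar(self) -> np.ndarray:
        """1/0 indicator of condition C1 over the retained time points."""
        one_period = np.r_[np.ones(self.block_tr), np.zeros(self.block_tr)]
        return np.tile(one_period, self.n_periods)


def make_condition_schedule(
    tr_s: float, block_s: float, n_periods: int, n_dummy: int
) -> ConditionSchedule:
    """Build the alternating two-condition block schedule.

    The default acquisition is TR = 3 s, 21 s blocks, 6 periods and 4 dummy
    scans, i.e. 88 acquired and 84 retained time points with a 14-TR period.
    """
    return ConditionSchedule(tr_s, block_s, n_periods, n_dummy)


DEFAULT_SCHEDULE = make_condition_schedule(3.0, 21.0, 6, 4)


@dataclass
class BoldRun:
    """A 4D voxel x time dataset with acquisition metadata.

    ``data`` has shape (nx, ny, nz, n_t) and includes dummy volumes;
    :meth:`retained` drops them.
    """

    data: np.ndarray
    tr_s: float
    n_dummy: int
    voxel_size_mm: float = 3.0
    schedule: ConditionSchedule | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BoldRun data must be 4D (x, y, z, t)")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def retained(self) -> np.ndarray:
        """Volumes after dummy removal, shape (nx, ny, nz, n_retained)."""
        return self.data[..., self.n_dummy:]

    def retained_matrix(self) -> np.ndarray:
        """Retained data flattened to (n_retained, n_voxels)."""
        ret = self.retained()
        return ret.reshape(-1, ret.shape[3]).T


@dataclass
class MotionTrace:
    """Six rigid-body head-position parameters per time point.

    Columns: dx, dy, dz in millimetres; rotations about x, y, z in degrees.
    These are cumulative positions (as written by a motion-correction step),
    not frame-to-frame increments.
    """

    params: np.ndarray
    tr_s: float = 3.0

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError("motion trace needs 6 columns (3 trans, 3 rot)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]

    def drop_dummies(self, n_dummy: int) -> "MotionTrace":
        return MotionTrace(self.params[n_dummy:], self.tr_s)


@dataclass
class Roi:
    """A labelled voxel set with centre of mass and peak statistic.

    ``voxels`` is an (n, 3) integer array of grid indices.  The centre of
    mass is reported in millimetres with the origin at the volume centre.
    """

    label: str
    hemisphere: str  # "L", "R" or "midline"
    voxels: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float = 3.0
    peak_z: float = float("nan")

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.size == 0:
            raise ValueError(f"ROI {self.label!r} has no voxels")

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    @property
    def center_of_mass_mm(self) -> np.ndarray:
        center = (np.asarray(self.grid_shape) - 1) / 2.0
        return (self.voxels.mean(axis=0) - center) * self.voxel_size_mm

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m
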