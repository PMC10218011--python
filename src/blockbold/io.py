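"""Standard-format I/O: NIfTI volumes, motion text, tables, ground truth."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import ROI_ORDER, BoldRun, ConditionSchedule, MotionTrace
from .synthetic import GroundTruth


def save_bold(run: BoldRun, path: str | Path) -> None:
    """Write a run as a NIfTI-1 volume with an isotropic diagonal affine."""
    affine = np.diag([run.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(run.data.astype(np.float32), affine)
    img.header.set_zooms((run.voxel_size_mm,) * 3 + (run.tr_s,))
    nib.save(img, str(path))


def load_bold(
    path: str | Path,
    n_dummy: int = 4,
    schedule: ConditionSchedule | None = None,
) -> BoldRun:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 3.0
    return BoldRun(np.asarray(img.dataobj, dtype=float), tr, n_dummy,
                   float(zooms[0]), schedule)


def save_motion(trace: MotionTrace, path: str | Path) -> None:
    """Six whitespace-delimited columns, one row per time point."""
    np.savetxt(str(path), trace.params, fmt="%.6f")


def load_motion(path: str | Path, tr_s: float = 3.0) -> MotionTrace:
    return MotionTrace(np.loadtxt(str(path)), tr_s)


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    d: dict = {
        "amplitudes": {k: float(v) for k, v in truth.amplitudes.items()},
        "phase_deg": float(truth.phase_deg),
        "rest_attenuation": float(truth.rest_attenuation),
        "spike_indices": list(map(int, truth.spike_indices)),
    }
    if truth.rest_corr is not None:
        d["rest_corr"] = [[float(x) for x in row] for row in truth.rest_corr]
    Path(path).write_text(yaml.safe_dump(d))


def load_ground_truth(path: str | Path) -> GroundTruth:
    d = yaml.safe_load(Path(path).read_text())
    return GroundTruth(
        amplitudes=d.get("amplitudes", {}),
        phase_deg=d.get("phase_deg", float("nan")),
        rest_corr=np.array(d["rest_corr"]) if "rest_corr" in d else None,
        rest_attenuation=d.get("rest_attenuation", 1.0),
        spike_indices=d.get("spike_indices", []),
    )


def matrix_to_csv(matrix: np.ndarray, path: str | Path) -> None:
    """Connectivity matrix as CSV with the fixed 7-label header."""
    pd.DataFrame(matrix, index=list(ROI_ORDER), columns=list(ROI_ORDER)) \
        .to_csv(str(path))


def matrix_from_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(str(path), index_col=0).to_numpy(dtype=float)
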