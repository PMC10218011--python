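"""Resting-state ROI-pair functional connectivity.

Each subject contributes a 7x7 Pearson correlation matrix between the
high-passed mean time courses of the seven ROIs, in the fixed order
MT+ R, MT+ L, V1, V6 R, V6 L, PIVC R, PIVC L.  Group matrices are
element-wise means over the available subjects.  Significance of a group
matrix is assigned through the "aggregate subject": each subject's ROI
series is z-scored and the series are concatenated; the correlation of the
concatenated signals equals the mean of the per-subject correlations (an
identity that holds exactly for equal-length z-scored runs) and its p-value
follows from the r -> t transform on the total sample size.  Group
differences are two-tailed two-sample t tests per cell, by default on
Fisher-z transformed correlations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .core import ROI_ORDER, BoldRun, Roi


def highpass_fourier(series: np.ndarray, n_cycles: int = 2) -> np.ndarray:
    """Remove constant, linear and Fourier terms up to ``n_cycles`` per run
    (GLM-Fourier high-pass)."""
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    t = np.arange(n, dtype=float)
    cols = [np.ones(n), t - t.mean()]
    for c in range(1, n_cycles + 1):
        cols.append(np.sin(2 * np.pi * c * t / n))
        cols.append(np.cos(2 * np.pi * c * t / n))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, series, rcond=None)
    return series - X @ beta


def roi_timecourses(run: BoldRun, rois: dict[str, Roi],
                    n_cycles: int = 2) -> np.ndarray:
    """(n_retained, 7) matrix of high-passed ROI mean series in the fixed
    ROI order; columns for absent ROIs are NaN."""
    ret = run.retained()
    out = np.full((ret.shape[3], len(ROI_ORDER)), np.nan)
    for j, label in enumerate(ROI_ORDER):
        roi = rois.get(label)
        if roi is None:
            continue
        series = ret[tuple(roi.voxels.T)].mean(axis=0)
        out[:, j] = highpass_fourier(series, n_cycles)
    return out


class RoiConnectivity(BaseEstimator):
    """Per-subject ROI correlation matrices with group-level statistics.

    scikit-learn style: ``fit(X)`` takes a list of per-subject
    (n_timepoints, n_rois) arrays (lengths may differ across subjects;
    missing ROIs are NaN columns) and ``transform`` returns the stacked
    per-subject correlation matrices.

    Attributes
    ----------
    matrices_ : (n_subjects, n_rois, n_rois) per-subject Pearson r.
    mean_ : element-wise group mean with pairwise subject exclusion.
    aggregate_r_, aggregate_p_ : aggregate-subject correlation and its
        significance.
    """

    def __init__(self, min_timepoints: int = 30):
        self.min_timepoints = min_timepoints

    def fit(self, X: list[np.ndarray], y=None) -> "RoiConnectivity":
        mats = [self._single(np.asarray(ts, float)) for ts in X]
        self.matrices_ = np.stack(mats)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean_ = np.nanmean(self.matrices_, axis=0)
        if len(X) >= 2:
            self.aggregate_r_, self.aggregate_p_ = aggregate_significance(X)
        return self

    def transform(self, X: list[np.ndarray] | None = None) -> np.ndarray:
        return self.matrices_

    def fit_transform(self, X: list[np.ndarray], y=None) -> np.ndarray:
        return self.fit(X).transform()

    def _single(self, ts: np.ndarray) -> np.ndarray:
        if ts.shape[0] < self.min_timepoints:
            raise ValueError(
                f"retained rest length {ts.shape[0]} < {self.min_timepoints}"
            )
        k = ts.shape[1]
        mat = np.full((k, k), np.nan)
        ok = ~np.any(np.isnan(ts), axis=0)
        if ok.sum() >= 2:
            sub = ts[:, ok]
            sd = sub.std(axis=0)
            const = sd == 0
            if const.any():
                warnings.warn("constant ROI series excluded from correlation")
                ok[np.flatnonzero(ok)[const]] = False
                sub = ts[:, ok]
            if ok.sum() >= 2:
                r = np.corrcoef(sub, rowvar=False)
                mat[np.ix_(ok, ok)] = r
        mat[np.ix_(ok, ok)] = np.clip(mat[np.ix_(ok, ok)], -1.0, 1.0)
        np.fill_diagonal(mat, np.where(ok, 1.0, np.nan))
        return mat


def roi_corr_matrix(rest_run: BoldRun, rois: dict[str, Roi]) -> np.ndarray:
    """7x7 symmetric Pearson matrix for one subject (NaN rows/columns for
    missing ROIs; such subjects drop out pairwise at the group stage)."""
    ts = roi_timecourses(rest_run, rois)
    return RoiConnectivity().fit([ts]).matrices_[0]


def group_mean_matrix(matrices: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Element-wise mean over subjects, ignoring missing-ROI cells."""
    arr = np.asarray(matrices, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] < 1:
        raise ValueError("need at least one matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(arr, axis=0)


def aggregate_significance(
    timecourses: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate-subject correlation and significance.

    Each subject's ROI series is z-scored (population SD) and concatenated;
    Pearson r on the concatenation equals, for equal-length runs, the mean
    of the per-subject correlations.  p comes from the r -> t transform
    with df = total time points - 2.  Returns (r matrix, p matrix).
    """
    if len(timecourses) < 2:
        raise ValueError("aggregate subject needs >= 2 subjects")
    k = np.asarray(timecourses[0]).shape[1]
    zs = []
    for ts in timecourses:
        ts = np.asarray(ts, dtype=float)
        sd = np.nanstd(ts, axis=0)
        mu = np.nanmean(ts, axis=0)
        const = sd == 0
        if const.any():
            warnings.warn("constant ROI series excluded from aggregate")
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (ts - mu) / np.where(sd > 0, sd, np.nan)
        zs.append(z)
    agg = np.vstack(zs)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = agg[:, [i, j]]
            keep = ~np.any(np.isnan(pair), axis=1)
            n = int(keep.sum())
            if n < 4:
                continue
            rij = float(np.corrcoef(pair[keep].T)[0, 1]) if i != j else 1.0
            rij = float(np.clip(rij, -1.0, 1.0))
            df = n - 2
            with np.errstate(divide="ignore"):
                t = rij * np.sqrt(df / max(1.0 - rij ** 2, 1e-300))
            pij = 0.0 if i == j else float(2.0 * stats.t.sf(abs(t), df))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return r, p


def compare_matrices(
    group_a: list[np.ndarray] | np.ndarray,
    group_b: list[np.ndarray] | np.ndarray,
    fisher: bool = True,
) -> np.ndarray:
    """Per-cell two-tailed two-sample t test between groups of matrices.

    By default the test is applied to Fisher-z transformed correlations
    (variance stabilisation); set ``fisher=False`` for raw r.  Cells with
    fewer than 2 subjects per group are NaN.
    """
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    k = A.shape[1]
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            a = A[:, i, j]
            b = B[:, i, j]
            a = a[~np.isnan(a)]
            b = b[~np.isnan(b)]
            if a.size < 2 or b.size < 2:
                continue
            if fisher:
                a = np.arctanh(np.clip(a, -0.999999, 0.999999))
                b = np.arctanh(np.clip(b, -0.999999, 0.999999))
            if a.std() == 0 and b.std() == 0:
                out[i, j] = out[j, i] = 1.0 if a.mean() == b.mean() else 0.0
                continue
            _, pv = stats.ttest_ind(a, b)
            out[i, j] = out[j, i] = float(pv)
    np.fill_diagonal(out, 1.0)
    return out


def significance_flags(p_matrix: np.ndarray,
                       levels: tuple[float, float] = (0.05, 0.01)) -> pd.DataFrame:
    """Upper-triangle table of cells significant at each level."""
    k = p_matrix.shape[0]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            pv = p_matrix[i, j]
            if np.isnan(pv):
                continue
            rows.append({
                "roi_i": ROI_ORDER[i], "roi_j": ROI_ORDER[j], "p": pv,
                "sig_05": bool(pv < levels[0]), "sig_01": bool(pv < levels[1]),
            })
    return pd.DataFrame(rows)
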