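"""V1-seed detection, lagged seed-correlation masking and ROI labelling.

The motion-vs-blank GLM localises activity along the calcarine sulcus; the
suprathreshold voxels inside a calcarine prior form the V1 seed.  The seed
time course is then cross-correlated with every voxel at temporal delays of
0 s and one TR; the union of the two thresholded correlation maps restricts
the subsequent coherent-vs-random GLM, whose suprathreshold foci (positive
or negative) are split into connected components and labelled from region
priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .core import Roi
from .glm import StatMap, threshold_map

#: 6-neighbour (face) adjacency for connected components.
_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def define_v1_seed(
    statmap_motion_vs_blank: StatMap,
    calcarine_prior: np.ndarray,
    p_threshold: float = 0.01,
    voxel_size_mm: float = 3.0,
) -> Roi:
    """Largest connected cluster of positive activation (p <= 0.01) inside
    the calcarine prior region."""
    prior = np.asarray(calcarine_prior, dtype=bool)
    if not prior.any():
        raise ValueError("calcarine prior region is empty")
    sel = threshold_map(statmap_motion_vs_blank, p_threshold, sign="pos") & prior
    if not sel.any():
        raise ValueError(
            "no suprathreshold voxels in the calcarine prior; review the "
            "p threshold or the prior region"
        )
    labels, n = ndimage.label(sel, structure=_STRUCTURE)
    sizes = ndimage.sum_labels(sel, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    voxels = np.argwhere(labels == best)
    peak_z = float(np.nanmax(statmap_motion_vs_blank.z[labels == best]))
    return Roi("V1", "midline", voxels, statmap_motion_vs_blank.grid_shape,
               voxel_size_mm, peak_z)


@dataclass
class LagCorrelationMap:
    """Seed-to-voxel Pearson correlation at each temporal delay.

    ``r`` and ``p`` map lag (in TRs) to 3D arrays; ``n_eff`` is the number
    of overlapping samples entering each correlation.
    """

    r: dict[int, np.ndarray]
    p: dict[int, np.ndarray]
    n_eff: dict[int, int]
    grid_shape: tuple[int, int, int]


def _pearson_with_p(seed: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise Pearson r of ``Y`` against ``seed`` and its two-sided p
    from the r -> t transform (df = n - 2).  Constant columns get r = 0,
    p = 1."""
    n = len(seed)
    s = seed - seed.mean()
    Yc = Y - Y.mean(axis=0)
    s_ss = float(s @ s)
    y_ss = (Yc ** 2).sum(axis=0)
    denom = np.sqrt(s_ss * y_ss)
    ok = denom > 0
    r = np.zeros(Y.shape[1])
    np.divide(s @ Yc, denom, out=r, where=ok)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~ok] = 1.0
    r[~ok] = 0.0
    return r, p


class SeedLagCorrelation(BaseEstimator):
    """Seed-to-voxel correlation maps at a set of temporal delays.

    scikit-learn style: ``fit(X, y)`` with ``X`` the (n_timepoints,
    n_voxels) data matrix and ``y`` the seed time course.  A positive lag of
    k TRs correlates the seed at time t with each voxel at time t + k, so
    voxels responding *after* the seed score highly at positive lags.

    Attributes
    ----------
    r_ : dict lag -> (n_voxels,) correlation.
    p_ : dict lag -> (n_voxels,) two-sided p (r -> t transform).
    n_eff_ : dict lag -> overlapping sample count.
    """

    def __init__(self, lags_tr: tuple[int, ...] = (0, 1), min_overlap: int = 10):
        self.lags_tr = lags_tr
        self.min_overlap = min_overlap

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SeedLagCorrelation":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("seed and data must have equal length")
        self.r_, self.p_, self.n_eff_ = {}, {}, {}
        for lag in self.lags_tr:
            k = abs(int(lag))
            n_ov = len(y) - k
            if n_ov < self.min_overlap:
                raise ValueError(f"overlap after lag {lag} below {self.min_overlap}")
            if lag >= 0:
                r, p = _pearson_with_p(y[: n_ov], X[k:])
            else:
                r, p = _pearson_with_p(y[k:], X[: n_ov])
            self.r_[int(lag)] = r
            self.p_[int(lag)] = p
            self.n_eff_[int(lag)] = n_ov
        return self


def lagged_correlation_map(
    run_matrix: np.ndarray,
    seed_timecourse: np.ndarray,
    grid_shape: tuple[int, int, int],
    lags_s: tuple[float, ...] = (0.0, 3.0),
    tr_s: float = 3.0,
) -> LagCorrelationMap:
    """Correlate the seed with every voxel at the given delays (multiples
    of TR), reshaped onto the acquisition grid."""
    lags_tr = []
    for lag in lags_s:
        k = lag / tr_s
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"lag {lag} s is not a multiple of TR = {tr_s} s")
        lags_tr.append(int(round(k)))
    est = SeedLagCorrelation(lags_tr=tuple(lags_tr)).fit(run_matrix, seed_timecourse)
    return LagCorrelationMap(
        r={lag: est.r_[lag].reshape(grid_shape) for lag in est.r_},
        p={lag: est.p_[lag].reshape(grid_shape) for lag in est.p_},
        n_eff=est.n_eff_,
        grid_shape=grid_shape,
    )


def union_mask(
    lag_map: LagCorrelationMap,
    p_threshold: float = 0.05,
    positive_only: bool = False,
) -> np.ndarray:
    """Union of the thresholded correlation maps over all lags.

    By default voxels of either correlation sign are admitted: cortex that
    responds to stimulation with the opposite polarity (the vestibular areas
    respond negatively) is anti-correlated with the seed yet belongs in the
    stimulus-driven mask.  Set ``positive_only=True`` to restrict the mask
    to positively coupled cortex.
    """
    mask = np.zeros(lag_map.grid_shape, dtype=bool)
    for lag, p in lag_map.p.items():
        sel = p < p_threshold
        if positive_only:
            sel &= lag_map.r[lag] > 0
        mask |= sel
    return mask


def label_rois(
    statmap: StatMap,
    mask: np.ndarray,
    scene_priors: dict[str, np.ndarray],
    p_threshold: float = 0.05,
    voxel_size_mm: float = 3.0,
) -> list[Roi]:
    """Label connected suprathreshold foci inside the mask from region priors.

    Components of either sign are kept (vestibular foci respond more to
    random than to coherent motion and carry negative contrasts).  Each
    component takes the label of the prior region it overlaps most; a
    component overlapping no prior is reported as "unassigned".  Components
    sharing a winning prior are merged under that label.
    """
    if not np.asarray(mask, bool).any():
        raise ValueError("mask is empty")
    rois: dict[str, list[np.ndarray]] = {}
    grid = statmap.grid_shape
    for sign in ("pos", "neg"):
        sel = threshold_map(statmap, p_threshold, sign=sign) & mask
        labels, n = ndimage.label(sel, structure=_STRUCTURE)
        for comp in range(1, n + 1):
            comp_mask = labels == comp
            best_label, best_overlap = "unassigned", 0
            for name, prior in scene_priors.items():
                overlap = int(np.sum(comp_mask & prior))
                if overlap > best_overlap:
                    best_label, best_overlap = name, overlap
            rois.setdefault(best_label, []).append(np.argwhere(comp_mask))
    out = []
    for name, pieces in sorted(rois.items()):
        voxels = np.vstack(pieces)
        hemi = "midline"
        if name.endswith(" L"):
            hemi = "L"
        elif name.endswith(" R"):
            hemi = "R"
        zvals = statmap.z[tuple(voxels.T)]
        peak = float(zvals[np.argmax(np.abs(zvals))])
        out.append(Roi(name, hemi, voxels, grid, voxel_size_mm, peak))
    return out
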