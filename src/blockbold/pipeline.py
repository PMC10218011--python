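"""End-to-end orchestration of the stimulus and resting-state analyses.

The stimulus pipeline for one subject runs: dummy drop -> motion screening
-> GLM on the motion-vs-blank series -> V1-seed detection in the calcarine
prior -> seed correlation maps at lags 0 and 1 TR -> union mask -> GLM on
the coherent-vs-random series inside the mask -> ROI labelling -> per-ROI
time-course extraction, period averaging, windowed mean response and
spectral SNR/phase.  The rest pipeline computes per-subject 7x7 ROI
correlation matrices, group means, aggregate-subject significance and
between-group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ROI_ORDER, BoldRun, MotionTrace, Roi
from .glm import Hrf, build_design, default_hrf, fit_glm, gamma_hrf
from .motion import ScreenResult, screen_run
from .seed import define_v1_seed, label_rois, lagged_correlation_map, union_mask
from .spectral import (
    extract_timecourse, mean_response, period_average, spectral_summary,
    split_periods,
)
from .connectivity import (
    aggregate_significance, compare_matrices, group_mean_matrix,
    roi_corr_matrix, roi_timecourses,
)

log = logging.getLogger("blockbold")


@dataclass
class PipelineConfig:
    """All analysis constants in one place (round-trips through YAML)."""

    seed_p_threshold: float = 0.01
    map_p_threshold: float = 0.05
    roi_p_threshold: float = 0.05
    fd_threshold_mm: float = 0.5
    translation_limit_mm: float = 4.0
    rotation_limit_mm: float = 5.0
    head_radius_mm: float = 50.0
    min_segment_tr: int = 28
    n_harmonics: int = 2
    response_window_tr: tuple[int, int] = (3, 6)
    lags_s: tuple[float, float] = (0.0, 3.0)
    mask_positive_only: bool = False
    hrf_onset_delay_s: float | None = None  # None -> calibrated default

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("response_window_tr", "lags_s"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class RunManifest:
    """Pointer to one functional series on disk."""

    subject_id: str
    age_group: str  # "5w", "8w" or "adult"
    series_type: str  # "blank-contrast", "random-contrast" or "rest"
    bold_path: str
    motion_path: str | None = None
    seed: int = 0


@dataclass
class SubjectResult:
    """Stimulus-pipeline output for one subject."""

    subject_id: str
    rois: dict[str, Roi]
    roi_table: pd.DataFrame
    responses: dict[str, np.ndarray]
    spectral: pd.DataFrame
    screen_blank: ScreenResult
    screen_random: ScreenResult
    excluded: bool = False
    reason: str = ""


def _screened_design(run: BoldRun, trace: MotionTrace, hrf: Hrf,
                     cfg: PipelineConfig) -> tuple[ScreenResult, object]:
    sched = run.schedule
    trace_ret = trace.drop_dummies(run.n_dummy)
    screen = screen_run(
        trace_ret,
        cfg.translation_limit_mm, cfg.rotation_limit_mm,
        cfg.head_radius_mm, cfg.fd_threshold_mm, cfg.min_segment_tr,
    )
    if screen.verdict == "exclude":
        return screen, None
    idx = screen.retained_index
    design = build_design(sched, hrf, trace_ret, cfg.n_harmonics, idx)
    return screen, design


def run_stimulus_pipeline(
    blank_run: BoldRun,
    blank_trace: MotionTrace,
    random_run: BoldRun,
    random_trace: MotionTrace,
    calcarine_prior: np.ndarray,
    scene_priors: dict[str, np.ndarray],
    config: PipelineConfig | None = None,
    subject_id: str = "subject",
) -> SubjectResult:
    """Run the full two-series stimulus analysis for one subject.

    ``calcarine_prior`` is the boolean "V1 territory" used for seed search;
    ``scene_priors`` maps ROI labels to boolean prior regions used for
    labelling (ground truth in synthetic mode, user-supplied otherwise).
    """
    cfg = config or PipelineConfig()
    sched = blank_run.schedule
    hrf = (default_hrf(sched.tr_s, sched.block_s, sched.n_periods)
           if cfg.hrf_onset_delay_s is None
           else gamma_hrf(cfg.hrf_onset_delay_s, tr_s=sched.tr_s))

    screen_b, design_b = _screened_design(blank_run, blank_trace, hrf, cfg)
    screen_r, design_r = _screened_design(random_run, random_trace, hrf, cfg)
    if design_b is None or design_r is None:
        bad = screen_b if design_b is None else screen_r
        log.warning("[%s] excluded by motion screening: %s", subject_id, bad.reason)
        return SubjectResult(
            subject_id, {}, pd.DataFrame(), {}, pd.DataFrame(),
            screen_b, screen_r, excluded=True, reason=bad.reason,
        )
    log.info("[%s] screening: blank=%s random=%s", subject_id,
             screen_b.verdict, screen_r.verdict)

    grid = blank_run.grid_shape
    Yb = blank_run.retained_matrix()
    Yr = random_run.retained_matrix()

    stat_blank = fit_glm(Yb, design_b, grid_shape=grid)
    seed_roi = define_v1_seed(stat_blank, calcarine_prior,
                              cfg.seed_p_threshold, blank_run.voxel_size_mm)

    seed_tc = Yb[:, np.ravel_multi_index(tuple(seed_roi.voxels.T), grid)]
    seed_tc = seed_tc.mean(axis=1)[design_b.retained_index]
    lag_map = lagged_correlation_map(
        Yb[design_b.retained_index], seed_tc, grid,
        lags_s=cfg.lags_s, tr_s=sched.tr_s,
    )
    mask = union_mask(lag_map, cfg.map_p_threshold, cfg.mask_positive_only)

    stat_random = fit_glm(Yr, design_r, grid_shape=grid)
    rois = {r.label: r for r in label_rois(
        stat_random, mask, scene_priors, cfg.roi_p_threshold,
        random_run.voxel_size_mm,
    )}
    rois["V1"] = seed_roi
    rois["V1"].peak_z = seed_roi.peak_z

    rows, spec_rows, responses = [], [], {}
    for label in ROI_ORDER:
        roi = rois.get(label)
        if roi is None:
            log.info("[%s] ROI %s not detected", subject_id, label)
            continue
        com = roi.center_of_mass_mm
        flat = np.ravel_multi_index(tuple(roi.voxels.T), grid)
        glm_amp = float(stat_random.beta_pct.reshape(-1)[flat].mean())
        rows.append({
            "roi": label, "hemisphere": roi.hemisphere, "n_voxels": roi.n_voxels,
            "x_mm": com[0], "y_mm": com[1], "z_mm": com[2], "peak_z": roi.peak_z,
            "glm_amplitude_pct": glm_amp,
        })
        tc = extract_timecourse(random_run, roi)
        periods, good = split_periods(tc, screen_r)
        pa = period_average(periods, good)
        responses[label] = pa.mean
        summ = spectral_summary(tc, good=good, roi_label=label,
                                hemisphere=roi.hemisphere)
        spec_rows.append({
            "roi": label, "hemisphere": roi.hemisphere,
            "n_good_periods": len(good),
            "mean_response_pct": mean_response(pa, cfg.response_window_tr),
            "amplitude_pct": summ.amplitude, "snr": summ.snr,
            "phase_deg": summ.phase_deg, "p": summ.p,
        })
        log.info("[%s] ROI %s: %d good periods", subject_id, label, len(good))

    return SubjectResult(
        subject_id, rois, pd.DataFrame(rows), responses,
        pd.DataFrame(spec_rows), screen_b, screen_r,
    )


@dataclass
class RestResult:
    """Rest-pipeline output for a cohort."""

    per_subject: dict[str, np.ndarray]
    group_means: dict[str, np.ndarray] = field(default_factory=dict)
    aggregate_p: dict[str, np.ndarray] = field(default_factory=dict)
    group_difference_p: np.ndarray | None = None


def run_rest_pipeline(
    rest_runs: dict[str, BoldRun],
    rois_by_subject: dict[str, dict[str, Roi]],
    groups: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> RestResult:
    """Connectivity analysis over a cohort of resting runs.

    ``groups`` maps subject id to a group name; with two groups present the
    per-cell two-tailed comparison is added (skipped with a warning when a
    group has fewer than two subjects).
    """
    cfg = config or PipelineConfig()
    per_subject, ts_by_subject = {}, {}
    for sid, run in rest_runs.items():
        rois = rois_by_subject[sid]
        per_subject[sid] = roi_corr_matrix(run, rois)
        ts_by_subject[sid] = roi_timecourses(run, rois, cfg.n_harmonics)

    groups = groups or {sid: "all" for sid in rest_runs}
    result = RestResult(per_subject=per_subject)
    by_group: dict[str, list[str]] = {}
    for sid in rest_runs:
        by_group.setdefault(groups[sid], []).append(sid)
    for g, sids in by_group.items():
        result.group_means[g] = group_mean_matrix([per_subject[s] for s in sids])
        if len(sids) >= 2:
            _, p = aggregate_significance([ts_by_subject[s] for s in sids])
            result.aggregate_p[g] = p
    if len(by_group) == 2:
        (ga, sa), (gb, sb) = by_group.items()
        if len(sa) >= 2 and len(sb) >= 2:
            result.group_difference_p = compare_matrices(
                [per_subject[s] for s in sa], [per_subject[s] for s in sb],
            )
        else:
            log.warning("group comparison skipped: a group has < 2 subjects")
    return result
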