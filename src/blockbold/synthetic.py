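"""Synthetic BOLD generator with ground truth.

Emulates the acquisition structure of the infant study: block-design runs
of 88 time points (4 dummies) at TR = 3 s with two 21-s conditions
alternating over 6 periods, resting runs of 124 time points (4 dummies),
3 mm isotropic voxels, and seven regions of interest (bilateral MT+, V6 and
PIVC plus midline V1) whose percent-signal-change amplitudes sit in the
0.2-0.8% range observed in infants, with the vestibular (PIVC) contrast
negative.  Noise is white Gaussian + AR(1) + linear drift per voxel; head
motion enters through six-parameter traces with smooth wander and optional
step-like spikes.  Every generated object carries its ground truth so the
downstream stages can be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_SCHEDULE, BoldRun, ConditionSchedule, MotionTrace, Roi, ROI_ORDER,
    make_condition_schedule,
)
from .glm import Hrf, default_hrf, fundamental_phase_deg

DEFAULT_GRID = (24, 24, 12)
DEFAULT_VOXEL_MM = 3.0
DEFAULT_BASELINE = 1000.0


@dataclass(frozen=True)
class RoiSpec:
    """One spherical ground-truth region.

    Amplitudes are percent signal change: ``amp_contrast`` for the
    C1 - C2 (coherent vs random) modulation, ``amp_blank`` for the
    stimulus-vs-blank modulation.  Either may be negative.
    """

    label: str
    center: tuple[int, int, int]
    radius_vox: float
    amp_contrast: float
    amp_blank: float

    @property
    def hemisphere(self) -> str:
        if self.label.endswith(" L"):
            return "L"
        if self.label.endswith(" R"):
            return "R"
        return "midline"


@dataclass
class SceneSpec:
    """Voxel grid, ROI layout and baseline intensity of the synthetic brain."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size_mm: float = DEFAULT_VOXEL_MM
    baseline: float = DEFAULT_BASELINE
    rois: tuple[RoiSpec, ...] = ()
    calcarine_prior: tuple[slice, slice, slice] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for spec in self.rois:
            vox = _sphere_voxels(spec.center, spec.radius_vox, self.grid_shape)
            if vox.shape[0] == 0:
                raise ValueError(f"ROI {spec.label} lies outside the grid")
            keys = set(map(tuple, vox))
            if keys & seen:
                raise ValueError(f"ROI {spec.label} overlaps another ROI")
            seen |= keys
            if not np.isfinite([spec.amp_contrast, spec.amp_blank]).all():
                raise ValueError(f"ROI {spec.label} has non-finite amplitude")

    def roi_voxels(self, label: str) -> np.ndarray:
        spec = self.roi_spec(label)
        return _sphere_voxels(spec.center, spec.radius_vox, self.grid_shape)

    def roi_spec(self, label: str) -> RoiSpec:
        for spec in self.rois:
            if spec.label == label:
                return spec
        raise KeyError(label)

    def priors(self) -> dict[str, np.ndarray]:
        """Boolean prior mask per ROI label (ground-truth region priors)."""
        out = {}
        for spec in self.rois:
            m = np.zeros(self.grid_shape, dtype=bool)
            vox = self.roi_voxels(spec.label)
            m[tuple(vox.T)] = True
            out[spec.label] = m
        return out

    def calcarine_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        if self.calcarine_prior is None:
            m[:] = True
        else:
            m[self.calcarine_prior] = True
        return m

    def membership_map(self) -> np.ndarray:
        """Integer label map: 0 outside, 1 + index into ROI_ORDER inside."""
        m = np.zeros(self.grid_shape, dtype=int)
        for spec in self.rois:
            idx = ROI_ORDER.index(spec.label) + 1
            vox = self.roi_voxels(spec.label)
            m[tuple(vox.T)] = idx
        return m

    def true_rois(self) -> dict[str, Roi]:
        return {
            spec.label: Roi(spec.label, spec.hemisphere,
                            self.roi_voxels(spec.label), self.grid_shape,
                            self.voxel_size_mm)
            for spec in self.rois
        }


def _sphere_voxels(center, radius, grid_shape) -> np.ndarray:
    g = np.indices(grid_shape)
    d2 = sum((g[i] - center[i]) ** 2 for i in range(3))
    vox = np.argwhere(d2 <= radius ** 2 + 1e-9)
    return vox


def default_scene() -> SceneSpec:
    """The seven-ROI infant scene at the study's observed amplitudes.

    Contrast (coherent vs random) amplitudes: MT+ 0.40, V6 0.23,
    PIVC -0.30 (random > coherent), V1 0 (not motion-selective).
    Stimulus-vs-blank amplitudes: MT+ 0.17, V6 0.11, PIVC -0.11, V1 0.30.
    """
    rois = (
        RoiSpec("MT+ L", (4, 9, 6), 2.0, 0.40, 0.17),
        RoiSpec("MT+ R", (20, 9, 6), 2.0, 0.40, 0.17),
        RoiSpec("V6 L", (8, 5, 9), 2.0, 0.23, 0.11),
        RoiSpec("V6 R", (16, 5, 9), 2.0, 0.23, 0.11),
        RoiSpec("PIVC L", (4, 15, 6), 2.0, -0.30, -0.11),
        RoiSpec("PIVC R", (20, 15, 6), 2.0, -0.30, -0.11),
        RoiSpec("V1", (12, 4, 5), 2.0, 0.0, 0.30),
    )
    return SceneSpec(
        rois=rois,
        calcarine_prior=(slice(8, 17), slice(1, 8), slice(2, 9)),
    )


@dataclass
class NoiseSpec:
    """Per-voxel noise model: white Gaussian (stationary SD as percent of
    baseline) filtered by an AR(1) recursion, plus a random linear drift."""

    white_sd_pct: float = 0.2
    ar1: float = 0.3
    drift_pct: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.ar1 < 1.0):
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.white_sd_pct < 0 or self.drift_pct < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis should recover."""

    amplitudes: dict[str, float] = field(default_factory=dict)
    phase_deg: float = float("nan")
    membership: np.ndarray | None = None
    rest_corr: np.ndarray | None = None
    rest_attenuation: float = 1.0
    spike_indices: list[int] = field(default_factory=list)
    regressor: np.ndarray | None = None


def _ar1_filter(white: np.ndarray, phi: float) -> np.ndarray:
    """AR(1)-filter along the last axis, innovations scaled so the
    stationary SD equals the input white SD."""
    if phi == 0:
        return white
    out = np.empty_like(white)
    scale = np.sqrt(1.0 - phi ** 2)
    out[..., 0] = white[..., 0]
    for t in range(1, white.shape[-1]):
        out[..., t] = phi * out[..., t - 1] + scale * white[..., t]
    return out


def _voxel_noise(rng: np.random.Generator, n_vox: int, n_t: int,
                 noise: NoiseSpec, baseline: float) -> np.ndarray:
    sd = noise.white_sd_pct / 100.0 * baseline
    eps = _ar1_filter(rng.standard_normal((n_vox, n_t)) * sd, noise.ar1)
    if noise.drift_pct > 0:
        slope = rng.standard_normal(n_vox) * (noise.drift_pct / 100.0 * baseline)
        ramp = np.linspace(-0.5, 0.5, n_t)
        eps += slope[:, None] * ramp[None, :]
    return eps


def simulate_block_run(
    scene: SceneSpec,
    schedule: ConditionSchedule = DEFAULT_SCHEDULE,
    hrf: Hrf | None = None,
    noise: NoiseSpec | None = None,
    motion_spec: dict | None = None,
    contrast: str = "contrast",
) -> tuple[BoldRun, MotionTrace, GroundTruth]:
    """Simulate one block-design run with its motion trace and ground truth.

    ``contrast`` selects which ROI amplitude drives the modulation:
    ``"contrast"`` for coherent-vs-random, ``"blank"`` for
    coherent-vs-blank.  The percent amplitude is defined relative to the
    run-mean intensity: the HRF-convolved C1 boxcar is demeaned before the
    modulation is applied, so a voxel's temporal mean equals its baseline
    and the GLM percent-signal-change estimate recovers the programmed
    amplitude exactly in the noiseless case.  Dummy volumes carry a
    decaying transient offset.
    """
    hrf = default_hrf(schedule.tr_s, schedule.block_s, schedule.n_periods) \
        if hrf is None else hrf
    noise = NoiseSpec() if noise is None else noise
    rng = np.random.default_rng(noise.seed)
    n_ret = schedule.n_retained
    nx, ny, nz = scene.grid_shape
    n_vox = nx * ny * nz

    reg = hrf.convolve(schedule.boxcar())
    reg_c = reg - reg.mean()

    amp = np.zeros(n_vox)
    for spec in scene.rois:
        a = spec.amp_contrast if contrast == "contrast" else spec.amp_blank
        flat = np.ravel_multi_index(tuple(scene.roi_voxels(spec.label).T),
                                    scene.grid_shape)
        amp[flat] = a

    data = scene.baseline * (1.0 + amp[:, None] / 100.0 * reg_c[None, :])
    if noise.white_sd_pct > 0 or noise.drift_pct > 0:
        data = data + _voxel_noise(rng, n_vox, n_ret, noise, scene.baseline)

    # dummy volumes: steady-state transient decaying over ~2 TRs
    if schedule.n_dummy > 0:
        k = np.arange(schedule.n_dummy)
        transient = 0.03 * scene.baseline * np.exp(-k / 2.0)
        dummies = data[:, :1] + transient[None, ::-1]
        data = np.concatenate([dummies, data], axis=1)

    run = BoldRun(
        data.reshape(nx, ny, nz, -1), schedule.tr_s, schedule.n_dummy,
        scene.voxel_size_mm, schedule,
    )

    mspec = dict(motion_spec or {})
    mspec.setdefault("seed", int(rng.integers(2 ** 31 - 1)))
    trace, spike_idx = simulate_motion_trace(
        n_timepoints=schedule.n_total, tr_s=schedule.tr_s, **mspec
    )

    truth = GroundTruth(
        amplitudes={
            s.label: (s.amp_contrast if contrast == "contrast" else s.amp_blank)
            for s in scene.rois
        },
        phase_deg=fundamental_phase_deg(hrf, schedule),
        membership=scene.membership_map(),
        spike_indices=spike_idx,
        regressor=reg_c,
    )
    return run, trace, truth


def simulate_motion_trace(
    n_timepoints: int,
    drift_sd: float = 0.03,
    spike_rate: float = 0.0,
    spike_mag: float = 2.0,
    seed: int = 0,
    tr_s: float = 3.0,
    n_spikes: int | None = None,
    spike_indices: list[int] | None = None,
) -> tuple[MotionTrace, list[int]]:
    """Six-parameter head-motion trace: smooth wander plus step spikes.

    The wander is white noise smoothed with a Gaussian kernel (stationary,
    SD ``drift_sd`` mm for translations and an equivalent arc length for
    rotations).  Spikes are persistent position steps of ``spike_mag`` mm
    applied to the x translation with alternating sign, at ``spike_indices``
    if given, else drawn at rate ``spike_rate`` per time point (or exactly
    ``n_spikes``).  Returns the trace and the spike indices.
    """
    if drift_sd < 0 or spike_rate < 0 or spike_mag < 0:
        raise ValueError("rates and magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_timepoints
    kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
    kernel /= kernel.sum()

    def wander(sd: float) -> np.ndarray:
        raw = rng.standard_normal(n + len(kernel))
        sm = np.convolve(raw, kernel, mode="same")[: n]
        return sm / max(sm.std(), 1e-12) * sd

    params = np.column_stack(
        [wander(drift_sd) for _ in range(3)]
        + [wander(np.rad2deg(drift_sd / 50.0)) for _ in range(3)]
    )

    if spike_indices is None:
        if n_spikes is not None:
            k = n_spikes
        else:
            k = int(rng.binomial(n - 2, spike_rate))
        spike_indices = sorted(
            rng.choice(np.arange(1, n - 1), size=min(k, n - 2), replace=False)
        ) if k > 0 else []
    spike_indices = [int(i) for i in spike_indices]
    for m, idx in enumerate(spike_indices):
        params[idx:, 0] += spike_mag * (1 if m % 2 == 0 else -1)
    return MotionTrace(params, tr_s), spike_indices


def default_rest_corr() -> np.ndarray:
    """Imposed ROI-pair correlation structure for rest, in the fixed ROI
    order: strong homotopic (interhemispheric) coupling for MT+, V6 and
    PIVC, moderate V1-V6 coupling, weak V1-MT+/PIVC coupling."""
    c = np.eye(7)

    def setr(a, b, r):
        i, j = ROI_ORDER.index(a), ROI_ORDER.index(b)
        c[i, j] = c[j, i] = r

    setr("MT+ R", "MT+ L", 0.7)
    setr("V6 R", "V6 L", 0.7)
    setr("PIVC R", "PIVC L", 0.6)
    setr("V1", "V6 R", 0.4)
    setr("V1", "V6 L", 0.4)
    for a in ("MT+ R", "MT+ L"):
        setr("V1", a, 0.1)
        for b in ("V6 R", "V6 L"):
            setr(a, b, 0.3)
        for b in ("PIVC R", "PIVC L"):
            setr(a, b, 0.3)
    setr("V1", "PIVC R", 0.1)
    setr("V1", "PIVC L", 0.1)
    for a in ("V6 R", "V6 L"):
        for b in ("PIVC R", "PIVC L"):
            setr(a, b, 0.2)
    # validity check at construction
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError("default rest correlation matrix is not PSD")
    return c


def simulate_rest_timecourses(
    target_corr: np.ndarray,
    n_timepoints: int,
    signal_sd_pct: float = 1.0,
    noise_sd_pct: float = 0.0,
    ar1: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Latent ROI series with population correlation ``target_corr``.

    Returns the (n_timepoints, n_rois) series (percent units) and the
    attenuation factor ``signal_var / (signal_var + noise_var)`` by which
    added independent measurement noise of SD ``noise_sd_pct`` shrinks the
    observed correlations.
    """
    C = np.asarray(target_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("target correlation must be square")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("target correlation must be symmetric with unit diagonal")
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-10:
        raise ValueError("target correlation matrix is not positive semidefinite")
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((C.shape[0], n_timepoints))
    lat = L @ _ar1_filter(z, ar1)  # same filter per row keeps the correlation
    lat = lat / lat.std(axis=1, keepdims=True).clip(1e-12) * signal_sd_pct
    if noise_sd_pct > 0:
        lat = lat + rng.standard_normal(lat.shape) * noise_sd_pct
    atten = signal_sd_pct ** 2 / (signal_sd_pct ** 2 + noise_sd_pct ** 2)
    return lat.T, atten


def simulate_rest_run(
    scene: SceneSpec,
    target_corr: np.ndarray | None = None,
    n_timepoints: int = 124,
    n_dummy: int = 4,
    noise: NoiseSpec | None = None,
    signal_sd_pct: float = 1.0,
    seed: int = 0,
) -> tuple[BoldRun, GroundTruth]:
    """Simulate a resting run whose ROI mean series realise ``target_corr``.

    Latent signals from a Cholesky factorisation of the target drive all
    voxels of each ROI; independent per-voxel noise attenuates the observed
    ROI-mean correlations by ``signal_var / (signal_var + noise_var / K)``
    for a K-voxel ROI, which is reported in the ground truth.
    """
    target_corr = default_rest_corr() if target_corr is None else np.asarray(target_corr)
    noise = NoiseSpec() if noise is None else noise
    n_ret = n_timepoints - n_dummy
    lat, _ = simulate_rest_timecourses(
        target_corr, n_ret, signal_sd_pct, 0.0, noise.ar1, seed,
    )
    nx, ny, nz = scene.grid_shape
    n_vox = nx * ny * nz
    data = np.full((n_vox, n_ret), scene.baseline)
    k_min = None
    for j, label in enumerate(ROI_ORDER):
        try:
            vox = scene.roi_voxels(label)
        except KeyError:
            continue
        flat = np.ravel_multi_index(tuple(vox.T), scene.grid_shape)
        data[flat] += scene.baseline * lat[:, j] / 100.0
        k_min = len(flat) if k_min is None else min(k_min, len(flat))

    rng = np.random.default_rng(seed + 1)
    if noise.white_sd_pct > 0 or noise.drift_pct > 0:
        # white per-voxel noise: keeps the ROI-mean attenuation analytic
        white = NoiseSpec(noise.white_sd_pct, 0.0, noise.drift_pct, noise.seed)
        data = data + _voxel_noise(rng, n_vox, n_ret, white, scene.baseline)

    if n_dummy > 0:
        kk = np.arange(n_dummy)
        transient = 0.03 * scene.baseline * np.exp(-kk / 2.0)
        data = np.concatenate([data[:, :1] + transient[None, ::-1], data], axis=1)

    sigma_n2 = (noise.white_sd_pct ** 2) / max(k_min or 1, 1)
    atten = signal_sd_pct ** 2 / (signal_sd_pct ** 2 + sigma_n2)
    run = BoldRun(data.reshape(nx, ny, nz, -1), 3.0, n_dummy,
                  scene.voxel_size_mm)
    truth = GroundTruth(
        membership=scene.membership_map(),
        rest_corr=np.asarray(target_corr, float),
        rest_attenuation=atten,
    )
    return run, truth
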