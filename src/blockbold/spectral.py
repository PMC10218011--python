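"""ROI time-course extraction, period averaging and spectral statistics.

For each ROI the spatially averaged signal is converted to percent signal
change, split into stimulation periods (14 TRs at the default schedule),
and summarised two ways:

* a windowed mean response — the average over TRs 3..6 of the period
  (1-based, inclusive), i.e. 9–18 s after stimulus onset, where the
  hemodynamic response plateaus;
* a spectral summary — the discrete Fourier amplitude and phase at the
  fundamental stimulus frequency.  SNR is the amplitude at the fundamental
  divided by the root-mean-square amplitude of the two adjacent frequency
  bins; the phase is reported relative to the stimulus boxcar so that a
  canonical hemodynamic response reads 64 degrees and later responses read
  larger phases.

Phases are averaged on the circle: the group mean is the angle of the
resultant of the (optionally SNR-weighted) unit vectors and the angular SD
is the RMS of wrapped deviations from that mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BoldRun, ConditionSchedule, Roi
from .motion import ScreenResult

RESPONSE_WINDOW_TR = (3, 6)  # 1-based, inclusive


@dataclass
class RoiTimecourse:
    """Percent-signal-change series of one ROI over the retained run."""

    values: np.ndarray
    schedule: ConditionSchedule
    roi_label: str = ""


def extract_timecourse(run: BoldRun, roi: Roi) -> RoiTimecourse:
    """Spatial mean over the ROI, as percent of its temporal mean."""
    if run.schedule is None:
        raise ValueError("run carries no condition schedule")
    ret = run.retained()
    series = ret[tuple(roi.voxels.T)].mean(axis=0)
    base = series.mean()
    if base == 0:
        raise ValueError("ROI temporal mean is zero; cannot form percent change")
    pct = 100.0 * (series / base - 1.0)
    return RoiTimecourse(pct, run.schedule, roi.label)


def split_periods(
    tc: RoiTimecourse,
    screen_result: ScreenResult | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Reshape the series into periods and list the good ones.

    A period is good iff all of its time points lie inside one retained
    still interval of the screening result.  Returns the full
    (n_periods, period_tr) matrix and the good-period indices.
    """
    sched = tc.schedule
    if len(tc.values) != sched.n_retained:
        raise ValueError("series length does not match the schedule")
    periods = tc.values.reshape(sched.n_periods, sched.period_tr)
    if screen_result is None or screen_result.verdict == "keep":
        good = list(range(sched.n_periods))
    else:
        good = []
        for p in range(sched.n_periods):
            a, b = p * sched.period_tr, (p + 1) * sched.period_tr
            if any(ia <= a and b <= ib for ia, ib in screen_result.intervals):
                good.append(p)
    if not good:
        raise ValueError("no complete stimulation period survives screening")
    return periods, good


@dataclass
class PeriodAverage:
    """Per-TR mean and SD across the good periods."""

    mean: np.ndarray
    sd: np.ndarray
    n_periods: int


def period_average(periods: np.ndarray, good: list[int] | None = None) -> PeriodAverage:
    sel = periods if good is None else periods[good]
    if sel.shape[0] < 1:
        raise ValueError("need at least one good period")
    sd = sel.std(axis=0, ddof=1) if sel.shape[0] > 1 else np.zeros(sel.shape[1])
    return PeriodAverage(sel.mean(axis=0), sd, sel.shape[0])


def mean_response(
    period_avg: PeriodAverage, window: tuple[int, int] = RESPONSE_WINDOW_TR
) -> float:
    """Mean of the period-average over the inclusive 1-based TR window."""
    lo, hi = window
    if lo < 1 or hi > len(period_avg.mean) or lo > hi:
        raise ValueError("window outside the period")
    return float(period_avg.mean[lo - 1: hi].mean())


@dataclass
class SpectralSummary:
    """SNR and phase of the fundamental stimulus frequency for one ROI."""

    snr: float
    phase_deg: float
    fundamental: int
    p: float
    amplitude: float
    roi_label: str = ""
    hemisphere: str = ""


def _boxcar_phase_rad(n_periods: int, period_tr: int) -> float:
    """Fundamental-bin phase of the 1/0 C1 boxcar with the given layout."""
    block = period_tr // 2
    box = np.tile(np.r_[np.ones(block), np.zeros(period_tr - block)], n_periods)
    return float(np.angle(np.fft.rfft(box)[n_periods]))


def spectral_summary(
    tc: RoiTimecourse | np.ndarray,
    n_periods: int | None = None,
    period_tr: int | None = None,
    good: list[int] | None = None,
    roi_label: str = "",
    hemisphere: str = "",
) -> SpectralSummary:
    """FFT SNR and phase at the fundamental frequency.

    Good periods are concatenated in order before the FFT so the fundamental
    falls on an exact bin (one cycle per period).  SNR is
    |A(f0)| / RMS(|A(f0-1)|, |A(f0+1)|); the significance p compares the
    fundamental power with the mean neighbour power through an F(2, 4)
    ratio, each bin power being a scaled chi-square(2) under Gaussian noise.
    Phase is measured relative to the C1-onset boxcar, positive = delayed,
    mapped to [0, 360).
    """
    if isinstance(tc, RoiTimecourse):
        sched = tc.schedule
        period_tr = sched.period_tr
        periods = tc.values.reshape(sched.n_periods, period_tr)
        if good is not None:
            periods = periods[good]
        series = periods.reshape(-1)
        n_periods = periods.shape[0]
        roi_label = roi_label or tc.roi_label
    else:
        series = np.asarray(tc, dtype=float)
        if n_periods is None or period_tr is None:
            raise ValueError("raw series needs n_periods and period_tr")
        if len(series) != n_periods * period_tr:
            raise ValueError("series length != n_periods * period_tr")
    if n_periods < 2:
        raise ValueError("need >= 2 periods: neighbour bins are undefined")

    spec = np.fft.rfft(series)
    k = n_periods
    amp = np.abs(spec[k])
    neigh = np.sqrt((np.abs(spec[k - 1]) ** 2 + np.abs(spec[k + 1]) ** 2) / 2.0)
    snr = float(amp / neigh) if neigh > 0 else float("inf")
    p = float(stats.f.sf(snr ** 2, 2, 4)) if np.isfinite(snr) else 0.0
    ref = _boxcar_phase_rad(n_periods, period_tr)
    phase = float(np.rad2deg(ref - np.angle(spec[k])) % 360.0)
    # normalised amplitude: fundamental cosine amplitude in percent units
    amp_pct = float(2.0 * amp / len(series))
    return SpectralSummary(snr, phase, k, p, amp_pct, roi_label, hemisphere)


def circular_mean_sd(
    phases_deg: np.ndarray | list[float],
    weights: np.ndarray | list[float] | None = None,
) -> tuple[float, float]:
    """Circular mean and angular SD via the resultant vector.

    The mean is the angle of the (weighted) resultant of the phase unit
    vectors; the SD is the root-mean-square of the wrapped deviations of
    each phase from the mean, deviations taken in (-180, 180].
    """
    ph = np.atleast_1d(np.asarray(phases_deg, dtype=float))
    if ph.size == 0:
        raise ValueError("need at least one phase")
    w = np.ones_like(ph) if weights is None else np.atleast_1d(np.asarray(weights, float))
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    rad = np.deg2rad(ph)
    res = np.sum(w * np.exp(1j * rad))
    if np.abs(res) < 1e-12 * max(w.sum(), 1.0):
        raise ValueError("zero resultant: circular mean undefined")
    mean = float(np.rad2deg(np.angle(res)) % 360.0)
    dev = wrap_deg(ph - mean)
    sd = float(np.sqrt(np.sum(w * dev ** 2) / w.sum()))
    return mean, sd


def wrap_deg(angles: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles in degrees to (-180, 180]."""
    return -((-np.asarray(angles) + 180.0) % 360.0 - 180.0)


def compare_groups(
    group_a: list[SpectralSummary] | np.ndarray,
    group_b: list[SpectralSummary] | np.ndarray,
    measure: str = "amplitude",
) -> tuple[float, float]:
    """Two-tailed two-sample comparison of amplitudes or phases.

    Amplitudes are compared with a standard two-sample t test.  Phases are
    compared on the circle: each group's phases are linearised as its
    circular mean plus wrapped deviations (small-dispersion approximation),
    the mean difference itself wrapped, and a pooled-variance t statistic
    formed.  Returns (statistic, two-sided p).
    """

    def pull(g, attr):
        if len(g) and isinstance(g[0], SpectralSummary):
            return np.array([getattr(s, attr) for s in g])
        return np.asarray(g, dtype=float)

    if measure == "amplitude":
        a, b = pull(group_a, "amplitude"), pull(group_b, "amplitude")
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs at least 2 members")
        if a.std() == 0 and b.std() == 0:
            return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        t, p = stats.ttest_ind(a, b)
        return float(t), float(p)
    if measure != "phase":
        raise ValueError("measure must be 'amplitude' or 'phase'")

    a, b = pull(group_a, "phase_deg"), pull(group_b, "phase_deg")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 members")
    mean_a, _ = circular_mean_sd(a)
    mean_b, _ = circular_mean_sd(b)
    dev_a = wrap_deg(a - mean_a)
    dev_b = wrap_deg(b - mean_b)
    diff = float(wrap_deg(mean_a - mean_b))
    na, nb = a.size, b.size
    ss = float((dev_a ** 2).sum() + (dev_b ** 2).sum())
    df = na + nb - 2
    if ss == 0:
        return (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
    se = np.sqrt(ss / df * (1.0 / na + 1.0 / nb))
    t = diff / se
    return float(t), float(2.0 * stats.t.sf(abs(t), df))
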