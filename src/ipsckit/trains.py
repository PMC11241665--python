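"""High-frequency train analysis: tonic/phasic decomposition, cumulative
phasic charge, biphasic linear fits, RRP back-extrapolation and recovery.

The cumulative charge of responses to a 100-pulse, 100 Hz train is biphasic:
a steep initial phase while the release-ready vesicle pool empties, then a
slower quasi-linear phase sustained by pool replenishment.  A straight line
fit to each phase and extrapolated to the train onset gives, as y-intercept,
an estimate of the pool available at onset (first phase: the tightly docked
subset; second phase: the whole readily releasable pool), while the slope of
the late fit estimates the replenishment rate.

Charges are normalized per cell to the first response's charge, so
y-intercepts are dimensionless ("first-response equivalents") and slopes are
normalized charge per second.  Supplying the quantal charge converts both to
vesicle counts / vesicles per second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .traces import SweepTrace, blank_artifact, estimate_baseline

__all__ = [
    "PhaseFit",
    "TrainResult",
    "tonic_phasic_split",
    "per_pulse_phasic_charge",
    "cumulative_series",
    "fit_biphasic",
    "rrp_report",
    "recovery_analysis",
    "analyze_train",
]

BLANK_MS = 0.5
ANCHOR_MS = 0.5          # pre-stimulus window feeding the tonic envelope
LAST_WINDOW_MS = 10.0    # charge window after the final train pulse
DEFAULT_PHASE1 = (2, 10)
DEFAULT_PHASE2 = (60, 100)


@dataclass
class PhaseFit:
    """OLS line over one phase of the normalized cumulative charge.

    ``slope`` is normalized charge per second; ``y_intercept`` the line's
    value extrapolated to the time of the first train pulse.
    """

    pulse_range: tuple[int, int]   # 1-based, inclusive
    slope: float
    y_intercept: float
    r_squared: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        first, last = self.pulse_range
        if not (last > first >= 1):
            raise ValueError("need last > first >= 1")
        if last - first + 1 < 3:
            raise ValueError("phase fit needs >= 3 points")


@dataclass
class TrainResult:
    """Full train decomposition for one cell."""

    charges: np.ndarray             # per-pulse phasic charges, pC
    tonic_charge: float             # envelope integral over the train, pC
    cumulative: np.ndarray          # normalized C_k (C_1 = 1)
    phase1: PhaseFit
    phase2: PhaseFit
    recovery: list[tuple[float, float]] = field(default_factory=list)
    recovery_tau: float | None = None
    flags: list[str] = field(default_factory=list)


def tonic_phasic_split(
    trace: SweepTrace,
) -> tuple[SweepTrace, np.ndarray, float]:
    """Split a train sweep into phasic trace and tonic envelope.

    The tonic envelope interpolates anchor values — the median of the 0.5 ms
    immediately preceding each stimulus, relative to the pre-train baseline —
    piecewise-linearly across the train.  Returns ``(phasic_trace,
    envelope_pA, tonic_charge_pC)``; the phasic trace is the blanked sweep
    minus baseline and envelope.
    """
    if trace.protocol != "train" or trace.stim_times.size < 100:
        raise ValueError("tonic/phasic split expects a train sweep "
                         "(>= 100 stimuli)")
    stim = trace.stim_times
    n_train = _n_train_pulses(stim)
    train_stim = stim[:n_train]
    if np.min(np.diff(train_stim)) < 2.0:
        raise ValueError("stimulus spacing < 2 ms; cannot anchor the envelope")

    clean = blank_artifact(trace, BLANK_MS)
    t_first = float(train_stim[0])
    base_win = (max(trace.t0, t_first - 26.0), t_first - 1.0)
    baseline = estimate_baseline(clean, base_win)

    anchors_t = np.empty(n_train + 2)
    anchors_v = np.empty(n_train + 2)
    anchors_t[0], anchors_v[0] = t_first, 0.0
    for k, t_k in enumerate(train_stim):
        seg = clean.slice_window(t_k - ANCHOR_MS, t_k)
        anchors_t[k + 1] = t_k
        anchors_v[k + 1] = float(np.median(seg)) - baseline
    anchors_v[1] = 0.0  # nothing tonic before the first pulse
    t_end = float(train_stim[-1]) + LAST_WINDOW_MS
    anchors_t[-1], anchors_v[-1] = t_end, anchors_v[-2]
    # strictly increasing x for interpolation
    anchors_t[0] -= 1e-9

    tt = clean.times()
    envelope = np.interp(tt, anchors_t, anchors_v, left=0.0, right=0.0)
    envelope[tt > t_end] = 0.0

    phasic = clean.copy()
    phasic.samples = clean.samples - baseline - envelope
    in_train = (tt >= t_first) & (tt < t_end)
    tonic_charge = abs(float(np.sum(np.minimum(envelope[in_train], 0.0)))
                       * clean.dt) / 1000.0
    return phasic, envelope, tonic_charge


def _n_train_pulses(stim: np.ndarray) -> int:
    """Number of leading regularly spaced train pulses (rest are recovery)."""
    gaps = np.diff(stim)
    isi = float(np.median(gaps[: min(20, gaps.size)]))
    bigger = np.flatnonzero(gaps > 1.8 * isi)
    return int(bigger[0]) + 1 if bigger.size else stim.size


def per_pulse_phasic_charge(
    phasic: SweepTrace,
    stim_times: np.ndarray | None = None,
    blank_ms: float = BLANK_MS,
) -> np.ndarray:
    """Rectified phasic charge per train pulse, pC.

    ``Q_k`` integrates the phasic trace over ``[t_k + blank, t_{k+1})`` (the
    final pulse uses a 10 ms window), clipping positive-going excursions, so
    all charges are >= 0.
    """
    stim = phasic.stim_times if stim_times is None else np.asarray(stim_times)
    n_train = _n_train_pulses(stim)
    train_stim = stim[:n_train]
    dt = phasic.dt
    q = np.empty(n_train)
    for k, t_k in enumerate(train_stim):
        t_stop = train_stim[k + 1] if k + 1 < n_train else t_k + LAST_WINDOW_MS
        i0 = phasic.index_of(t_k + blank_ms)
        i1 = phasic.index_of(min(t_stop, phasic.t_end))
        seg = np.minimum(phasic.samples[i0:i1], 0.0)
        q[k] = abs(float(np.sum(seg)) * dt) / 1000.0
    return q


def cumulative_series(charges: np.ndarray) -> np.ndarray:
    """Normalized cumulative charge ``C_k = sum_{i<=k} Q_i / Q_1`` (C_1 = 1)."""
    q = np.asarray(charges, float)
    if q.size == 0 or q[0] <= 0:
        raise ValueError("first-pulse charge must be positive; "
                         "cell excluded from normalized analysis")
    return np.cumsum(q) / q[0]


def _ols_phase(c: np.ndarray, t_s: np.ndarray, first: int, last: int
               ) -> PhaseFit:
    """OLS over 1-based pulse window [first, last]; intercept at t of pulse 1."""
    idx = np.arange(first - 1, last)
    x, y = t_s[idx], c[idx]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PhaseFit(pulse_range=(first, last), slope=float(slope),
                    y_intercept=float(intercept), r_squared=r2)


def fit_biphasic(
    cumulative: np.ndarray,
    stim_times: np.ndarray,
    phase1: tuple[int, int] = DEFAULT_PHASE1,
    phase2: tuple[int, int] = DEFAULT_PHASE2,
    auto_breakpoint: bool = False,
) -> tuple[PhaseFit, PhaseFit]:
    """Two straight-line fits to the normalized cumulative charge.

    The time axis is seconds relative to the first train pulse, so the
    y-intercept is the line's value at train onset.  With
    ``auto_breakpoint=True`` the windows become ``[2, b]`` / ``[b+1, last]``
    with the breakpoint ``b`` chosen in pulses 5-50 to minimize the total
    two-segment squared error.  A result where the early slope does not
    exceed the late slope is flagged ``no_steep_phase``.
    """
    c = np.asarray(cumulative, float)
    if c.size < 100:
        raise ValueError("biphasic fit expects >= 100 cumulative points")
    stim = np.asarray(stim_times, float)[: c.size]
    t_s = (stim - stim[0]) / 1000.0

    if auto_breakpoint:
        last = c.size
        best_b, best_sse = None, np.inf
        for b in range(5, 51):
            f1 = _ols_phase(c, t_s, 2, b)
            f2 = _ols_phase(c, t_s, b + 1, last)
            sse = _phase_sse(c, t_s, f1) + _phase_sse(c, t_s, f2)
            if sse < best_sse:
                best_b, best_sse = b, sse
        phase1 = (2, best_b)
        phase2 = (best_b + 1, last)

    fit1 = _ols_phase(c, t_s, *phase1)
    fit2 = _ols_phase(c, t_s, *phase2)
    if fit1.slope <= fit2.slope:
        warnings.warn("no steep early phase: phase-1 slope <= phase-2 slope",
                      stacklevel=2)
        fit1.flags.append("no_steep_phase")
        fit2.flags.append("no_steep_phase")
    return fit1, fit2


def _phase_sse(c: np.ndarray, t_s: np.ndarray, fit: PhaseFit) -> float:
    idx = np.arange(fit.pulse_range[0] - 1, fit.pulse_range[1])
    pred = fit.slope * t_s[idx] + fit.y_intercept
    return float(np.sum((c[idx] - pred) ** 2))


@dataclass
class RRPReport:
    """Back-extrapolation estimates, normalized and (optionally) in vesicles."""

    rrp_tight: float            # phase-1 y-intercept, first-response units
    rrp_total: float            # phase-2 y-intercept
    replenish_norm: float       # phase-2 slope, normalized charge / s
    rrp_tight_vesicles: float | None = None
    rrp_total_vesicles: float | None = None
    replenish_vesicles_s: float | None = None
    flags: list[str] = field(default_factory=list)


def rrp_report(
    phase1: PhaseFit,
    phase2: PhaseFit,
    q1_charge: float | None = None,
    q_charge: float | None = None,
) -> RRPReport:
    """Interpret the phase fits as pool sizes and replenishment rate.

    With the first-response charge ``q1_charge`` and the quantal charge
    ``q_charge`` supplied, normalized estimates are also expressed as vesicle
    counts (intercept * Q1 / q) and vesicles per second.
    """
    rep = RRPReport(rrp_tight=phase1.y_intercept,
                    rrp_total=phase2.y_intercept,
                    replenish_norm=phase2.slope,
                    flags=sorted(set(phase1.flags) | set(phase2.flags)))
    if q1_charge is not None and q_charge is not None and q_charge > 0:
        scale = q1_charge / q_charge
        rep.rrp_tight_vesicles = phase1.y_intercept * scale
        rep.rrp_total_vesicles = phase2.y_intercept * scale
        rep.replenish_vesicles_s = phase2.slope * scale
    return rep


def recovery_analysis(
    intervals_ms: np.ndarray,
    q_recovery: np.ndarray,
    q_first: float,
    q_steady: float,
) -> tuple[np.ndarray, float]:
    """Recovery fractions after the train and a single-exponential time constant.

    ``fraction_i = (Q_rec,i - Q_ss) / (Q_1 - Q_ss)`` clipped to [0, 1.5];
    the refill time constant comes from fitting ``1 - exp(-t / tau)``.
    Raises when the steady-state charge is not below the first response.
    """
    t = np.asarray(intervals_ms, float)
    qr = np.asarray(q_recovery, float)
    if t.size < 3:
        raise ValueError("need >= 3 recovery intervals")
    if q_first <= q_steady:
        raise ValueError("Q_1 <= steady-state charge; recovery undefined")
    frac = np.clip((qr - q_steady) / (q_first - q_steady), 0.0, 1.5)
    if np.all(frac >= 1.0):
        return frac, 0.0

    def model(tt, tau):
        return 1.0 - np.exp(-tt / tau)

    popt, _ = optimize.curve_fit(model, t, frac, p0=[300.0],
                                 bounds=(1e-6, 1e7), maxfev=5000)
    return frac, float(popt[0])


def analyze_train(
    trace: SweepTrace,
    phase1: tuple[int, int] = DEFAULT_PHASE1,
    phase2: tuple[int, int] = DEFAULT_PHASE2,
    auto_breakpoint: bool = False,
) -> TrainResult:
    """Full per-cell train pipeline: split, charges, cumulative, fits, recovery."""
    phasic, _env, tonic_q = tonic_phasic_split(trace)
    charges = per_pulse_phasic_charge(phasic)
    cum = cumulative_series(charges)
    fit1, fit2 = fit_biphasic(cum, trace.stim_times, phase1, phase2,
                              auto_breakpoint)

    result = TrainResult(charges=charges, tonic_charge=tonic_q,
                         cumulative=cum, phase1=fit1, phase2=fit2,
                         flags=sorted(set(fit1.flags) | set(fit2.flags)))

    stim = trace.stim_times
    n_train = _n_train_pulses(stim)
    rec_stim = stim[n_train:]
    if rec_stim.size >= 3:
        t_train_end = stim[n_train - 1]
        q_rec = np.empty(rec_stim.size)
        for i, t_k in enumerate(rec_stim):
            # local pre-pulse baseline absorbs any residual tonic current
            pre = phasic.slice_window(t_k - 2.0, t_k - 0.2)
            local = float(np.median(pre))
            i0 = phasic.index_of(t_k + BLANK_MS)
            i1 = phasic.index_of(min(t_k + LAST_WINDOW_MS, phasic.t_end))
            seg = np.minimum(phasic.samples[i0:i1] - local, 0.0)
            q_rec[i] = abs(float(np.sum(seg)) * phasic.dt) / 1000.0
        q_ss = float(np.mean(charges[-10:]))
        try:
            frac, tau = recovery_analysis(rec_stim - t_train_end, q_rec,
                                          float(charges[0]), q_ss)
            result.recovery = list(zip((rec_stim - t_train_end).tolist(),
                                       frac.tolist()))
            result.recovery_tau = tau
        except ValueError:
            result.flags.append("recovery_undefined")
    return result
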