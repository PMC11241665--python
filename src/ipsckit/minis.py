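"""Spontaneous (miniature) IPSC detection and kinetics.

Detection is two-stage: candidate onsets are found where the low-pass-filtered
derivative crosses a robust (MAD-scaled) threshold in the event polarity, and
each candidate is confirmed by normalized cross-correlation of its derivative
with a template built from the configured kinetics.  Per-cell kinetics come
from a biexponential fit to the trough-normalized mean waveform, which is how
group statistics are computed; optional per-event fits are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .synthgen import EventKinetics, make_kernel
from .traces import SweepTrace

__all__ = [
    "DetectionConfig",
    "MiniEvent",
    "MiniCellSummary",
    "detect_minis",
    "rise_time",
    "fit_biexp_decay",
    "decay_segment",
    "iei_cdf",
    "mean_normalized_waveform",
    "summarize_cell",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables of the two-stage mini detector (all constants live here)."""

    k_deriv: float = 4.0          # derivative threshold, multiples of MAD scale
    corr_min: float = 0.6         # template cross-correlation acceptance
    refractory_ms: float = 2.0    # events closer than this are merged
    lowpass_khz: float = 1.0      # pre-filter cutoff
    template_ms: float = 3.0      # derivative-template correlation window
    baseline_ms: float = 10.0     # pre-event baseline window
    peak_search_ms: float = 5.0   # onset -> peak search window
    abs_deriv_floor: float = 5.0  # pA/ms fallback when noise estimate is zero
    k_amp: float = 3.0            # amplitude gate, multiples of raw noise sd
    kinetics: EventKinetics = field(
        default_factory=lambda: EventKinetics(0.25, 0.8, 1.3, 6.0))
    fit_event_decay: bool = False  # per-event biexponential fits (slow)


@dataclass
class MiniEvent:
    """One detected spontaneous event (times in ms, amplitude magnitude pA)."""

    onset: float
    peak_time: float
    amplitude: float
    rise_time_20_80: float
    decay_fit: tuple[float, float, float, float] | None = None  # a1,t1,a2,t2
    fit_quality: float | None = None
    #: candidates merged into this event within the refractory window; they
    #: count toward frequency but are excluded from kinetics averaging
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.peak_time <= self.onset:
            raise ValueError("peak_time must follow onset")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class MiniCellSummary:
    """Per-cell summary used for group comparison."""

    cell_id: str
    condition: str
    frequency: float          # Hz
    n_events: int
    duration_s: float
    median_amplitude: float   # pA
    median_rise_time: float   # ms
    a1: float | None = None   # from the mean-waveform decay fit
    tau1: float | None = None
    a2: float | None = None
    tau2: float | None = None


def _mad_scale(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _lowpass(samples: np.ndarray, dt: float, cutoff_khz: float) -> np.ndarray:
    nyq = 0.5 / dt  # kHz
    if cutoff_khz >= nyq:
        return samples.copy()
    sos = signal.butter(4, cutoff_khz / nyq, output="sos")
    return signal.sosfiltfilt(sos, samples)


def detect_minis(trace: SweepTrace, cfg: DetectionConfig | None = None
                 ) -> list[MiniEvent]:
    """Detect spontaneous inward events; output sorted by onset.

    Raises on recordings shorter than 1 s.  With a zero noise estimate
    (noise-free synthetic input) the derivative threshold falls back to
    ``cfg.abs_deriv_floor``.
    """
    cfg = cfg or DetectionConfig()
    if trace.duration_s < 1.0:
        raise ValueError("recording shorter than 1 s")
    dt = trace.dt
    # raw-noise scale from first differences (robust to events); a noise-free
    # trace needs no pre-filtering, which keeps onsets sample-accurate
    sigma_raw = _mad_scale(np.diff(trace.samples)) / np.sqrt(2.0)
    if sigma_raw > 1e-12:
        filt = _lowpass(trace.samples, dt, cfg.lowpass_khz)
    else:
        filt = trace.samples.astype(float)
    deriv = np.gradient(filt) / dt  # pA/ms

    sigma = _mad_scale(deriv)
    thr = cfg.k_deriv * sigma if sigma > 1e-9 else cfg.abs_deriv_floor

    below = deriv < -thr
    edges = np.flatnonzero(np.diff(below.astype(np.int8)) == 1) + 1
    if below.size and below[0]:
        edges = np.concatenate([[0], edges])

    # template stage: correlate the local derivative with the derivative of
    # an identically filtered kernel, both aligned at their derivative trough
    tmpl = -make_kernel(cfg.kinetics, dt)  # negative-going, like the events
    tmpl_f = _lowpass(np.concatenate([np.zeros(tmpl.size // 2), tmpl]),
                      dt, cfg.lowpass_khz)
    tmpl_d = np.gradient(tmpl_f) / dt
    j_t = int(np.argmin(tmpl_d))
    n_pre = int(round(1.0 / dt))
    n_post = int(round(max(cfg.template_ms - 1.0, 1.0) / dt))
    tmpl_seg = tmpl_d[j_t - n_pre:j_t + n_post]
    tmpl_seg = tmpl_seg - tmpl_seg.mean()
    tmpl_norm = float(np.sqrt(np.sum(tmpl_seg**2)))
    n_align = int(round(1.5 / dt))  # derivative-trough search after crossing

    onsets: list[int] = []
    for i0 in edges:
        j = i0 + int(np.argmin(deriv[i0:i0 + n_align]))
        seg = deriv[j - n_pre:j + n_post]
        if seg.size < n_pre + n_post:
            continue
        segc = seg - seg.mean()
        denom = float(np.sqrt(np.sum(segc**2))) * tmpl_norm
        if denom == 0:
            continue
        corr = float(np.dot(segc, tmpl_seg)) / denom
        if corr >= cfg.corr_min:
            onsets.append(int(i0))

    # merge events within the refractory window, remembering multiplicity
    merged: list[int] = []
    extra: list[int] = []
    refr = int(round(cfg.refractory_ms / dt))
    for i in onsets:
        if merged and i - merged[-1] < refr:
            extra[-1] += 1
            continue
        merged.append(i)
        extra.append(0)

    n_base = int(round(cfg.baseline_ms / dt))
    n_peak = int(round(cfg.peak_search_ms / dt))
    amp_floor = cfg.k_amp * sigma_raw
    events: list[MiniEvent] = []
    for j, i0 in enumerate(merged):
        b0 = max(0, i0 - n_base)
        if j > 0:  # do not let the previous event's peak leak into baseline
            b0 = max(b0, merged[j - 1] + n_peak // 2)
        base = float(np.median(filt[b0:i0])) if i0 > b0 else float(filt[i0])
        p_stop = min(filt.size, i0 + n_peak)
        i_peak = i0 + int(np.argmin(filt[i0:p_stop]))
        amp = base - float(filt[i_peak])
        if amp <= 0 or amp < amp_floor:
            continue
        seg_t = (np.arange(i0, i_peak + 1) - i0) * dt
        seg_y = base - filt[i0:i_peak + 1]  # magnitude, rising to peak
        try:
            rt = rise_time(seg_t, seg_y)
        except ValueError:
            rt = dt
        ev = MiniEvent(onset=trace.t0 + i0 * dt,
                       peak_time=trace.t0 + max(i_peak, i0 + 1) * dt,
                       amplitude=amp, rise_time_20_80=rt,
                       multiplicity=1 + extra[j])
        if cfg.fit_event_decay:
            stop = min(filt.size, i_peak + int(round(25.0 / dt)))
            if j + 1 < len(merged):
                stop = min(stop, merged[j + 1])
            dec_t = (np.arange(i_peak, stop) - i_peak) * dt
            dec_y = (base - filt[i_peak:stop]) / amp
            if dec_t.size * dt >= 5.0:
                a1, t1, a2, t2, rss = fit_biexp_decay(dec_t, dec_y)
                ev.decay_fit = (a1, t1, a2, t2)
                ev.fit_quality = rss
        events.append(ev)
    return events


def rise_time(seg_t: np.ndarray, seg_y: np.ndarray) -> float:
    """20-80% rise time (ms) of a magnitude segment rising from ~0 to peak.

    Crossing times are linearly interpolated between samples; with a
    non-monotone rise the first 20% and the last 80% crossing before the peak
    are used.  A single-sample rise returns the sampling-interval bound.
    """
    seg_t = np.asarray(seg_t, float)
    seg_y = np.asarray(seg_y, float)
    if seg_t.size < 2:
        return float(seg_t[-1] - seg_t[0]) if seg_t.size else 0.0
    i_peak = int(np.argmax(seg_y))
    if i_peak == 0:
        return float(seg_t[1] - seg_t[0])
    peak = seg_y[i_peak]
    lo, hi = 0.2 * peak, 0.8 * peak

    def _cross(level: float, last: bool) -> float:
        idx = np.flatnonzero((seg_y[:i_peak] < level) &
                             (seg_y[1:i_peak + 1] >= level))
        if idx.size == 0:
            return seg_t[0] if not last else seg_t[i_peak]
        i = idx[-1] if last else idx[0]
        f = (level - seg_y[i]) / (seg_y[i + 1] - seg_y[i])
        return float(seg_t[i] + f * (seg_t[i + 1] - seg_t[i]))

    t20 = _cross(lo, last=False)
    t80 = _cross(hi, last=True)
    return max(t80 - t20, 0.0)


# ---------------------------------------------------------------------------
# Biexponential decay fitting
# ---------------------------------------------------------------------------

def _biexp(t: np.ndarray, a1: float, tau1: float, a2: float,
           tau2: float) -> np.ndarray:
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def _nnls_amplitudes(t: np.ndarray, y: np.ndarray, tau1: float,
                     tau2: float) -> tuple[float, float, float]:
    """Best nonnegative (a1, a2) for fixed time constants; returns (a1, a2, rss)."""
    basis = np.column_stack([np.exp(-t / tau1), np.exp(-t / tau2)])
    coef, rnorm = optimize.nnls(basis, y)
    return float(coef[0]), float(coef[1]), float(rnorm**2)


def _amplitudes_offset(t: np.ndarray, y: np.ndarray, tau1: float, tau2: float
                       ) -> tuple[float, float, float, float]:
    """(a1, a2, c, rss) with a1, a2 >= 0 and a free additive offset c."""
    e1, e2 = np.exp(-t / tau1), np.exp(-t / tau2)
    basis = np.column_stack([e1, e2, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    if coef[0] >= 0 and coef[1] >= 0:
        rss = float(np.sum((basis @ coef - y) ** 2))
        return float(coef[0]), float(coef[1]), float(coef[2]), rss
    # constrained fallback: drop the offending exponential
    best = None
    for cols, pick in (((e1,), 0), ((e2,), 1)):
        b = np.column_stack([*cols, np.ones_like(t)])
        cf, *_ = np.linalg.lstsq(b, y, rcond=None)
        if cf[0] < 0:
            continue
        rss = float(np.sum((b @ cf - y) ** 2))
        if best is None or rss < best[3]:
            a = [0.0, 0.0]
            a[pick] = float(cf[0])
            best = (a[0], a[1], float(cf[1]), rss)
    if best is None:
        a1, a2, rss = _nnls_amplitudes(t, y, tau1, tau2)
        best = (a1, a2, 0.0, rss)
    return best


def fit_biexp_decay(
    t: np.ndarray,
    y: np.ndarray,
    normalize: bool = False,
    n_tau_grid: int = 12,
    offset: bool = False,
) -> tuple[float, float, float, float, float]:
    """Least-squares biexponential fit of a decay segment.

    Fits ``y(t) = a1*exp(-t/tau1) + a2*exp(-t/tau2) [+ c]`` with
    ``a1, a2 >= 0`` and ``tau1 < tau2`` by variable projection: amplitudes
    are solved linearly on a log grid of (tau1, tau2) pairs, and the best
    grid starts are refined with a bounded local optimizer.  ``offset=True``
    adds a free additive constant that absorbs residual baseline bias (as in
    averaged waveforms from busy recordings).  Returns ``(a1, tau1, a2,
    tau2, rss)``; for a well-resolved single exponential the slow amplitude
    collapses to ~0 and the result degenerates gracefully.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 8 or t[-1] - t[0] < 5.0:
        raise ValueError("decay segment must span >= 5 ms")
    if normalize and y[0] != 0:
        y = y / y[0]

    def _solve(t1: float, t2: float) -> tuple[float, float, float]:
        if offset:
            a1, a2, _c, rss = _amplitudes_offset(t, y, t1, t2)
            return a1, a2, rss
        return _nnls_amplitudes(t, y, t1, t2)

    span = max(t[-1] - t[0], 1.0)
    taus = np.geomspace(max(2 * (t[1] - t[0]), 0.05), 2 * span, n_tau_grid)
    starts: list[tuple[float, float, float, float, float]] = []
    for i, t1 in enumerate(taus):
        for t2 in taus[i + 1:]:
            a1, a2, rss = _solve(t1, t2)
            starts.append((rss, t1, t2, a1, a2))
    starts.sort(key=lambda s: s[0])

    def _obj(log_taus: np.ndarray) -> float:
        t1 = np.exp(log_taus[0])
        t2 = t1 + np.exp(log_taus[1])
        return _solve(t1, t2)[2]

    best = None
    for rss0, t1, t2, a1, a2 in starts[:5]:
        res = optimize.minimize(
            _obj, x0=[np.log(t1), np.log(max(t2 - t1, 1e-3))],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400})
        t1f = float(np.exp(res.x[0]))
        t2f = t1f + float(np.exp(res.x[1]))
        a1f, a2f, rssf = _solve(t1f, t2f)
        if best is None or rssf < best[4]:
            best = (a1f, t1f, a2f, t2f, rssf)
    assert best is not None
    a1, tau1, a2, tau2, rss = best
    if a1 == 0.0 and a2 > 0.0:
        # degenerate single exponential landed on the slow component
        a1, tau1, a2, tau2 = a2, tau2, 0.0, 10.0 * tau2
    return a1, tau1, a2, tau2, rss


def iei_cdf(event_times: Sequence[float] | Sequence[MiniEvent]
            ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of inter-event intervals: (sorted IEIs, cumulative frac)."""
    times = np.asarray(
        [e.onset if isinstance(e, MiniEvent) else float(e)
         for e in event_times])
    if times.size < 2:
        raise ValueError("need >= 2 events for an IEI distribution")
    ieis = np.sort(np.diff(np.sort(times)))
    frac = np.arange(1, ieis.size + 1) / ieis.size
    return ieis, frac


def mean_normalized_waveform(
    trace: SweepTrace,
    events: Sequence[MiniEvent],
    pre_ms: float = 2.0,
    post_ms: float = 25.0,
    pre_clear_ms: float = 35.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-aligned average waveform, each event scaled to unit trough.

    Events are excluded when a neighbouring onset falls inside the segment or
    within ``pre_clear_ms`` before the peak — the latter keeps decay tails of
    preceding events from biasing the local baseline and the averaged decay.
    Raises unless >= 10 clean events remain.  Returns ``(t_rel_peak_ms,
    waveform)`` with trough value -1 (inward polarity preserved).
    """
    dt = trace.dt
    n_pre = int(round(pre_ms / dt))
    n_post = int(round(post_ms / dt))
    onsets = np.array([e.onset for e in events])
    acc = []
    for i, ev in enumerate(events):
        if ev.multiplicity > 1:
            continue
        i_peak = trace.index_of(ev.peak_time)
        if i_peak - n_pre < 0 or i_peak + n_post > trace.n_samples:
            continue
        # clean = no neighbouring onset in the segment or the pre-window
        lo_t, hi_t = ev.peak_time - max(pre_clear_ms, pre_ms), \
            ev.peak_time + post_ms
        mask = (onsets >= lo_t) & (onsets <= hi_t)
        if np.count_nonzero(mask) > 1:
            continue
        seg = trace.samples[i_peak - n_pre:i_peak + n_post].astype(float)
        base = np.median(seg[:max(1, n_pre // 2)])
        seg = seg - base
        trough = seg[n_pre]
        if trough >= 0:
            continue
        acc.append(seg / abs(trough))
    if len(acc) < 10:
        raise ValueError(f"only {len(acc)} clean events; need >= 10")
    w = np.mean(acc, axis=0)
    w /= abs(w.min())  # unit trough by construction
    t = (np.arange(-n_pre, n_post)) * dt
    return t, w


def summarize_cell(trace: SweepTrace, events: Sequence[MiniEvent],
                   decay_window_ms: float = 25.0) -> MiniCellSummary:
    """Cell-level summary; kinetics from the mean-waveform decay fit."""
    n = int(sum(e.multiplicity for e in events))
    summ = MiniCellSummary(
        cell_id=trace.cell_id, condition=trace.condition,
        frequency=n / trace.duration_s, n_events=n,
        duration_s=trace.duration_s,
        median_amplitude=float(np.median([e.amplitude for e in events]))
        if n else float("nan"),
        median_rise_time=float(np.median([e.rise_time_20_80 for e in events]))
        if n else float("nan"))
    try:
        t, w = mean_normalized_waveform(trace, events,
                                        post_ms=decay_window_ms)
    except ValueError:
        return summ
    dec_t, dec_y = decay_segment(w, trace.dt)
    a1, t1, a2, t2, _ = fit_biexp_decay(dec_t, dec_y, offset=True)
    summ.a1, summ.tau1, summ.a2, summ.tau2 = a1, t1, a2, t2
    return summ


#: decay fits start this long after the trough so the rising phase has
#: completed and does not masquerade as an extra fast component
DECAY_SKIP_MS = 1.0


def decay_segment(waveform: np.ndarray, dt: float,
                  skip_ms: float = DECAY_SKIP_MS
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Extract the decay of a trough-normalized waveform for biexp fitting.

    Returns ``(t, y)`` with ``t`` starting at zero ``skip_ms`` after the
    trough and ``y`` the positive-magnitude decay normalized to its first
    sample.
    """
    w = np.asarray(waveform, float)
    i0 = int(np.argmin(w)) + int(round(skip_ms / dt))
    if i0 >= w.size - 2:
        raise ValueError("waveform too short for a decay segment")
    y = -w[i0:]
    return (np.arange(w.size - i0) * dt), y / y[0]
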