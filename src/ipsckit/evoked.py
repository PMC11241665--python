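"""Evoked IPSC analysis: input-output calibration, single-stimulus charge /
CV / failures, pharmacology wash time course, and paired-pulse ratios with
overlap correction.

Charge windows follow the convention stimulus+2 ms to stimulus+100 ms (or the
next stimulus), with the baseline taken from the 10 ms preceding the
stimulus.  The paired-pulse ratio is amplitude-based by default: the first
response's biexponential decay is extrapolated under the second response and
subtracted before the second amplitude is read — essential at 10 ms ISI where
the responses overlap heavily.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .minis import DECAY_SKIP_MS, fit_biexp_decay, _biexp
from .synthgen import EventKinetics
from .traces import ChargeMeasure, SweepTrace, blank_artifact, \
    estimate_baseline, integrate_charge

__all__ = [
    "EvokedResponse",
    "PairedPulseResult",
    "measure_response",
    "io_curve",
    "single_stim_stats",
    "charge_timecourse",
    "paired_pulse_ratio",
]

CHARGE_START_MS = 2.0    # charge window start after the stimulus
CHARGE_END_MS = 100.0    # charge window end after the stimulus
FAIL_WIN = (2.0, 20.0)   # failure-classification peak-search window
FAIL_K = 3.0             # failure threshold, multiples of noise sd
BLANK_MS = 0.5           # stimulus-artifact blank


@dataclass
class EvokedResponse:
    """One stimulus' measured response (magnitudes; pA / pC / ms)."""

    stim_time: float
    amplitude: float
    charge: ChargeMeasure
    is_failure: bool
    latency: float

    def __post_init__(self) -> None:
        if not self.is_failure and self.amplitude <= 0:
            raise ValueError("non-failure response must have amplitude > 0")


@dataclass
class PairedPulseResult:
    """Amplitudes after overlap correction and their ratio."""

    isi: float
    ppr: float
    a1: float
    a2: float
    q1: float | None = None
    q2: float | None = None
    ppr_charge: float | None = None

    def __post_init__(self) -> None:
        if self.ppr <= 0:
            raise ValueError("ppr must be positive")


def _noise_sd(trace: SweepTrace, t_end: float, span_ms: float = 20.0) -> float:
    """Robust noise sd (pA) from a pre-stimulus stretch ending at ``t_end``."""
    t_start = max(trace.t0, t_end - span_ms)
    seg = trace.slice_window(t_start, t_end)
    return 1.4826 * float(np.median(np.abs(seg - np.median(seg))))


def measure_response(
    trace: SweepTrace,
    stim_time: float,
    window_end: float | None = None,
    noise_sd: float | None = None,
) -> EvokedResponse:
    """Amplitude, charge and failure classification for one stimulus.

    A response is a failure when the peak deviation inside the 2-20 ms
    post-stimulus window stays below ``FAIL_K`` times the noise sd.
    """
    clean = blank_artifact(trace, BLANK_MS)
    base_win = (max(trace.t0, stim_time - 10.0 - 1.0), stim_time - 1.0)
    baseline = estimate_baseline(clean, base_win)
    if noise_sd is None:
        noise_sd = _noise_sd(clean, stim_time - 1.0)

    w_end = stim_time + (window_end if window_end is not None else CHARGE_END_MS)
    w_end = min(w_end, clean.t_end)
    charge = integrate_charge(clean, (stim_time + CHARGE_START_MS, w_end),
                              baseline)

    seg = clean.slice_window(stim_time + FAIL_WIN[0],
                             min(stim_time + FAIL_WIN[1], clean.t_end))
    dev = baseline - seg  # inward events -> positive magnitudes
    i_peak = int(np.argmax(dev))
    amp = float(dev[i_peak])
    latency = FAIL_WIN[0] + i_peak * clean.dt
    is_failure = amp < FAIL_K * noise_sd
    return EvokedResponse(stim_time=stim_time,
                          amplitude=amp if not is_failure else max(amp, 0.0),
                          charge=charge, is_failure=is_failure,
                          latency=latency)


def io_curve(
    strengths: Sequence[float],
    charges: Sequence[float],
    target_fraction: float = 0.65,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Input-output curve and the calibration stimulus strength.

    Returns ``(strengths, charges, s_cal)`` where ``s_cal`` is the
    interpolated strength whose response is ``target_fraction`` of the
    maximum plateau.  If the curve is still rising > 10% per step at its last
    point, a warning is emitted and the last point is used as the maximum.
    """
    s = np.asarray(strengths, float)
    q = np.asarray(charges, float)
    if s.size < 4:
        raise ValueError("need >= 4 stimulus strengths")
    if np.any(np.diff(s) <= 0):
        raise ValueError("stimulus strengths must be strictly increasing")
    q_max = float(np.max(q))
    i_max = int(np.argmax(q))
    if i_max == s.size - 1 and s.size >= 2:
        prev = q[-2]
        if prev > 0 and (q[-1] - prev) / prev > 0.10:
            warnings.warn("no response plateau reached; using the last point "
                          "as the maximum", stacklevel=2)
    target = target_fraction * q_max
    if q_max == 0 or np.all(q >= target):
        return s, q, float(s[0])
    # first bracketing pair on the rising limb
    for i in range(s.size - 1):
        lo, hi = q[i], q[i + 1]
        if lo < target <= hi:
            f = (target - lo) / (hi - lo)
            return s, q, float(s[i] + f * (s[i + 1] - s[i]))
    return s, q, float(s[i_max])


def single_stim_stats(responses: Sequence[EvokedResponse]
                      ) -> tuple[float, float, float]:
    """(median charge pC, CV of non-failure charges, failure rate).

    CV is NaN (flagged) when every stimulus failed.
    """
    if len(responses) < 10:
        raise ValueError("need >= 10 responses")
    fails = sum(r.is_failure for r in responses)
    rate = fails / len(responses)
    qs = np.array([r.charge.q for r in responses if not r.is_failure])
    if qs.size == 0:
        return float("nan"), float("nan"), rate
    cv = float(np.std(qs, ddof=1) / np.mean(qs)) if qs.size > 1 else 0.0
    return float(np.median(qs)), cv, rate


def charge_timecourse(
    sweep_times_s: Sequence[float],
    charges: Sequence[float],
    baseline_span_s: tuple[float, float] | None = None,
    drug_span_s: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Per-sweep charge over experiment time, plus the drug block fraction.

    ``block = 1 - mean(Q drug plateau) / mean(Q baseline)``; returns ``None``
    for the block fraction when no drug period is annotated.
    """
    t = np.asarray(sweep_times_s, float)
    q = np.asarray(charges, float)
    if t.size != q.size:
        raise ValueError("sweep times and charges differ in length")
    if drug_span_s is None:
        return t, q, None
    if baseline_span_s is None:
        baseline_span_s = (float(t[0]), float(drug_span_s[0]))
    in_base = (t >= baseline_span_s[0]) & (t < baseline_span_s[1])
    in_drug = (t >= drug_span_s[0]) & (t <= drug_span_s[1])
    if np.count_nonzero(in_base) < 3:
        raise ValueError("baseline period must hold >= 3 sweeps")
    q_base = float(np.mean(q[in_base]))
    q_drug = float(np.mean(q[in_drug]))
    return t, q, 1.0 - q_drug / q_base


def paired_pulse_ratio(
    trace: SweepTrace,
    isi: float,
    kinetics: EventKinetics | None = None,
    mode: Literal["amplitude", "charge"] = "amplitude",
) -> PairedPulseResult:
    """Paired-pulse ratio with decay-extrapolation overlap correction.

    The first response's decay (biexponential fit over the segment preceding
    the second stimulus) is extrapolated under the second response and
    subtracted before the second amplitude is measured.  Raises (flagged)
    when the first response is a failure.
    """
    if trace.stim_times.size != 2:
        raise ValueError("paired sweep must carry exactly 2 stimuli")
    t1, t2 = (float(x) for x in trace.stim_times)
    if abs((t2 - t1) - isi) > trace.dt:
        raise ValueError(f"stimulus spacing {t2 - t1} does not match isi {isi}")

    clean = blank_artifact(trace, BLANK_MS)
    base_win = (max(trace.t0, t1 - 11.0), t1 - 1.0)
    baseline = estimate_baseline(clean, base_win)
    noise = _noise_sd(clean, t1 - 1.0)
    dt = clean.dt

    y = baseline - clean.samples  # magnitude, events positive
    i1 = clean.index_of(t1 + BLANK_MS)
    i2 = clean.index_of(t2)
    i1_peak = i1 + int(np.argmax(y[i1:i2]))
    a1 = float(y[i1_peak])
    if a1 < FAIL_K * noise and noise > 0:
        raise ValueError("first response classified as failure; PPR undefined")

    # fit the first decay up to just before the second stimulus (starting
    # 1 ms past the peak, clear of the rising phase), then extrapolate
    i_fit0 = i1_peak + int(round(DECAY_SKIP_MS / dt))
    i_fit_end = clean.index_of(t2 - BLANK_MS)
    dec_t = (np.arange(i_fit0, i_fit_end) - i_fit0) * dt
    dec_y = y[i_fit0:i_fit_end]
    if dec_t.size >= 8 and dec_t[-1] >= 5.0:
        f1, tt1, f2, tt2, _ = fit_biexp_decay(dec_t, dec_y)
    else:  # very short ISIs: fall back to configured kinetics for the tail
        k = kinetics or EventKinetics(0.25, 0.8, 1.3, 6.0)
        y0 = float(y[i_fit0])
        f1, tt1, f2, tt2 = y0 * k.a1, k.tau1, y0 * k.a2, k.tau2
    i_end = min(clean.n_samples, clean.index_of(t2 + 20.0))
    ext_t = (np.arange(i2, i_end) - i_fit0) * dt
    corrected = y[i2:i_end] - _biexp(ext_t, f1, tt1, f2, tt2)

    i2_search = clean.index_of(t2 + BLANK_MS) - i2
    a2 = float(np.max(corrected[i2_search:]))
    if a2 <= 0:
        raise ValueError("second response not detectable above the "
                         "extrapolated first-response decay")
    result = PairedPulseResult(isi=isi, ppr=a2 / a1, a1=a1, a2=a2)

    # charge-based PPR (optional route): subtract the extrapolated decay, then
    # integrate each response over its own window
    # matched-length charge windows for the charge-based ratio
    q_len = min(isi - CHARGE_START_MS, 20.0 - CHARGE_START_MS)
    q1 = integrate_charge(clean, (t1 + CHARGE_START_MS,
                                  t1 + CHARGE_START_MS + q_len), baseline).q
    i_q0 = clean.index_of(t2 + CHARGE_START_MS) - i2
    i_q1 = min(corrected.size, i_q0 + int(round(q_len / dt)))
    q2_dev = np.minimum(-corrected[i_q0:i_q1], 0.0)  # inward sign convention
    q2 = abs(float(np.sum(q2_dev)) * dt) / 1000.0
    result.q1, result.q2 = q1, q2
    if q1 > 0:
        result.ppr_charge = q2 / q1
    if mode == "charge":
        if result.ppr_charge is None:
            raise ValueError("charge-based PPR undefined (first charge is 0)")
        result.ppr = result.ppr_charge
    return result
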