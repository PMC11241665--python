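# Methods

This note documents the models, conventions and numerical choices behind
`ipsckit`, and what the synthetic validation does and does not establish.

## Units and sign conventions

Internal canonical units are ms (time), pA (current) and pC (charge);
conversions happen only at I/O boundaries (pA·ms = fC; divide by 1000 for
pC). With a high-chloride internal solution, GABA-A currents at a negative
holding potential are inward, i.e. negative-going. All analysis operates on
deviations from a local baseline rectified toward that event polarity —
positive-going noise excursions are clipped rather than allowed to cancel
event charge — and every reported amplitude and charge is a magnitude.

## The generative model

The simulator implements a deliberately minimal two-pool quantal scheme; it
is a modelling choice consistent with the standard interpretation of
train-based pool estimation (tight docking = immediately releasable subset,
late cumulative slope = replenishment, PPR > 1 = facilitation), not a claim
about mechanism.

State per terminal population: pool occupancy `n` (start `n_tight`, capacity
`n_max`) and facilitation `F` (start 0). For stimulus `k` after gap `Δ`:

1. effective release probability `p_k = min(1, p_rel + F_k)`;
2. released quanta `r_k ~ Binomial(n_k, p_k)` (stochastic engine) or
   `r_k = n_k·p_k` with a real-valued pool (deterministic engine);
3. pool update `n ← min(n_max, n − r_k + ρ)` with replenishment
   `ρ ~ Poisson(replenish_rate·Δ/1000)` or its mean;
4. facilitation update `F ← (F + facil_increment)·exp(−Δ/facil_tau)`;
5. after the last train pulse the pool refills toward `n_tight` as
   `n(Δ) = n_tight − (n_tight − n)·exp(−Δ/recovery_tau)` (recovery probes).

Each released quantum transfers `q_charge` (lognormal multiplicative jitter
with CV `amp_cv`, mean 1). A fraction `tonic_fraction` of every pulse's
charge is injected as a slow exponential current (τ = 50 ms, a fixed
modelling choice — the tonic component's mechanism and magnitude have no
measured counterpart here); the rest drives the fast kernel

    w(t) = (1 − e^(−t/τ_rise)) · (a1·e^(−t/τ1) + a2·e^(−t/τ2)),

unit-normalized at its peak. Phasic onsets lag each stimulus by a fixed 1 ms
synaptic delay; a ±400 pA biphasic stimulus artifact (0.4 ms) is injected so
the blanking stage is exercised. Gaussian recording noise (`noise_sd`,
default 3 pA) is added throughout. Spontaneous events are an independent
homogeneous Poisson process at `mini_rate`.

Reproducibility: every cohort derives per-cell `SeedSequence`s by
`SeedSequence([master_seed, stream]).spawn(n_cells)`; a fixed master seed
makes entire pipeline runs bit-identical.

## Condition presets and calibration

`preset("sham")` and `preset("bbbd")` define the two study conditions. The
directly specified values are the spontaneous rates (20.25 vs 12.15 Hz) and
the fast decay constants (τ1 = 1.52 vs 1.11 ms; τ_rise 0.25 ms, a1 = 0.8 and
τ2 = 6 ms shared, since rise time, fast-amplitude and slow component do not
differ between conditions). The free release parameters were calibrated once,
by solving (`p_rel`, `facil_increment`) per condition with a root finder on
the deterministic pipeline so that the measured paired-pulse ratio at 10 ms
and the measured phase-1 cumulative-charge intercept equal the target group
medians (sham 1.27 / 1.89; BBBd 1.58 / 1.23):

| parameter | sham | bbbd |
|---|---|---|
| n_tight | 3600 | 1800 |
| p_rel | 0.0935 | 0.0494 |
| facil_increment | 0.0414 | 0.0367 |
| facil_tau (ms) | 80 | 80 |
| replenish_rate (/s) | 2250 | 540 |
| q_charge (pC) | 0.1 | 0.1 |
| tonic_fraction | 0.3 | 0.3 |
| recovery_tau (ms) | 500 | 500 |

Two structural observations from that calibration are worth recording.
First, the target pairs are only jointly reachable in a low-`p_rel`, mild
facilitation regime: above `p_rel ≈ 0.3` the facilitation needed to push the
PPR above 1 drives the phase-1 intercept past ~2.2 regardless of the other
parameters. Second, normalized (first-response-unit) quantities are
invariant to pool scale, so `n_tight` is free to set the signal-to-noise of
the stochastic engine; it is set large (3600/1800, halved in the BBBd
condition consistent with a pool reduced by about half) so that binomial
counting noise in per-cell PPRs and intercepts stays well inside the 10–15%
recovery tolerances with 12-cell cohorts. The absolute evoked amplitudes
this implies (several nA) are those of compound responses to field
stimulation of many boutons; only normalized quantities are interpreted.

## Analysis conventions

- **Baseline** is the median (not mean) of a window ending 1 ms before the
  first stimulus (evoked) or a 10 ms pre-event window (minis).
- **Artifact blanking** replaces 0.5 ms after each stimulus by linear
  interpolation; idempotent.
- **Mini detection** is two-stage: candidates where the low-pass-filtered
  (1 kHz) current derivative crosses 4× its MAD-based noise scale in the
  inward direction, confirmed when the local derivative correlates ≥ 0.6
  with the derivative of an identically filtered kernel template, both
  aligned at their derivative trough. Candidates within a 2 ms refractory
  window merge into one event but keep their multiplicity, which counts
  toward frequency (merged events are excluded from kinetics averaging). An
  amplitude gate at 3× the raw noise SD (estimated from first differences)
  suppresses residual false positives; noise-free input skips the filter so
  onsets stay sample-accurate, and a zero noise estimate falls back to an
  absolute derivative threshold.
- **Mean waveform**: peak-aligned average of events scaled to unit trough,
  excluding events with a neighbouring onset inside the segment *or within
  35 ms before the peak*. The pre-exclusion matters: at 12–20 Hz the decay
  tails of preceding events otherwise bias the local baseline and the
  averaged decay (≈ −20% on τ1). The average is renormalized to unit trough.
- **Decay fits** start 1 ms after the trough (`DECAY_SKIP_MS`) so the rising
  phase, which the pure two-exponential model cannot represent, has
  completed; fitting from the peak itself biases τ1 by ≈ +20%. Fits use
  variable projection — amplitudes solved linearly (non-negative) on a log
  grid of (τ1, τ2) pairs, the five best starts refined by Nelder–Mead — and,
  for averaged waveforms from busy recordings, include a free additive
  offset that absorbs residual conditional background. A collapsed slow
  amplitude degenerates gracefully to a single exponential.
- **Rise time** is 20–80% with linear interpolation; non-monotone rises use
  the first 20% and last 80% crossing before the peak.
- **Evoked charge** integrates stimulus+2 ms to stimulus+100 ms (or the next
  stimulus); failures are responses whose 2–20 ms peak stays below 3× the
  noise SD (an automated stand-in for by-eye classification).
- **PPR** is amplitude-based (charge-based available): the first response's
  decay is fit from 1 ms past its peak up to the second stimulus and
  extrapolated under the second response before the second amplitude is
  read. On identical noiseless 10 ms pairs this recovers PPR = 1.000 ± 0.01.
- **Tonic/phasic split**: the tonic envelope linearly interpolates anchors
  (median of the 0.5 ms before each train stimulus, relative to the
  pre-train baseline); phasic = blanked trace − baseline − envelope. The
  anchors necessarily include undecayed kernel tails, so with the default
  τ2 = 6 ms kernel the envelope overestimates a pure tonic component by
  ~10–20%; the per-pulse charge windows `[t_k+0.5, t_{k+1})` compensate
  kernel-tail spill only where consecutive charges vary slowly.
- **Biphasic fit**: OLS over pulses 2–10 and 60–100 on `C_k` vs time in
  seconds from train onset; the y-intercept is the line's value at the first
  pulse. An optional breakpoint search (pulses 5–50, minimizing total
  two-segment SSE, phase 1 from pulse 2, phase 2 to the last pulse) replaces
  the fixed windows. A phase-1 slope not exceeding the phase-2 slope flags
  `no_steep_phase`.
- **Recovery**: probe charges use a local 2 ms pre-pulse baseline (absorbing
  residual tonic current); `fraction = (Q_rec − Q_ss)/(Q_1 − Q_ss)` clipped
  to [0, 1.5], with `Q_ss` the mean of the last ten train charges, fit by
  `1 − exp(−t/τ_rec)`.
- **Group comparison**: Lilliefors-corrected KS on both groups at α = 0.05
  gates pooled-variance Student's t vs two-sided Mann–Whitney (exact tail
  enumeration when the pooled tie-free sample has ≤ 16 values, tie-corrected
  normal approximation otherwise). Quartiles use linear interpolation;
  IQR is Q3 − Q1. No multiple-testing correction is applied, matching the
  reporting convention the analysis mirrors.

## Problem sizes

Cohort analyses use 9 + 8 cells (the demo), 12-cell cohorts for the PPR and
train recoveries, 20 cells × 100 s for the spontaneous-frequency recovery,
and 2000 replicates for the type-I-error calibration; these sizes give the
medians comfortable margins against their tolerances while keeping any
single stage in the seconds-to-minutes range on one CPU.

## What the synthetic validation shows — and what it does not

Passing parameter recovery shows the analysis correctly inverts data that
satisfy the model's assumptions: linear summation of identical quantal
kernels, stationary Poisson spontaneous activity, binomial release with
additive facilitation, white Gaussian noise. Real recordings violate several
of these — series-resistance filtering and its drift, non-stationary rates,
multi-site kernel heterogeneity, correlated (1/f, line) noise, receptor
saturation and desensitization during trains — so recovered accuracy here is
an upper bound on real-data accuracy, not an estimate of it. Known
model-internal caveats:

- The facilitation variable stays elevated immediately after the train, so
  short-interval recovery probes ride on an increased release probability;
  with facilitation on, fitted `τ_rec` underestimates the generative refill
  constant. The recovery comparison between conditions is still meaningful
  (both share the confound); absolute τ_rec recovery is verified with
  facilitation disabled.
- Under first-response normalization, second-phase intercepts scale like
  `1/p_eff` and therefore *differ* between the calibrated conditions even
  though their absolute pool-per-charge interpretation would not; only the
  first-phase intercept is treated as a condition-discriminating readout.
- The per-pulse charge windows correct kernel-tail spill exactly only in
  steady state; across sharp release transients (full depletion within a few
  pulses) individual `Q_k` can deviate locally by tens of percent while the
  cumulative curve and its fits remain accurate to a few percent.
- Cells within a simulated cohort share one parameter set, so between-cell
  spread reflects sampling noise only and is far narrower than the IQRs of
  real cohorts. Group tests on the synthetic cohorts consequently flag even
  physiologically trivial side effects (e.g. the slightly larger unit
  amplitude implied by a faster-decaying kernel at fixed quantal charge) as
  significant. Significance flags here validate the statistical machinery
  and the direction/size of the designed effects — they are not a power
  analysis for real experiments.
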