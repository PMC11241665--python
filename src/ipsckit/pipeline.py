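"""End-to-end orchestration: simulate two cohorts, run every analysis stage,
compare the groups, and write tables, figures and a reproducibility manifest.

Everything is driven by :class:`RunConfig`; a rerun with the same config and
seed is bit-identical.  The per-cell seed-splitting rule lives in
:func:`ipsckit.synthgen.cell_seeds`.
"""

from __future__ import annotations

import dataclasses
import json
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evoked, minis, stats, synthgen, trains

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "simulate_cohort_cell", "analyze_cell", "cohort_frame"]

#: metrics compared between conditions by default
COMPARED_METRICS = (
    "mini_frequency_hz",
    "mini_tau1_ms",
    "ppr_isi10",
    "phase1_intercept",
    "phase2_intercept",
    "phase2_slope_per_s",
    "recovery_tau_ms",
)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 1
    n_sham: int = 9
    n_bbbd: int = 8
    mini_duration_s: float = 100.0
    isis_ms: tuple[float, ...] = (10.0, 15.0, 20.0, 50.0, 100.0)
    dt_ms: float = 0.1
    out_dir: str | None = None
    run_minis: bool = True
    run_paired: bool = True
    run_trains: bool = True
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.n_sham < 1 or self.n_bbbd < 1:
            raise ValueError("cohort sizes must be >= 1")


@dataclass
class PipelineResult:
    """Per-cell tables for both cohorts plus the group comparisons."""

    cells: pd.DataFrame
    comparisons: dict[str, stats.GroupComparison]
    config: RunConfig
    iei_curves: dict[str, list[tuple[np.ndarray, np.ndarray]]] = field(
        default_factory=dict)

    def significant(self) -> dict[str, bool]:
        return {k: v.significant for k, v in self.comparisons.items()}


def analyze_cell(
    condition: str,
    cell_id: str,
    seed: np.random.SeedSequence,
    cfg: RunConfig,
) -> tuple[dict[str, float | str], tuple[np.ndarray, np.ndarray] | None]:
    """Simulate and analyze one cell; returns its summary row and IEI CDF."""
    params = synthgen.preset(condition)
    streams = seed.spawn(2 + len(cfg.isis_ms))
    row: dict[str, float | str] = {"cell_id": cell_id, "condition": condition}
    iei = None

    if cfg.run_minis:
        trace, _truth = synthgen.simulate_minis(
            params, cfg.mini_duration_s, cfg.dt_ms, streams[0])
        trace.cell_id, trace.condition = cell_id, condition
        det_cfg = minis.DetectionConfig(kinetics=params.kernel)
        events = minis.detect_minis(trace, det_cfg)
        summ = minis.summarize_cell(trace, events)
        row.update(mini_frequency_hz=summ.frequency,
                   mini_n_events=summ.n_events,
                   mini_amplitude_pa=summ.median_amplitude,
                   mini_rise_ms=summ.median_rise_time,
                   mini_tau1_ms=summ.tau1, mini_tau2_ms=summ.tau2,
                   mini_a1=summ.a1)
        if len(events) >= 2:
            iei = minis.iei_cdf(events)

    if cfg.run_paired:
        for i, isi in enumerate(cfg.isis_ms):
            trace, _ = synthgen.simulate_evoked(
                params, synthgen.paired_protocol(isi), cfg.dt_ms,
                streams[1 + i], engine="stochastic")
            trace.cell_id, trace.condition = cell_id, condition
            try:
                ppr = evoked.paired_pulse_ratio(trace, isi, params.kernel)
                row[f"ppr_isi{int(isi)}"] = ppr.ppr
            except ValueError:
                row[f"ppr_isi{int(isi)}"] = float("nan")

    if cfg.run_trains:
        trace, _ = synthgen.simulate_evoked(
            params, synthgen.train_protocol(), cfg.dt_ms, streams[-1],
            engine="stochastic")
        trace.cell_id, trace.condition = cell_id, condition
        try:
            res = trains.analyze_train(trace)
            row.update(phase1_intercept=res.phase1.y_intercept,
                       phase1_slope_per_s=res.phase1.slope,
                       phase2_intercept=res.phase2.y_intercept,
                       phase2_slope_per_s=res.phase2.slope,
                       tonic_charge_pc=res.tonic_charge,
                       recovery_tau_ms=res.recovery_tau
                       if res.recovery_tau is not None else float("nan"))
        except ValueError:
            row.update(phase1_intercept=float("nan"),
                       phase2_intercept=float("nan"))
    return row, iei


# backwards-compatible alias used by the drivers
simulate_cohort_cell = analyze_cell


def cohort_frame(cfg: RunConfig) -> tuple[pd.DataFrame,
                                          dict[str, list]]:
    """Simulate + analyze both cohorts; returns the cell table and IEI CDFs."""
    rows = []
    ieis: dict[str, list] = {"sham": [], "bbbd": []}
    for condition, n_cells, stream in (("sham", cfg.n_sham, 0),
                                       ("bbbd", cfg.n_bbbd, 1)):
        seeds = synthgen.cell_seeds(cfg.seed, n_cells, stream=stream)
        for i, seed in enumerate(seeds):
            row, iei = analyze_cell(condition, f"{condition}_{i:02d}",
                                    seed, cfg)
            rows.append(row)
            if iei is not None:
                ieis[condition].append(iei)
    return pd.DataFrame(rows), ieis


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the configured stages and (optionally) write the result bundle."""
    cells, ieis = cohort_frame(cfg)
    comparisons: dict[str, stats.GroupComparison] = {}
    for metric in COMPARED_METRICS:
        col = {"ppr_isi10": "ppr_isi10"}.get(metric, metric)
        if col not in cells.columns:
            continue
        a = cells.loc[cells.condition == "sham", col].to_numpy(float)
        b = cells.loc[cells.condition == "bbbd", col].to_numpy(float)
        try:
            comparisons[metric] = stats.compare_groups(metric, a, b)
        except ValueError:
            continue

    result = PipelineResult(cells=cells, comparisons=comparisons, config=cfg,
                            iei_curves=ieis)
    if cfg.out_dir is not None:
        _write_bundle(result)
    return result


def _write_bundle(result: PipelineResult) -> None:
    cfg = result.config
    out = cfg.out_dir
    assert out is not None
    os.makedirs(out, exist_ok=True)
    result.cells.to_csv(os.path.join(out, "cells.tsv"), sep="\t", index=False)

    summary = {
        name: {
            "median_sham": c.median_a, "iqr_sham": c.q3_a - c.q1_a,
            "median_bbbd": c.median_b, "iqr_bbbd": c.q3_b - c.q1_b,
            "test": c.test, "statistic": c.statistic, "p_value": c.p_value,
            "significant": c.significant,
        }
        for name, c in result.comparisons.items()
    }
    with open(os.path.join(out, "comparisons.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if cfg.make_figures:
        _write_figures(result, out)


def _write_figures(result: PipelineResult, out: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"sham": "black", "bbbd": "magenta"}

    # IEI CDFs
    fig, ax = plt.subplots(figsize=(4, 3))
    for cond, curves in result.iei_curves.items():
        for i, (x, f) in enumerate(curves):
            ax.step(x, f, color=colors[cond], alpha=0.5,
                    label=cond if i == 0 else None)
    ax.set_xlabel("inter-event interval (ms)")
    ax.set_ylabel("cumulative fraction")
    ax.set_xlim(0, 400)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(os.path.join(out, "iei_cdf.png"), dpi=150)
    plt.close(fig)

    # PPR and phase-1 intercept box plots
    for metric, fname in (("ppr_isi10", "ppr_isi10.png"),
                          ("phase1_intercept", "phase1_intercept.png")):
        if metric not in result.cells.columns:
            continue
        fig, ax = plt.subplots(figsize=(3, 3))
        data = [result.cells.loc[result.cells.condition == c, metric]
                .dropna() for c in ("sham", "bbbd")]
        ax.boxplot(data, tick_labels=["sham", "BBBd"])
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(os.path.join(out, fname), dpi=150)
        plt.close(fig)

    # example cumulative-charge curves with biphasic fits
    cfg = result.config
    if cfg.run_trains:
        fig, ax = plt.subplots(figsize=(4, 3))
        for cond in ("sham", "bbbd"):
            params = synthgen.preset(cond)
            trace, _ = synthgen.simulate_evoked(
                params, synthgen.train_protocol(), cfg.dt_ms,
                synthgen.cell_seeds(cfg.seed, 1, stream=9)[0])
            res = trains.analyze_train(trace)
            t = (trace.stim_times[:res.cumulative.size]
                 - trace.stim_times[0]) / 1000.0
            ax.plot(t, res.cumulative, color=colors[cond], label=cond)
            for fit, style in ((res.phase1, "--"), (res.phase2, ":")):
                ax.plot(t, fit.y_intercept + fit.slope * t, style,
                        color=colors[cond], lw=1)
        ax.set_xlabel("time from train onset (s)")
        ax.set_ylabel("cumulative charge (Q1 units)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(os.path.join(out, "cumulative_charge.png"), dpi=150)
        plt.close(fig)
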