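"""Core trace data model and shared signal plumbing.

Everything downstream (mini detection, evoked analysis, train analysis) operates
on :class:`SweepTrace` objects: a sampled membrane-current recording in
voltage clamp together with its stimulus timestamps and labels.

Canonical internal units are **ms / pA / pC** (time / current / charge);
conversions happen only at I/O boundaries.  With the high-chloride internal
solution used for these recordings, IPSCs are inward, i.e. negative-going
deflections; all reported amplitudes and charges are magnitudes.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SweepTrace",
    "ChargeMeasure",
    "TraceFormatError",
    "estimate_baseline",
    "blank_artifact",
    "integrate_charge",
    "read_trace",
    "write_trace",
]

#: protocol tag -> (min expected stimuli, max expected stimuli); None = unbounded
_PROTOCOL_STIM_COUNTS = {
    "minis": (0, 0),
    "single": (1, 1),
    "paired": (2, 2),
    "train": (100, None),
    "io_curve": (1, None),
    "unknown": (0, None),
}

_CONDITIONS = ("sham", "bbbd", "unknown")


class TraceFormatError(ValueError):
    """Raised when a trace file cannot be parsed or fails validation."""


@dataclass
class SweepTrace:
    """A sampled current recording (pA) with stimulus timestamps (ms).

    Parameters
    ----------
    samples
        Membrane current per time step, pA.  Must be finite.
    dt
        Sampling interval, ms (> 0).
    t0
        Time of the first sample, ms.
    stim_times
        Strictly increasing stimulus timestamps inside the recording, ms.
    holding_potential
        Holding potential, mV (informational only).
    cell_id, condition, protocol
        Labels.  ``condition`` is one of ``sham | bbbd | unknown``;
        ``protocol`` one of ``minis | single | paired | train | io_curve |
        unknown`` and must be consistent with the stimulus count.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    holding_potential: float = -70.0
    cell_id: str = ""
    condition: str = "unknown"
    protocol: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.condition not in _CONDITIONS:
            raise ValueError(f"unknown condition tag {self.condition!r}")
        if self.protocol not in _PROTOCOL_STIM_COUNTS:
            raise ValueError(f"unknown protocol tag {self.protocol!r}")
        if self.stim_times.size:
            if np.any(np.diff(self.stim_times) <= 0):
                raise ValueError("stim_times must be strictly increasing")
            if self.stim_times[0] < self.t0 or self.stim_times[-1] > self.t_end:
                raise ValueError("stim_times must lie within the recording")
        lo, hi = _PROTOCOL_STIM_COUNTS[self.protocol]
        n = self.stim_times.size
        if n < lo or (hi is not None and n > hi):
            raise ValueError(
                f"protocol {self.protocol!r} expects "
                f"{lo}{'+' if hi is None else f'..{hi}'} stimuli, got {n}"
            )

    # -- geometry -----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def t_end(self) -> float:
        """Time just past the last sample, ms."""
        return self.t0 + self.samples.size * self.dt

    @property
    def duration_s(self) -> float:
        return self.samples.size * self.dt / 1000.0

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) * self.dt

    def index_of(self, t: float) -> int:
        """Sample index containing time ``t`` (ms)."""
        return int(round((t - self.t0) / self.dt))

    def slice_window(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples in ``[t_start, t_end)``; raises on out-of-range windows."""
        if t_end <= t_start:
            raise ValueError("empty window: t_end must exceed t_start")
        if t_start < self.t0 - 0.5 * self.dt or t_end > self.t_end + 0.5 * self.dt:
            raise ValueError(
                f"window [{t_start}, {t_end}] outside trace "
                f"[{self.t0}, {self.t_end}]"
            )
        i0 = max(0, self.index_of(t_start))
        i1 = min(self.samples.size, self.index_of(t_end))
        return self.samples[i0:i1]

    def copy(self) -> "SweepTrace":
        return replace(self, samples=self.samples.copy(),
                       stim_times=self.stim_times.copy())


@dataclass(frozen=True)
class ChargeMeasure:
    """A rectified charge integral over a window.

    ``q`` is the charge magnitude in pC; ``window`` the ``[t_start, t_end]``
    integration interval in ms; ``baseline`` the subtracted current level (pA).
    """

    q: float
    window: tuple[float, float]
    baseline: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("charge magnitude must be >= 0")
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed start")


def estimate_baseline(trace: SweepTrace, window: tuple[float, float]) -> float:
    """Median current (pA) in ``window`` — robust to events in the window tails."""
    seg = trace.slice_window(*window)
    if seg.size < 10:
        raise ValueError(f"baseline window holds {seg.size} samples; need >= 10")
    return float(np.median(seg))


def blank_artifact(trace: SweepTrace, blank_ms: float = 0.5) -> SweepTrace:
    """Replace samples within ``blank_ms`` after each stimulus by interpolation.

    Field stimulation leaves a brief artifact at each stimulus time; samples in
    ``[t_stim, t_stim + blank_ms]`` are replaced by the straight line between
    the bounding samples.  Returns a new trace; the input is unmodified.
    Idempotent on its own output.
    """
    if blank_ms < 0:
        raise ValueError("blank_ms must be >= 0")
    out = trace.copy()
    if blank_ms == 0 or not trace.stim_times.size:
        return out
    s = out.samples
    for t_stim in trace.stim_times:
        i0 = max(0, trace.index_of(t_stim))
        i1 = min(s.size - 1, trace.index_of(t_stim + blank_ms))
        if i1 <= i0:
            continue
        lo = s[i0 - 1] if i0 > 0 else s[i1]
        hi = s[i1]
        s[i0:i1] = np.linspace(lo, hi, i1 - i0 + 2)[1:-1]
    return out


def integrate_charge(
    trace: SweepTrace,
    window: tuple[float, float],
    baseline: float,
    polarity: int = -1,
) -> ChargeMeasure:
    """Rectified charge integral over ``window``, in pC.

    The deviation from ``baseline`` is rectified toward the event polarity
    (inward/negative by default) before summation, so positive-going noise
    excursions do not cancel event charge.  ``q = |sum(dev) * dt|`` with
    pA*ms = fC, returned in pC.
    """
    seg = trace.slice_window(*window)
    if seg.size == 0:
        raise ValueError("empty integration window")
    dev = seg - baseline
    if polarity < 0:
        dev = np.minimum(dev, 0.0)
    else:
        dev = np.maximum(dev, 0.0)
    q_fc = abs(float(np.sum(dev)) * trace.dt)
    return ChargeMeasure(q=q_fc / 1000.0, window=(window[0], window[1]),
                         baseline=baseline)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------
# Tabular dialect: UTF-8; '#'-prefixed "key=value" header lines with keys
# dt_ms, t0_ms, cell_id, condition, protocol, holding_mV and comma-separated
# stim_times_ms; then rows "time_ms<TAB>current_pA".

_HEADER_KEYS = ("dt_ms", "t0_ms", "cell_id", "condition", "protocol",
                "holding_mV", "stim_times_ms")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        return "container"
    return "tabular"


def write_trace(trace: SweepTrace, path: str, fmt: str | None = None) -> None:
    """Write a trace as tabular text (default) or an HDF5 container."""
    fmt = _infer_format(path, fmt)
    if fmt == "tabular":
        _write_tabular(trace, path)
    elif fmt == "container":
        _write_container(trace, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_trace(path: str, fmt: str | None = None) -> SweepTrace:
    """Read a trace written by :func:`write_trace` (lossless round trip)."""
    fmt = _infer_format(path, fmt)
    if fmt == "tabular":
        return _read_tabular(path)
    if fmt == "container":
        return _read_container(path)
    if fmt == "nwb":  # optional adapter
        return _read_nwb(path)
    raise ValueError(f"unknown format {fmt!r}")


def _write_tabular(trace: SweepTrace, path: str) -> None:
    buf = io.StringIO()
    stims = ",".join(repr(float(t)) for t in trace.stim_times)
    buf.write(f"# dt_ms={float(trace.dt)!r}\n")
    buf.write(f"# t0_ms={float(trace.t0)!r}\n")
    buf.write(f"# cell_id={trace.cell_id}\n")
    buf.write(f"# condition={trace.condition}\n")
    buf.write(f"# protocol={trace.protocol}\n")
    buf.write(f"# holding_mV={float(trace.holding_potential)!r}\n")
    buf.write(f"# stim_times_ms={stims}\n")
    t = trace.times()
    for ti, si in zip(t, trace.samples):
        buf.write(f"{float(ti)!r}\t{float(si)!r}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def _read_tabular(path: str) -> SweepTrace:
    meta: dict[str, str] = {}
    times: list[float] = []
    samples: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise TraceFormatError(
                        f"{path}:{lineno}: malformed header line (no '=')")
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TraceFormatError(
                    f"{path}:{lineno}: expected 'time_ms<TAB>current_pA'")
            try:
                times.append(float(parts[0]))
                samples.append(float(parts[1]))
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path}:{lineno}: non-numeric field: {exc}") from None
    if "dt_ms" not in meta:
        raise TraceFormatError(f"{path}: missing required header key 'dt_ms'")
    if len(samples) < 2:
        raise TraceFormatError(f"{path}: fewer than 2 data rows")
    tarr = np.asarray(times)
    if np.any(np.diff(tarr) <= 0):
        bad = int(np.argmax(np.diff(tarr) <= 0)) + 2
        raise TraceFormatError(
            f"{path}: time column not strictly increasing near data row {bad}")
    try:
        dt = float(meta["dt_ms"])
        t0 = float(meta.get("t0_ms", tarr[0]))
        holding = float(meta.get("holding_mV", -70.0))
        stim_field = meta.get("stim_times_ms", "")
        stim = np.asarray(
            [float(x) for x in stim_field.split(",") if x.strip()])
    except ValueError as exc:
        raise TraceFormatError(f"{path}: bad header value: {exc}") from None
    try:
        return SweepTrace(
            samples=np.asarray(samples), dt=dt, t0=t0, stim_times=stim,
            holding_potential=holding, cell_id=meta.get("cell_id", ""),
            condition=meta.get("condition", "unknown"),
            protocol=meta.get("protocol", "unknown"))
    except ValueError as exc:
        raise TraceFormatError(f"{path}: validation failed: {exc}") from None


def _write_container(trace: SweepTrace, path: str, group: str = "sweep0") -> None:
    import h5py

    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("samples", data=trace.samples)
        g.create_dataset("stim_times", data=trace.stim_times)
        g.attrs["dt_ms"] = trace.dt
        g.attrs["t0_ms"] = trace.t0
        g.attrs["holding_mV"] = trace.holding_potential
        g.attrs["cell_id"] = trace.cell_id
        g.attrs["condition"] = trace.condition
        g.attrs["protocol"] = trace.protocol


def _read_container(path: str, group: str | None = None) -> SweepTrace:
    import h5py

    with h5py.File(path, "r") as fh:
        keys = sorted(fh.keys())
        if not keys:
            raise TraceFormatError(f"{path}: container holds no sweep groups")
        g = fh[group or keys[0]]
        if "samples" not in g:
            raise TraceFormatError(f"{path}:{g.name}: missing 'samples' dataset")
        if "stim_times" not in g:
            raise TraceFormatError(
                f"{path}:{g.name}: missing 'stim_times' dataset")
        try:
            return SweepTrace(
                samples=g["samples"][...], dt=float(g.attrs["dt_ms"]),
                t0=float(g.attrs.get("t0_ms", 0.0)),
                stim_times=g["stim_times"][...],
                holding_potential=float(g.attrs.get("holding_mV", -70.0)),
                cell_id=str(g.attrs.get("cell_id", "")),
                condition=str(g.attrs.get("condition", "unknown")),
                protocol=str(g.attrs.get("protocol", "unknown")))
        except ValueError as exc:
            raise TraceFormatError(
                f"{path}:{g.name}: validation failed: {exc}") from None


def _read_nwb(path: str) -> SweepTrace:  # pragma: no cover - optional adapter
    try:
        import pynwb  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "reading NWB files requires the optional 'pynwb' package") from exc
    from pynwb import NWBHDF5IO

    with NWBHDF5IO(path, "r") as fio:
        nwb = fio.read()
        series = next(iter(nwb.acquisition.values()))
        rate = float(series.rate)
        return SweepTrace(
            samples=np.asarray(series.data[:], dtype=float) * 1e12,
            dt=1000.0 / rate,
            t0=float(series.starting_time or 0.0) * 1000.0,
            protocol="unknown")
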