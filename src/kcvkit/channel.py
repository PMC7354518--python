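"""Two-state single-channel gating: simulation, idealization, estimation.

A channel flips between closed and open states with voltage-dependent
rates k(V) = k0 * exp(s*V). Traces are continuous-time Markov chains
sampled at a fixed rate, with the open level at gamma*(V - E_rev)*1e-3 pA
(gamma in pS, V in mV), Gaussian noise per sample, and an optional
low-pass filter (4th order, cascaded single-pole sections). Idealization
uses two-level amplitude clustering with a half-amplitude threshold and
short-event merging; conductance is the slope of the open-level I/V line
through the origin, by default over positive voltages only because fast
"flicker" gating plus filtering depresses the apparent open level on the
negative branch.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "GatingModel",
    "SimConfig",
    "Trace",
    "Segment",
    "IdealizedTrace",
    "ChannelEstimate",
    "FlickerReport",
    "simulate_trace",
    "idealize",
    "open_probability",
    "iv_and_conductance",
    "flicker_artifact_check",
    "flicker_model",
    "SLOW_GATING_RATE",
    "FAST_FLICKER_RATE",
]

SLOW_GATING_RATE = 20.0     # 1/s, resolved gating reference
FAST_FLICKER_RATE = 5000.0  # 1/s, unresolved at a 1-kHz corner


@dataclass(frozen=True)
class GatingModel:
    """Voltage-dependent two-state gating plus single-channel conductance."""

    k_co0: float                 # opening rate at 0 mV, 1/s
    k_oc0: float                 # closing rate at 0 mV, 1/s
    s_co: float = 0.0            # 1/mV
    s_oc: float = 0.0            # 1/mV
    gamma_pS: float = 87.0
    reversal_mV: float = 0.0     # symmetric solutions

    def __post_init__(self) -> None:
        if self.k_co0 <= 0 or self.k_oc0 <= 0:
            raise ValueError("rate constants must be strictly positive")
        if self.gamma_pS <= 0:
            raise ValueError("unitary conductance must be positive")

    def k_co(self, v_mV: float) -> float:
        return self.k_co0 * math.exp(self.s_co * v_mV)

    def k_oc(self, v_mV: float) -> float:
        return self.k_oc0 * math.exp(self.s_oc * v_mV)

    def stationary_po(self, v_mV: float) -> float:
        kco, koc = self.k_co(v_mV), self.k_oc(v_mV)
        return kco / (kco + koc)

    def open_level_pA(self, v_mV: float) -> float:
        return self.gamma_pS * (v_mV - self.reversal_mV) * 1e-3


@dataclass(frozen=True)
class SimConfig:
    """Acquisition settings for simulated recordings."""

    fs: float = 5000.0           # Hz
    duration: float = 10.0       # s
    noise_sd: float = 1.0        # pA
    filter_corner: float | None = 1000.0  # Hz; None disables filtering
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_corner is not None and self.fs <= 2 * self.filter_corner:
            raise ValueError("sampling rate must exceed twice the filter corner")
        if self.duration * self.fs < 1e3:
            raise ValueError("trace must contain at least 1000 samples")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs)


@dataclass(frozen=True)
class Trace:
    """A sampled current trace at one holding voltage.

    ``states`` is the hidden open/closed indicator used by simulator
    oracles; it is absent for traces read back from disk.
    """

    voltage_mV: float
    fs: float
    current_pA: np.ndarray
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        cur = np.asarray(self.current_pA, dtype=float)
        object.__setattr__(self, "current_pA", cur)
        if not np.all(np.isfinite(cur)):
            raise ValueError("non-finite current values")
        if self.states is not None and len(self.states) != len(cur):
            raise ValueError("state vector length mismatch")

    def __len__(self) -> int:
        return len(self.current_pA)


@dataclass(frozen=True)
class Segment:
    state: str                   # "open" | "closed"
    n_samples: int


@dataclass(frozen=True)
class IdealizedTrace:
    """Alternating dwell segments plus the two estimated current levels."""

    segments: tuple[Segment, ...]
    closed_level_pA: float
    open_level_pA: float
    n_samples: int

    def __post_init__(self) -> None:
        if sum(s.n_samples for s in self.segments) != self.n_samples:
            raise ValueError("segment durations must sum to trace length")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.state == b.state:
                raise ValueError("segments must strictly alternate")

    @property
    def open_samples(self) -> int:
        return sum(s.n_samples for s in self.segments if s.state == "open")

    def dwell_times(self, state: str, fs: float) -> list[float]:
        """Dwell durations in seconds, excluding the censored end segments."""
        inner = self.segments[1:-1] if len(self.segments) > 2 else ()
        return [s.n_samples / fs for s in inner if s.state == state]


@dataclass(frozen=True)
class ChannelEstimate:
    """Per-voltage open levels and Po plus the fitted conductance."""

    voltages_mV: tuple[float, ...]
    open_levels_pA: tuple[float, ...]
    open_probabilities: tuple[float, ...]
    gamma_pS: float
    gamma_se_pS: float
    fit_voltages_mV: tuple[float, ...]


def _single_pole_lowpass(x: np.ndarray, fs: float, corner: float, n_sections: int = 4) -> np.ndarray:
    """Cascaded first-order low-pass sections (forward only, causal)."""
    alpha = 1.0 - math.exp(-2.0 * math.pi * corner / fs)
    y = np.asarray(x, dtype=float)
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    for _ in range(n_sections):
        y, _ = lfilter(b, a, y, zi=np.array([(1.0 - alpha) * y[0]]))
    return y


def simulate_trace(model: GatingModel, v_mV: float, config: SimConfig) -> Trace:
    """Simulate one seeded trace of two-state gating at a holding voltage."""
    rng = np.random.default_rng(config.seed)
    kco, koc = model.k_co(v_mV), model.k_oc(v_mV)
    if not (kco > 0 and koc > 0) or not (math.isfinite(kco) and math.isfinite(koc)):
        raise ValueError("gating rates must be positive and finite at the simulated voltage")
    n = config.n_samples
    dt = 1.0 / config.fs

    # exponential dwells; start state drawn from the stationary distribution
    states = np.empty(n, dtype=np.int8)
    state = int(rng.random() < kco / (kco + koc))
    t_idx = 0
    while t_idx < n:
        rate = koc if state else kco
        dwell = rng.exponential(1.0 / rate)
        n_dwell = max(1, round(dwell / dt))
        end = min(n, t_idx + n_dwell)
        states[t_idx:end] = state
        t_idx = end
        state = 1 - state

    open_level = model.open_level_pA(v_mV)
    current = states * open_level + rng.normal(0.0, config.noise_sd, size=n)
    if config.filter_corner is not None:
        current = _single_pole_lowpass(current, config.fs, config.filter_corner)
    return Trace(voltage_mV=v_mV, fs=config.fs, current_pA=current, states=states)


def _two_means_1d(x: np.ndarray, tol: float = 1e-9, max_iter: int = 200) -> tuple[float, float]:
    """Deterministic 1-D 2-means; centers initialized at the 5/95 percentiles."""
    lo, hi = np.percentile(x, [5.0, 95.0])
    if lo == hi:
        raise ValueError("degenerate all-constant trace")
    c0, c1 = float(lo), float(hi)
    for _ in range(max_iter):
        mid = 0.5 * (c0 + c1)
        mask = x > mid
        if not mask.any() or mask.all():
            break
        n0, n1 = float(np.mean(x[~mask])), float(np.mean(x[mask]))
        if abs(n0 - c0) < tol and abs(n1 - c1) < tol:
            c0, c1 = n0, n1
            break
        c0, c1 = n0, n1
    return c0, c1


def flicker_model(
    gamma_pS: float,
    slow_rate: float = SLOW_GATING_RATE,
    fast_rate: float = FAST_FLICKER_RATE,
    v_ref_mV: float = 120.0,
) -> GatingModel:
    """Gating that is resolved at +v_ref but flickers at -v_ref.

    Both rates follow k(V) = k0*exp(s*V) with k0 the geometric mean of the
    slow and fast rates and s chosen so k(+v_ref) = slow and
    k(-v_ref) = fast: openings are well resolved on the positive branch
    and unresolved (filter-truncated) on the negative branch.
    """
    k0 = math.sqrt(slow_rate * fast_rate)
    s = -math.log(fast_rate / slow_rate) / (2.0 * v_ref_mV)
    return GatingModel(k_co0=k0, k_oc0=k0, s_co=s, s_oc=s, gamma_pS=gamma_pS)


def _run_length_encode(is_open: np.ndarray) -> list[list[int]]:
    """[state, length] runs of a boolean sample-state vector."""
    arr = is_open.astype(np.int8)
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(arr)]))
    return [[int(arr[s]), int(e - s)] for s, e in zip(starts, ends)]


def _merge_short_runs(runs: list[list[int]], min_event_samples: int) -> list[list[int]]:
    """Merge runs shorter than the minimum into their neighbors.

    Shortest-first (ties: leftmost), via a doubly-linked list plus a heap.
    Merging an interior run joins its two equal-state neighbors into one.
    """
    if len(runs) <= 1:
        return runs
    state = [s for s, _ in runs]
    length = [n for _, n in runs]
    prev = list(range(-1, len(runs) - 1))
    nxt = list(range(1, len(runs) + 1))
    nxt[-1] = -1
    alive = [True] * len(runs)
    n_alive = len(runs)
    heap = [(n, i) for i, n in enumerate(length)]
    heapq.heapify(heap)

    while heap and n_alive > 1:
        n, i = heapq.heappop(heap)
        if not alive[i] or length[i] != n:
            continue
        if n >= min_event_samples:
            break
        p, q = prev[i], nxt[i]
        if p >= 0 and q >= 0:
            # absorb run i and its right neighbor into the left neighbor
            length[p] += length[i] + length[q]
            alive[i] = alive[q] = False
            n_alive -= 2
            nxt[p] = nxt[q]
            if nxt[q] >= 0:
                prev[nxt[q]] = p
            heapq.heappush(heap, (length[p], p))
        else:
            neighbor = q if p < 0 else p
            length[neighbor] += length[i]
            alive[i] = False
            n_alive -= 1
            if p < 0:
                prev[neighbor] = -1
            else:
                nxt[neighbor] = -1
            heapq.heappush(heap, (length[neighbor], neighbor))

    head = next(i for i in range(len(runs)) if alive[i] and prev[i] == -1)
    out = []
    i = head
    while i >= 0:
        out.append([state[i], length[i]])
        i = nxt[i]
    return out


def idealize(
    trace: Trace, min_event_samples: int = 5, single_level: str | None = None
) -> IdealizedTrace:
    """Half-amplitude threshold idealization.

    Levels come from two-level amplitude clustering; the threshold is
    their midpoint; events shorter than ``min_event_samples`` are merged
    into their neighbors; levels are then re-estimated from segment
    interiors (edge samples near transitions are excluded). A trace known
    to dwell in one state only must be flagged via
    ``single_level="open"`` or ``"closed"``.
    """
    x = trace.current_pA
    if single_level is not None:
        if single_level not in ("open", "closed"):
            raise ValueError("single_level must be 'open' or 'closed'")
        level = float(np.mean(x))
        return IdealizedTrace(
            segments=(Segment(single_level, len(x)),),
            closed_level_pA=level if single_level == "closed" else 0.0,
            open_level_pA=level if single_level == "open" else 0.0,
            n_samples=len(x),
        )
    if np.ptp(x) == 0:
        raise ValueError("degenerate all-constant trace (flag single_level?)")
    c_lo, c_hi = _two_means_1d(x)
    # the level nearer zero current is the closed level
    if abs(c_lo) <= abs(c_hi):
        closed_c, open_c = c_lo, c_hi
    else:
        closed_c, open_c = c_hi, c_lo
    threshold = 0.5 * (closed_c + open_c)
    sign = 1.0 if open_c >= closed_c else -1.0
    is_open = (sign * x) > (sign * threshold)

    runs = _merge_short_runs(_run_length_encode(is_open), min_event_samples)
    segments = tuple(Segment("open" if s else "closed", n) for s, n in runs)

    # re-estimate levels from segment interiors
    edge = 2
    open_vals, closed_vals = [], []
    pos = 0
    for s, n in runs:
        lo = pos + (edge if n > 2 * edge else 0)
        hi = pos + n - (edge if n > 2 * edge else 0)
        vals = x[lo:hi]
        (open_vals if s else closed_vals).append(vals)
        pos += n
    open_level = float(np.mean(np.concatenate(open_vals))) if open_vals else closed_c
    closed_level = float(np.mean(np.concatenate(closed_vals))) if closed_vals else open_c
    return IdealizedTrace(
        segments=segments,
        closed_level_pA=closed_level,
        open_level_pA=open_level,
        n_samples=len(x),
    )


def open_probability(ideal: IdealizedTrace) -> float:
    """Fraction of samples spent in the open state."""
    return ideal.open_samples / ideal.n_samples


def iv_and_conductance(
    traces: Sequence[Trace],
    fit_voltages: Iterable[float] | None = None,
    min_event_samples: int = 5,
) -> ChannelEstimate:
    """Idealize traces, build the open-level I/V relation, fit conductance.

    The conductance is the least-squares slope through the origin of
    open-level current (mean open minus mean closed level, pA) against
    voltage (mV), over ``fit_voltages`` — by default the positive voltages
    present, since flicker gating makes the negative branch an apparent,
    not a unitary, conductance. Traces at the same voltage are averaged.
    """
    if not traces:
        raise ValueError("no traces supplied")
    by_v: dict[float, list[Trace]] = {}
    for t in traces:
        by_v.setdefault(t.voltage_mV, []).append(t)
    voltages = tuple(sorted(by_v))

    levels, pos = [], []
    for v in voltages:
        i_vals, po_vals = [], []
        for t in by_v[v]:
            ideal = idealize(t, min_event_samples=min_event_samples)
            i_vals.append(ideal.open_level_pA - ideal.closed_level_pA)
            po_vals.append(open_probability(ideal))
        levels.append(float(np.mean(i_vals)))
        pos.append(float(np.mean(po_vals)))

    if fit_voltages is None:
        fit = tuple(v for v in voltages if v > 0)
    else:
        fit = tuple(sorted(fit_voltages))
        missing = set(fit) - set(voltages)
        if missing:
            raise ValueError(f"fit voltages {sorted(missing)} not present in data")
    if len(fit) < 2:
        raise ValueError("need at least 2 distinct voltages to fit a conductance")

    v_arr = np.array(fit)
    i_arr = np.array([levels[voltages.index(v)] for v in fit])
    slope = float(np.sum(v_arr * i_arr) / np.sum(v_arr**2))  # pA/mV = nS
    resid = i_arr - slope * v_arr
    dof = max(len(fit) - 1, 1)
    se = float(math.sqrt(np.sum(resid**2) / dof / np.sum(v_arr**2)))
    return ChannelEstimate(
        voltages_mV=voltages,
        open_levels_pA=tuple(levels),
        open_probabilities=tuple(pos),
        gamma_pS=slope * 1000.0,
        gamma_se_pS=se * 1000.0,
        fit_voltages_mV=fit,
    )


@dataclass(frozen=True)
class FlickerReport:
    """Apparent conductance asymmetry caused by unresolved fast gating."""

    voltages_mV: tuple[float, ...]
    apparent_i_fast_pA: tuple[float, ...]
    apparent_i_slow_pA: tuple[float, ...]
    gamma_fit_fast_pS: float
    gamma_fit_slow_pS: float
    neg_over_pos_ratio_fast: float
    neg_over_pos_ratio_slow: float

    @property
    def artifact_present(self) -> bool:
        return self.neg_over_pos_ratio_fast < 0.9 and self.neg_over_pos_ratio_slow > 0.9


def flicker_artifact_check(
    model_fast: GatingModel,
    model_slow: GatingModel,
    config: SimConfig,
    voltages: Sequence[float] = (-120.0, -80.0, -40.0, 40.0, 80.0, 120.0),
) -> FlickerReport:
    """Compare apparent open levels of fast vs slow gating under filtering.

    Fast gating beyond the filter corner truncates openings, so the
    apparent negative-branch conductance drops below the fitted (positive
    branch) conductance; slow gating stays symmetric.
    """

    def apparent(model: GatingModel) -> tuple[list[float], float]:
        amps = []
        traces = []
        for k, v in enumerate(voltages):
            t = simulate_trace(model, v, replace(config, seed=config.seed + 1000 * k))
            traces.append(t)
            ideal = idealize(t)
            amps.append(abs(ideal.open_level_pA - ideal.closed_level_pA))
        est = iv_and_conductance(traces)
        return amps, est.gamma_pS

    fast_amps, fast_gamma = apparent(model_fast)
    slow_amps, slow_gamma = apparent(model_slow)

    def ratio(amps: list[float]) -> float:
        neg = [a / abs(v) for a, v in zip(amps, voltages) if v < 0]
        pos = [a / abs(v) for a, v in zip(amps, voltages) if v > 0]
        return float(np.mean(neg) / np.mean(pos))

    return FlickerReport(
        voltages_mV=tuple(voltages),
        apparent_i_fast_pA=tuple(fast_amps),
        apparent_i_slow_pA=tuple(slow_amps),
        gamma_fit_fast_pS=fast_gamma,
        gamma_fit_slow_pS=slow_gamma,
        neg_over_pos_ratio_fast=ratio(fast_amps),
        neg_over_pos_ratio_slow=ratio(slow_amps),
    )


def write_trace(trace: Trace, path) -> None:
    """Two-column text trace (time_s, current_pA) with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# voltage_mV={trace.voltage_mV:g} fs_Hz={trace.fs:g}\n")
        fh.write("time_s\tcurrent_pA\n")
        for i, c in enumerate(trace.current_pA):
            fh.write(f"{i / trace.fs:.6f}\t{c:.6f}\n")


def read_trace(path) -> Trace:
    """Read a trace written by :func:`write_trace`."""
    voltage = fs = None
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("voltage_mV="):
                        voltage = float(tok.split("=", 1)[1])
                    elif tok.startswith("fs_Hz="):
                        fs = float(tok.split("=", 1)[1])
            elif line and not line.startswith("time_s"):
                values.append(float(line.split("\t")[1]))
    if voltage is None or fs is None:
        raise ValueError(f"{path}: missing voltage/fs header")
    return Trace(voltage_mV=voltage, fs=fs, current_pA=np.array(values))
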