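"""Calcium-driven isometric twitch simulation.

A twitch is 1 s at 1 ms steps by default: the model is initialized from the
per-head/per-site steady state at the resting calcium, then driven by the
parametric calcium transient while every head and regulatory site is
propagated with matrix-exponential Markov steps and the lattice is settled
in isometric force balance.  Boundary force is converted to stress through
the hexagonal unit-cell cross-sectional area.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _engine
from .kinetics import RateFactors, calcium_transient, srx_rates, thin_filament_rates
from .lattice import build_lattice, cross_sectional_area
from .markov import FORBIDDEN_T, build_rate_matrix, steady_state_init
from .params import ModelConfig

#: conversion from pN over mm^2 to mN/mm^2
PN_TO_MN = 1e-9

SRX_STATE = 6
BOUND = (2, 3, 4)


class NoTwitchError(ValueError):
    """The trace has no positive excursion above baseline."""


class SimulationError(RuntimeError):
    """Mechanics solver failed inside a run; carries the timestep index."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"isometric balance failed at timestep {step}")


@dataclass
class TwitchTrace:
    """Stress vs time with provenance metadata."""

    time: np.ndarray            # s
    stress: np.ndarray          # mN/mm^2
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.time.shape != self.stress.shape:
            raise ValueError("time and stress must have equal length")
        if not np.all(np.isfinite(self.stress)):
            raise ValueError("stress trace contains non-finite values")

    def to_tsv(self) -> str:
        buf = io.StringIO()
        for k in sorted(self.metadata):
            buf.write(f"# {k}: {self.metadata[k]}\n")
        buf.write("time_s\tstress_mN_mm2\n")
        for t, s in zip(self.time, self.stress):
            buf.write(f"{t:.6f}\t{s:.8g}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "TwitchTrace":
        meta: dict[str, Any] = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
            elif not line.startswith("time_s"):
                t, s = line.split("\t")
                rows.append((float(t), float(s)))
        arr = np.array(rows)
        return cls(time=arr[:, 0], stress=arr[:, 1], metadata=meta)


@dataclass
class TwitchSummary:
    """Peak stress and activation-relative timing statistics (ms)."""

    peak_stress: float
    t_peak: float
    t50_rising: float
    t50_falling: float


@dataclass
class OccupancyLog:
    """Per-state occupancy fractions over time."""

    time: np.ndarray                 # s
    head_fractions: np.ndarray       # (n_steps, 6), states 1..6
    site_fractions: np.ndarray       # (n_steps, 4), states 1..4

    @property
    def srx_fraction(self) -> np.ndarray:
        return self.head_fractions[:, SRX_STATE - 1]

    @property
    def bound_fraction(self) -> np.ndarray:
        return self.head_fractions[:, [s - 1 for s in BOUND]].sum(axis=1)


# ---------------------------------------------------------------------------
# initialization

def _initial_states(config: ModelConfig, ca0: float, rng: np.random.Generator):
    """Sample initial head/site states from per-unit stationary distributions.

    Uses the matrix-exponential machinery's dt->infinity limit at the
    resting calcium and rest geometry; binding of a head is admitted only if
    its paired site was sampled permissive and unoccupied.
    """
    import warnings

    from ._engine import pack_params
    state = build_lattice(config)
    lat = config.lattice
    par = pack_params(config)

    tr = thin_filament_rates(np.asarray(ca0), False, config.thin)
    qt = build_rate_matrix({(1, 2): float(tr["rt12"]), (2, 1): float(tr["rt21"]),
                            (2, 3): float(tr["rt23"]), (3, 2): float(tr["rt32"]),
                            (3, 4): float(tr["rt34"]), (4, 3): float(tr["rt43"]),
                            (4, 1): float(tr["rt41"])},
                           n_states=4, forbidden=FORBIDDEN_T)
    pi_t = steady_state_init(qt)
    nthn, nst = lat.n_thin, lat.nodes_per_thin
    site_state = rng.choice(4, size=(nthn, nst), p=pi_t).astype(np.int8)

    dx = state.head_dx()
    _, rx61 = srx_rates(np.asarray(ca0), config.kinetics)
    fac = np.ones(9)
    head_state = np.zeros(state.n_heads, dtype=np.int8)
    occ = np.zeros((nthn, nst), dtype=np.int64)
    cap = lat.site_capacity
    q6 = np.zeros((6, 6))
    for h in range(state.n_heads):
        g, j = state.head_thin[h], state.head_site[h]
        gate = bool(site_state[g, j] == 3 and occ[g, j] < cap)
        u_w, u_s, f_s = _engine._head_strain(dx[h], par)
        _engine._head_q(q6, u_w, u_s, f_s, float(rx61), gate, par, fac)
        with warnings.catch_warnings():
            # gated heads make states 2..5 transient; the component-wise
            # stationary fallback is exactly what we want here
            warnings.simplefilter("ignore")
            pi = steady_state_init(q6)
        s = int(rng.choice(6, p=pi))
        if s in (1, 2, 3):
            if gate:
                occ[g, j] += 1
            else:
                s = 0
        head_state[h] = s
    return head_state, site_state


def _factor_array(factors: RateFactors | None) -> np.ndarray:
    if factors is None:
        return np.ones(9)
    return factors.to_array()


# ---------------------------------------------------------------------------
# main entry points

def run_model(config: ModelConfig,
              factors: RateFactors | None = None,
              seed: int | tuple = 0,
              ca_series: np.ndarray | None = None,
              hold_pca: float | None = None,
              log_heads: bool = False):
    """Low-level run returning (trace, occupancy, head_log).

    ``ca_series`` overrides the parametric transient; ``hold_pca`` holds
    calcium constant (steady-state studies).  ``seed`` may be an int or a
    tuple fed to :class:`numpy.random.SeedSequence`.
    """
    n_steps = config.n_steps
    t = np.arange(n_steps) * config.dt / 1000.0
    if ca_series is None:
        if hold_pca is not None:
            ca_series = np.full(n_steps, 10.0 ** (-hold_pca))
        else:
            ca_series = calcium_transient(t, config.calcium)
    ca_series = np.asarray(ca_series, dtype=float)
    if ca_series.shape != (n_steps,):
        raise ValueError("calcium series length must match the step count")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    head_state0, site_state0 = _initial_states(config, float(ca_series[0]), rng)

    state = build_lattice(config)
    lat = config.lattice
    nh = state.n_heads
    uniforms = rng.random((n_steps, nh + lat.n_thin * lat.nodes_per_thin))
    par = _engine.pack_params(config)
    out = _engine.run_twitch(
        ca_series, par, _factor_array(factors),
        state.x_thick_rest, state.x_thin_rest,
        state.head_thick, state.head_crown, state.head_thin,
        head_state0, site_state0,
        lat.k_thick_segment, lat.k_thin_segment, lat.crown_spacing,
        lat.thin_repeat, lat.half_sarcomere_length,
        lat.titin_a, lat.titin_b, float(state.titin_rest_gap),
        uniforms, log_heads)
    force, head_counts, site_counts, head_log, status, fail_step = out
    if status != _engine.STATUS_OK:
        raise SimulationError(int(fail_step))

    area = cross_sectional_area(lat)
    stress = force * PN_TO_MN / area
    trace = TwitchTrace(time=t, stress=stress, metadata={
        "factors": np.array2string(_factor_array(factors), precision=6),
        "seed": str(seed),
        "replicates": "1",
        "config": config.hash(),
    })
    occ = OccupancyLog(time=t,
                       head_fractions=head_counts / nh,
                       site_fractions=site_counts / (lat.n_thin * lat.nodes_per_thin))
    return trace, occ, (head_log if log_heads else None)


def simulate_twitch(factors: RateFactors | None, config: ModelConfig,
                    seed: int | tuple = 0) -> TwitchTrace:
    """One stochastic isometric twitch under the configured transient."""
    trace, _, _ = run_model(config, factors, seed)
    return trace


def average_replicates(factors: RateFactors | None, config: ModelConfig,
                       n: int = 50, seed: int | tuple = 0) -> TwitchTrace:
    """Pointwise mean of ``n`` independent-seed twitches (default 50).

    Replicate r uses the seed tuple ``(*seed, r)`` so any replicate can be
    regenerated standalone.
    """
    if n < 1:
        raise ValueError("replicate count must be >= 1")
    base = (seed,) if isinstance(seed, int) else tuple(seed)
    acc = None
    trace = None
    for r in range(n):
        trace = simulate_twitch(factors, config, seed=base + (r,))
        acc = trace.stress if acc is None else acc + trace.stress
    mean = acc / n
    meta = dict(trace.metadata)
    meta["replicates"] = str(n)
    meta["seed"] = str(base)
    return TwitchTrace(time=trace.time, stress=mean, metadata=meta)


def state_occupancy(config: ModelConfig,
                    factors: RateFactors | None = None,
                    seed: int | tuple = 0,
                    hold_pca: float | None = None) -> OccupancyLog:
    """Per-state occupancy fractions over a run (state logging enabled)."""
    _, occ, _ = run_model(config, factors, seed, hold_pca=hold_pca,
                          log_heads=False)
    return occ


# ---------------------------------------------------------------------------
# summary statistics

def twitch_summary(trace: TwitchTrace, onset_s: float = 0.0) -> TwitchSummary:
    """Peak stress, time to peak and 50% rise/relaxation times.

    Stress is measured above the pre-onset baseline; times are reported in
    ms relative to activation onset (the stimulus time).  Crossings are
    linearly interpolated between samples.
    """
    t_ms = (trace.time - onset_s) * 1000.0
    y = trace.stress - np.interp(onset_s, trace.time, trace.stress)
    mask = t_ms >= 0
    t_ms, y = t_ms[mask], y[mask]
    if y.size < 3 or np.max(y) <= 0 or np.ptp(y) == 0:
        raise NoTwitchError("trace has no positive excursion above baseline")
    ipk = int(np.argmax(y))
    peak = float(y[ipk])
    if ipk == 0 or np.all(np.diff(y) >= 0):
        raise NoTwitchError("trace is monotone; no twitch to summarize")
    half = peak / 2.0

    def cross(tt, yy, level):
        above = yy >= level
        idx = np.flatnonzero(above[1:] != above[:-1])
        if idx.size == 0:
            return None
        i = idx[0]
        f = (level - yy[i]) / (yy[i + 1] - yy[i])
        return float(tt[i] + f * (tt[i + 1] - tt[i]))

    t50r = cross(t_ms[:ipk + 1], y[:ipk + 1], half)
    t50f = cross(t_ms[ipk:], y[ipk:], half)
    if t50r is None or t50f is None:
        raise NoTwitchError("50% crossings not found")
    return TwitchSummary(peak_stress=peak, t_peak=float(t_ms[ipk]),
                         t50_rising=t50r, t50_falling=t50f)
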