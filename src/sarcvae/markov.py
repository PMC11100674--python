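"""Continuous-time Markov machinery: rate matrices, matrix-exponential
transition probabilities, state sampling, and steady-state initialization.

State transitions are propagated per timestep with ``P = exp(Q dt)`` rather
than the first-order ``1 - exp(-r dt)`` approximation: the matrix
exponential conserves probability exactly for any step size and captures
multi-step paths (``p_15 > 0`` even though ``r_15 = 0``), which is what
permits 1 ms steps despite near-instantaneous rates at high strain.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.linalg import expm, null_space

#: structurally forbidden crossbridge transitions (1-based state labels)
FORBIDDEN_X = ((1, 5), (5, 4))
#: forbidden thin-filament transition
FORBIDDEN_T = ((1, 4),)


def build_rate_matrix(rates: dict[tuple[int, int], float] | np.ndarray,
                      n_states: int | None = None,
                      forbidden=()) -> np.ndarray:
    """Assemble a conservative rate matrix Q (1/ms).

    ``rates`` is either a dense matrix of off-diagonal rates or a mapping
    ``(i, j) -> r_ij`` with 1-based state labels.  The diagonal is set so
    every row sums to exactly zero; ``forbidden`` entries are hard zeros.
    """
    if isinstance(rates, dict):
        if n_states is None:
            n_states = max(max(i, j) for i, j in rates)
        q = np.zeros((n_states, n_states))
        for (i, j), r in rates.items():
            if i == j:
                raise ValueError("diagonal entries are derived, not supplied")
            q[i - 1, j - 1] = r
    else:
        q = np.array(rates, dtype=float)
        np.fill_diagonal(q, 0.0)
    if np.any(q < 0):
        raise ValueError("transition rates must be non-negative")
    for i, j in forbidden:
        q[i - 1, j - 1] = 0.0
    np.fill_diagonal(q, 0.0)
    # compensated per-row sums: every row then sums to exactly zero under
    # compensated (fsum) summation, and to within a few ulp under numpy's
    # pairwise summation
    diag = [-math.fsum(row) for row in q]
    np.fill_diagonal(q, diag)
    return q


def transition_probabilities(q: np.ndarray, dt: float) -> np.ndarray:
    """Stochastic matrix ``P = exp(Q dt)`` (dt in ms).

    Uses scaling-and-squaring Pade approximation via :func:`scipy.linalg.expm`.
    Rows are clipped of tiny negative round-off and renormalized at the
    1e-12 level.
    """
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("rate matrix must be finite")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    p = expm(q * dt)
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    return p


def sample_transition(p: np.ndarray, current_state: int, u: float) -> int:
    """Next state by cumulative inversion of row ``current_state`` (0-based).

    Deterministic given ``(p, current_state, u)``: returns the smallest j
    with ``cumsum(P[i, :j+1]) > u``.
    """
    if not (0.0 <= u < 1.0):
        raise ValueError("uniform draw must lie in [0, 1)")
    c = np.cumsum(p[current_state])
    return int(np.searchsorted(c, u, side="right"))


def steady_state_init(q: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution pi with ``pi Q = 0`` and ``sum(pi) = 1``.

    Computed from the null space of ``Q^T``.  For a reducible chain the
    null space has dimension > 1; a component-wise stationary distribution
    (uniform mixture of the extremal ones) is returned with a warning.
    """
    q = np.asarray(q, dtype=float)
    ns = null_space(q.T, rcond=tol)
    if ns.shape[1] == 0:
        raise ValueError("rate matrix has no stationary distribution")
    if ns.shape[1] > 1:
        warnings.warn("reducible rate matrix: returning a component-wise "
                      "stationary distribution", stacklevel=2)
    pi = np.abs(ns).sum(axis=1)
    return pi / pi.sum()
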