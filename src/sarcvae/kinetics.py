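"""Baseline transition rates of the crossbridge cycle and thin filament.

Crossbridge cycle (per head, states 1..6):

    1 DRX -> 2 loosely bound -> 3 post-powerstroke -> 4 rigor-like
      -> 5 detached/ADP -> 1, with 1 <-> 6 (SRX) exchange.

Forward rates depend on the head's strain through the weak/strong spring
energies ``U_W``, ``U_S`` (KT) and the strong-state axial force ``F_S``;
reverse rates follow Boltzmann detailed balance against the state free
energies ``G_i``, so stationary occupancies of isolated pairs reproduce
``p_j/p_i = exp(-(G_j - G_i))``.

Thin filament (per regulatory site, states 1..4): calcium binding,
cTnC-cTnI switching and tropomyosin movement, with reverse rates derived
from the printed equilibrium constants and a x100 nearest-neighbour
cooperative boost of the activating forward rates.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import least_squares

from .params import (FACTOR_NAMES, CalciumParams, ConfigurationError,
                     KineticParams, ThinFilamentParams)

_EXP_CLIP = 60.0  # exponent clip; keeps rates finite near strain walls


def _clip_exp(x):
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


# ---------------------------------------------------------------------------
# crossbridge rates

def crossbridge_forward_rates(u_w, u_s, f_s, params: KineticParams):
    """Strain-dependent forward rates ``rx12, rx23, rx34, rx45, rx51`` (1/ms).

    ``u_w``/``u_s`` are the weak/strong spring energies (KT) and ``f_s`` the
    strong-state axial force (KT/nm) at the head's current nearest-site
    geometry.  ``rx15`` and ``rx54`` are structural zeros.  Rates are
    clipped at ``params.rate_ceiling``.
    """
    u_w = np.asarray(u_w, dtype=float)
    u_s = np.asarray(u_s, dtype=float)
    f_s = np.asarray(f_s, dtype=float)
    if not (np.all(np.isfinite(u_w)) and np.all(np.isfinite(u_s))):
        raise ValueError("strain energies must be finite")
    p = params
    rx12 = p.tau * _clip_exp(-u_w)
    rx23 = p.A * (1.0 + np.tanh(p.B + p.C * (u_w - u_s)))
    if p.rx34_form == "printed":
        rx34 = p.D * (1.0 + np.tanh(_clip_exp(-f_s)))
    else:  # force_tanh
        rx34 = p.D * (1.0 + np.tanh(p.rx34_kappa * f_s))
    if p.rx45_form == "shifted":
        rx45 = p.E * np.maximum(0.0, u_s - p.G4_offset + _clip_exp(-f_s))
    else:  # printed
        rx45 = p.E * np.maximum(0.0, u_s + p.dG_ATP + _clip_exp(-f_s))
    rx51 = np.broadcast_to(np.asarray(p.H, dtype=float), u_w.shape).copy()
    out = dict(rx12=rx12, rx23=rx23, rx34=rx34, rx45=rx45, rx51=rx51)
    return {k: np.minimum(v, p.rate_ceiling) for k, v in out.items()}


def reverse_rate(r_fwd, g_i, g_j, ceiling: float = 1e3):
    """Detailed-balance reverse rate ``r_ji = r_ij * exp(G_j - G_i)``.

    The convention is Boltzmann-consistent: an isolated reversible pair
    equilibrates at ``p_j/p_i = r_ij/r_ji = exp(-(G_j - G_i))``, occupying
    the lower-free-energy state more.
    """
    r_fwd = np.asarray(r_fwd, dtype=float)
    if np.any(r_fwd < 0):
        raise ValueError("forward rate must be non-negative")
    return np.minimum(r_fwd * _clip_exp(np.asarray(g_j, float) - np.asarray(g_i, float)),
                      ceiling)


def free_energies(u_w, u_s, params: KineticParams):
    """State free energies ``G1..G4`` (KT) at the given strain energies."""
    return (np.asarray(params.G1, dtype=float) + 0.0 * np.asarray(u_w, float),
            np.asarray(u_w, float) + params.G2_offset,
            np.asarray(u_s, float) + params.G3_offset,
            np.asarray(u_s, float) + params.G4_offset)


def srx_rates(ca, params: KineticParams):
    """DRX<->SRX exchange: ``rx16`` constant, ``rx61`` a Hill function of
    calcium rising from ``rx61_base`` to ``rx61_max`` (1/ms)."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("calcium concentration must be positive")
    hill = ca ** params.hill_b / (params.ca50 ** params.hill_b + ca ** params.hill_b)
    rx61 = params.rx61_base + (params.rx61_max - params.rx61_base) * hill
    rx16 = np.broadcast_to(np.asarray(params.rx16, dtype=float), ca.shape).copy()
    return rx16, rx61


# ---------------------------------------------------------------------------
# thin filament rates

def thin_filament_rates(ca, neighbor_active, params: ThinFilamentParams):
    """All forward and reverse regulatory-unit rates (1/ms) at ``ca`` (M).

    Reverse rates come from the equilibrium constants (calcium cancels in
    ``rt21``); cooperativity multiplies the activating forward rates by
    ``coop_factor`` when ``neighbor_active`` and leaves reverse rates
    unchanged.  ``rt14 = 0`` always.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("calcium concentration must be positive")
    p = params
    boost = np.where(np.asarray(neighbor_active, bool), p.coop_factor, 1.0)
    rates = {
        "rt12": p.rt12_coeff * ca * boost,
        "rt23": p.rt23 * np.ones_like(ca) * boost,
        "rt34": p.rt34 * np.ones_like(ca) * boost,
        "rt41": p.rt41 * np.ones_like(ca) * (
            boost if p.coop_on_deactivation else 1.0),
        "rt21": (p.rt12_coeff / p.Kt1_coeff) * np.ones_like(ca),
        "rt32": (p.rt23 / p.Kt2) * np.ones_like(ca),
        "rt43": (p.rt34 / p.Kt3) * np.ones_like(ca),
        "rt14": np.zeros_like(ca),
    }
    return rates


# ---------------------------------------------------------------------------
# calcium transient

def calcium_transient(t, params: CalciumParams):
    """Intracellular calcium concentration (M) at time ``t`` (s).

    ``ca(t) = ca_dia + (ca_sys - ca_dia) * exp(-b (t^a - t_p)^2 / w^2)``;
    the transient is bounded between the diastolic and systolic anchors and
    peaks at ``t = t_p^(1/a)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    p = params
    shape = np.exp(-p.b * (t ** p.a - p.t_p) ** 2 / p.w ** 2)
    ca = p.ca_dia + (p.ca_sys - p.ca_dia) * shape
    if not np.all(np.isfinite(ca)):
        raise ConfigurationError("calcium transient is non-finite")
    return ca


def pca(ca):
    """-log10 of a molar calcium concentration."""
    return -np.log10(np.asarray(ca, dtype=float))


def fit_calcium_transient(t, ca, params: CalciumParams | None = None) -> CalciumParams:
    """Fit the three shape parameters (a, t_p, w) to a measured transient.

    The pCa anchors are taken from ``params`` (they set the absolute
    magnitude, as the measurement is typically ratiometric).  Returns a new
    :class:`CalciumParams`.
    """
    base = params or CalciumParams()
    t = np.asarray(t, float)
    ca = np.asarray(ca, float)

    def resid(x):
        a, t_p, w = x
        trial = CalciumParams(pca_dia=base.pca_dia, pca_sys=base.pca_sys,
                              a=a, t_p=t_p, w=w, b=base.b)
        return (calcium_transient(t, trial) - ca) / base.ca_sys

    sol = least_squares(resid, x0=[base.a, base.t_p, base.w],
                        bounds=([1e-3, 1e-3, 1e-3], [5.0, 5.0, 5.0]))
    a, t_p, w = sol.x
    return CalciumParams(pca_dia=base.pca_dia, pca_sys=base.pca_sys,
                         a=float(a), t_p=float(t_p), w=float(w), b=base.b)


# ---------------------------------------------------------------------------
# rate factors

@dataclass
class RateFactors:
    """Nine multiplicative perturbations of the baseline rates.

    Stored as plain multipliers in ``[0.1, 100]``; inference operates on
    log10 scale.  Each named factor scales one forward rate, and its
    detailed-balance / equilibrium-constant reverse partner inherits the
    scaling automatically.
    """

    rx12: float = 1.0
    rx23: float = 1.0
    rx34: float = 1.0
    rx45: float = 1.0
    rx16: float = 1.0
    rt12: float = 1.0
    rt23: float = 1.0
    rt34: float = 1.0
    rt41: float = 1.0

    LOWER = 0.1
    UPPER = 100.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ConfigurationError(f"factor {f.name} must be positive")
            if not (self.LOWER <= v <= self.UPPER):
                raise ConfigurationError(
                    f"factor {f.name}={v} outside the prior range "
                    f"({self.LOWER}, {self.UPPER})")

    @classmethod
    def from_array(cls, values, names=FACTOR_NAMES) -> "RateFactors":
        return cls(**dict(zip(names, map(float, values))))

    def to_array(self, names=FACTOR_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    def log10_array(self, names=FACTOR_NAMES) -> np.ndarray:
        return np.log10(self.to_array(names))

    def replace(self, **kw) -> "RateFactors":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        for k in kw:
            if k not in d:
                raise KeyError(f"unknown rate factor {k!r}")
        d.update(kw)
        return RateFactors(**d)


def apply_rate_factors(base_rates: dict, factors: RateFactors) -> dict:
    """Scale named forward rates by their factors.

    ``base_rates`` maps rate names (e.g. ``"rx12"``) to values; only names
    present in the factor vector are scaled, everything else is returned
    untouched.  Reverse rates are not in the map — they are derived from
    the scaled forward rates downstream.
    """
    out = dict(base_rates)
    for name in FACTOR_NAMES:
        if name in out:
            out[name] = out[name] * getattr(factors, name)
    return out
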