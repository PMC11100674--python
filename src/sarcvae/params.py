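"""Model parameters and configuration.

All energies are expressed in units of KT, lengths in nm, forces in pN unless
stated otherwise, rates in 1/ms and calcium concentrations in molar.  Every
constant that the half-sarcomere model uses is collected here in frozen-ish
dataclasses so a complete model configuration can be dumped to / loaded from a
single YAML document.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

#: thermal energy scale used to convert spring forces (KT/nm) to pN.
KT_PN_NM = 4.1


class ConfigurationError(ValueError):
    """Raised when a configuration value is physically inadmissible."""


@dataclass
class CrossbridgeSpringParams:
    """Two-spring (linear + torsional) myosin head.

    ``r`` is the polar distance from the head root to its nearest binding
    site and ``theta`` the lever angle relative to the thick-filament axis.
    The weak (pre-powerstroke) and strong (post-powerstroke) states differ
    only in their rest coordinates; the powerstroke shortens the lever
    (``r_S < r_W``) and swings it toward the M-line (``theta_S > theta_W``).
    """

    k_r: float = 5.0          # KT / nm^2
    k_theta: float = 40.0     # KT / rad^2
    r_W: float = 19.93        # nm
    r_S: float = 16.4         # nm
    theta_W: float = 47.16    # degrees by default (see ``angle_unit``)
    theta_S: float = 73.2
    #: the printed rest angles exceed 2*pi, so a literal radian reading is
    #: dimensionally implausible; degrees is the default interpretation.
    angle_unit: str = "deg"

    def __post_init__(self) -> None:
        if self.k_r <= 0 or self.k_theta <= 0:
            raise ConfigurationError("crossbridge spring stiffnesses must be positive")
        if not self.r_S < self.r_W:
            raise ConfigurationError("powerstroke must shorten the lever (r_S < r_W)")
        if self.angle_unit not in ("deg", "rad"):
            raise ConfigurationError(f"unknown angle unit {self.angle_unit!r}")

    @property
    def theta_W_rad(self) -> float:
        return math.radians(self.theta_W) if self.angle_unit == "deg" else self.theta_W

    @property
    def theta_S_rad(self) -> float:
        return math.radians(self.theta_S) if self.angle_unit == "deg" else self.theta_S


@dataclass
class LatticeConfig:
    """Geometry of the half-sarcomere filament lattice.

    The default geometry is 4 thick and 8 thin filaments packed hexagonally
    with transverse periodic boundaries.  Thick filaments are anchored at the
    M-line, thin filaments at the Z-disc; titin links each thick filament's
    free end to the Z-disc.  Crossbridge crowns sit every ``thick_repeat/3``
    nm along a thick filament; one myosin-accessible target zone (binding
    site) faces a given neighbour every ``thin_repeat`` nm of thin filament.
    Filament segment stiffnesses are the whole-filament measurements scaled
    to the repeat distances (2020 pN/nm per 43 nm of thick filament,
    1743 pN/nm per 38.7 nm of thin filament).
    """

    n_thick: int = 4
    n_thin: int = 8
    thick_repeat: float = 43.0       # nm, crown triplet repeat
    thin_repeat: float = 38.7        # nm, binding-site repeat
    k_thick: float = 2020.0          # pN/nm per thick_repeat segment
    k_thin: float = 1743.0           # pN/nm per thin_repeat segment
    nodes_per_thick: int = 60        # crowns per thick filament
    nodes_per_thin: int = 30         # binding sites per thin filament
    heads_per_node: int = 3
    #: face-to-face distance between neighbouring thick filaments; only used
    #: for the cross-sectional area that converts force to stress.
    lattice_spacing: float = 42.0    # nm
    half_sarcomere_length: float = 1200.0  # nm
    #: effective radial distance from a head's root to the thin-filament
    #: binding-site axis at fixed lattice spacing.  Not printed anywhere;
    #: calibrated so that the resting/active state-occupancy anchors of the
    #: kinetic scheme are met (see docs/methods.md).
    radial_gap: float = 15.4         # nm
    #: axial stagger of binding-site target zones between thin filaments,
    #: as a fraction of ``thin_repeat`` distributed over the filaments
    #: (filament g is shifted by g/n_thin of a repeat).  Emulates the
    #: helical offset of target zones between neighbouring filaments and
    #: densifies the head/site axial-offset distribution.
    thin_stagger: float = 1.0
    #: how many heads one binding-site target zone can hold simultaneously.
    #: A zone spans ~3 accessible actin monomers per pseudo-repeat, so a
    #: capacity above one is physically plausible; calibrated against the
    #: maximal-activation bound-fraction anchor (see docs/methods.md).
    site_capacity: int = 2
    titin_a: float = 220.0           # pN
    titin_b: float = 0.0045          # 1/nm

    def __post_init__(self) -> None:
        for name in ("thick_repeat", "thin_repeat", "k_thick", "k_thin",
                     "lattice_spacing", "half_sarcomere_length", "radial_gap",
                     "titin_a", "titin_b"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("n_thick", "n_thin", "nodes_per_thick", "nodes_per_thin",
                     "heads_per_node"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.heads_per_node > 6:
            raise ConfigurationError("at most 6 azimuthal head directions per crown")
        if self.n_thick not in (1, 2, 4):
            raise ConfigurationError("n_thick must be one of 1, 2, 4 for the "
                                     "periodic hexagonal packing")
        if self.n_thin != 2 * self.n_thick:
            raise ConfigurationError("hexagonal packing requires n_thin = 2*n_thick")

    @property
    def crown_spacing(self) -> float:
        """Axial distance between crossbridge crowns (3 crowns per repeat)."""
        return self.thick_repeat / 3.0

    @property
    def k_thick_segment(self) -> float:
        """Stiffness of one inter-crown thick-filament segment (pN/nm)."""
        return self.k_thick * self.thick_repeat / self.crown_spacing

    @property
    def k_thin_segment(self) -> float:
        """Stiffness of one inter-site thin-filament segment (pN/nm)."""
        return self.k_thin

    @property
    def n_heads(self) -> int:
        return self.n_thick * self.nodes_per_thick * self.heads_per_node

    @property
    def n_sites(self) -> int:
        return self.n_thin * self.nodes_per_thin


@dataclass
class KineticParams:
    """Crossbridge 6-state cycle constants.

    States: 1 DRX (detached, ATP), 2 loosely bound, 3 post-powerstroke,
    4 rigor-like, 5 detached (ADP), 6 SRX.  Free energies (KT):
    ``G1``, ``G2 = U_W + G2_offset``, ``G3 = U_S + G3_offset``,
    ``G4 = U_S + G4_offset``; the full cycle drops ``dG_ATP``.
    Reverse rates follow Boltzmann detailed balance,
    ``r_ji = r_ij * exp(G_j - G_i)``.
    """

    G1: float = -2.3
    G2_offset: float = -4.3
    G3_offset: float = -18.6
    G4_offset: float = -20.72
    dG_ATP: float = -23.0
    tau: float = 7.2      # 1/ms, attachment prefactor
    A: float = 0.8        # 1/ms
    B: float = 5.0
    C: float = 0.4
    D: float = 0.9        # 1/ms
    E: float = 1.2        # 1/ms
    H: float = 0.1        # 1/ms
    rx16: float = 0.05        # 1/ms  (50 s^-1), DRX -> SRX
    rx61_base: float = 0.05   # 1/ms  (50 s^-1), SRX -> DRX at zero calcium
    rx61_max: float = 0.5     # 1/ms, saturating SRX -> DRX
    ca50: float = 1e-6        # M, half-activation of the SRX exit rate
    hill_b: float = 4.0
    #: rates are clipped here to keep the rate matrix well conditioned near
    #: the steep strain walls of the energy landscape.
    rate_ceiling: float = 1e3  # 1/ms
    #: functional form of the 3->4 (ADP release) rate; "printed" is
    #: D*(1 + tanh(exp(-F_S))), "force_tanh" is D*(1 + tanh(kappa*F_S)).
    rx34_form: str = "force_tanh"
    rx34_kappa: float = -0.4
    #: 4->5 (ATP-induced detachment) rate; "shifted" rectifies
    #: E*(U_S - G4_offset + exp(-F_S)) at zero, "printed" uses
    #: E*(U_S + dG_ATP + exp(-F_S)) which is negative for most geometries.
    rx45_form: str = "shifted"

    def __post_init__(self) -> None:
        for name in ("tau", "A", "D", "E", "H", "rx16", "rx61_base",
                     "rx61_max", "ca50", "hill_b", "rate_ceiling"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.rx34_form not in ("printed", "force_tanh"):
            raise ConfigurationError(f"unknown rx34_form {self.rx34_form!r}")
        if self.rx45_form not in ("printed", "shifted"):
            raise ConfigurationError(f"unknown rx45_form {self.rx45_form!r}")


@dataclass
class ThinFilamentParams:
    """Four-state thin-filament regulatory unit.

    States: 1 off, 2 calcium bound to cTnC, 3 cTnC-cTnI interaction switched,
    4 tropomyosin moved (myosin-permissive).  Reverse rates are derived from
    the equilibrium constants and are never stored independently:
    ``rt21 = rt12*[Ca]/ (Kt1*[Ca]) = rt12_coeff/Kt1_coeff`` (calcium cancels),
    ``rt32 = rt23/Kt2``, ``rt43 = rt34/Kt3``.  The 4->1 transition is one-way
    (``rt14 = 0``).  Nearest-neighbour cooperativity multiplies the
    *activating* forward rates (1->2, 2->3, 3->4) by ``coop_factor`` when a
    neighbouring site is in a calcium-bound state.
    """

    rt12_coeff: float = 37650.0    # 1/(M*ms)
    rt23: float = 33.4             # 1/ms
    rt34: float = 0.13             # 1/ms
    rt41: float = 0.77             # 1/ms
    Kt1_coeff: float = 260000.0    # 1/M
    Kt2: float = 130.0
    Kt3: float = 0.91
    coop_factor: float = 100.0
    #: whether cooperativity also accelerates the 4->1 deactivation; the
    #: activating-only convention is the default (see docs/methods.md).
    coop_on_deactivation: bool = False

    def __post_init__(self) -> None:
        for name in ("rt12_coeff", "rt23", "rt34", "rt41",
                     "Kt1_coeff", "Kt2", "Kt3", "coop_factor"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")


@dataclass
class CalciumParams:
    """Parametric intracellular calcium transient.

    ``ca(t) = ca_dia + (ca_sys - ca_dia) * exp(-b * (t^a - t_p)^2 / w^2)``

    with ``t`` in seconds.  ``a`` sets the rise/fall asymmetry (peak at
    ``t_p^(1/a)``), ``w`` the width, and ``b`` (units s^(1-a)) the overall
    scale.  The transient is anchored in absolute terms between the diastolic
    and systolic pCa bounds.  Defaults emulate a mouse ventricular transient
    at ~33 C (time to peak ~30 ms, 50% decay ~120 ms after stimulus).
    """

    pca_dia: float = 7.0
    pca_sys: float = 6.0
    a: float = 0.22
    t_p: float = 0.462
    w: float = 0.198
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.pca_sys >= self.pca_dia:
            raise ConfigurationError("systolic pCa must be below diastolic pCa")
        if self.a <= 0 or self.w <= 0 or self.b <= 0:
            raise ConfigurationError("calcium shape parameters must be positive")

    @property
    def ca_dia(self) -> float:
        return 10.0 ** (-self.pca_dia)

    @property
    def ca_sys(self) -> float:
        return 10.0 ** (-self.pca_sys)


#: the nine baseline rates whose multiplicative factors are inferred.
FACTOR_NAMES = ("rx12", "rx23", "rx34", "rx45", "rx16",
                "rt12", "rt23", "rt34", "rt41")

THICK_FACTOR_NAMES = ("rx12", "rx23", "rx34", "rx45", "rx16")
THIN_FACTOR_NAMES = ("rt12", "rt23", "rt34", "rt41")


@dataclass
class ModelConfig:
    """Complete configuration of the half-sarcomere model."""

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    springs: CrossbridgeSpringParams = field(default_factory=CrossbridgeSpringParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    thin: ThinFilamentParams = field(default_factory=ThinFilamentParams)
    calcium: CalciumParams = field(default_factory=CalciumParams)
    dt: float = 1.0            # ms
    duration: float = 1000.0   # ms
    kt: float = KT_PN_NM       # pN*nm
    #: emit stress with the passive (titin) baseline subtracted
    subtract_baseline: bool = True
    #: mechanics fixed-point solve
    solver_tol: float = 1e-4   # nm
    solver_max_iter: int = 100

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        d = dict(d)
        kw: dict[str, Any] = {}
        for name, sub in (("lattice", LatticeConfig),
                          ("springs", CrossbridgeSpringParams),
                          ("kinetics", KineticParams),
                          ("thin", ThinFilamentParams),
                          ("calcium", CalciumParams)):
            if name in d:
                kw[name] = sub(**d.pop(name))
        kw.update(d)
        return cls(**kw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text))

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def reduced_lattice_config(**overrides: Any) -> ModelConfig:
    """A small lattice used for calibration runs and desk-scale studies.

    One thick and two thin filaments (transverse periodicity makes the
    geometry consistent) with 27 crowns of 2 heads: 27 crowns complete one
    full cycle of the crown/site axial-offset registration (lcm of the
    14.33 nm crown spacing and the 38.7 nm site repeat), so the head strain
    distribution matches the full lattice.  Kinetic constants are identical
    to the full model; only the lattice is smaller, so per-head state
    statistics are unchanged up to Monte-Carlo error.
    """
    lat = dict(n_thick=1, n_thin=2, nodes_per_thick=27, nodes_per_thin=11,
               heads_per_node=2, half_sarcomere_length=440.0)
    lat.update(overrides.pop("lattice", {}))
    return ModelConfig(lattice=LatticeConfig(**lat), **overrides)
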