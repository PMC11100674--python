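"""Half-sarcomere filament lattice and isometric mechanics.

The half-sarcomere is a 3D lattice of elastic thick and thin filaments with
transverse periodic boundaries.  Thick filaments are chains of crossbridge
crowns anchored at the M-line (x = 0); thin filaments are chains of binding
sites anchored at the Z-disc (x = half_sarcomere_length); titin links each
thick filament's free end to the Z-disc as a passive exponential spring.
Axial node positions are the mechanical degrees of freedom: the radial
lattice spacing is fixed, and every bound crossbridge couples its crown to
its paired binding site through the two-spring (linear + torsional) head.

The isometric force balance is solved per filament as a linear spring chain
under the (nonlinear, geometry-dependent) crossbridge point loads, iterated
to a fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import (KT_PN_NM, ConfigurationError, CrossbridgeSpringParams,
                     LatticeConfig, ModelConfig)

#: crossbridge states considered attached to actin
BOUND_STATES = (2, 3, 4)
#: attached states that load the strong (post-powerstroke) spring
STRONG_STATES = (3, 4)


class SolverError(RuntimeError):
    """Isometric balance failed to converge; carries the residual norm."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"mechanics fixed point not converged after {iterations} "
            f"iterations (residual {residual:.3e} nm)")


# ---------------------------------------------------------------------------
# crossbridge springs

def crossbridge_energy(r, theta, state: str, params: CrossbridgeSpringParams):
    """Elastic energy (KT) of a head at polar coordinates ``(r, theta)``.

    ``state`` selects the weak- or strong-state rest coordinates; ``theta``
    is in radians.
    """
    r0, th0 = _rest(state, params)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("polar distance r must be positive")
    return 0.5 * params.k_r * (r - r0) ** 2 + 0.5 * params.k_theta * (theta - th0) ** 2


def crossbridge_force(r, theta, state: str, params: CrossbridgeSpringParams):
    """Spring forces ``(k_r*(r-r0), k_theta*(theta-theta0))``.

    The radial component is in KT/nm, the torsional in KT/rad; both are the
    exact gradients of :func:`crossbridge_energy` in their coordinate.
    """
    r0, th0 = _rest(state, params)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("polar distance r must be positive")
    return params.k_r * (r - r0), params.k_theta * (theta - th0)


def _rest(state: str, params: CrossbridgeSpringParams):
    if state == "weak":
        return params.r_W, params.theta_W_rad
    if state == "strong":
        return params.r_S, params.theta_S_rad
    raise ValueError(f"unknown crossbridge spring state {state!r}")


def head_geometry(dx, radial_gap):
    """Polar coordinates of a head whose site sits ``dx`` nm toward the
    Z-disc at fixed radial distance ``radial_gap``."""
    dx = np.asarray(dx, dtype=float)
    r = np.sqrt(dx * dx + radial_gap * radial_gap)
    theta = np.arctan2(radial_gap, dx)
    return r, theta


def axial_site_force(dx, radial_gap, state: str,
                     params: CrossbridgeSpringParams, kt: float = KT_PN_NM):
    """Axial force (pN, +x toward the Z-disc) a bound head exerts on its site.

    Computed as ``-dU/d(dx)`` at fixed radial gap; the reaction on the crown
    is equal and opposite.
    """
    r, theta = head_geometry(dx, radial_gap)
    f_r, f_th = crossbridge_force(r, theta, state, params)
    # dr/d(dx) = dx/r ; dtheta/d(dx) = -radial_gap/r^2
    du_ddx = f_r * (np.asarray(dx, float) / r) + f_th * (-radial_gap / (r * r))
    return -du_ddx * kt


def axial_site_stiffness(dx, radial_gap, state: str,
                         params: CrossbridgeSpringParams,
                         kt: float = KT_PN_NM):
    """Local axial stiffness ``d^2 U / d(dx)^2`` of a bound head (pN/nm).

    Used to stabilize the force-balance iteration; negative curvature is
    clamped to zero by the callers.
    """
    dx = np.asarray(dx, dtype=float)
    d = radial_gap
    r2 = dx * dx + d * d
    r = np.sqrt(r2)
    r0, th0 = _rest(state, params)
    dr = r - r0
    dth = np.arctan2(d, dx) - th0
    term_r = params.k_r * ((dx / r) ** 2 + dr * d * d / (r2 * r))
    term_t = params.k_theta * (d * d / (r2 * r2) + 2.0 * dth * d * dx / (r2 * r2))
    return (term_r + term_t) * kt


def titin_force(delta_l, config: LatticeConfig):
    """Passive titin tension ``a*exp(b*dL)`` in pN; dL in nm."""
    return config.titin_a * np.exp(config.titin_b * np.asarray(delta_l, dtype=float))


def cross_sectional_area(config: LatticeConfig) -> float:
    """Cross-sectional area of the model in mm^2.

    The hexagonal unit cell is a rhombus of side ``lattice_spacing`` centred
    on a thick filament (it contains 1 thick and 2 thin filaments); the model
    area is ``n_thick`` such cells.  For the default 4-thick lattice this is
    the printed "4 times the area of the unit cell".
    """
    s = config.lattice_spacing
    area_nm2 = config.n_thick * s * s * math.sin(math.radians(60.0))
    return area_nm2 * 1e-12  # nm^2 -> mm^2


# ---------------------------------------------------------------------------
# lattice construction

@dataclass
class HalfSarcomereState:
    """Mechanical and kinetic state of the lattice.

    Positions are absolute axial coordinates (nm) with the M-line at 0 and
    the Z-disc at ``half_sarcomere_length``.  ``head_site`` is the current
    nearest-site pairing and is recomputed whenever positions change.
    """

    config: ModelConfig
    x_thick: np.ndarray        # (n_thick, nodes_per_thick)
    x_thin: np.ndarray         # (n_thin, nodes_per_thin)
    x_thick_rest: np.ndarray
    x_thin_rest: np.ndarray
    head_thick: np.ndarray     # (n_heads,) thick filament index
    head_crown: np.ndarray     # (n_heads,) crown index
    head_thin: np.ndarray      # (n_heads,) target thin filament index
    head_site: np.ndarray      # (n_heads,) paired site node index
    head_state: np.ndarray     # (n_heads,) in 1..6
    site_state: np.ndarray     # (n_thin, nodes_per_thin) in 1..4
    site_occupant: np.ndarray  # (n_thin, nodes_per_thin) head id or -1
    titin_rest_gap: float = 0.0
    neighbours: np.ndarray = field(default=None)  # (n_thick, 6) thin ids

    # -- derived quantities ----------------------------------------------
    @property
    def n_heads(self) -> int:
        return self.head_thick.size

    def head_positions(self) -> np.ndarray:
        return self.x_thick[self.head_thick, self.head_crown]

    def head_dx(self) -> np.ndarray:
        """Axial offset site minus head for the current pairing."""
        xs = self.x_thin[self.head_thin, self.head_site]
        return xs - self.head_positions()

    def repair(self) -> None:
        """Recompute the nearest-site pairing from current positions.

        Each detached head pairs with the axially nearest site on its
        azimuthal target thin filament (minimal 3D distance at fixed radial
        spacing); ties break toward the lower site index.  Attached heads
        keep the site they are bound to.
        """
        xh = self.head_positions()
        # distances to every node of the target filament
        d = np.abs(self.x_thin[self.head_thin] - xh[:, None])
        nearest = np.argmin(d, axis=1).astype(np.int64)
        bound = self.bound_spring_states() > 0
        self.head_site = np.where(bound, self.head_site, nearest)

    def titin_extension(self) -> np.ndarray:
        """Titin length change per thick filament relative to build."""
        gap = self.config.lattice.half_sarcomere_length - self.x_thick[:, -1]
        return gap - self.titin_rest_gap

    def bound_spring_states(self) -> np.ndarray:
        """Spring selection per head: 0 detached, 1 weak, 2 strong."""
        s = np.zeros(self.n_heads, dtype=np.int8)
        s[self.head_state == 2] = 1
        s[np.isin(self.head_state, STRONG_STATES)] = 2
        return s

    def boundary_force(self) -> float:
        """Total axial force transmitted to the Z-disc (pN).

        Sum of thin-filament anchor-segment tensions plus the titin
        tensions; equals the M-line reaction by Newton's third law.
        """
        lat = self.config.lattice
        k = lat.k_thin_segment
        # anchor-segment stretch > 0 when the chain is pulled toward the
        # M-line; tension then pulls the Z-disc inward (contractile).
        stretch0 = self.x_thin_rest[:, 0] - self.x_thin[:, 0]
        return float(np.sum(k * stretch0) + np.sum(
            titin_force(self.titin_extension(), lat)))


def _transverse_positions(config: LatticeConfig):
    """Thick/thin transverse coordinates and periodic supercell vectors."""
    s = config.lattice_spacing
    a1 = np.array([s, 0.0])
    a2 = np.array([s / 2.0, s * math.sqrt(3.0) / 2.0])
    n1 = {1: (1, 1), 2: (2, 1), 4: (2, 2)}.get(config.n_thick)
    if n1 is None:
        raise ConfigurationError("n_thick must be one of 1, 2, 4")
    if config.n_thin != 2 * config.n_thick:
        raise ConfigurationError("hexagonal packing requires n_thin = 2*n_thick")
    nx, ny = n1
    thick, thin = [], []
    for i in range(nx):
        for j in range(ny):
            base = i * a1 + j * a2
            thick.append(base)
            thin.append(base + (a1 + a2) / 3.0)
            thin.append(base + 2.0 * (a1 + a2) / 3.0)
    return np.array(thick), np.array(thin), nx * a1, ny * a2


def _neighbour_table(config: LatticeConfig) -> np.ndarray:
    """Six azimuthally ordered thin-filament neighbours per thick filament.

    Computed by minimum-image search over the periodic supercell; in small
    lattices distinct azimuth slots may map to the same thin filament.
    """
    thick, thin, L1, L2 = _transverse_positions(config)
    table = np.zeros((config.n_thick, 6), dtype=np.int64)
    for f, tp in enumerate(thick):
        cands = []
        for g, sp in enumerate(thin):
            for i in (-1, 0, 1):
                for j in (-1, 0, 1):
                    vec = sp + i * L1 + j * L2 - tp
                    cands.append((np.hypot(*vec), math.atan2(vec[1], vec[0]), g))
        cands.sort()
        dmin = cands[0][0]
        near = sorted({(round(ang, 9), g) for d, ang, g in cands
                       if d < dmin * 1.05})
        slots = [g for _, g in near]
        table[f] = [slots[k % len(slots)] for k in range(6)]
    return table


def build_lattice(config: ModelConfig, seed: int = 0) -> HalfSarcomereState:
    """Construct the resting lattice.

    All heads start in state 1 (DRX), all sites in state 1 (off); node
    positions are at their spring rest spacing.  The seed is recorded for
    provenance only — geometry is deterministic and the kinetic RNG stream
    is owned by the simulator.
    """
    lat = config.lattice
    nthk, ncr = lat.n_thick, lat.nodes_per_thick
    nthn, nst = lat.n_thin, lat.nodes_per_thin
    L = lat.half_sarcomere_length
    if ncr * lat.crown_spacing >= L:
        raise ConfigurationError("thick filament longer than the half-sarcomere")
    if nst * lat.thin_repeat >= L:
        raise ConfigurationError("thin filament longer than the half-sarcomere")

    x_thick = np.tile(np.arange(1, ncr + 1) * lat.crown_spacing, (nthk, 1))
    x_thin = np.tile(L - np.arange(1, nst + 1) * lat.thin_repeat, (nthn, 1))
    # helical target-zone stagger between thin filaments
    stagger = (np.arange(nthn) % nthn) / nthn * lat.thin_repeat * lat.thin_stagger
    x_thin = x_thin + stagger[:, None] - stagger.max() / 2.0

    nbr = _neighbour_table(lat)
    hpn = lat.heads_per_node
    head_thick, head_crown, head_thin = [], [], []
    for f in range(nthk):
        for c in range(ncr):
            for k in range(hpn):
                az = (2 * k + (c % 2)) % 6
                head_thick.append(f)
                head_crown.append(c)
                head_thin.append(nbr[f, az])
    state = HalfSarcomereState(
        config=config,
        x_thick=x_thick.astype(float),
        x_thin=x_thin.astype(float),
        x_thick_rest=x_thick.copy().astype(float),
        x_thin_rest=x_thin.copy().astype(float),
        head_thick=np.array(head_thick, dtype=np.int64),
        head_crown=np.array(head_crown, dtype=np.int64),
        head_thin=np.array(head_thin, dtype=np.int64),
        head_site=np.zeros(len(head_thick), dtype=np.int64),
        head_state=np.ones(len(head_thick), dtype=np.int8),
        site_state=np.ones((nthn, nst), dtype=np.int8),
        site_occupant=np.full((nthn, nst), -1, dtype=np.int64),
        titin_rest_gap=L - x_thick[0, -1],
        neighbours=nbr,
    )
    state.repair()
    return state


# ---------------------------------------------------------------------------
# isometric force balance

def _chain_solve(rest: np.ndarray, loads: np.ndarray, k: float) -> np.ndarray:
    """Equilibrium positions of an end-anchored linear spring chain.

    ``rest`` are the rest positions along +x with node 0 adjacent to the
    anchor and indices increasing toward the free end; ``loads`` are the
    signed axial loads (pN, +x) on each node.  Segment ``s`` must carry the
    summed load of every node outboard of it, so the displacements follow
    from one cumulative sum: ``u_s = sum_{t<=s} (sum_{j>=t} loads_j) / k``.
    The same formula covers both anchoring directions because the load signs
    carry the orientation.
    """
    outboard = np.cumsum(loads[::-1])[::-1]        # sum_{j>=s} loads[j]
    return rest + np.cumsum(outboard) / k


def _chain_solve_stiff(rest: np.ndarray, x_cur: np.ndarray,
                       loads: np.ndarray, stiff: np.ndarray,
                       k: float) -> np.ndarray:
    """Chain equilibrium with grounded stabilizing springs at loaded nodes.

    Solves ``k(u_{i+1} - 2u_i + u_{i-1}) + L_i - s_i (u_i - u_i^cur) = 0``
    (anchor at u = 0, free far end) for the displacement field ``u``.
    ``L_i`` is the attached-spring load evaluated at the current geometry
    and ``s_i >= 0`` its local stiffness, which damps the cross-filament
    fixed point without changing its solution.
    """
    from scipy.linalg import solveh_banded
    n = rest.size
    u_cur = x_cur - rest
    ab = np.zeros((2, n))
    ab[1, :] = 2.0 * k + stiff
    ab[1, -1] = k + stiff[-1]
    ab[0, 1:] = -k
    rhs = loads + stiff * u_cur
    u = solveh_banded(ab, rhs, lower=False)
    return rest + u


def solve_isometric_balance(state: HalfSarcomereState,
                            config: ModelConfig | None = None) -> float:
    """Settle node positions under the current crossbridge/titin loads.

    Fixed-point iteration: evaluate the (nonlinear) crossbridge and titin
    point loads at the current geometry, re-solve every filament as a linear
    chain, re-pair heads, and repeat until the largest node displacement per
    sweep is below ``solver_tol``.  Returns the final residual (nm).
    Raises :class:`SolverError` on non-convergence.
    """
    cfg = config or state.config
    lat = cfg.lattice
    springs = cfg.springs
    tol, max_iter = cfg.solver_tol, cfg.solver_max_iter
    residual = np.inf
    for it in range(1, max_iter + 1):
        spring_sel = state.bound_spring_states()
        dx = state.head_dx()
        f_site = np.zeros_like(dx)
        k_site = np.zeros_like(dx)
        for sel, name in ((1, "weak"), (2, "strong")):
            m = spring_sel == sel
            if np.any(m):
                f_site[m] = axial_site_force(dx[m], lat.radial_gap, name,
                                             springs, cfg.kt)
                k_site[m] = np.maximum(
                    axial_site_stiffness(dx[m], lat.radial_gap, name,
                                         springs, cfg.kt), 0.0)

        thin_loads = np.zeros_like(state.x_thin)
        thick_loads = np.zeros_like(state.x_thick)
        thin_stiff = np.zeros_like(state.x_thin)
        thick_stiff = np.zeros_like(state.x_thick)
        bound = spring_sel > 0
        idx_thin = (state.head_thin[bound], state.head_site[bound])
        idx_thick = (state.head_thick[bound], state.head_crown[bound])
        np.add.at(thin_loads, idx_thin, f_site[bound])
        np.add.at(thick_loads, idx_thick, -f_site[bound])
        np.add.at(thin_stiff, idx_thin, k_site[bound])
        np.add.at(thick_stiff, idx_thick, k_site[bound])
        ext = state.titin_extension()
        thick_loads[:, -1] += titin_force(ext, lat)
        thick_stiff[:, -1] += lat.titin_a * lat.titin_b * np.exp(lat.titin_b * ext)

        new_thick = np.empty_like(state.x_thick)
        new_thin = np.empty_like(state.x_thin)
        for f in range(lat.n_thick):
            new_thick[f] = _chain_solve_stiff(
                state.x_thick_rest[f], state.x_thick[f], thick_loads[f],
                thick_stiff[f], lat.k_thick_segment)
        for g in range(lat.n_thin):
            new_thin[g] = _chain_solve_stiff(
                state.x_thin_rest[g], state.x_thin[g], thin_loads[g],
                thin_stiff[g], lat.k_thin_segment)

        residual = max(float(np.max(np.abs(new_thick - state.x_thick))),
                       float(np.max(np.abs(new_thin - state.x_thin))))
        state.x_thick = new_thick
        state.x_thin = new_thin
        state.repair()
        if residual < tol:
            # final plain-chain polish: re-solve against the converged
            # loads without the stabilizing diagonals, which makes every
            # filament exactly at equilibrium for the evaluated loads and
            # the boundary reactions balance to machine precision
            spring_sel = state.bound_spring_states()
            dx = state.head_dx()
            f_site = np.zeros_like(dx)
            for sel, name in ((1, "weak"), (2, "strong")):
                m = spring_sel == sel
                if np.any(m):
                    f_site[m] = axial_site_force(dx[m], lat.radial_gap, name,
                                                 springs, cfg.kt)
            thin_loads = np.zeros_like(state.x_thin)
            thick_loads = np.zeros_like(state.x_thick)
            bound = spring_sel > 0
            np.add.at(thin_loads,
                      (state.head_thin[bound], state.head_site[bound]),
                      f_site[bound])
            np.add.at(thick_loads,
                      (state.head_thick[bound], state.head_crown[bound]),
                      -f_site[bound])
            for g in range(lat.n_thin):
                state.x_thin[g] = _chain_solve(
                    state.x_thin_rest[g], thin_loads[g], lat.k_thin_segment)
            # titin self-consistency converges at rate (titin slope /
            # filament stiffness) ~ 1e-2 per pass
            for _ in range(3):
                loads = thick_loads.copy()
                loads[:, -1] += titin_force(state.titin_extension(), lat)
                for f in range(lat.n_thick):
                    state.x_thick[f] = _chain_solve(
                        state.x_thick_rest[f], loads[f], lat.k_thick_segment)
            state.repair()
            return residual
    raise SolverError(residual, max_iter)


def total_elastic_energy(state: HalfSarcomereState) -> float:
    """Total elastic energy (pN*nm) — the brute-force objective.

    Filament chain springs + bound crossbridge two-spring energies + the
    titin exponential potential.  Used as an independent oracle for the
    fixed-point solver.
    """
    cfg = state.config
    lat = cfg.lattice
    e = 0.0
    # segment stretches measured against the rest positions (the anchor has
    # zero displacement), so axial stagger offsets carry no elastic energy
    for f in range(lat.n_thick):
        u = np.concatenate(([0.0], state.x_thick[f] - state.x_thick_rest[f]))
        e += 0.5 * lat.k_thick_segment * float(np.sum(np.diff(u) ** 2))
    for g in range(lat.n_thin):
        u = np.concatenate(([0.0], state.x_thin[g] - state.x_thin_rest[g]))
        e += 0.5 * lat.k_thin_segment * float(np.sum(np.diff(u) ** 2))
    spring_sel = state.bound_spring_states()
    dx = state.head_dx()
    for sel, name in ((1, "weak"), (2, "strong")):
        m = spring_sel == sel
        if np.any(m):
            r, th = head_geometry(dx[m], lat.radial_gap)
            e += cfg.kt * float(np.sum(crossbridge_energy(r, th, name,
                                                          cfg.springs)))
    ext = state.titin_extension()
    e += float(np.sum(lat.titin_a / lat.titin_b * np.exp(lat.titin_b * ext)))
    return e
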