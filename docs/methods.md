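# Methods

`sarcvae` couples a spatially explicit stochastic model of an isometric
cardiac half-sarcomere to an amortized Bayesian inverse-inference pipeline.
This note records the model, its assumptions, the numerical choices, and
the places where the design was genuinely open.

## The half-sarcomere model

### Lattice mechanics

The half-sarcomere is a 3D lattice of 4 thick and 8 thin filaments packed
hexagonally with transverse periodic boundaries (reduced lattices of 1 or 2
thick filaments keep the same packing through the periodic images).  Each
filament is a chain of linear springs: thick filaments carry crossbridge
crowns every 43/3 nm and are anchored at the M-line; thin filaments carry
one myosin-accessible target zone per 38.7 nm facing each neighbour and are
anchored at the Z-disc.  Whole-filament stiffness measurements (2020 pN/nm
per 43 nm of thick filament, 1743 pN/nm per 38.7 nm of thin filament) set
the segment spring constants.  Titin ties each thick filament's free end to
the Z-disc as a passive exponential element `F = a·exp(b·ΔL)` with
a = 220 pN and b = 0.0045 nm⁻¹, measured from the build geometry.

A myosin head is a linear plus torsional spring pair
(`k_r` = 5 KT/nm², `k_θ` = 40 KT/rad²) whose polar coordinates `(r, θ)`
are fixed by the axial offset to its paired binding site and a constant
radial gap.  The weak (pre-powerstroke) and strong (post-powerstroke)
conformations differ only in rest coordinates (`r_W` = 19.93 nm,
`r_S` = 16.4 nm, `θ_W` = 47.16°, `θ_S` = 73.2°; the printed rest angles
exceed 2π rad, so they are interpreted as degrees — a config switch
restores the literal radian reading).  Spring energies are in units of KT;
forces convert to pN through KT = 4.1 pN·nm.

Isometric mechanics: at fixed half-sarcomere length and fixed radial
spacing, axial node positions equilibrate under the (nonlinear) crossbridge
point loads plus titin.  Each filament is an end-anchored linear chain, so
given the loads its displacement field is a single cumulative sum; the
nonlinearity is handled by fixed-point iteration (tolerance 1e-4 nm, max
100 sweeps, adaptive damping).  Crossbridge stiffness (~20 pN/nm axially)
is far below segment stiffness (~1.7–6 ·10³ pN/nm), so the iteration
contracts quickly.  Boundary force is the summed thin-filament
anchor-segment tension plus titin, and equals the M-line reaction; stress
is force over the hexagonal unit-cell cross-section (one rhombus of side
equal to the 42 nm lattice spacing per thick filament).  Traces are
emitted with the passive (titin) baseline subtracted by default.

Geometry the sources leave open, fixed here and calibrated (see
*Calibration*): the radial head-root-to-site gap (15.4 nm), a per-filament
axial stagger of target zones (filament g shifted by g/n_thin of a repeat,
emulating the helical offset between neighbouring filaments and densifying
the offset distribution), a target-zone capacity of 2 simultaneously bound
heads (a zone spans ~3 accessible actin monomers), 60 crowns × 3 heads per
thick filament, 30 zones per thin filament, half-sarcomere length 1200 nm.

### Kinetics

Crossbridges cycle through six states — 1 DRX (detached, ATP), 2 loosely
bound, 3 post-powerstroke, 4 rigor-like, 5 detached (ADP), 6 SRX — with
strain-dependent forward rates

* `r12 = τ·e^(−U_W)` (τ = 7.2 ms⁻¹), gated on the paired zone being in the
  myosin-permissive state with free capacity;
* `r23 = A·(1 + tanh(B + C·(U_W − U_S)))` (A = 0.8 ms⁻¹, B = 5, C = 0.4);
* `r34 = D·(1 + tanh(κ·F_S))` (D = 0.9 ms⁻¹, κ = −0.4 nm/KT): ADP release
  slowed under positive (contractile) load — the rate-limiting step.  The
  literal published expression reduces to `D·(1+tanh(e^(−F_S)))`, which
  keeps the strong-state dwell near 1 ms at every load and makes the cycle
  insensitive to `r34`; the force-tanh form restores the load dependence
  that the biology (and the inference results on this rate) requires.  The
  literal form remains available as `rx34_form="printed"`.
* `r45 = E·max(0, U_S − G4_offset + e^(−F_S))` (E = 1.2 ms⁻¹): the
  published expression with ΔG_ATP in place of the −20.72 KT G4 offset is
  negative for essentially all bound geometries (rate zero, rigor heads
  trapped forever); the shifted, rectified form keeps detachment strain
  accelerated while letting the cycle complete.  `rx45_form="printed"`
  restores the literal expression.
* `r51 = H` = 0.1 ms⁻¹ (ATP re-binding); `r15 = r54 = 0` structurally.

State free energies are `G1 = −2.3`, `G2 = U_W − 4.3`, `G3 = U_S − 18.6`,
`G4 = U_S − 20.72` (KT), with the cycle dropping ΔG_ATP = −23 KT.  Reverse
rates follow Boltzmann detailed balance `r_ji = r_ij·e^(G_j − G_i)`, so an
isolated pair equilibrates at `p_j/p_i = e^(−(G_j−G_i))` — the lower free
energy more occupied.  All rates are clipped at 10³ ms⁻¹ to keep the rate
matrix well conditioned near the steep strain walls.  `F_S` is the axial
component of the strong-spring force at the current geometry (in KT/nm,
positive when the head pulls its site toward the M-line).

DRX↔SRX exchange: `r16` = 50 s⁻¹; `r61` rises from 50 s⁻¹ as a Hill
function of calcium (half-activation 1 µM, coefficient 4, ceiling 10× the
base — the ceiling, midpoint and coefficient are not published and are
config-exposed).

Thin-filament regulatory units follow a four-state chain (off → Ca-bound →
switched → myosin-permissive) with forward rates `rt12 = 37 650·[Ca] ms⁻¹`,
`rt23 = 33.4`, `rt34 = 0.13`, `rt41 = 0.77 ms⁻¹` (one-way deactivation,
`rt14 = 0`) and reverse rates derived from the equilibrium constants
(`Kt1 = 260 000·[Ca]`, `Kt2 = 130`, `Kt3 = 0.91`; calcium cancels in
`rt21`).  Nearest-neighbour cooperativity multiplies the *activating*
forward rates (1→2, 2→3, 3→4) by 100 when a neighbour is calcium-bound.
Multiplying the deactivating forward `rt41` as well (a literal "all
forward rates" reading) gives the permissive state a ~13 µs lifetime at
peak calcium and abolishes activation, so the activating-only convention
is the default (config-exposed).

The calcium transient is
`ca(t) = ca_dia + (ca_sys − ca_dia)·exp(−b·(t^a − t_p)²/w²)` anchored
between diastolic pCa 7 and systolic pCa 6.  The shape parameters
(a = 0.22, t_p = 0.462, w = 0.198, b = 1) were chosen once to emulate a
mouse ventricular transient near 33 °C — time to peak 30 ms, 50 % decay
~120 ms after the stimulus — and a least-squares utility
(`fit_calcium_transient`) calibrates them to a measured trace.  One
transient drives all simulations; calcium-handling feedback is out of
scope.

Nine rate factors {rx12, rx23, rx34, rx45, rx16, rt12, rt23, rt34, rt41},
log-uniform on (0.1, 100), multiply their forward rates; derived reverse
rates inherit the scaling through the detailed-balance / equilibrium
relations, and `rx16` deliberately shifts the DRX/SRX balance (its partner
`rx61` is an independent rate, not a detailed-balance image).

### State propagation

Each 1 ms step builds one 6-state rate matrix per head (at its current
nearest-zone geometry) and one 4-state matrix per regulatory unit, with
conservation diagonals, and advances states with the matrix exponential
`P = e^{Q·dt}` (scaling-and-squaring [6/6] Padé), sampled by cumulative
inversion of one pre-drawn uniform per unit per step.  The exponential
conserves probability for any step size and captures multi-step paths
(`p15 > 0` despite `r15 = 0`), which is what permits 1 ms steps.  The
`dt → ∞` limit provides steady-state initialization at the resting
calcium.  Heads update first (sequentially, so zone capacity is respected),
then zones, with cooperativity flags frozen at the start-of-step states;
mechanics re-equilibrates whenever an attachment changed.  Whether bound
heads should sterically hold their zone in the permissive state is unknown;
it is not implemented, and zones may deactivate under a bound head.

Three controlled approximations keep the compiled kernel fast; each was
re-verified against the occupancy anchors at measurement precision:
detached heads whose per-step binding probability is below 1e-5 evolve on
the exact analytic two-state DRX↔SRX propagator (states 2–5 unreachable);
per-head propagators are cached until the head's axial offset moves 0.02 nm,
its binding gate flips, or the SRX-exit rate drifts 5·10⁻³ ms⁻¹; the two
shared 4-state propagators are cached until calcium drifts 0.5 %.

Everything is reproducible bit-for-bit from `(config, factors, seed)`:
uniforms are pre-drawn from a seed-sequence spawned per
`(master seed, record, replicate)`.

### Calibration

Two published steady-state anchors pin the open parameters: ~50 % of heads
in SRX in resting muscle, and ~10 % of crossbridges attached at maximal
activation (pCa 4).  The first follows analytically from the equal 50 s⁻¹
DRX↔SRX rates (measured: 50.0 ± 0.2 %).  The second constrains the open
geometry and the `r34` form: scans of the radial gap alone plateau near
6 % bound, and the defaults (radial gap 15.4 nm, zone capacity 2,
κ = −0.4) yield 8.7–9.2 %, inside the anchor's ±5-point band.  The same
defaults give full-lattice twitches with peak stress ~25–55 mN/mm², time
to peak ~40–125 ms and 50 % relaxation ~60–170 ms — the physiological
range for mouse trabeculae at body-ish temperature — and the expected
directional responses: rt12↑ raises and prolongs the twitch, rt41↑
truncates it, rx34↓ raises the peak and prolongs relaxation, rx16↓
recruits more heads (the myosin-activator signature), rx45 is weakly
constrained.

## Training data

A corpus record pairs a factor vector (log-uniform over the prior box)
with the pointwise mean of `replicates` independent twitches (1 s at 1 ms;
production default 50 replicates).  Records are seeded from
`(master seed, record index, replicate)`, so generation is embarrassingly
parallel, chunk-resumable, and any record regenerates bit-identically on
its own.  A seeded split labels a validation fraction (default 1 %);
standardization subtracts one global scalar mean and divides by one global
standard deviation computed from the training split only, and the stored
statistics are applied unchanged to validation records and inference-time
targets.  Factors are regressed on log10 scale mapped affinely to the unit
box.  Reduced-dimension corpora (a named subset varied, the rest frozen at
supplied values, optionally centred on a given vector) are first-class —
they drive the intervention workflow.  The container is one chunked HDF5
file (traces, factors, split labels, statistics, provenance metadata).

## The CVAE

Three sub-networks share a fully connected feature trunk over the
average-pooled (×10), standardized trace: the recognition encoder Q1
(trace features ⊕ true scaled factors → unimodal diagonal Gaussian over an
nz-dimensional latent), the prior encoder R1 (trace features →
m-component Gaussian mixture over the latent), and the decoder R2 (trace
features ⊕ latent point → m-component Gaussian mixture over the factor
space).  The network core is a compact numpy reverse-mode autodiff engine
written for this package (dense layers, ReLU, logsumexp/mixture densities;
gradients verified against central finite differences in the test suite),
with Adam optimization.  Predicted log-variances pass through a smooth
±8 tanh bound to keep mixture densities finite.

Training minimizes `−L + α·KL`, where `L` is the R2 log-density at the
true factors with the latent drawn from Q1 by reparameterization, and the
Kullback–Leibler term between Q1 and the mixture R1 — no closed form —
uses the standard single-sample Monte-Carlo estimate `log q_Q1(z) −
log q_R1(z)` at the drawn point.  The annealing weight α is 0 for the
first 30 epochs and ramps linearly to 1 over the next 60, which prevents
the collapse into the trivial KL = 0 minimum; after the ramp, training
continues until a 20-epoch validation-loss patience criterion (epoch caps
are config).  Inference never touches Q1: ancestral sampling draws
z ~ R1(trace), then factors ~ R2(trace, z), repeated n times
(default 5000).  Samples landing outside the prior box are kept and
reported as a diagnostic fraction, never clipped.

Full-scale defaults are nz = 8, m = 16, trunk width 128 (the architecture
depth/width is not published; these are config).  At the reduced corpus
scale (~2000 records) a deliberately small network — trunk 48, heads 32,
nz = 6, m = 16, lr 3·10⁻⁴ — is used: with 128-wide trunks the negative
log-likelihood overfits and the posterior under-disperses (90 % intervals
covering ~60 %), while the small network is calibrated (probability–
probability deviations ≤ 0.10, 90 % coverage ≈ 85–90 %).  Calibration is
part of the method's own acceptance loop, as a probability–probability
diagnostic over a validation set: for each record, the fraction of
posterior samples below the truth is computed per factor (ties broken at
random — measure zero for continuous samples); across records these are
U(0,1) for a perfect posterior, and their empirical CDF against the
diagonal exposes over- (below) or under-confidence (above).

## Posterior analysis and workflows

Corner summaries build per-factor and pairwise Gaussian KDEs (Scott's
rule) on log10 axes over the prior box [10⁻¹, 10²].  The reported "most
probable" factor combination is the sample maximizing the joint KDE,
refined by coordinate ascent on the KDE surface; per-marginal modes are
reported alongside, since a joint mode and assembled marginal modes can
differ.  Zero-variance dimensions are carried as point masses and flagged.

Condition comparisons use the signed two-sample Kolmogorov–Smirnov
statistic per factor: magnitude is the classical sup-distance between
empirical CDFs, sign negative when the reference (control) CDF is the
smaller at the maximizing point.

The intervention workflow mirrors the therapeutic-target procedure: build
a hybrid factor vector (control inference with the calcium-affinity pair
rt12/rt41 swapped to the variant's values), generate a reduced corpus with
the thin-filament factors frozen at the hybrid values and the thick
factors varied, train a second model on that space, condition on the
control twitch, and simulate the posterior-peak factor combination as the
candidate intervention.  A frozen-set mismatch between the dataset and the
requested hybrid raises before any sampling.

## Verification scales and what they show

The acceptance suite runs, by design, at desk scale: occupancy anchors on
the reduced lattice (1–2 thick filaments, 27 crowns — one complete cycle
of the crown/zone offset registration, so the per-head strain distribution
matches the full lattice) with 20 replicate seeds; and an inverse-problem
study with 3 varied factors {rt12, rx34, rx16}, 2200 records (2000
train / 200 validation), 8 replicates per record, on the 27-head corpus
lattice.  The synthetic corpus exercises exactly the statistical structure
the method must handle — Monte-Carlo replicate noise, log-uniform priors,
strongly informative (rt12, rx34) and weakly informative directions — but
not everything real data brings: no experimental measurement noise or
drift, no inter-preparation variability, a single shared calcium
transient, and a forward model identical between corpus and target
(no model misspecification).  Passing calibration here shows the inference
machinery is correct and honest about uncertainty at this scale; it does
not certify posterior widths on experimental twitches.  Production-scale
corpora (9 factors, ~10⁶ records, 50 replicates, full lattice) use the
same code paths through the per-record seed contract.

## Known limitations

Isometric only (no shortening/lengthening protocols, no compliant radial
spacing dynamics, no multi-half-sarcomere series coupling); one calcium
transient for all simulations; no steric zone-holding by bound heads; the
printed `r34`/`r45` strain forms are internally inconsistent and the
repaired defaults, while calibrated to the published anchors, are a
modelling choice; the stress magnitude depends on unpublished geometry and
should be read as order-of-magnitude physiological rather than fitted.
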