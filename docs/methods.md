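# Methods

This note documents the models implemented in `coronams`, the choices made
where the published description of this class of models leaves freedom, and
what the synthetic test data do and do not establish.

## Coarse-grained model

Each amino acid is one bead at its Cα.  Beads carry the residue's average
mass (so protein masses match molecular weights), its formal charge at
neutral pH (Lys/Arg +1, Asp/Glu −1, His neutral, termini uncharged — the
conventional CG protonation at pH 7), and a class label
(charged = {K,R,D,E,H}, polar = {S,T,N,Q,Y,C,W},
non-polar = {A,V,L,I,M,F,G,P}).

**Bonded terms.**  Harmonic virtual bonds and pseudo-angles plus a cosine
pseudo-dihedral, minimised at the reference structure (Go-like):

    U = Σ k_b (r − R)² + Σ k_θ (θ − θ₀)² + Σ k_φ (1 − cos(φ − φ₀))

R, θ₀, φ₀ are measured on the input coordinates.  The stiffnesses are not
dictated by the model class; defaults are k_b = 100 kcal/mol/Å²,
k_θ = 20 kcal/mol/rad², k_φ = 1 kcal/mol — stiff enough to preserve the
fold at 310 K, soft enough for 10 fs timesteps.  All are configurable.

**Non-bonded terms.**
* Protein–protein excluded volume: Morse,
  U = ε[(1 − e^{−α(r−r₀)})² − 1] with ε = 0.01 kcal/mol, α = 0.70 Å⁻¹,
  r₀ = 0.95 nm = 9.5 Å (α is read as Å⁻¹ and r₀ converted from nm).
* Electrostatics: Debye-Hückel,
  U = (e²/4πε₀ε_r) z_i z_j e^{−r/l_D}/r with ε_r = 10, Bjerrum length
  l_b = 7 Å, ionic strength 150 mM; l_D = (8π l_b I)^{−1/2} ≈ 7.93 Å is
  always derived, never set.  Coulomb constant 332.06 kcal·Å/mol.
* Protein–gold: 12-6 Lennard-Jones per residue type,
  U = 4·(13·ε_aa)[(σ_aa/r)¹² − (σ_aa/r)⁶].  The ×13 factor is the average
  number of gold surface atoms in contact with one amino acid.  The
  per-residue ε_aa/σ_aa table ships as an editable text file with neutral
  placeholder values (0.10/0.14/0.18 kcal/mol by class, σ = 5 Å); users
  supplying a calibrated amino-acid–gold parameter set simply replace the
  file.  No quantitative claim in this package depends on the placeholder
  values.
* Gold LJ and Debye-Hückel act additively on protein–NP bead pairs (the
  NP bead charge is −0.5 e).

**Cutoffs.**  All non-bonded interactions are truncated and shifted at
12 Å.  The 8.5 Å "local" / 12 Å "non-local" distinction is preserved as an
energy bookkeeping split only; applying one functional form with a single
shift keeps the force field continuous in energy without a switching
function.  Pairs one to three bonds apart are excluded.

**Nanoparticle.**  A rigid hollow sphere of beads on a deterministic
Fibonacci (golden-angle) lattice — quasi-uniform coverage with < 20%
spacing spread.  Defaults: 15 nm diameter, 5160 beads, −0.5 e per bead;
total charge −2580 e ≡ 860 citrate ions at −3 e (fully deprotonated).
The particle never moves; it is the static adsorbent.  Rescaling to other
diameters preserves surface bead density and per-bead charge.

**Dynamics.**  Velocity-Verlet; units Å/fs/Da/kcal·mol⁻¹.  Periodic cubic
box with minimum image (chosen to avoid wall artifacts; the NP sits at the
box centre).  Thermostats: Berendsen weak coupling for the heating ladder
(10→310 K in 50 K steps, coupling 10 fs), and Langevin via the BAOAB
splitting for production ("stochastic thermostat", friction
γ = 1/coupling-time).  Maxwell-Boltzmann initial velocities.  Proteins are
placed by rejection sampling with ≥ 10 Å clearance.  Desk-scale defaults
(≤10⁶ steps, ≤10 proteins, reduced bead-count NPs in tests) stand in for
the full 500 ns, 100-protein production runs; all protocol numbers are
configuration, not code.

The integrator's kinetic temperature is exact for free particles; with the
default bonded stiffnesses, discretization depresses the measured kinetic
temperature by ~2.5% at the 10 fs production timestep (a known O(dt²)
thermostat artifact).  Canonical-sampling checks therefore run at 2 fs,
where the bias is below the test tolerance.

## Meso-scale model

Each protein is a sphere of mass M_i and radius R_i.  The reference
proteins are myoglobin (16.7 kDa), hemoglobin (64.5 kDa) and trypsin
(23.3 kDa) with radii taken as the effective uniform-sphere radius
R_i = R_G·√(5/3) from their gyration radii (16.39, 25.30, 17.19 Å).  The
`gyration` rule (R_i = R_G) remains available.

* Protein–protein: U = ε_ij (σ_ij/r)²⁴, σ_ij = R_i + R_j.  Protein
  cohesion is neglected; ε_ij defaults to 0.6 kcal/mol ≈ 1 k_BT so the
  term is a soft excluded-volume wall only (configurable, including 0).
* Protein–NP: U = 4|ε|[(σ_A/z)²⁴ − (σ_A/z)¹²], σ_A = R_i·2^{1/12}.
  **z is the centre-to-surface distance.**  Reading z as centre-to-centre
  is dimensionally inconsistent with σ_A ≈ R_i (the well would sit inside
  a 75 Å particle); with the surface convention the minimum −|ε| sits at
  z = R_i·2^{1/6}, i.e. the sphere touching the gold — the physically
  intended geometry.  The engine additionally applies an always-active
  excluded-volume core ε_ij(R_i/z)²⁴ so the particle stays impenetrable
  when |ε| → 0; at the well minimum this adds ~0.04 kcal/mol and is
  negligible against the calibrated depths.
* Well depths start from ε = −RT ln K_a (R = 1.987×10⁻³ kcal/mol/K,
  T = 310 K) with measured association constants (MB 6.6×10⁵, HB 0.3×10⁵,
  TRP 3.6×10⁵ M⁻¹) and are then refined; the package carries the refined
  values −8.90 (MB), −7.30 (HB), −8.59 (TRP) kcal/mol as defaults and
  provides `calibrate_epsilon_scale`, which multiplies all depths by a
  common factor chosen so a reference single-component run reproduces a
  target plateau.  With |ε| ≈ 12–14 k_BT binding is effectively
  irreversible on accessible timescales, so plateaus are set largely by
  surface packing and arrival kinetics and the calibration typically
  selects the unit factor.

**Dynamics.**  Langevin (BAOAB) with per-sphere friction γ_i = c·R_i
(Stokes-like; c defaults to 10⁻³ ps⁻¹/Å).  This gives diffusion
D_i = k_BT/(M_i γ_i), faster than aqueous values by a common factor — a
deliberate time-scale compression that preserves the diffusivity
*ordering* (MB fastest, HB slowest) driving the competition kinetics.
Timestep 0.1 ps; periodic box; NP fixed at the centre.  The adsorbed flag
uses hysteresis to avoid flicker: attach at z ≤ 1.2·z_min, detach at
z > 1.5·z_min (z_min = R_i·2^{1/6}); counts are reported at the attach
criterion.

**Reduced study conditions.**  The full system (2400 spheres, 25 μs) is
not desk scale.  The package's reduced conditions, chosen once: 600
spheres (equal counts per type in competition runs), box edge 80 nm,
2.5×10⁶ steps (0.25 μs), three seeds; single-component references use 200
spheres.  The box is smaller than solvent-matched scaling would give so
that arrival flux saturates the surface within the reduced run; the
plateau is packing-limited well before the sphere reservoir depletes, so
concentration mainly sets the approach rate, not the plateau.  The
per-type split of competition runs is taken as equal thirds.

**What the reduced runs show.**  Single-component plateaus ≈ 40 (MB),
18 (HB), 35 (TRP); three-component totals ≈ 42–44 with MB > TRP > HB and
every type suppressed well below its single-component plateau — the
competitive-corona pattern, with hemoglobin hit hardest.  Known
limitation: with the reported radii and well depths, excluded-volume
packing caps trypsin near the myoglobin level, so the model does not
reproduce a *higher* single-component trypsin plateau than myoglobin; the
published larger trypsin count must involve effects (shape, charge
distribution, refinement details) outside this sphere model.

## Adsorption capacity estimation

N_bound(t) is fitted with the stretched exponential

    N(t) = N_max (1 − exp(−(t/τ)^α))

(the saturating sign convention — a positive exponent diverges and cannot
describe adsorption).  Fitting is trust-region nonlinear least squares with
a small multistart grid over (N_max, τ, α) initial guesses, bounds
N_max, τ > 0, α ∈ (0, 2]; standard errors come from the asymptotic
covariance.  Degenerate inputs (constant or all-zero series) and
non-convergence return a result flagged unsuccessful rather than raising
by default.  Generator round trips recover N_max to ≲1% on noiseless
(integer-rounded) series and within 5% in the mean over noisy replicates.

Geometric estimators (proteins as rigid patches):
Wang N = 4R_NP²/R_G²; Calzolai N = 0.65[(R_NP+2R_p)³−R_NP³]/R_p³;
Dell'Orco N = 4(R_NP−R_p)²/R_p².  All round to the nearest integer.  The
protein radius entering the latter two is not fixed by the model;
back-calculation suggests an effective-sphere radius (hence the
`effective` default in `to_meso_protein`), but only the Wang values are
treated as exactly reproducible.

## Contact and binding-site analysis

A residue is in contact when its Cα is **strictly** closer than 6.5 Å to
the NP surface.  Per-residue contact probability is normalised over the
frames in which the protein is adsorbed; per-class shares are fractions of
all contact events (summing to 100%).  The binding site is the set of
residues in contact for at least 70% of the adsorbed frames (inclusive
comparison, per "at least").

## Secondary structure from Cα geometry

P-SEA-style rules on the Cα trace: a four-residue window is helical when
d(i,i+3) ∈ [5.0, 6.0] Å and the pseudo-dihedral is +50°±30°; a
three-residue window is strand when d(i,i+2) ∈ [6.4, 7.0] Å, the pseudo
bond angle is ≥ 115° and the pseudo-dihedral is extended (|φ| ≥ 120°).
Windows assert only their central residue(s); helix runs < 4 and strand
runs < 3 are smoothed away; remaining residues are turns where the chain
reverses (pseudo-angle < 100° or d(i,i+2) < 5 Å) and unordered otherwise.
On ideal geometry this assigns ≥ 90% helix to generated helices and
≥ 70% strand over hairpin strand residues, while self-avoiding random
walks stay below 20% helix+strand.

## Synthetic data

Toy proteins are geometric idealizations: helix (1.5 Å rise/residue, 100°
twist, 2.3 Å radius — 3.83 Å Cα spacing), hairpin (two 3.8 Å-spaced
zigzag strands joined by a four-residue circular arc solved so every
connecting bond is exactly 3.8 Å; the resulting ~12 Å strand separation is
wider than real hairpins), self-avoiding random-walk coils (bond angles
85–135°), and mixed concatenations.  Sequences realize requested
non-polar/polar/charged fractions by largest-remainder rounding with
uniform sampling inside each class.  Adsorption series are the stretched
exponential plus i.i.d. Gaussian noise, rounded and clipped at zero —
the simplest model that exercises the fitter's robustness.  Contact
fixtures put residue i in contact in exactly round(f_i·n_frames) leading
frames with the protein adsorbed throughout, making persistence fractions
exact by construction.

Passing tests on these inputs establish the correctness of the operators
(geometry, counting rules, fitting, integrator physics), not the realism
of any particular protein: the toys have no side chains, no native
topology beyond the motif, and no heme or disulfide chemistry (covalent
S–Au binding is outside the classical model by design).

## Numerical choices

* Forces are analytic throughout and verified against finite differences
  (< 10⁻⁴ kcal/mol/Å); the pair-list path is verified against an O(N²)
  double loop (≤ 10⁻¹⁰ relative).
* CG pair search: k-d tree with a 2 Å skin, rebuilt when any bead moves
  half the skin.  Meso pair search: Verlet list with a 10 Å skin rebuilt
  every 100 steps inside the numba kernel (free spheres move ≪ skin/2 in
  that window at 310 K).
* The meso kernel caps pair forces below r = 0.7σ_ij and NP forces below
  z = 0.05σ_A to keep rare deep overlaps finite; equilibrium
  configurations never reach these caps.
* Random numbers: every generator and engine is a pure function of its
  seed; engine state carries its generator so repeated calls continue one
  deterministic stream.  Meso noise is drawn in numpy per block and passed
  into the kernel, keeping trajectories bit-reproducible across runs.
* Degenerate inputs: empty structures, missing Cα atoms, impossible
  packings, non-finite coordinates during integration, and unfittable
  curves all raise typed errors (or return flagged results where the
  contract asks for a flag).
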