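# Methods

`tropofil` implements a multiscale chain of models that turns molecular-scale
properties of cardiac tropomyosin (TPM1) into sarcomere-level functional
predictions, and uses it to compare wild-type tropomyosin with the
hypertrophic-cardiomyopathy-associated S215L substitution.  Three model
layers are chained: a coarse-grained elastic model of the tropomyosin chain,
an equilibrium-thermodynamic mapping of blocked/closed interaction energies,
and a stochastic Markov model of thin-filament regulatory units.  This note
documents each layer, its assumptions, the free choices that had to be made,
and what the synthetic inputs do and do not emulate.

## Synthetic MD inputs

The pipeline consumes two kinds of molecular-dynamics-derived data, both
emulated by `tropofil.synthetic_md` so that every downstream stage is
testable without an MD engine:

* **Flexibility profiles** — per-residue angular fluctuation (δ, degrees) of
  the tropomyosin superhelical backbone over one 142-residue half-molecule
  (284 residues in the full coiled coil, halved).  A profile is a positive
  baseline plus an optional Gaussian-shaped local bump plus i.i.d. Gaussian
  noise (default SD 0.02°), truncated to stay positive.  The mutant is
  emulated as a single localized flexibility increase centered at the
  position of residue 215 within the C-terminal half (index 73), width 5
  residues.  Real MD δ-profiles are not flat and the published figure prints
  no per-residue values; only the downstream effect on the effective chain
  stiffness γ is constrained, so the baseline (0.980°) is chosen so a
  uniform WT profile fits γ = 60 kJ mol⁻¹ rad⁻² exactly, and the mutant bump
  amplitude (2.584°) is solved by bisection so the perturbed profile fits
  γ = 31.6.  Passing chain tests therefore validates the δ→κ→γ machinery,
  not any claim about the true shape of the MD flexibility curve.
* **Interaction-energy ensembles** — per-frame tropomyosin–actin(–troponin I)
  interaction energies (kcal/mol) in the blocked (B) and closed (C)
  regulatory states, drawn i.i.d. Gaussian with the published mean ± SD over
  500 frames.  A Gaussian is the only defensible choice because only mean
  and SD are reported; real MD frames are autocorrelated, which the
  generator does not emulate (it affects error bars, not means).

## Coarse-grained chain stiffness

Each half-molecule is a cable of torsional springs in series, one per
residue.  Per-residue stiffness comes from equipartition,
κ_i = RT/⟨δ_i²⟩ (δ in radians, R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹, T = 300 K, the
MD temperature).  Equipartition is the standard parameter-free way to turn a
fluctuation amplitude into a stiffness and preserves the relative profile.
With one end fixed and the other displaced azimuthally by θ ∈ [0°, 35°], the
internal node angles relax to the minimum-energy configuration — solved
exactly via the tridiagonal stationarity system — and the resulting
energy-vs-θ curve is fit by unweighted least squares (uniform θ grid) to
E = ½γθ², through the origin because E(0) = 0 is exact.  For springs in
series the fitted γ equals the closed form (Σ1/κ_i)⁻¹ to machine precision;
the closed form is kept as an independent oracle in the tests rather than as
the implementation.  γ is reported in kJ mol⁻¹ rad⁻² (with a per-degree²
display option); on this convention the published WT/mutant values 60 and
31.6 correspond to ~1° per-residue fluctuations, a physically sensible MD
magnitude.  Radial motion and explicit actin surface geometry are outside
the model: the chain is two-dimensional in the azimuthal sense.

## Blocked/closed energetics and K_BC

The B-vs-C interaction-energy difference is defined as mean(C) − mean(B),
positive when the blocked state is more favorable: +1213.3 kcal/mol for WT
and +155.1 kcal/mol for S215L from the published 500-frame means, an 87.2%
decrease in magnitude.  The WT blocked-closed equilibrium constant
K_BC = 0.76 is a calibration constant of the regulatory model, not computed
here.  The Gibbs relation K_BC = e^(−ΔG/RT) converts it to ΔG_WT; the mutant
free energy is scaled proportionally by the energy-difference ratio
(155.1/1213.3 ≈ 0.128), and inverting the relation gives
K_BC,mut = 0.76^0.128 ≈ 0.97.  Temperature cancels algebraically in the
power form; the code asserts this numerically.  Note the proportional
scaling maps raw interaction-energy differences of order 10³ kcal/mol onto a
ΔG of order 0.1 kcal/mol; the package reproduces this proportionality as
defined without endorsing it as a thermodynamic identity.

## The 24-state regulatory-unit model

The thin filament is 26 regulatory units in series.  Each unit's state is
the product of four factors — TnC calcium site (free/bound), TnI switch
peptide (unbound/bound), TnI inhibitory peptide (actin-bound/released), and
tropomyosin position (B/C/M) — giving 24 states.  Only one factor changes
per transition.  Published rate constants (kCa± = 350 µM⁻¹s⁻¹/1000 s⁻¹,
kSP± = 180/300, kIP± = 620/225, kMD± = 550/225, k_ref,BC = 675, f_XY = 225,
δ = 0.48, λ = 0.008, η = µ = 9) are used as printed.  The wiring that
connects them is **not** printed anywhere accessible (the source model is
described only in prior literature), so it is reconstructed here and every
choice below is a documented default, overridable through
`ModelParameters`:

* Calcium binding is mass-action (kCa⁺·[Ca]); switch-peptide binding uses
  kSP⁺ when calcium is bound and λ·kSP⁺ when free (weak calcium-independent
  binding).
* The inhibitory peptide can release from actin (kIP⁺) only when the switch
  peptide is bound **and** tropomyosin is out of B; it re-binds at kIP⁻
  except while myosin is attached (bound myosin occludes its actin site).
* Tropomyosin may occupy B only while the inhibitory peptide is
  actin-bound: transitions into B are forbidden otherwise, and the
  (B, released) corner states — unreachable from the physical start state —
  get an escape rate f_XY into C.  M is reachable only from C, and strong
  myosin binding (C→M, kMD⁺) requires the inhibitory peptide released,
  because the inhibitory peptide occupies the actin surface myosin needs.
  These two occlusion rules make activation a genuine relay: Ca²⁺ → switch
  peptide → inhibitory-peptide release (gated by B-state occupancy) →
  myosin binding, and deactivation requires myosin detachment before the
  unit can re-lock into B.
* Nearest-neighbor cooperativity: the three tropomyosin positions map to
  azimuthal angles x_C = 0, x_B = −η·(25°/9) = −25°, x_M = +µ·(10°/9) = +10°
  (η and µ scale structural base offsets chosen from the literature
  azimuthal excursions of tropomyosin on actin: the B→C shift is much larger
  than C→M).  A unit at position x with neighbors at x_l, x_r carries
  elastic energy ½γ[(x−x_l)² + (x−x_r)²].  Tropomyosin transitions use a
  thermodynamically split form: forward = k_ref·K^δ·e^(−δ·ΔE/RT),
  reverse = k_ref·K^(δ−1)·e^((1−δ)·ΔE/RT), with ΔE the chain-energy change
  of the move given the neighbors' current positions and δ = 0.48 the
  published splitting fraction; the pair equilibrium is exactly K·e^(−ΔE/RT)
  regardless of δ, so γ modulates kinetics and neighbor coupling without
  corrupting K_BC.  The same split is applied to C↔M around the kMD pair —
  the myosin-bound position is also a chain position, and without this term
  γ would not modulate maximal activation.  End units have one neighbor
  (free-end condition).  The base-offset magnitudes are the single genuinely
  free scale of the reconstruction; they were fixed once against the WT
  phenotype the published control simulation was itself tuned to (calcium
  sensitivity near pCa50 ≈ 6, near-zero resting force) and then frozen.
* The published split of the equilibrium bias between forward and reverse
  rates means the neighbor-free B↔C rate ratio equals K_BC exactly; with
  myosin attachment disabled the stationary flux across the B|C cut
  balances exactly, which the tests verify against the linear-algebra
  stationary solution.

Force is the number of units in M (dimensionless, 0–26); per-filament vs
per-unit normalization is immaterial because all comparisons are ratios.

### Integration

The integrator is fixed-step kinetic Monte Carlo: per step and unit, one
uniform variate selects among transition probabilities rate×dt, reading both
neighbors' current tropomyosin positions.  A guard requires
(max total exit rate)×dt ≤ 0.1, with the bound computed exactly over all
states and neighbor contexts; by default dt is chosen automatically under
the guard (≈3×10⁻⁶ s for γ = 60 where strain-boosted rates reach
~3×10⁴ s⁻¹, 2×10⁻⁵ s otherwise).  Units are updated sequentially in place
within a step; at the guarded dt the difference from a synchronous update is
negligible.  Fixed-step rather than event-driven integration was chosen
because the twitch protocol has time-varying calcium.  A single-unit
stationary distribution solved by linear algebra (restricted to the unique
closed communicating class; the transient (B, released) and (bound, M)
corners get probability zero) is the exact oracle for the sampler, matched
to total variation < 0.02 in the tests.

### Protocols

* **Steady state**: 5 s at constant calcium from the all-off start state;
  force averaged over the final 25%.  Steady-state force is converted to
  motility velocity by a constant (effective filament viscosity), which
  leaves the fitted pCa50 and Hill coefficient invariant, and velocity–pCa
  points are fit with the Hill equation v = vmax/(1+10^(n_H(pCa−pCa50)))
  (base-10 pCa form, the motility-literature convention).
* **Twitch**: equilibrate 1.5 s at the 0.1 µM diastolic level, then a
  calcium transient rising to 1 µM — a difference of exponentials
  (τ_rise = 20 ms, τ_decay = 150 ms, both configurable) normalized to peak
  exactly at 1 µM.  The source transient data are not reproduced anywhere
  accessible; the mutant/WT comparisons are ratio-based and insensitive to
  modest shape changes.  The reference protocol averages 1920 trajectories
  and 10 repeated twitch simulations; desk and test runs scale down (see
  below).  Twitch metrics: diastolic force (pre-stimulus mean), peak force,
  time to peak (stimulus to max), RT50 (peak to the first crossing of
  diastolic + half the peak elevation, linearly interpolated), and the
  force–time integral above the diastolic baseline (reported raw and
  peak-normalized, since the published normalization is unstated).  Metric
  extraction optionally applies a 10 ms moving average first to suppress
  Monte-Carlo noise in peak and crossing detection.

## Pipeline and determinism

`run_pipeline` executes profiles→γ, energies→K_BC, then four filament
parameter sets — WT (γ=60, K_BC=0.76), γ-only (31.6, 0.76), K_BC-only
(60, 0.97), combined mutant (31.6, 0.97) — through both protocols, and
tabulates each observable relative to WT.  Every stochastic stage derives
its seed from the master seed plus the stage's numerical inputs, so a rerun
is byte-identical and a "mutant" configured identically to WT gives exactly
unit ratios.  Reports embed the configuration hash and seed.

## Problem sizes used in the test suite

Stochastic checks use fixed seeds and reduced ensembles: single-unit oracle
at 64 trajectories × 10⁵ steps; twitch comparisons at 640 trajectories per
genotype (2 repeats × 320) over a trimmed interval (1.2 s diastolic
equilibration + 1.2 s post-stimulus, both verified sufficient for
convergence and full relaxation) with 20 ms metric smoothing — peak-time
detection on the flat twitch top dominates the noise of the relaxation
metric, so the heavier averaging measures the model rather than the
estimator; steady-state direction checks at 8–16 trajectories per pCa point
on 5-point grids.  The pipeline's own defaults remain the reference sizes
(1920 trajectories, 10 twitch repeats).

## Known limitations

* The regulatory-unit wiring is a reconstruction; the printed rate constants
  are honored, but readers with access to the original model description
  should align the gating choices and record deviations.
  Quantitative twitch fold-changes (though not their directions) depend on
  these choices.
* Whole-filament behavior emerges from nearest-neighbor coupling only; no
  explicit crossbridge mechanics, sarcomere-length dependence, SRX/DRX
  myosin states, or pharmacology.
* The γ-only twitch at sub-saturating calcium shows a larger peak than WT in
  this reconstruction (its steady-state maximal activation is lower, as
  required); the combined-mutant and K_BC-only phenotypes carry the
  comparisons.
* Absolute forces are regulatory-unit counts; only ratios and shifts are
  meaningful for comparison with experiments.
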