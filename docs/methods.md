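# Methods

`remotecat` reimplements, as a tested pipeline, the computational workflow
used to identify and characterize *remote* catalytic residues in E. coli
ornithine transcarbamoylase (OTC): residues in the second and third shell
around the active site that contribute to catalysis without contacting the
substrates. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data tests do and do not show.

## Active-site layers (`remotecat.structure`)

Residues are partitioned into shells around the bound ligand:

* **first layer** — minimum heavy-atom distance to any ligand atom
  ≤ 4.0 Å (configurable). This deterministic distance rule replaces
  surface-complementarity contact detection; 4.0 Å is a conventional
  heavy-atom contact threshold and reproduces the expected first-shell
  membership of the OTC active site.
* **second / third layer** — minimum heavy-atom distance ≤ 5.0 Å to any
  residue of the previous shell, whole-residue distances, lowest eligible
  shell wins.

Residues are identified per (chain, residue number); inter-chain contacts
count toward shells because trimeric active sites sit at subunit
interfaces. Alternate conformers resolve to the highest-occupancy atom
(ties: alphabetically first altloc id); waters are dropped; hydrogens are
excluded from all distances. Missing atoms are tolerated (a warning lists
residues with under half their expected heavy atoms); no repair is
attempted. Whether published shell distances were measured to heavy atoms
only is not documented anywhere we know of; we use nearest-heavy-atom and
treat ±1 Å as the meaningful resolution of such comparisons.

## Titration model (`remotecat.titration`)

A rigid-geometry microstate model over the ionizable sites (Asp, Glu, His,
Cys, Tyr, Lys, Arg, N-/C-termini; model-compound intrinsic pKas 3.9, 4.1,
6.5, 8.3, 10.1, 10.5, 12.5, 8.0, 3.2):

    E(s; pH) = Σ_i ln(10)·kT·γ_i(s)·(pH − pKa_int,i)
             + Σ_{i<j} K_ij·c_i(s)·c_j(s)

with γ_i the protonation indicator, c_i(s) the state charge (acid 0/−1,
base +1/0) and a screened-Coulomb kernel
K_ij = 332.06·exp(−r_ij/λ_D)/(ε·r_ij) kcal/mol (defaults ε = 20,
λ_D = 8 Å, kT = 0.593 kcal/mol at 298 K). The protonation term is applied
identically to acids and bases, so an isolated site follows
Henderson–Hasselbalch (HH) exactly and total protonation is non-increasing
in pH — a thermodynamic identity the tests assert. The reported interaction
matrix W_ij is the kernel evaluated at the full charges of the ionized
forms. This model deliberately omits conformational (rotamer) relaxation
and Poisson–Boltzmann solvation: it is a desk-scale stand-in that captures
*coupled* titration behaviour with an exact small-system oracle, not a pKa
predictor.

θ(pH) is computed by exact Boltzmann enumeration up to 20 sites and by
Metropolis Monte Carlo beyond. The MC kernel proposes single-site flips
plus simultaneous flips of strongly coupled pairs (|K_ij| ≳ 2 kT); pair
moves are required for mixing across salt-bridge-like locked pairs.
Defaults: 10³ burn-in, 10⁵ samples per pH point (4×10⁵ for the coupling
correlation matrix, whose near-zero entries need more samples), fixed
default seed 1234. Verified accuracy at defaults: max |θ_MC − θ_exact|
≤ 0.02 up to 15 sites.

**Anomaly features.** The buffering density f = −dθ/dpH (central
differences, clipped at 0, normalized to unit mass) is summarized by its
third and fourth central moments, plus the integrated absolute deviation
of θ from the best-fit HH curve (pKa fit by bounded scalar least squares).
Sites whose θ changes by < 10⁻³ across the window are flagged undefined
rather than scored zero. The deviation area is the scalar anomaly score
fed to score fusion. Buffer range, where reported, is the pH width with
0.1 ≤ θ ≤ 0.9 — a convention, since no quantitative criterion is standard.

**Coupling.** Pearson correlation of protonation indicators across
microstates at a fixed pH (default report threshold |r| ≥ 0.3). Sites with
protonation variance below 10⁻⁹ (θ at 0 or 1 to within ~10⁻⁹) are reported
as undefined (NaN), not as zero correlation.

## Monotone score fusion (`remotecat.pool`)

Per-residue features (electrostatic anomaly, conservation, pocket
geometry; each oriented so larger = more functional-like) are fused by
least-squares isotonic regression over the componentwise partial order:
fitted values minimize squared error subject to x ≤ y componentwise ⇒
f(x) ≤ f(y). The exact projection onto the monotone cone is computed by
recursive block partitioning, each split a maximum-weight closure problem
solved as a min-cut (networkx max-flow). In one dimension this reduces
exactly to pool-adjacent-violators (asserted to 10⁻¹⁰ against an
independent PAVA); small multi-feature instances are checked against a
quadratic-programming oracle. Prediction for a new point is the maximum
fitted value over dominated training points (0 if none) — conservative and
monotone by construction. Scores are normalized by the maximum (top residue
= 1.00), ranked descending with ties broken by ascending residue number,
and thresholded at a normalized score of 0.01. Training labels in the
demonstration come from the synthetic generator's known functional sites;
no attempt is made to reproduce any published training corpus. Residues
with missing features are dropped with a warning, not imputed.

## Kinetics (`remotecat.kinetics`)

The citrulline-assay reduction: a least-squares calibration line
(absorbance vs citrulline, R² warning below 0.98); initial rates as the
slope of the early linear window of a progress curve (points below 10%
substrate conversion, minimum 3 — standard practice, since raw plate data
are never published); and unweighted nonlinear least squares of
v = Vmax·S/(KM+S) (optionally 1/v² weighted), initialized at
Vmax₀ = max v and KM₀ = S at half-max by interpolation, with tight
convergence tolerances (1e-13) and parameter scaling so noiseless data are
recovered to ≤ 10⁻⁶ relative error across KM ∈ [0.05, 20] mM.
Non-convergence is flagged, never silently replaced. kcat = Vmax/[E];
kcat/KM in 10⁴ M⁻¹s⁻¹ is kcat[s⁻¹]/KM[mM] × 0.1. Comparison tables accept
a separately averaged kcat/KM per variant (replicate-ratio averaging means
the ratio column need not equal kcat(avg)/KM(avg)); fold-decrease ×
relative efficiency = 1 exactly before the 2-significant-figure display
rounding.

## Thermal shift and binding (`remotecat.stability`)

Melt curves (default grid 4–100 °C in 0.2 °C steps) are Savitzky–Golay
smoothed (window 2 °C, order 3 — instrument smoothing is never published)
and differentiated; Tm is the highest peak of |dRFU/dT|, refined by a
local parabolic fit over ±1.5 °C, which beats both the grid resolution and
residual derivative noise. Using the derivative magnitude makes the result
invariant to affine rescaling of RFU regardless of instrument sign
convention. Boundary peaks are flagged, never silently returned; a second
transition ≥ 5 °C away at ≥ 20% of the main peak is reported as secondary.
Ligand stabilization is called at ΔTm ≥ 2.0 °C — the wild-type +CP shift
in the reference panel is exactly 2 °C and is treated as stabilization.

Difference spectra: all four spectra (mixture, apo protein, buffer,
substrate alone) are normalized by the apo maximum, then
D = mixture − apo − substrate + buffer. The published description of this
subtraction is grammatically ambiguous; this sign convention is the one
that makes D ≡ 0 under non-interaction, so a flat difference spectrum
means no binding signal. A 310 nm peak is called present when max D in
305–315 nm exceeds 3× the mean replicate SD in the window (single
replicates require an absolute threshold).

## SAXS (`remotecat.saxs`)

* Coordinate Rg: weighted second moment (mass, electron, or uniform).
* Debye profile: exact double sum with electron-count form factors
  (per-residue beads above 20 000 scatterers); I(0) = (Σf)².
* Guinier fit: iterative window selection on ln I vs q², trimmed to
  q·Rg ≤ 1.3 and refit to convergence. The default fit includes a q⁴
  curvature term and reports Rg from the q→0 slope: a straight line over
  the whole qRg ≤ 1.3 window carries an intrinsic ≈ 1.8% bias on compact
  (sphere-like) curves, which the curvature term removes (sphere recovered
  to 0.1%; exactly Gaussian curves are unaffected). The straight-line R²
  on the final window is reported as the linearity diagnostic.
* Kratky: q²I(q), and dimensionless ((qRg)², I/I0) when a Guinier fit is
  available. Folded iff the dimensionless curve peaks at qRg ∈ [1.4, 2.2]
  (compact globules peak near √3) *and* decays to ≤ peak/1.5 by qRg = 3;
  otherwise unfolded/extended (an ideal Debye coil rises to a plateau of 2
  and never qualifies). Thresholds configurable.
* P(r) from structure: weighted pair-distance histogram;
  Rg² = ∫r²P dr / (2∫P dr).
* Indirect Fourier transform: P(r) expanded on cubic B-splines (~30
  knots) on [0, r_max]; basis functions touching the endpoints are dropped
  (P(0) = P(r_max) = 0) and non-negative coefficients enforce P ≥ 0; the
  coefficients minimize ‖I − Ac‖² + α‖D₂c‖² by NNLS, with α increased
  ×10 automatically (up to 10⁶) on ill-conditioning. Round-trip accuracy
  on noise-free curves: ≤ 2% L2.

The three Rg routes (coordinates, P(r), Guinier-of-Debye) agree within 1%
/ 0.5 Å on synthetic structures, and this identity chain is asserted in
the tests. Published crystal-structure Rg values include no documented
hydration treatment; coordinate Rg targets them only to ±1 Å, and no
hydration shell is modelled. Ab initio bead reconstruction, envelope
averaging, and absolute-scale calibration are out of scope.

## Trajectories (`remotecat.trajectory`)

Kabsch least-squares superposition (proper rotations enforced; collinear
configurations warn), RMSF about the per-site mean, and PCA of the 3N×3N
covariance of centered Cα coordinates (plain, not mass-weighted;
eigenvalues non-increasing; components beyond rank are zero). Per-subunit
and subunit-averaged RMSF reporting are both available. Note that
superposing onto an arbitrary frame leaves the whole trajectory in that
frame's (possibly rotated) basis — comparisons against a known mode must
align onto the same reference the mode is expressed in.

## Synthetic data (`remotecat.simulate`)

The generators define the study conditions for every test:

* **structure** — Cα + pseudo-side-chain residues placed on rays around a
  tight ligand cluster at radii 3.8 / 8.0 / 12.2 / 18 Å, so shells are
  4.2 Å apart (inside the 5 Å shell rule) and shell skips exceed it;
  infeasible layer plans are rejected and every emitted structure is
  closed-loop verified against its own plan.
* **kinetics** — v = kcat·[E]·S/(KM+S) on 10 log-spaced concentrations
  over the assay designs (ornithine 0.05–48 mM, carbamoyl phosphate
  0.04–16 mM), multiplicative Gaussian noise, default CV 3%.
* **melt curves** — two-state sigmoid (width 1.5 °C) with baseline and
  additive noise on the 4–100 °C / 0.2 °C grid; recovery is tested for Tm
  across 50–76 °C, the range spanned by the variant panel, at noise SD
  0.5% of the transition amplitude.
* **spectra** — Gaussian tryptophan emission band (335 nm) plus a
  binding-induced Gaussian at 310 nm whose apo-normalized height is the
  generator parameter; replicated with additive noise.
* **scattering** — sphere, Gaussian (Guinier), ideal-coil, or
  Debye-from-structure curves on a finely binned q grid (1000 points to
  0.45 Å⁻¹, as radially averaged SEC-SAXS data are), multiplicative noise
  with σ = cv·I.
* **trajectories** — isotropic Gaussian fluctuations about a helical
  reference with a per-site RMSF profile, plus an optional planted
  collective mode that is first orthogonalized against rigid-body
  translations/rotations (so it is purely internal and survives
  superposition), and optional random rigid-body motion per frame.

All generators are deterministic under a fixed seed and return a manifest
of the generating truth. What passing these tests shows: each analysis
stage inverts its own generative model at realistic noise. What it does
not show: robustness to instrument artifacts (plate edge effects, detector
masking, baseline drift, aggregation), to model mismatch (non-two-state
melting, inter-particle interference), or pKa accuracy against experiment
— none of which the generators emulate.

## Reproduction scope

Quantities recomputed by the pipeline from printed inputs (score-cutoff
membership, efficiency ratios and fold-decreases, the 3 × 333 = 999
construct bead count) are exact worked examples. Published experimental
values themselves — measured kinetic constants, melting temperatures,
solution Rg values, microsecond MD fluctuations — derive from unpublished
raw data or cluster-scale simulation and are out of reach at desk scale;
the property-based recovery studies above are their substitutes. Problem
sizes used by the test suite and the acceptance script (≤ 15-site
enumerations, 200-replicate recovery studies, 400-frame trajectories) were
chosen to exercise each estimator's asymptotics while keeping the full
suite in the tens of seconds.
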