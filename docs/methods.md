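# Methods

This note records the models implemented in `junctionmd`, the numerical
choices behind them, and what the synthetic-data generators do and do not
emulate.

## Junction bookkeeping

A base-pair step is addressed as `xn^i_(h,b)`: construct topology
(J/B/D/N/d), core-sequence id, isomer (1/2), helix (1/2), step index.
Helix 1 contains strand I in isomer 1 and strand II in isomer 2; helix 2
contains strand III / strand IV respectively, and the step order follows
the 5′→3′ direction of that reading strand.  Pseudo-duplexes are 16 bp
(two 8-bp arms stacked coaxially); the three terminal steps at each end
fray and are excluded, so physical steps 4–12 carry indices 1–9.  Strand
labels are Roman numerals user-facing; indices are 0-based internally and
1-based in every serialized form.

The packaged `j1.json`/`j24.json` topologies are *synthetic fixtures*: the
original constructs' full arm sequences are not available in
machine-readable form, so the fixture strands were built to be fully
Watson–Crick consistent and to carry the documented core dinucleotides
(J1: CT at isomer 1 helix 1 and TG at isomer 2 helix 2; J24: CA, TA, GG).
All bookkeeping logic is sequence-agnostic, so replacing the fixtures with
measured sequences is a data change only.

Variants are expressed as edits to the pairing/connectivity maps: the
nicked duplex extracts one pseudo-duplex and places a backbone break in
the complement at the position mirroring the crossover (position 8|9);
the duplex omits the break; single-crossover constructs (SXB/SXD) nick one
of the two crossing strands.  Which crossing strand counts as "left" is an
explicit per-topology declaration (`crossovers`), not a geometric
inference.

## Step-parameter geometry

Base frames are fitted by Kabsch least squares of the embedded standard
base geometry (Olson et al. consensus reference frame; planar rings at
z = 0) onto the observed ring atoms — ring atoms only by default
(purines N9 C8 N7 C5 C6 N1 C2 N3 C4, pyrimidines N1–C6), with an optional
C1′ switch.  Sugar/phosphate atoms never enter frame fitting; they are
used only in backbone PCA.  The complementary base's frame is flipped
180° about its x-axis before pairing (the standard convention), and the
base-pair frame is the geodesic mid-rotation with the midpoint origin;
pairs whose z-axes open beyond 90° warn but still compute.

Step parameters follow the CEHS mid-frame construction: with pair frames
(R₁,o₁), (R₂,o₂), the bend angle γ about the hinge axis z₁×z₂ is removed
symmetrically from both frames, twist is the signed angle between the
x-axes about the common mid z, (tilt, roll) = γ·(ĥ·x_m, ĥ·y_m), and
(shift, slide, rise) = R_mᵀ(o₂−o₁).  `rebuild_step` inverts this exactly
(closed form, no iteration); the roundtrip is exact to ≈1e-13 over random
draws and the suite enforces 1e-8.  Twist is reported in (−180°, 180°], so
strong core untwisting appears as values well below 36°.  Degenerate
geometry (γ → 0) falls back to pure twist about the common z-axis.

## Deformability

Per-step sample covariance `C_h` uses the n−1 denominator (immaterial at
the frame counts involved, but unbiased); stiffness is
`F_h = k_B T C_h⁻¹` with k_B = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298 K
by default, giving kcal·mol⁻¹·Å⁻² / kcal·mol⁻¹·deg⁻² force-constant
blocks.  No decorrelation thinning is applied before the covariance (an
optional stride exists for sensitivity checks).  `det C_h` is the
configurational volume; display rings at 10/100 Å³·deg³.  Deviation
reports match steps to a B-form reference by local dinucleotide context,
fall back to a user-supplied literature table when a context is missing
(the source is recorded per step), suppress mean deviations below
0.2 Å / 2°, and carry the ring scales 0.5/1.0 Å, 5/10° (means) and
1/2 kcal·mol⁻¹·Å⁻², 0.005/0.01 kcal·mol⁻¹·deg⁻² (stiffness diagonals —
the report exposes diagonal entries; scalarizations are left to the
caller).

## Essential dynamics

Frames are superposed on frame 0, averaged, re-referenced, and iterated
until the mean shifts by < 10⁻⁴ Å RMSD (max 100 iterations).  The
coordinate covariance is the unweighted ensemble average (mass weighting
appears only in the entropy estimate).  After eigendecomposition the six
smallest-magnitude eigenvalues — numerical remnants of the rigid-body
modes removed by superposition — are discarded; a rank warning is raised
when they are not ≪ the leading eigenvalue or when frames < 3N.
Eigenvector signs are fixed by making the largest-magnitude component
positive.  Because superposition leaves the global orientation arbitrary,
`align_modes` co-rotates a ModeSet onto a reference structure before any
comparison with externally defined vectors.

Projection surfaces use 0.2 Å × 0.2 Å bins (0.04 Å²), free energy
−k_B T ln(n/n_max) at 298 K, zero at the most populated bin, with empty
bins flagged NaN rather than zero.

## Entropy and end-state free energies

The Schlitter estimate mass-weights the coordinate covariance
(C′ = M^{1/2} C M^{1/2} — the self-referential printed variant of this
equation is treated as a typographical slip), takes its eigenvalues as the
classical variances ⟨q_i²⟩, and evaluates
S′ = ½k Σ ln[1 + (kTe²/ħ²)⟨q_i²⟩] in SI before converting to
kcal·mol⁻¹·K⁻¹.  S′ upper-bounds the exact quantum-harmonic entropy of
the same Gaussian model (used as the test oracle).  Convergence is
declared when S′ changes by < 1% over the last 20% of frames; unconverged
estimates are reported alongside, never inside, MM-PBSA totals.

MM-PBSA combination is pure bookkeeping over externally computed tables
(tab-separated FRAME [BASE [STRAND]] INT ELE VDW PB SA, kcal/mol):
E_gas = INT+ELE+VDW, ΔG_solv = PB+SA, ΔG = E_gas + ΔG_solv − TS′.
Per-base rows must sum to molecular rows within 10⁻³ kcal/mol when both
are present; isomer differences ΔΔE = ΔE_Iso1 − ΔE_Iso2 are formed
per base and conserve totals exactly.  The SA column may carry either the
LCPO or the molecular-surface split; the table's source tag records which.

Conformer thermodynamics: ΔΔG = −RT ln(fr_I/fr_II) at a configurable
temperature (default 298 K, the simulation temperature; the experimental
temperature is not separately specified).  Fractions of exactly 0 or 1
return signed infinities with a bound flag, mirroring "≥ 0.95"-style
reporting.

## Enhanced-sampling statistics

The collective variable is the projection of the optimally superposed
deviation from a reference onto a fixed unit vector in R³ⁿ (centers of
geometry removed, Kabsch rotation, then ν·Δx).  The default window layout
is five overlapping windows [−5,−1], [−2,3], [1,6], [4,8], [6,10] Å of 15
force bins each (the printed "[−2,−3]" interval is read as [−2,3]; windows
must cover [−5,10] and overlap).  The colvar↔J_twist map is affine,
calibrated by −5 Å ↔ −90° and +10 Å ↔ +90°, and exposed as configuration.
Note the layout tension between 5×15 bin centers and a uniform 46-point
grid: the merged stitched grid has 69 distinct points under the former;
both layouts are supported and neither is forced.

Per window the PMF is the trapezoid integral of −⟨F⟩ over bin centers;
windows are stitched by least-squares constant offsets evaluated on their
overlaps via not-a-knot cubic splines (exact for polynomial PMFs, robust
to noisy edge bins — preferred over endpoint matching), and the global
minimum gauges A = 0.  Empty bins are interpolated with a warning.

The ABF error bound is (ξ_b−ξ_a)·σ/√K·√(1+2τ) with σ² the pooled force
variance, τ the force correlation length in samples, and **K the per-bin
force-evaluation count** (mean over the interval).  With K read as the
total count over all bins the expression numerically equals ≈1 standard
deviation of the trapezoid estimator and would not function as the upper
limit it is meant to be; with per-bin K it bounds the SD with a
√n_bins-fold margin, which is the reading implemented here.  Bins sampled
for less than 5 ns equivalent (500 samples at 10 ps) are flagged, the
floor chosen above the ≈4 ns decorrelation time of the slower unbiased
arm-roll coordinate.

Blocking analysis (Flyvbjerg–Petersen) halves the series by pairwise
averaging, estimates the SE of the mean per level, and declares a plateau
at the first level whose successive SE increments stay within their error
bars for three consecutive levels; the plateau SE averages the next four
levels (deeper levels carry < 16 blocks and only add noise).  The
integrated correlation time follows from
τ_c = dt·((SE_plateau/SE_naive)² − 1)/2; if no plateau appears the last
level is returned as a lower bound with a warning.

## tr-FRET model

I(t) = Σ_i fr_i ∫ P_i(R) Σ_j α_j exp[−(t/τ_j)(1+(R₀/R)⁶)] dR with
truncated-Gaussian P_i (renormalized on R > 0, 96-node Gauss–Legendre
quadrature over R̄ ± 6σ).  Defaults, all configurable: R₀ = 55 Å for the
fluorescein/tetramethylrhodamine pair (standard literature value; not
printed with the measurements); a biexponential intrinsic donor decay
(amplitudes 0.7/0.3, lifetimes 4.0/2.5 ns — fluorescein on DNA is
typically biexponential); distance means 40/65 Å and widths 5 Å for the
near (isomer I) and far (isomer II) dye arrangements.  The fit optimizes
fr_IsoI alone by default (distances and widths fixable or releasable),
with Poisson weights 1/√max(counts,1) and an overall scale; confidence
intervals come from a Poisson-resampling bootstrap.  Fractions within
0.01 of a boundary are flagged `at_bound`.

## Synthetic-data generators

The generators emulate the *statistical* structure the analyses assume and
nothing more — no force-field realism, no sequence-dependent coupling
between steps, no anisotropic dye photophysics:

* **Step ensembles**: stationary AR(1) multivariate Gaussians per step
  with marginal covariance k_B T F⁻¹; default mean (0,0,3.4 Å,0,0,36°) and
  a diagonally dominant B-DNA-like default covariance.  AR(1) is the
  chosen correlation model because the only time-correlation constraints
  available are scalar decorrelation times; richer kinetics would be
  unverifiable.  Coordinates are realized by chaining `rebuild_step` from
  the identity frame and placing idealized base geometries in the pair
  frames (reading base in-frame, complement flipped), so re-extraction
  reproduces the drawn parameters exactly.
* **Mode ensembles**: a helical mean structure plus AR(1) Gaussian
  amplitudes on unit mode vectors orthogonalized against the rigid-body
  space (so superposition cannot absorb them), isotropic coordinate noise,
  and optional per-frame random rigid motions to exercise superposition.
* **ABF force bins**: mean force −dA/dξ at bin centers plus noise with the
  estimator's standard error σ√(1+2τ)/√K; bins record σ², K, τ.
* **Decays**: the donor-decay model scaled to a total photon count and
  Poisson-sampled.

Every generator is fully determined by its seed and emits a provenance
block (seed + spec hash).  Passing tests on these inputs demonstrates the
estimators' correctness and calibration under their own assumptions; real
trajectories add anharmonicity, slow conformational switching, and
sequence coupling that the generators deliberately omit.

## Problem sizes and tolerances

The reference checks run at the sizes the statistics require rather than
trajectory scale: 10⁵ frames for stiffness recovery (< 5% Frobenius
error), 8×10³ frames for two-mode PCA recovery (variances within 5%,
|cosine| > 0.99), 10⁵ samples for blocking (τ within 25%), 200 replicates
for ABF-bound coverage (≥ 90%), 10⁶ photons per decay fit (fr within
±0.05, matching the measurement precision class).  Geometric identities
are enforced at 10⁻⁸ (roundtrip) and 10⁻¹⁰ (rigid-motion invariance);
matrix identities at 10⁻⁸.  Base-frame fitting under 0.05 Å ring noise
recovers rotations to ~1.1° median (Monte-Carlo calibrated).

## Known limitations

* No intra-base-pair parameters (buckle, propeller, opening), groove
  geometry, or backbone torsions.
* No trajectory-format zoo: multi-model PDB and PDB directories only.
* The PB/SA solvers, force-field evaluation and LCPO decomposition are
  external; only their tables are consumed.
* Entropy: quasiharmonic only; no normal-mode alternative.
* FRET: no κ² / anisotropy modelling, no IRF deconvolution by default, no
  global multi-construct analysis.
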