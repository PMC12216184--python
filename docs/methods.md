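# Methods

`fuzzycomplex` reimplements, at desk scale, the quantitative analysis chain
used to characterise *fuzzy* peptide–domain complexes — bound states in
which a disordered peptide (here modelled on the p53 TAD2 element binding
the FOXO4 Forkhead domain and its D-retro-inverso peptide mimic) remains
conformationally heterogeneous.  Each stage is a self-contained model with
an explicit forward counterpart in `fuzzycomplex.synthetic`, so every
estimator can be validated against planted ground truth.

## Chemical shift perturbation mapping (`csp`)

For an amide cross-peak the scalar perturbation is

    CSP = sqrt(ΔδH² + ΔδN²/7)

The nitrogen scaling divisor is fixed at 7 (not the also-common 25/5
variants); it is a package constant, not a parameter.  Binding-site
classification defaults to CSP > mean + 1·SD over scored residues; the rule
(mean + k·SD, or an absolute ppm cutoff) is configurable and recorded in
output metadata, because no universal threshold exists.  Peaks present in
the free spectrum but vanished in the ligand-added one are reported as
*broadened* — exchange broadening marks the interface but yields no CSP
number, so these residues are excluded from statistics rather than scored
as zero.

Fast-exchange K_D fitting models the observed per-residue CSP at each
titration point as Δδ_max,r · f_bound, with f_bound the exact root of the
single-site quadratic in total concentrations.  One global K_D is fitted by
profiled least squares (Δδ_max per residue solved linearly inside the K_D
search), which keeps the problem one-dimensional and well conditioned.
Peak matching across points is by residue index — assignments are assumed
transferred, as is standard when titrations start from assigned spectra.

The competition readout quantifies displacement experiments: per residue,
reversion = 1 − CSP(free→competed)/CSP(free→complexed), clipped to [0, 1],
averaged over residues whose denominator exceeds a noise floor
(default 0.005 ppm, configurable).  It is scale-invariant by construction.

## Spin relaxation (`relaxation`)

Decays are fitted with M_z(t) = M0·exp(−R·t) + C by Levenberg–Marquardt
(lmfit), initialised from a log-linear regression on offset-subtracted
data.  The offset C is free by default and fixable at zero; with C free at
least four distinct delays are required.  Replicate delays (both packaged
delay lists contain one) are kept as independent points to preserve the
error structure.  Non-decaying data are flagged `converged=False`, never
silently returned.

R1ρ→R2 conversion uses R2 = (R1ρ − R1·cos²θ)/sin²θ with
θ = arctan(ω1/Ω) ∈ (0, π/2].  The spin-lock field strength ω1 is a required
input — there is no defensible default, so none is provided.  A literal
legacy variant θ = arctan(1/Ω) is available behind `legacy_form=True` for
comparison with older analyses only; it is dimensionally inconsistent.

The heteronuclear NOE is I_sat/I_ref with first-order error propagation
from the two spectral noise SDs; the implementation uses the form
sqrt((σ_sat/I_ref)² + (I_sat·σ_ref/I_ref²)²), which remains defined at
I_sat = 0.

Secondary shifts ΔδCα − ΔδCβ use a packaged neighbor-uncorrected
random-coil Cα/Cβ table (replaceable by any mapping with the same shape);
positive runs indicate helical propensity and are reported as such, not
asserted as structure.

## PRE distance restraints (`pre`)

Intensity ratios follow the Battiste–Wagner attenuation
I_para/I_dia = R2_dia·exp(−Γ2·t)/(R2_dia + Γ2); Γ2 is recovered by Brent
root finding on a bracketing interval (the forward form is strictly
monotone).  The evolution period t defaults to 10 ms (a typical HSQC INEPT
transfer period) and must be adjusted to the experiment.  Distances come
from the Solomon–Bloembergen relation with K = 1.23×10⁻³² cm⁶ s⁻² and a
default electron–proton correlation time τ_c = 4 ns.

Classification into restraint classes: ratio < 0.15 → upper bound 14 Å
(bleached: only "close" is defensible); ratio > 0.85 → lower bound 18 Å
(unaffected: only "far" is defensible); otherwise a range restraint of
± 4 Å around the Solomon–Bloembergen distance.  All thresholds are
configurable and recorded in the restraint-file metadata.  Spin-label
orientational uncertainty is absorbed by four geometric label copies
(tetrahedral spread about the CA→CB direction, 8 Å arm) whose
r⁻⁶-summed effective distance enters restraint evaluation; `min` mode is
available as the conservative alternative.

## Restrained annealing (`structure`)

The package deliberately replaces a molecular force field with the *logic*
of the restrained-annealing protocol: the goal is a reproducible,
desk-scale surrogate for ensemble calculations, not a CNS reimplementation.

* Representation: backbone + Cβ (N, CA, C, O, CB) with ideal bond geometry
  built from φ/ψ torsions (ω fixed trans).  The Cβ improper
  dihedral(N, C, CA, CB) = +120° reproduces the reference L-alanine
  geometry; D chains flip all torsion signs, making the D build the exact
  mirror image of the L build (verified to machine precision, which also
  guarantees the mirror-image complex equivalence used for retro-inverso
  work).  Side-chain atom selections map to Cβ with a +3 Å pseudo-atom
  padding on the upper bound, recorded per restraint.
* Energy: flat-bottom harmonic distance restraints (zero inside
  [lower, upper], k·violation² outside, k = 1 per Å²), harmonic
  flat-bottom dihedral restraints (default half-width 10°, k = 0.01 per
  deg²), harmonic positional tethers for template atoms (default 100
  reduced units Å⁻², representing a 10,000 kcal mol⁻¹ Å⁻² template
  restraint scaled by 1/100 into the reduced energy unit), and a
  soft-sphere steric term ((2.8 − d)² for non-bonded heavy-atom pairs
  closer than 2.8 Å, excluding same/adjacent residues).
* Search: per model, flexible torsions are randomised, then Metropolis
  annealing over φ/ψ rotations and (for fully flexible chains) rigid-body
  moves, geometric cooling 50 → 0.02 over 200 cycles × 50 moves, followed
  by a 2000-move zero-temperature quench with small amplitudes.  Move
  amplitudes shrink linearly with temperature.  Deterministic per seed;
  an empty restraint set returns the input unchanged (nothing to anneal
  against).  Hydrogen-bond helical restraints are encoded as O(i)–N(i+4)
  distances (2.8–3.3 Å by default).
* Selection and statistics: lowest-n-of-N energy selection with stable
  id tie-breaks; Kabsch superposition RMSD; two-pass mean-structure RMSF;
  quality-threshold clustering at 2 Å backbone RMSD (largest-neighbourhood
  seed, deterministic tie-break); Ramachandran basin populations with
  default α (φ ∈ [−100, −30], ψ ∈ [−67, −7]) and β (φ ∈ [−180, −90],
  ψ ∈ [90, 180]) windows.

The planted toy complex (20-residue helical host, 8-residue helical guest,
12 truth-derived intermolecular CA–CA restraints plus hydrogen-bond and
dihedral restraints) is the recovery benchmark: restraints generated from
the planted pose must be satisfiable at zero violation, and best-of-20
annealing recovers the pose to well under 2 Å backbone RMSD.

## Markov state models (`msm`)

Backbone torsions are featurised as (sin, cos) pairs (continuous across the
±180° wrap), reduced by tICA (symmetrised lagged covariance vs.
instantaneous covariance, generalised eigenproblem, diagonal
regularisation 10⁻¹⁰·trace), discretised by k-means++ (fixed seed), and
counted with a sliding window at the lag.  The production defaults are
85 microstates, a lag of 5 ns at the trajectory stride, and 1500 frames
per system — typical for µs-scale trajectories of small disordered
peptides — while tests and the acceptance suite run the same pipeline at
desk scale (12 microstates, 4000-frame synthetic trajectories), which the
planted 3-state dynamics fully determine.

Estimation is restricted to the largest strongly connected count set
(dropped states are named in a warning).  The reversible estimator is the
standard maximum-likelihood fixed point on the symmetrised counts,
iterated to 10⁻¹² in the stationary weights, which guarantees detailed
balance; a row-normalised nonreversible estimator is available.
Row-stochasticity, stationarity and detailed balance are asserted on every
constructed model.

PCCA+ uses the inner-simplex algorithm on the dominant right eigenvectors
(computed via the π-symmetrised matrix); memberships are clipped to [0, 1]
and renormalised, with crisp assignment by argmax.  The
Chapman–Kolmogorov test compares T(τ)^k coarse-grained onto the crisp
metastable sets against models re-estimated at kτ; uncertainty bands come
from a trajectory block bootstrap (blocks of 10·k·τ frames kept as
separate trajectories so no spurious transitions are counted across
seams; 100 resamples, 95% percentile bands by default).  Free-energy
surfaces are −kT·ln(p/p_max) over a 2-D histogram of the leading tICA
coordinates with unobserved bins NaN-masked rather than infinite.

## One-site ITC (`itc`)

The forward Wiseman model updates cell concentrations per injection with
the perfusion approximation (scaling by 1 − v/2V₀), solves the single-site
quadratic for the complex, and computes heats from the change in complex
*moles* with macromolecule moles conserved (the volume displaced by an
injection has already reacted, so its heat belongs to the cell record).
This convention makes the cumulative heat at saturation equal
n·ΔH·[cell]₀·V₀ exactly, which anchors the fit's enthalpy scale; the
proprietary instrument-software correction differs in detail, so fitted
baselines are not expected to be numerically identical to vendor output.
The default scheme is 18 × 15 µL injections at 25 °C into a 1.4 mL cell.

`OneSiteBindingModel.fit()` estimates (n, K_a, ΔH, offset) by nonlinear
least squares (K_a parameterised as log K_a), initialised from the
inflection molar ratio and the first-injection heat.  The c-value
n·K_a·[cell]₀ is reported with a low-confidence flag outside 1–1000.  An
optional first-injection discard is off by default.  Thermodynamic algebra
uses R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and the 1 M standard state:
ΔG = RT·ln K_D, −TΔS = ΔG − ΔH.

`audit_thermo_table` recomputes K_D from published (ΔH, −TΔS) records and
flags each row consistent/inconsistent against the printed K_D within the
stated SD (or 15% where the SD is below rounding resolution).  The audit
reports; it never adjusts a printed value.

## Synthetic data (`synthetic`)

Every generator is the forward model of exactly one analysis stage and is
seeded through `numpy.random.default_rng` (integer state, platform
independent).  Noise is Gaussian on ppm values, intensities and heats,
expressed as fractions of signal; torsion emissions are wrapped Gaussians
truncated at ±3σ.  What the generators deliberately do **not** emulate:
spectral lineshapes and overlap, intermediate-exchange broadening
lineshape effects, baseline drift and integration error in thermograms,
force-field-realistic torsion correlations, or spin-label rotamer
ensembles beyond the four-copy geometric spread.  Passing recovery suites
therefore demonstrate estimator correctness under the stated statistical
assumptions, not robustness to every pathology of real spectra.

## Problem sizes and numerical choices

Recovery suites use 50 titrations / 50 thermograms / 100 decay curves /
100 PRE cases / 20 annealed models / 20 MSM replicates of 4000 frames —
sizes chosen so the whole validation chain runs in minutes on one core
while keeping Monte-Carlo error well below the asserted tolerances.
Tie-breaks are deterministic everywhere (model id, lowest index); root
finding and fixed-point iterations converge to 10⁻¹²; eigenvalue sorts are
by magnitude with explicit real-part extraction for reversible matrices.

## Known limitations

* The annealer explores torsion + rigid-body space with Metropolis moves;
  it is a surrogate for Cartesian simulated annealing, adequate for
  restraint-driven pose recovery but not for force-field-quality ensembles.
* Backbone + Cβ representation cannot express side-chain packing; NOE
  selections to side-chain protons are honoured only through the Cβ
  pseudo-atom padding.
* PRE inversion assumes a single effective correlation time and no
  exchange averaging between bound and free states.
* The CK test's bootstrap bands are percentile bands; coverage is
  approximate for very short trajectories.
* ITC errors are asymptotic fit errors; replicate-to-replicate scatter of
  real experiments is typically larger.
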