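# Methods

This note documents the models and procedures `asymfold` implements, the
assumptions behind them, the defaults that matter, and what the synthetic
generators do and do not emulate.

## Exchange stoichiometry and the asymmetry line

Donor and cyclodextrin concentrations for MβCD-mediated outer-leaflet
exchange follow

    Cd = a · Ca · asym / (1 − asym)
    Cm = n · Cd + (Cd · K) / n

with `a` the exchange-accessible lipid fraction (default 0.5, the outer
leaflet of a large unilamellar vesicle), `n = 4` the CD–lipid complex
stoichiometry, and `K` an empirically derived donor-class constant (292
for PC/PG/PS donors, 150 for PE). The Cm formula is dimensionally
irregular as commonly quoted (K carries units of M⁻³ yet enters linearly);
we evaluate it exactly as written in the caller's unit system and attempt
no conversion. The 70% CD–lipid saturation at which K was calibrated is
stored as plan metadata only — no quantitative mapping from saturation to
the arithmetic exists, since K absorbs it empirically.

A liposome with total donor fraction f after a single round of
outside-only exchange has all donor in its outer leaflet, so its predicted
ζ is the symmetric calibration evaluated at f/a. Classification against
this asymmetry line uses a relative ±10% band on the predicted ζ
magnitude; we read the published margin as shading of the line itself, so
a relative band is the natural interpretation (an absolute band in mV
would make the test arbitrarily permissive near ζ = 0). The symmetric
calibration is a monotone piecewise-linear interpolant through measured
(fraction, ζ) points; extrapolation beyond the calibrated range is an
error rather than a guess.

Preparations are grouped to the nearest 10% asymmetry and excluded when
more than 3 percentage points from the nearest bin.

## ζ-potential ensemble

Features: monovalent salt (M), divalent salt (M), pH, hydrodynamic radius
(nm), temperature (°C), mean headgroup charge per lipid (e), mean lipid
T_m over non-cholesterol lipids (°C, renormalized), cholesterol mole
fraction. Cholesterol is excluded from the T_m average only; it
contributes (zero) charge like any other lipid.

Each member is an XGBoost regressor (squared-error loss, learning rate
0.05, max depth 6, min child weight 2.5, row subsample 0.85 per tree,
feature subsample 0.85 per node, ≤400 trees) early-stopped with patience
25 on its own random 25% validation split. Per-sample weights come from
the measurement standard deviations by an affine map sending the smallest
sd to 0.625 and the largest to 0.375 — the published range fixes only the
scale, and inverse-error weighting (small sd → large weight) is the
standard choice; missing sds get the midpoint 0.5. A member is accepted
when its validation MAE is below 5 mV, otherwise retrained with a fresh
seed (up to 10× the ensemble size attempts); the deployed ensemble
averages 50 members. Member diversity comes entirely from the random
validation split and the row/feature subsampling seeds (seed = base + i).

Fourfold cross-validation is diagnostic, not part of the deployed model:
per fold we train a smaller ensemble (`cv_members`, default 8) and report
per-fold and mean MAE. Leave-one-feature-out ablation likewise retrains
`ablation_members` (default 4) per fold per feature; these reduced counts
keep the 8-feature ablation tractable while the MAE deltas they measure
are far larger than the member-to-member spread. Gain-based importance is
collected from every deployed member and summarized as min/median/max.

The literature-table inclusion filter implements three predicates (known
lipid T_m; NaCl/KCl buffer salt; no ethanol); assembling the table is the
user's task.

## Curve fitting

**Folding kinetics.** One-phase model F(t) = F₀ + A(1 − e^(−kt)), two-phase
analogue with k₁ > k₂. Nonlinear least squares from a multi-start grid
k₀ ∈ {1, 10, 100}/t_max (and its pairs for two phases), best RMSE wins.
The two-phase model is adopted only when it improves RMSE by ≥20% **and**
the rates separate by ≥3-fold — a quantitative version of the "high
residual error in one-phase fits" criterion that avoids overfitting a
second phase to noise. The completion fraction is the observed end-of-trace
rise over the fitted total amplitude (the fitted asymptote serves as the
100% reference when no orthogonal folding-yield estimate is supplied;
when one is, it is used directly). Fits completing below 0.75 are returned
with `accepted=False`: their rate constants are not usable, matching the
practice of not fitting traces that fold to ≲75% amplitude. No drift term
is included by default; traces needing one should be detrended upstream.

**Urea titrations.** Four-parameter logistic
f(u) = lower + (upper − lower)/(1 + e^((u−Pm)/s)); P_m is the
half-amplitude midpoint and its uncertainty comes from the fit covariance.
A logistic is used rather than a thermodynamic linear-extrapolation model
because only apparent midpoints are interpreted downstream — the folding
reaction is not reversible enough for equilibrium free energies. Fits with
amplitude (upper − lower) < 0.2 are refused: a midpoint placed on a nearly
flat curve is noise.

**Laurdan.** GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀), defined for positive total
intensity; the melting midpoint is the extremum of the first differential
of GP vs T. On dense uniform grids the derivative is taken with a 9-point
quadratic Savitzky–Golay filter so that point noise does not displace the
extremum, and the extremum is refined by a parabola through its two
neighbours; on sparse or irregular grids plain central differences are
used. A curve whose derivative magnitude never exceeds twice its median
(flat or linear GP) raises a no-transition error instead of returning a
spurious midpoint.

**Spectra.** Deconvolution solves non-negative least squares over the raw
wavelength grid (references resampled linearly). Non-negativity is imposed
because the scales are physical concentrations. Nearly collinear
references are flagged (`ill_conditioned`) rather than rejected, since the
NNLS solution remains well-defined.

## Permutation inference

The test statistic is the difference of group means (absolute value for
two-sided). All C(n_a+n_b, n_a) distinct reassignments of the pooled
values are enumerated when their number is ≤ 10⁶; otherwise distinct
assignments are sampled without replacement by drawing unique combination
ranks (bigint-safe) and unranking them through the combinatorial number
system. Counting is **inclusive** — assignments with statistic ≥ the
observed one, the observed labelling among them. Strictly-greater counting
would report p = 0 for fully separated data, which no valid permutation
test can do; inclusive counting gives the correct floor 2/C(n,k)
two-sided (2/70 ≈ 0.029 at 4+4). Float ties are absorbed by a relative
tolerance of 1e−12. The one-sided mode tests in the direction of the
observed difference. The paired t-test is the classical two-tailed test on
per-pair differences (n−1 df), refusing exactly-constant differences.

## Membrane-depth enrichment and the PEP

Residues are assigned to half-open 1 Å slabs [i, i+1) by Cα z (membrane
normal, origin at the bilayer centre, extracellular positive), pooled
across structures aligned on their membrane centres. Enrichment of amino
acid r in slab s is

    log₂ [ (n_sr + c)/(n_s + 20c) ÷ (B_r + c)/(B + 20c) ]

with pseudocount c = 0.5 guarding empty cells; slabs with no residues are
NaN, never 0. Backgrounds: whole protein, or soluble regions only (TM
residues removed from both slabs and background) — the mode in which
surface-proximal signals are not swamped by the hydrophobic TM
composition. Significance thresholds are computed separately for
enrichment and depletion as the standard deviations of all positive and
all negative cells, restricted to slabs within 50 Å of the membrane centre
so that sparse far-field cells do not inflate the thresholds; flags are
set at 2σ and 3σ.

Patch detection pools Lys+Arg enrichment per extracellular slab (centre
above +half_thickness) and reports the maximal contiguous run exceeding
2σ_enrich, its band relative to the outer-leaflet plane, peak slab, and an
enrichment-weighted centroid over all >2σ slabs (the centroid is the
stable location estimate; the single peak slab jitters within the band).
A run must span at least 2 slabs (`min_slabs`): with dozens of
extracellular slabs a lone-slab 2σ excursion occurs by chance even in null
data, while a physical patch is several Å wide. Sequence-mode profiles
concentrate each residue offset into a single pseudo-distance slab, so
callers use `min_slabs=1` there.

The residue-count→distance calibration takes, for each offset k along the
chain from the nearest transmembrane residue, the median |Cα z| over all
loop/turn residues; isotonic regression enforces monotonicity, offsets
with <10 observations are flagged low-confidence, and k = 0 is anchored by
boundary TM residues only (TM residues chain-adjacent to a loop or turn),
so the mapping starts at the membrane boundary. Because extracellular
loops reach much further than the short periplasmic turns, the calibration
accepts an optional side filter; the extracellular-side calibration is the
appropriate one for the patch analysis. Sequence records (topology labels
S/L/T/X for strand/extracellular loop/periplasmic turn/soluble) are placed
at +calibration(k) (loops) or −calibration(k) (turns and termini, which in
β-barrels are periplasmic) and analysed identically.

External filtering stages (identity clustering, signal-peptide removal,
model-confidence and strand-count thresholds) are assumed pre-applied to
the input cohort; the module is count-agnostic.

## Lipid contacts and occupancy

A residue–lipid-molecule pair contributes one contact per frame when any
particle pair is within 0.55 nm, with orthorhombic minimum-image wrapping
(triclinic boxes are rejected). Counting per molecule pair rather than per
particle pair keeps the concentration/time normalization
raw/(n_lipids(species) × n_frames) interpretable. Normalization uses
absolute lipid counts; a mole-fraction variant is a caller-side rescale.

Site occupancy uses dual-cutoff hysteresis per lipid molecule: binding
starts when the minimum distance to the site drops to 0.475 nm and ends
only above 0.8 nm, suppressing boundary rebinding artefacts; occupancy is
the fraction of frames with ≥1 bound lipid of the species. Running
simulations, force-field handling and equilibration diagnostics are out of
scope; trajectories arrive as arrays or a plain frame table.

## Synthetic generators

All generators are deterministic in their seed and return a truth sidecar.
Preset truths anchor the headline systems: folding rate constants
5 × 10⁻⁴ s⁻¹ (DMPC-like) and 2.2 × 10⁻² s⁻¹ (DMPG-like, a 44-fold ratio in
the >40-fold regime), titration midpoints 4.5 M and 2.3 M urea, laurdan
melting midpoints 24 °C and 23 °C. Default noise levels are 1% of
amplitude (kinetics), 0.03 folded-fraction units (titrations), 0.002 GP
units (laurdan) — each a realistic instrument-level figure at which the
corresponding fitter recovers its preset truth within the preset's
declared tolerance (5% relative, 0.15 M, 0.25 °C); this recovery is itself
a test.

The ζ table (default n = 315 rows) draws features uniformly from broad
plausible ranges (salt 0–0.5 M, pH 3–10, T_m −20–60 °C, charge −1–+1,
cholesterol 0–0.5) and plants a charge-dominant linear effect of
30 mV per elementary charge with Gaussian noise; heteroscedastic per-row
sds (default U(0.5, 2) mV) populate the weighting path.

The membrane cohort builds idealized β-barrels: even-count TM strands
spanning ±15 Å (half-thickness default) with hydrophobic-biased
composition, extracellular loops of 8–14 residues arcing to ~14 Å above
the outer leaflet, periplasmic turns of 3–5 residues; loop/turn
composition is uniform over the 20 amino acids except inside the planted
band (default centre 8 Å, width 4 Å above the leaflet), where the Lys/Arg
draw probability is multiplied by the excess factor (default 3; 1 gives a
null cohort). Matched topology-labelled sequences share the same residues.

The trajectory generator plants a binding site of known occupancy: binder
lipids follow an i.i.d. per-frame bound/unbound schedule with the stated
bound fraction — bound frames inside the short occupancy cutoff, unbound
frames (and every non-binder lipid) beyond the long cutoff — so the
planted occupancy equals the realized bound-frame fraction exactly and
hysteresis slack is zero.

What the generators do **not** emulate: real membrane geometry or lipid
diffusion, instrument drift and photobleaching, correlated noise,
non-uniform real amino-acid background composition, or the heterogeneity
of real structure cohorts. Passing tests therefore demonstrate that the
estimators recover known truths under idealized noise at realistic
magnitudes — not that real data meet those idealizations.

## Problem sizes and numerics

Test and acceptance runs use sizes chosen to exercise the statistics
meaningfully on a single CPU: 315-row ζ tables with the full 50-member
ensemble (reduced member counts for CV/ablation as above), 200-trace
kinetic recovery suites, 20 cohorts of 40 barrels for patch localization,
and a few thousand trajectory frames for occupancy. Curve fits bound rate
constants strictly positive, cap iterations at 2 × 10⁴ per start and pick
the best multi-start RMSE; degenerate inputs (flat titrations, linear GP
curves, zero-variance differences, extrapolated calibrations) raise typed
errors rather than returning numbers.

## Known limitations

- The Cm stoichiometry is evaluated as printed; its unit irregularity is
  inherited, not resolved.
- The asymmetry-line classifier cannot distinguish hypotheses when their
  predictions coincide (zero donor fraction) or both fall within the band.
- The ζ ensemble is a tree model: predictions plateau between training
  points and single-feature sweeps can show ≤0.5 mV local non-monotonicity.
- Sequence-mode enrichment inherits the dilution of the residue-count
  calibration (one offset pools loops of different lengths), so its peaks
  are broader and its localization coarser (±2 Å) than structure mode.
- The permutation test's sampled path assumes the rank sampler can hold
  `n_samples` distinct ranks in memory (fine up to ~10⁷).
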