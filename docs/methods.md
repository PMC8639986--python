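# Methods

`rtkquant` implements five quantitative analyses used to characterize the
oligomerization and conformation of a membrane receptor tyrosine kinase
(the motivating system is EphA2, whose kinase–SAM linker carries the
phosphosite cluster S892/S897/T898/S899/S901), together with synthetic-data
generators that produce inputs with known ground truth for each stage.

## Monomer–dimer FRET equilibrium (`rtkquant.fret`)

**Model.** Receptors at total surface density [T] partition between
monomers and dimers by mass action with a two-dimensional dissociation
constant K_diss = [M]²/[D]. The dimeric protomer fraction is

    f_D([T]; K) = ([T] − (K/4)(√(1 + 8[T]/K) − 1)) / [T]

and the FRET efficiency measured in a membrane region with acceptor
fraction x_A is FRET = f_D·x_A·Ẽ, where the intrinsic FRET Ẽ is the
efficiency inside one donor–acceptor dimer — a structural constant.
Surface-density units are arbitrary but shared by [T] and K_diss; the
package never converts to molecules/µm² (instrument calibration is out of
scope).

**Numerics.** `dimeric_fraction` evaluates the algebraically identical
form f_D = 1 − 2/(1 + √(1 + 8T/K)). The textbook expression subtracts two
nearly equal quantities when T ≪ K and loses all significant digits; the
reformulated one is exact at both extremes, so no series switch-over is
needed. Tests verify agreement with a brute-force mass-action root finder
to 1e−10 over a 10⁴-point log grid spanning nine orders of magnitude of
T/K.

**Fitting.** `fit_dimerization` minimizes Σ(FRET_i/x_A,i − f_D(T_i; K)Ẽ)²
with equal weights (optional inverse-variance weights accepted; the
measurement protocol does not prescribe weighting). Parameters are
optimized as (log K, logit Ẽ) so positivity and Ẽ ∈ (0, 1] hold without a
constrained solver; log K is clamped to ±300 inside the residual so line
searches cannot underflow. Without a starting point, a multi-start over a
13-point log-spaced K grid covering 10⁻²–10⁴ × median(T) guards against
local minima. Standard errors come from the Gauss–Newton curvature at the
optimum, delta-method-transformed to the natural scale. If rescaling K
downward by successive decades changes the objective by less than
1e−10·(1 + RSS), the data do not bound K from below (e.g. constitutive
dimers, f_D ≡ 1); the fit reports the smallest K in the flat region and
sets `non_identifiable`. `bootstrap_fit` provides case-resampling
percentile intervals, deterministic given its seed.

## Fluctuation brightness (`rtkquant.fif`)

**Model.** Images are tiled into 15×15-pixel segments anchored at the mask
bounding-box origin; partial edge segments are discarded so every segment
has 225 pixels and variance estimates are comparable. Per segment,
brightness is ε = σ²/⟨I⟩ − 1 for a photon-counting detector and
ε = (σ² − σ_D²)/⟨I⟩ for an analog detector with read-noise variance σ_D².
The conventions differ by the shot-noise floor: applied to an underlying
photon stream, the analog formula reads one unit above the photon-counting
one (in practice the analog gain calibration absorbs it); neither
estimator is invariant under a deterministic intensity pedestal, which is
why background offsets must be removed upstream. For a mixture of s-mers
at per-pixel densities μ_s with photon yield q per fluorophore, the
apparent brightness converges to ε_app = q·Σμ_s s²/Σμ_s s
(law of total variance for the compound Poisson process); this closed form
is the oracle for all brightness tests.

**Distributions.** Variance uses the unbiased (n−1) estimator. Brightness
histograms use log-spaced bins over the central 99% of positive values by
default (configurable); out-of-range values are clipped into the edge bins
so every per-cell histogram sums to exactly 1. Cells are the unit of
averaging: the reported curve is the across-cell mean with standard error
SD/√n_cells per bin, and segment counts per cell are not equalized.
Negative-ε segments (possible from noise) stay in distributions but are
excluded from concentration proxies. `compare_to_references` places a
distribution relative to monomer/dimer control distributions by median
ratios, with "at control" meaning within 10% relative (configurable).

## SAXS primary analysis (`rtkquant.saxs`)

**Guinier.** ln I is regressed on q² over the largest low-q window
satisfying q_max·Rg ≤ 1.3 (the standard globular cutoff, configurable),
starting from the 5 lowest points and growing outward; a noisy positive
slope on a tiny initial window is skipped rather than treated as
aggregation, and the error is raised only when no window yields a negative
slope. Rg = √(−3·slope), I0 = exp(intercept).

**Forward model.** `debye_intensity` evaluates
I(q) = Σ_ij w_i w_j sin(qr_ij)/(qr_ij) exactly for ≤ 2000 points and via a
pair-distance histogram (0.1 Å bins by default) above that; the two routes
agree to < 1e−3 relative in tests. Point weights default to 1: per-atom
form factors and hydration shells scale absolute intensity, not the
shape-level quantities computed here, and are out of scope.

**P(r).** From coordinates, P(r) is the weighted pair-distance histogram
(1 Å bins), normalized to unit area, with D_max the exact maximum pairwise
distance and Rg from the second moment Rg² = ∫r²P(r)dr/2. From a
scattering curve, `ift_pr` inverts I(q) = 4π∫P(r)·sinc(qr)dr on a
101-point r grid per candidate D_max with P(0) = P(D_max) = 0 pinned,
non-negativity enforced by NNLS, and a second-difference smoothness
penalty. The smoothness weight is chosen per candidate by an L-curve
heuristic — the largest α whose χ² stays within 10% of the
least-regularized fit — on a dimensionless grid anchored to the ratio of
the Frobenius norms of the weighted design matrix and the penalty
operator. Candidate selection is a parsimony rule: among candidates whose
χ² is within 5% of the best, the smallest D_max wins (excess support costs
nothing in χ² but spreads oscillatory artifacts), with roughness as the
tie-break; under-sized candidates are excluded by their χ² blow-up. When a
curve carries no experimental σ, residuals are weighted relatively (1% of
I, floored at 1e−8·max I) so all q decades contribute shape information.
The reported D_max is the end of the recovered support (last grid point
holding ≥ 1e−4 of the peak), at the r-grid resolution; comparisons should
use ±1 bin tolerance. GNOM's exact regularization is deliberately not
reproduced bit-for-bit — round-trip tests (structure → Debye → IFT)
bound the error instead: D_max within 10% and Rg within 3% on sphere and
dumbbell fixtures.

**Comparisons.** `compare_pr` interpolates both distributions onto a
common grid zero-padded to the larger D_max and reports ΔD_max, ΔRg, the
difference in mass beyond the pooled 0.9 quantile (tail prominence — the
signature of an elongating conformational change), and the L1 distance.
Delta fields negate exactly under argument swap.

## HDX-MS uptake (`rtkquant.hdx`)

Uptake is the replicate-mean centroid shift against the undeuterated
control; the global back-exchange correction divides by (1 − factor), 0.25
by default (the typical loss determined from disordered-termini
standards). Relative fractional uptake divides by the exchange-competent
amide count: peptide length − 2 − interior prolines (the N-terminal
residue retains no amide deuterium, the second exchanges back too fast,
prolines have no backbone NH); the alternative length − 1 − prolines
convention is available. Difference profiles match (peptide, time) pairs
across conditions; the pooled SD is the quadrature sum of the two
conditions' replicate SDs on the RFU scale, and |Δ| > 2 × pooled SD flags
significance (multiplier configurable). Because the threshold pools SDs
rather than standard errors, it is conservative — about 2σ√3 on the SD of
a triplicate-mean difference — which keeps the false-flag rate of a null
comparison near 2–3% rather than the ~12% a naive 2-SE rule with 4 degrees
of freedom would give. Residue maps assign each covered residue the
unweighted mean RFU of its covering peptides; uncovered residues carry
NaN. The time grid defaults to {0, 0.5, 1, 2, 5} min with triplicates.

## Kinase screen and phosphosite statistics (`rtkquant.screen`)

Rankings sort descending by signal (ties by name) and report cumulative
signal fractions; `threshold_count` uses strict ">" (matching the
">50,000 CPM" convention of radioassay reporting). CPM and RLU are never
mixed in one comparison. `site_preference` first averages substrate
variants differing only in the last residue, then compares substrate
groups pairwise: when two groups differ in exactly one site's
availability, the signal ratio attributes activity (≥10× "mainly
phosphorylates", ≥3× "prefers", else indifferent); when they differ only
in one site's pre-phosphorylation, a ≥3× win for the primed variant reads
"requires priming" — the acidophilic-kinase pattern. The thresholds are
package defaults (reported with every result) since such comparisons are
conventionally described qualitatively. `multisite_fraction` and
`site_correlation` are count-weighted tallies and Pearson correlation
(constant columns flagged NaN), cross-checked against brute-force
recomputation.

## Synthetic data (`rtkquant.synthetic`)

Each generator draws from exactly the statistical model its analysis
assumes, so parameter recovery tests the analysis rather than the
generator. All generators are deterministic given their seed; sub-streams
are spawned per region/row/peptide so partial regeneration is stable.

- **FRET** (`gen_fret_dataset`): defaults K_diss = 200, Ẽ = 0.55, 300
  regions, densities log-uniform over 20–2000 (expression spans orders of
  magnitude across cells, and a log-uniform draw covers the transition
  region evenly), acceptor fractions uniform on 0.4–0.8 (around the 2:1
  acceptor:donor transfection target), additive Gaussian noise of SD 0.03
  on efficiency, clipped to [0, 1] — the simplest model consistent with
  the few-percent scatter of region-level FRET measurements.
- **Membrane images** (`gen_membrane_image`): per pixel, N_s ~ Poisson(μ_s)
  units per species, then photons ~ Poisson(q·ΣN_s·s); defaults 256×256,
  one monomeric species at μ = 5, q = 3. Empirical mean and variance match
  ⟨I⟩ = qΣμ_s s and σ² = ⟨I⟩ + q²Σμ_s s² within 3 Monte-Carlo SEs over
  10⁶ pixels. No point-spread function, diffusion, or frame series: the
  model is spatial, single-frame, per-pixel-independent — sufficient for
  the segment-statistics estimator, but silent on spatial correlations real
  optics introduce.
- **Toy structures** (`gen_toy_structure`): bead models with closed-form
  geometry — solid sphere (Rg = R√(3/5), D_max = 2R), shell, dumbbell
  (D_max = separation + 2R), two-domain-with-linker. Shape-only scattering
  with unit weights.
- **HDX** (`gen_hdx_dataset`): per-residue exponential exchange,
  exchange-competent amides excluding prolines and each peptide's two
  N-terminal residues, a global back-exchange loss on all in-solution
  uptake, and Gaussian replicate noise (0.05 Da default) on centroids.
  Centroid shifts are expressed in deuteron units (1 Da per deuteron), so
  a fully exchanged, corrected peptide has RFU exactly 1; the 0.6% H→D
  mass defect is a scale factor the arithmetic never sees. EX1 bimodality
  and peptide-level back-exchange variation are not modeled.
- **Kinase tables** (`gen_kinase_table`): a sorted lognormal sample fixes
  the rank order; an order-preserving power transform is solved so the top
  n_top kinases hold exactly the requested share of total signal (defaults
  mirror a 298-kinase screen with the top 45 holding 70%). Shares at or
  below n_top/n are rejected as infeasible for a descending ranking.

**What passing tests do and do not show.** The generators realize ideal
versions of each measurement: no spatial PSF correlations, no
photobleaching, no peptide misassignment, no inter-batch SAXS background
errors. Passing recovery tests therefore demonstrates correctness of the
estimators under their stated assumptions, not robustness to every
real-data artifact; the configurable thresholds (Guinier cutoff,
significance multiplier, preference ratios) are the knobs a practitioner
would adjust when those assumptions are strained.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make Monte-Carlo
error comfortably smaller than the tolerances they check: 300 regions ×
30 seeds for FRET recovery, 255×255-pixel frames (289 segments) per
brightness condition, 3000-bead structures with 120-point curves for SAXS
round trips, a 56-residue construct with 6 peptides × 100 seed pairs for
HDX difference detection, and 298-kinase tables for screen analytics.
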