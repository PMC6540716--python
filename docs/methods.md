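# Methods

This note documents the statistical models behind `exudomics`, the
defaults of the synthetic-data generator, and the numerical choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The analysis model

All community statistics operate on a binary samples × features matrix:
a feature is *present* when its aligned LC-MS intensity strictly exceeds
a threshold (default 0). Two filters precede binarization, in a fixed
order:

1. **Blank filter** — a feature present in ≥ 50 % of water-control
   samples is treated as a procedural artefact and removed. The boundary
   is inclusive; blanks are pooled across regions by default (a
   stratified per-region mode exists but is not the default because the
   pooling choice is not fixed by the protocol the filter mimics).
2. **Singleton filter** — a feature observed at most once across all
   exudate samples is removed. Occurrence is counted over exudate
   samples only; blanks are a different population (configurable).

The order blank-filter → singleton-filter → binarize is fixed and
idempotent; provenance entries record every parameter.

### Chemical richness

Per-sample richness is the binary row sum. Species differences are
tested by one-way ANOVA at the sample level (sample counts per species
are unbalanced by design); a summary-level mode (mean or median per
species) is provided because both response choices are defensible for
violin-plot style summaries. Degenerate inputs follow explicit
contracts: zero between-group variance reports F = 0, p = 1; perfect
separation with zero within-group variance reports F = ∞, p = 0.

The Scheffé all-pairs test declares a pair (i, j) different when

|mean_i − mean_j| > sqrt((k − 1) · F_{α; k−1, N−k} · MSE · (1/n_i + 1/n_j)).

Letters come from the insert-and-absorb algorithm with groups ordered by
descending mean, which makes the display deterministic and guarantees
the invariant *shared letter ⇔ non-significant pair* (the suite asserts
it exhaustively).

### Species-specificity screen

For each compound and focal group, with k occurrences among the focal
group's n samples and k′ among the remaining n′, the screen conditions
on the total count T = k + k′ and evaluates the one-sided exact tail
P(X ≥ k) for X ~ Binomial(T, p₀), p₀ = n/(n + n′). "Probability > 0.95"
is implemented as tail p < 0.05. This conditional-on-T construction is
the canonical exact one-vs-rest test; the original description leaves
the null's exact form open, so it is a documented interpretation, not a
verified reproduction. Compounds qualifying for several species are
attributed to the smallest p-value (ties broken by species label), so
per-species counts are disjoint. Genus screens pool congeneric samples
(the two *Galium* species by default) against all others and are
independent of the per-species attribution. No multiple-testing
correction is applied by default, mirroring the per-test criterion; a
Benjamini–Hochberg mode exists but is off.

Two calibration facts matter for interpretation. First, the exact test
is conservative: discreteness alone keeps the achieved level below the
nominal 0.05, and under independent-Bernoulli occupancy the true
conditional law of k given T is hypergeometric, whose variance is
smaller than the binomial null's — both effects push the realized
per-test flag rate below nominal (the acceptance suite measures it as a
one-sided bound). Second, with ~10 tests per compound and thousands of
unstructured compounds, per-test α accumulates into a non-trivial
family-wise flag count; that is a property of the screen itself, which
the recovery metrics against planted truth quantify.

### Ordination

PCA, RDA and partial RDA are implemented directly on the SVD. For RDA
the centered response Y is projected onto the column space of the
centered predictors X via a rank-revealing solver; constrained axes are
the principal axes of the fitted values, eigenvalue_i = s_i²/(n − 1),
proportions are relative to the total variance of centered Y, and
residual axes complete the decomposition so that constrained +
unconstrained (+ conditioned, in the partial case) equals the total
variance to 1e−8. Species enter as a full one-hot indicator matrix; the
pseudoinverse handles its rank deficiency without an arbitrary
reference level. A model whose predictors leave no residual degrees of
freedom (rank ≥ n − 1) is rejected as saturated. In partial RDA the
projection cutoff for the residualized predictors is taken relative to
the scale of the *original* predictors, so directions numerically
annihilated by the conditioning cannot resurface as spurious
constrained variance.

Binary matrices are centered but not scaled before ordination:
presence/absence columns already share one scale.

DCA is correspondence analysis with detrending by segments (default
26) and no nonlinear rescaling: axis 1 is the plain CA axis; each later
axis is extracted by reciprocal averaging, detrended against all
previous axes each iteration (segment means subtracted), and normalized
in the row-weighted metric. Rescaling is omitted because the axes serve
as numeric predictors downstream and rescaling conventions vary between
implementations. Eigenvalues for detrended axes are the contraction
factor of the converged iteration, clipped to [0, 1].

Hierarchical clustering uses Euclidean distance and complete linkage —
the documented defaults of the clustering functions the analysis
mimics; on a binary matrix Euclidean distance is the square root of the
Hamming count. Dendrograms export as Newick with branch lengths derived
from merge heights.

### Trait–exudate coupling and variance attribution

Procrustes analysis runs on the PCA site scores of each matrix (all
axes with nonzero eigenvalue by default; the number of retained axes is
configurable because the original choice is not recorded). In the
symmetric mode both configurations are centered and scaled to unit sum
of squares; m² = 1 − (Σ singular values of X'Y)² and the correlation is
√(1 − m²), invariant under translation, rotation, reflection and
uniform scaling of either configuration. Column counts may differ; the
statistic uses the rectangular cross-product, equivalent to
zero-padding the narrower configuration. The permutation test shuffles
rows of one configuration and uses the add-one convention
p = (1 + #{perm ≥ observed})/(1 + B), which keeps the Monte-Carlo test
exactly valid; the smallest attainable p is 1/(B + 1).

Variance partitioning computes the Ezekiel-adjusted R²,
1 − (1 − R²)(n − 1)/(n − p − 1) with p = rank of the centered
predictors, for every non-empty union of 1–4 predictor sets, then
solves the inclusion–exclusion system exactly for the Venn fractions;
the residual is 1 − adjR² of the full model and all fractions sum to
one to machine precision. Adjusted R² is used because unbalanced
designs make raw R² incomparable across predictor ranks — and it is
what makes small negative fractions possible; they are reported, not
clipped. Plot enters as plot-identity indicators (the alternative, a
set of environmental covariates, is not specified by the design being
mirrored). The single-variable table partitions variance over
{Species, Plot, one variable} per growth form, one row per trait,
neighborhood metric (total cover, DCA axes 1–4, richness, Shannon) or
LUI.

### Land-use intensity

LUI = F_i/F_r + M_i/M_r + G_i/G_r per plot-year: fertilization
(kg N ha⁻¹ yr⁻¹), mowing frequency (yr⁻¹) and grazing intensity
standardized by reference means — computed per year across plots, per
region-year when a region column is present (within-site
standardization), or supplied as fixed constants. The reported index is
the 2006–2014 mean. A plot sitting at the reference means scores
exactly 3.

### MS/MS compound classes

Spectra (negative mode, [M−H]⁻ assumed) are reduced to fragments with
raw intensity strictly above 1000, normalized to base peak 1, and only
fragments with normalized intensity strictly above 0.1 participate in
matching. Neutral losses are precursor − fragment for every retained
fragment (non-positive losses discarded). The rule table maps
characteristic fragments and neutral losses to class or modifier labels
within ±0.005 Da (configurable per rule — Q-ToF-scale accuracy; no
tolerance is prescribed by the protocol mimicked). All shipped target
masses are computed from monoisotopic atomic masses at import time
(hexose/deoxyhexose/pentose/hexuronic losses, SO₃, HPO₃, H₂O, CO₂,
coumaroyl loss, deprotonated hydroxycinnamate fragments, flavonoid
retro-Diels-Alder fragments, hexose/sulfate/phosphate anions). Labels
aggregate per spectrum; modifiers co-occur freely with classes, so
combinations like *glycosylated + sulfated + phosphorylated* round-trip
exactly. Matching is independent of rule order, and shrinking a
tolerance never adds labels. The shipped table is a chemically standard
stand-in for an in-house database; users can load their own TSV.

## The synthetic study

The generator emulates the design the statistics were built for: ten
species (five forbs — including two congeneric *Galium* species — and
five grasses) with the unbalanced per-species sample counts
38, 41, 37, 39, 28, 40, 40, 48, 37, 41 (total 389), 46 plots in three
regions, and 30 water blanks processed like exudates. Feature classes
are planted with known labels:

- 270 compounds shared across all species (occupancy 0.8),
- species-specific compounds, focal occupancy 0.8 vs background 0.02,
  more numerous in forbs (60, 120, 90, 180, 84 per forb; summing 534)
  than grasses (19, 18, 18, 18, 18; summing 91),
- 150 compounds specific to the pooled *Galium* pair,
- 4,369 unstructured background compounds with per-feature occupancy
  uniform in [0.05, 0.5],
- 100 blank contaminants occupying ≥ 80 % of blanks (and 10 % of
  exudates), and 150 singletons present in exactly one sample,

so the two filters remove exactly the contaminants and singletons and
leave a 389 × 5,414 matrix. Presence is Bernoulli per sample with a
logistic plot shift (sd 0.5 log-odds; occupancies 0 and 1 are fixed
points) — the simplest occupancy model consistent with a
presence/absence analysis. Intensities are log-normal conditional on
presence; since downstream analysis binarizes, only positivity matters.
Traits are species mean + plot shift + noise over the 18 standard
above-/belowground traits, with trait records for 302 of 389 samples
(field campaigns rarely measure every plant); the species effect size
controls the recoverable Procrustes correlation. Neighborhood covers
follow fixed per-plot Dirichlet community profiles with log-normal
within-plot noise, so their ordination clusters by plot. Land-use
components follow plot-level regimes persistent across the nine years
2006–2014. Spectra carry the diagnostic peaks of their planted classes
plus configurable noise, either away from all rule windows or placed
inside the windows of unplanted rules to probe degradation.

What the generator does *not* emulate: chromatographic or raw-signal
structure, adducts and isotope patterns, intensity correlations between
features, phylogenetic trait structure, or spatial autocorrelation
between plots. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated occupancy
model, not instrument-level fidelity. A mortality/attrition parameter
exists but defaults to 0 because the per-species counts above are
already post-attrition field counts.

## Problem sizes and determinism

Every generator and every permutation test takes an explicit integer
seed; identical seeds give bit-identical outputs, and the pipeline
writes all artifacts with fixed numeric formatting so reruns are
byte-comparable. The test suite exercises the full 389-sample study for
end-to-end checks and calibration (10,000-feature null screens,
999-permutation protest at 302 samples, 200 × 199-permutation null
protest replicates); unit tests run on small fixtures. The acceptance
script uses the same study sizes.

## Known limitations

- The specificity null is an interpretation (see above); per-test
  calibration is verified against it, not against the original
  software's output.
- DCA eigenvalues for detrended axes are iteration contraction factors,
  comparable to but not identical with other implementations' reported
  values; only axis scores are consumed downstream.
- The asymmetric Procrustes mode scales one configuration only and is
  provided for completeness; all shipped analyses use the symmetric
  statistic.
- Adjusted-R² partitions can go slightly negative; they are reported
  as computed.
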