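# Methods

## Rarefaction of reported allele counts

The estimator inverts the sampling process that links a population's true
total allele count to the count a finite study observes.

**Frequency model.** For a total count `Na ≥ 2`, allele `i ∈ 1..Na` has
frequency `z_i ∝ i / (Na + 1 − i)`, normalized to sum to one. Frequencies
are strictly increasing in `i`, so the spectrum contains several fairly
common alleles and few vanishingly rare ones. This is deliberately
conservative: rare-allele-heavy spectra would imply much larger upward
corrections. The floor of 2 reflects that a monomorphic locus carries no
rarefiable signal.

**Sampling model.** A pool of `pool_size` diploid genotypes (default 10⁶)
is built by random union of gametes, i.e. `2·pool_size` i.i.d. draws from
the spectrum, which realizes Hardy–Weinberg genotype proportions in
expectation. `reps` samples (default 100) of `n` genotypes are drawn
without replacement and the mean distinct-allele count recorded. The
closed-form counterpart treats the pool as carrying the expected integer
copy count `c_i` of each allele (largest-remainder apportionment) and
computes the per-allele absence probability
`C(2·pool_size − c_i, 2n) / C(2·pool_size, 2n)`; the expected distinct
count is the sum of presence probabilities. The `fast_path` switch
substitutes this expectation for the Monte-Carlo inner loop; both routes
are kept and cross-validated against each other in the tests.

**Search.** The target is `max(2, round_half_up(reported))`; reported
means are fractional (averages over loci) while the procedure is defined
on whole counts, so rounding to the nearest integer is applied before the
search. Candidates are evaluated outward from the target in both
directions; whenever a candidate improves the incumbent, at least 10
further candidates are examined beyond it before that direction stops.
Ties prefer the smaller candidate. There is no statistical ceiling.
Because the expected sampled count is strictly increasing in both the
candidate count and `n`, the objective is unimodal in expectation and the
estimate can never fall below the target (sampling only loses alleles).

**Saturation guard.** When `n` is very small relative to the reported
count, the expected observed count approaches its ceiling of `2n` gene
copies so slowly that successive candidates improve the objective by
amounts below any practical resolution; the Monte-Carlo search then
terminates only by noise, and the analytic search would not terminate at
all. A hard cap (`max_candidates`, default 1000 evaluations per search)
bounds the loop and logs a warning. In this regime the rarefied count is
a lower bound, not a point estimate — a genuine identifiability limit of
rarefaction from a mean count alone, not an artifact of this
implementation.

## Taxonomy-proxy tree and Brownian covariance

Without a calibrated phylogeny, shared history is read off the Linnean
classification: an ultrametric tree with five equal-length edge levels
(class, order, family, genus, species) and total depth 1. Under Brownian
motion the trait covariance of species `i, j` is the depth of their most
recent common ancestor — 0, 0.2, 0.4, 0.6 or 0.8 — and 1 on the diagonal,
interpretable as the fraction of root-to-tip history shared. Equal edge
lengths are the standard choice when no branch-length information exists;
they make `V` a Gram matrix (positive semi-definite by construction). A
diagonal nugget of 1e-8 restores strict positive definiteness where
needed, in particular when a resampled species set contains duplicates
(off-diagonal covariance 1). All species are placed under a common root;
after the bony-fish trim this is equivalent to treating the retained
class as the root.

## PGLS and the bootstrap

`β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` is computed by Cholesky whitening (`V = LLᵀ`;
OLS on `L⁻¹X, L⁻¹y`), with an eigenvalue-clip fallback at 1e-10 for
non-PD inputs and `σ̂² = rᵀV⁻¹r/(n−p)`. Categorical predictors use
cell-means coding (one indicator per level, no intercept), so each
coefficient is that level's ancestry-corrected mean; continuous
predictors use intercept + slope and the slope is reported.

**Bootstrap scheme.** Intervals are percentile intervals from a pairs
bootstrap on the whitened model: the rows of `(L⁻¹X, L⁻¹y)` are
exchangeable under the model, so resampling them with replacement and
refitting by OLS resamples the GLS estimating equations. At `V = I` this
is exactly the classical i.i.d. pairs bootstrap. The alternative of
resampling raw species rows and rebuilding `V` with duplicated tips at
covariance ~1 was evaluated and rejected: a cluster of `k` identical
copies at correlation ~1 carries the GLS weight of roughly one
observation, so resample multiplicities are silently discarded and the
intervals are systematically too narrow (measured directly: on i.i.d.
data with `V = I` the rebuild scheme produced intervals ~40% narrower
than the classical bootstrap). Resamples that empty a factor level are
redrawn and counted. The default 10,000 iterations can be lowered in
config; the packaged tests and the acceptance script use 150–1000.

**Decisions.** A coefficient is nonzero when its closed 95% interval
excludes 0; two groups differ when their closed intervals do not overlap
(touching endpoints overlap). The overlap rule is the field's reporting
convention and is kept as the headline decision, but it is conservative
here: per-group cell means share the deep-ancestry variance components
(the common class and order effects), which inflate each marginal
interval yet cancel in any between-group contrast. The suite therefore
also reports percentile intervals of pairwise coefficient differences
computed from the joint bootstrap draws; these are the calibrated basis
for ground-truth recovery checks.

## Model suite

Filter chain: keep the largest-sample study per species → drop extinct /
extinct-in-the-wild → trim to bony fishes (Osteichthyes, with
Actinopterygii accepted as a synonym) → rarefy once (all models consume
the same rarefied values) → per-model drops (missing heterozygosity only
from heterozygosity-response models; data-deficient / not-evaluated
species only from conservation models; missing traits only from the
corresponding life-history models). Habitat models fit
marine/freshwater/mixed cell means on all bony fishes; conservation and
life-history models run separately within marine and freshwater subsets;
mixed-habitat species appear only in the habitat models. Models with
fewer than `min_n = 10` usable species are skipped with a recorded
reason. Fecundity spans 10²–10⁷ eggs, so a `log10` transform is available
(default off for arbitrary input tables; the synthetic experiments use
raw age in years and log10 eggs on the latent scale).

## Synthetic worlds

The generator emits species tables with the exact statistical structure
the analysis assumes, so every stage is a parameter-recovery problem.

* **Taxonomy**: balanced per-class hierarchies pruned by seeded sampling
  to target sizes; the default world has 463 species in three classes
  (426 bony fishes, 32 cartilaginous fishes, 5 lampreys), coarsely
  emulating the ragged family sizes of real compilations.
* **Latent trait**: each species' true total allele count is
  `base (15, freshwater) + 11.3·marine (half for mixed) +
  0·threatened − 0.9·(age − mean) − 0.5·(log10 fecundity − mean) +
  Brownian deviation` with tip variance `σ²_BM = 25`, rounded and floored
  at 2. The zero conservation effect encodes the finding the suite should
  reproduce as a null; the marine effect and negative life-history slopes
  are the signals it should detect.
* **Observation**: each study draws `n` HWE genotypes per locus from the
  same parametric spectrum the estimator assumes (`n` lognormal, clipped
  to 10–974, mean ≈ 77; loci lognormal, clipped to 4–300, mean ≈ 14) and
  reports the distinct-allele count and heterozygote fraction averaged
  over loci. Observed heterozygosity is therefore mechanically linked to
  the allele count through HWE rather than independently injected
  (`habitat_delta_het` exists for decoupled experiments, default 0).

**What the generator does not emulate**: real allele-frequency spectra
(real loci need not follow the parametric model — passing closure tests
show the estimator inverts its own assumed spectrum, not that the
spectrum is right for any particular taxon); heterozygosity levels
comparable to field data (the HWE link yields higher heterozygosity per
allele count than real, structured populations show, so synthetic
heterozygosity coefficients sit above published ranges while allele-count
effects are on scale); correlation between habitat and taxonomy
(habitats are assigned i.i.d.); measurement error in life-history traits.

## Numerical choices and problem sizes

Frequency vectors are exact to 1e-12 normalization; hypergeometric
absence probabilities use log-gamma arithmetic; covariance factorizations
use Cholesky with eigenvalue clipping at 1e-10 as fallback; ties in the
rarefaction search break toward smaller counts; degenerate inputs (empty
tables, emptied factor levels, all-filtered datasets) raise or warn as
documented per function. Every random path flows from a single seed
through `numpy.random.default_rng` child seeds, making tables, searches
and bootstrap draws byte-reproducible.

The packaged test and acceptance workloads use scaled sizes chosen to
exercise every property at comfortable margins: Monte-Carlo/analytic
agreement on pools of 2×10⁵ with 200 replicates; closure grids at pool
10⁵ with 100 replicates; bootstrap calibration on 200 replicate
40-species Brownian datasets at 500 iterations; full-suite runs at the
complete 463-species scale with the analytic rarefaction path and 1000
bootstrap iterations. Full paper-scale Monte-Carlo rarefaction
(pool 10⁶, 100 reps per candidate) is the library default for real
analyses.

## Known limitations

* Rank-based covariance quantizes relatedness to five levels; real
  divergence times within a rank vary by orders of magnitude.
* The rarefied count is reported as an integer; fractional reported
  means are rounded before the search, discarding sub-allele precision.
* In the saturated regime (small `n`, large reported count) the rarefied
  value is a capped lower bound (see the saturation guard above).
* The CI-overlap decision rule is conservative for between-group
  questions; use the difference intervals for calibrated contrasts.
* No measurement-error model for heterozygosity; studies are weighted
  equally regardless of locus count once past the filters.
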