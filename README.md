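# fishdiv

Comparative analysis of microsatellite genetic diversity across fish
species: sample-size correction of reported allele counts, phylogenetic
regression on a taxonomy-proxy tree, and a synthetic-data test bench with
known ground truth.

## The problem

Published population-genetic surveys report, per species, a mean observed
heterozygosity and a mean number of alleles per locus, estimated from
anywhere between 10 and ~1000 genotyped individuals. Allele counts grow
with sample size, so raw counts are not comparable across studies — and
most studies do not publish the per-locus allele frequencies that
established maximum-likelihood rarefaction needs. Comparisons across
species are further confounded by shared evolutionary history: two
congeners are not independent data points.

`fishdiv` addresses both problems for a species-level compilation table
and then asks the comparative questions: do marine and freshwater fishes
differ in diversity, do threatened species carry less variation, and how
does diversity covary with age at maturity and fecundity?

## Methods in brief

**Rarefaction.** For a candidate total allele count `Na`, allele `i` is
assigned frequency

```
z_i = (i / (Na + 1 - i)) / Σ_j (j / (Na + 1 - j)),   i = 1..Na
```

a conservative spectrum with several common alleles. A pool of 10⁶
Hardy–Weinberg genotypes is built from it, samples of `n` genotypes
(the study's sample size) are drawn without replacement 100 times, and the
mean distinct-allele count is recorded. The rarefied estimate is the
candidate minimizing `|mean_sampled(Na, n) − reported|`, searched outward
in both directions with a floor of 2, no ceiling, and 10 extra candidates
examined beyond any new optimum. A closed-form hypergeometric expectation
(`fast_path`) replaces the Monte-Carlo inner loop when speed matters.

**PGLS.** Shared ancestry is approximated from Linnean ranks: an
ultrametric tree with five equal edge levels (class → order → family →
genus → species), total depth 1, so the Brownian trait covariance of two
species is the depth of their most recent common ancestor (0.8 for
congeners, 0.2 for class-mates, 0 across classes). Models are fit by
generalized least squares, `y = Xβ + ε`, `ε ~ N(0, Vσ²)`, with cell-means
coding so categorical coefficients are taxonomically corrected group
means. Confidence intervals come from a pairs bootstrap of the whitened
model; groups are compared by CI overlap, with joint-draw difference CIs
reported alongside.

**Model suite.** Fourteen models: habitat (2 responses × all bony fishes,
marine/freshwater/mixed cell means), conservation status (2 responses × 2
habitats, threatened vs not-threatened from IUCN categories), and life
history (2 responses × 2 habitats × {age at maturity, fecundity}, slope
models).

## Worked example

```sh
fishdiv simulate --preset small --seed 3 --outdir sim/
fishdiv rarefy --input sim/species.csv --output rarefied.csv \
    --seed 4 --fast-path --pool-size 200000
```

```
wrote sim/species.csv and sim/truth.json
rarefied 30 records; mean |rarefied - reported| = 5.84
```

The 30 simulated studies under-counted alleles by 5.84 per locus on
average — shallow studies miss rare alleles, and the rarefaction restores
them. Fitting the habitat model on the same table:

```sh
fishdiv fit --input sim/species.csv --response rarefied_alleles \
    --predictor habitat --config cfg.yaml --seed 6
```

```
"marine":     {"estimate": 26.9, "lower": 21.0, "upper": 36.9}
"freshwater": {"estimate": 11.2, "lower":  4.9, "upper": 21.3}
"mixed":      {"estimate": 23.7, "lower": 15.7, "upper": 34.1}
```

Coefficients are the ancestry-corrected mean rarefied allele counts per
habitat with 95% bootstrap intervals: this small world was generated with
marine species carrying more alleles than freshwater ones, and the fit
recovers that. The full pipeline (`fishdiv run`) applies the
best-study/extinct/bony-fish filters, rarefies once, and fits all fourteen
models, writing `results.tsv`, `results.json`, `results.md` and
`tree.nwk`.

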