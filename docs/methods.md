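# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic generator does and does not
emulate, and the known limitations.

## Data model and conventions

Mutation coordinates are 1-based, fully closed (VCF convention) on a single
genome build; the package never lifts over — inputs are expected to be
pre-normalized. Mutation identity is the tuple (chrom, pos, ref, alt) and
deliberately excludes the disease label: the same variant recorded for two
diseases counts once in mutation totals while contributing to both disease
gene sets. Gene symbols are compared case-sensitively after whitespace
trimming with no alias resolution; disease names are normalized to
lowercase with collapsed whitespace, and a user-supplied synonym map covers
matching to externally named phenotype resources. Count ratios in the merge
summary are rounded half-up to one decimal. The merged gene union is the
exact inclusion–exclusion value of the two input catalogs.

## Genetic similarity screen

The 2×2 membership table is tested with a Pearson chi-square on 1 df,
upper-tail p. No Yates continuity correction by default (a flag enables
it); the choice is recorded in the run log. The test universe defaults to
the union of the catalog's disease gene sets — the natural scope when the
catalog itself defines the genes under study — and is configurable to the
full catalog universe or a genome-wide list. A zero row or column margin
(an empty set, or a set equal to the universe) is degenerate: statistic 0,
p = 1, flagged rather than guessed. Significance uses raw p-values at the
0.05 cutoff; a Benjamini–Hochberg adjusted column is available for users
but does not drive any flag. The chi-square approximation is only trusted
where expected counts are moderate; the null-calibration tests therefore
run in a regime (universe 1000, sets of 200, expected overlap ≈ 40) where
the asymptotics hold, which checks the implementation rather than the
small-count behaviour of the test itself.

## Region contrasts and the "highly expressed" rule

Each gene is contrasted region-vs-rest, where "rest" is the pooled mean of
all non-region samples (not the mean of per-region means; the alternative
is available by flag). Tests always run on the log2 scale; linear-scale
input is transformed as log2(x + pseudocount), pseudocount 1 by default.
Fold change is reported on the declared scale: the ratio of arithmetic
means for linear data, 2^(Δ log2 mean) — a geometric-mean ratio — for log2
data. A gene is highly expressed in a region when fold ≥ 2 (boundary
inclusive, the literal reading of "one time higher") **and** the two-sided
contrast p < alpha; the fold filter supplies directionality. Note the
consequence: under a pure null the *flag* rate is far below alpha (the fold
filter almost never passes), so calibration statements apply to the
p-value rate, with the flag rate bounded above by it.

The default `eb` moderation re-implements the standard empirical-Bayes
variance shrinkage for expression contrasts: sample variances s²_g with d_g
residual df are assumed scaled-F around a prior s₀² with d₀ prior df;
(d₀, s₀²) are estimated by method of moments on log s²_g (digamma/trigamma
moment equations, trigamma inverted by Newton iteration), and the
moderated t uses posterior variances (d₀ s₀² + d_g s²_g)/(d₀ + d_g) on
d₀ + d_g df. When the observed log-variance spread is no wider than the
chi-square sampling noise, d₀ = ∞ and all genes share s₀². Degenerate
genes (zero variance, zero difference) get t = 0, p = 1.

## Context enrichment

The enrichment score is N_over/(N_G1 × N_G2); it is symmetric in the two
set sizes and strictly increasing in the overlap. The Fisher exact test is
two-tailed by the minimum-likelihood summation rule (all hypergeometric
outcomes no more probable than the observed one), the common exact-test
convention. The enrichment background defaults to the union of all marker
sets for cell-type analysis (a genome-wide background is accepted by
flag) and to the study's full gene list for region analysis; disease genes
are intersected with the background before testing, and a disease with no
genes in the background yields an all-zero profile with a warning rather
than an error. No multiple-testing correction is applied across the 25 (or
10) contexts — the significance flag is the raw p < 0.05 — with a BH
column emitted alongside.

## Profile distance

Profiles are binarized on score ≠ 0 (any overlap), not on FET
significance: the distance's "binary" convention thresholds on nonzero
values, and significance-based binarization is offered as
`binarize=significant`. With a/b/c the both/only-first/only-second nonzero
position counts, distance = (b + c)/(a + b + c); joint-zero positions are
ignored. When neither profile has a nonzero entry the distance is
undefined (NaN), excluded from rankings and correlations, and reported
separately — no sentinel values. Ranking ties break lexicographically by
pair name for reproducibility. Only range, symmetry and identity are
asserted as invariants; the triangle inequality is not relied upon. No
p-value is attached to a distance (there is no defined test for one).

## Phenotype layer

Multiple matchings of one disease pair in the phenotype resource are
pooled across row orderings and averaged arithmetically. Correlations are
Pearson (two-sided p via the t transform) or Spearman (scipy's asymptotic
p at all n; an exact small-n rank method is not exposed by the backend).
Pairs missing from either side or with undefined similarity are dropped
and counted, so the retained n is always reported. The genetic-layer
correlation is computed over pairs that share at least one gene, mirroring
how such pair sets are assembled in practice. Group comparisons use Welch
(unequal-variance) t-tests on the k lowest-distance pairs, a stated middle
rank range, and the k highest; group definitions must be disjoint.

## Synthetic cohorts

Defaults are the study scale: 20 diseases × 20 genes drawn from a 424-gene
universe; 25 marker contexts of 30 genes; 10 regions × 10 samples × 1000
genes; phenotype slope 0.1 with noise sd 0.005, putting scores on the
~0.02–0.05 scale typical of DMN-style resources.

Planted structure is *constructive*: each planted pair overlap is a
dedicated shared gene block allocated before unique fills, so realized
overlaps equal the planted matrix exactly and recovery tests are
deterministic given the seed. The default plants a chain of 14 overlapping
neighbour pairs with overlap counts cycling 9, 4, 8, 5, 7, 6 (proportions
0.2–0.45; the minimum of 4 keeps every planted pair unambiguously
significant at the default universe), and seeds both members of planted
pair i into marker context i at fraction 0.6. Mutations are generated per
gene (1–3 variants) with each linked disease carrying a ~70% subset, so
gene-sharing diseases share some but not all variants — gene-level
similarity is stronger than mutation-level, as in real catalogs.
Expression plants two genes per region at +2 log2 under noise sd 0.5,
comfortably but not trivially above the fold-2 calling threshold.
`planted_overlaps=None` switches to independent uniform draws (the null
model for calibration); an empty list means constructively disjoint sets.
All randomness derives from one root seed through named substreams, so any
input kind regenerates independently and byte-identically.

What the generator does **not** emulate: real marker-gene structure
(hierarchically related cell subtypes, shared markers between related
types), probe-level microarray artefacts, batch or covariate structure in
expression, literature-curation biases in mutation catalogs, or semantic
phenotype matching. Passing recovery tests therefore demonstrates that the
pipeline detects the signals it models, at realistic scale and noise — not
that those signals are extractable from any particular real resource.

## Problem sizes in the checks

The acceptance-style checks use 100 replicates of the study-scale preset
for recovery rates, 600 single-pair replicates for genetic null
calibration, 400 × 200 genes (plain t, exactly calibrated under the
normal null) plus one 2000-gene replicate (moderated t) for region null
calibration, and exhaustive enumerations for the three statistical kernels
(all 2×2 tables with background ≤ 40 for the FET, all cell values ≤ 12
for the chi-square, all binary profile pairs of length ≤ 6 for the
distance). The standalone report script uses 50 recovery and 400/200 null
replicates.

## Known limitations

* The chi-square screen at real catalog scale (sets of ~20 genes in a
  ~400-gene universe) operates with small expected overlap counts, where
  the 1-df approximation is anti-conservative; the FET-based enrichment
  machinery is exact and preferable when counts are tiny.
* Region contrasts model region-vs-rest only; no covariates, batch terms
  or probe-to-gene mapping.
* The asymmetric binary distance discards effect-size information by
  construction; two profiles with identical supports but very different
  scores are at distance 0.
* Phenotype matching is name-based (plus synonym map); no semantic
  ontology matching.
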