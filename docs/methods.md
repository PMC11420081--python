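# Methods

This note records the statistical model behind each stage, the parameter
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Inputs and filtering

Every stage consumes differential-expression summary tables: per gene, a
stable identifier, symbol, log2 fold change, mean normalized expression
(the baseMean role) and an unadjusted P value. Two thresholds recur:

- `deg_p_threshold` (default 0.05): a gene is a DEG when its unadjusted P
  is below this; up/down direction is the sign of its log2 fold change
  (exactly 0 is neither).
- `mean_expr_floor` (default 20, exclusive-keep): genes with mean
  expression ≤ 20 are excluded before any correlation or direction
  statistic, the conventional low-expression baseMean filter.

Files are TSV or CSV (tab/comma auto-detected; files containing both in
the header are rejected rather than guessed, since silent mis-parsing
corrupts every downstream statistic). Floats are serialized with 17
significant digits, which round-trips IEEE doubles exactly; reading parses
through Python's correctly-rounded `float`, not pandas' fast path, for the
same reason.

## Ortholog resolution

Ortholog correspondence tables (mouse symbol, human symbol, human gene ID)
are many-to-many. Resolution keeps, for each mouse symbol: its unique
candidate when there is only one; otherwise the candidate whose human
symbol equals the ASCII upper-casing of the mouse symbol (mouse
nomenclature capitalizes the first letter only, human symbols are fully
upper-case). No fuzzy or alias matching is attempted — the rule is exact
and reproducible. Symbols with no match under the rule are dropped and
excluded from all downstream background universes; two distinct IDs both
matching exactly indicate a corrupt table and raise. When two mouse genes
resolve to one human ID after re-keying, the row with the smaller P value
is kept: the map must stay one-to-one for hypergeometric universes, and
minimum-P preserves the strongest evidence.

## The four per-cluster analyses

**DEG-count excess.** Larger clusters yield more DEGs for power reasons
alone, so raw DEG counts are not comparable. The expected count per
cluster is an ordinary least-squares regression (with intercept) of DEG
count on cell count across clusters, floored at 0.5 so the contingency
table below stays positive. A 2×K table is formed with row 1 = observed
counts and row 2 = rounded expected counts; the adjusted standardized
residual of each observed cell under the independence model,
r_c = (O_c − Ê_c)/√(Ê_c (1 − rowprop₁)(1 − colprop_c)), is converted to an
upper one-tailed standard-normal P. Two constructions were open here
(which cell's residual; Pearson vs adjusted residual); the adjusted
residual of the observed-row cell is used, matching the standard
chi-square-test residual semantics, and is verified in the tests against
statsmodels' independent implementation. Note the construction treats both
rows as sampled, which makes it conservative for Poisson-dispersed counts;
see the generator section.

**Gene-set overlaps.** Overlap between a cluster's DEGs and a gene set is
tested with the inclusive upper-tail hypergeometric probability
P(X ≥ k), with the gene set intersected with the background universe
first. The background is the set of genes detected in the experiment and
successfully mapped to human IDs — not the whole genome — since only those
genes could have appeared as DEGs.

**Heritability slot.** SNP-heritability enrichment of the top-N DEGs
(default N = 1000, by unadjusted P, ties broken by larger |log2fc| then
gene ID) is an external computation (stratified LD-score regression); the
pipeline accepts its per-label P values as a file and passes them through.
For self-contained runs a permutation stub scores the gene list by its
summed per-gene score against same-size uniformly drawn lists; permutation
P values use the add-one rule (k+1)/(R+1), which is a valid test and never
returns 0 (a requirement of the downstream Fisher combination).

**Rank-sum integration.** Within each analysis, clusters are ranked by
ascending P with average ranks on exact ties (ties across clusters are
rare but must not distort the sum). The total score is the sum of the four
ranks; smaller means more disease-associated. Equal totals are ordered by
the Fisher combined probability of the cluster's P values
(X = −2Σln p ~ χ² with 2m df), then by cluster label so output order is
deterministic. Fisher's statistic sums the logs in sorted order, making it
invariant to input permutation at floating-point precision. If any
analysis lacks a P value for any cluster (e.g. no heritability source),
that analysis is dropped for *all* clusters and the total runs over the
remaining ones — 3-analysis and 4-analysis sums are never mixed — with the
drop recorded in the run metadata. Negative-deviation clusters keep their
(large) residual P and are ranked like any other; no cluster is excluded.

**Cell-composition test.** The genotype × cluster contingency table is
tested by a Monte-Carlo Fisher exact test: tables are sampled from the
fixed-margins null (Patefield's algorithm) and
p = (1 + #{tables with probability ≤ observed})/(reps + 1), with a 1e-7
relative tolerance on the probability comparison because exact
floating-point ties are the common case. An exact enumeration mode (2×K)
exists for small tables and is the oracle in the tests.

## Reversal statistics

An up-regulated DEG of the untreated mutant–wildtype comparison counts as
reversed when its treatment-effect log2 fold change is negative (and
symmetrically for down-regulated); exactly 0 counts as not reversed, the
conservative choice since sign(0) is undefined. Classification depends
only on signs, hence is invariant to positive rescaling of the effect fold
changes. Counts are tested against Binomial(n, 0.5) with the exact
two-sided point-probability ("minlike") definition — the sum of all
outcome probabilities not exceeding that of the observed count — which for
p₀ = 0.5 equals the doubled smaller tail capped at 1. Tail evaluation goes
through exact distribution functions and keeps full double precision into
the 1e-44 range the real data produce.

Steiger's test compares two correlations r_jk, r_jh sharing variable j on
the same n observations: both are Fisher z-transformed, and

    r̄ = (r_jk + r_jh)/2
    ψ̄ = r_kh(1 − 2r̄²) − ½ r̄²(1 − 2r̄² − r_kh²)
    s̄ = ψ̄/(1 − r̄²)²
    z = (z_jk − z_jh) √((n − 3)/(2 − 2s̄))

with a two-sided normal P. The inputs n and r_kh are always computed from
the data at hand (shared filtered gene count and the empirical correlation
between the two non-shared vectors), since published reports typically
omit them. |r| = 1 is rejected (Fisher z undefined), which is why a
reversal report without a genuine independent reference comparison skips
the Steiger block rather than comparing a vector with itself.

## The synthetic generator

The generator works at the summary-statistic level — fold changes, mean
expressions and P values — not read counts, because the downstream
statistics consume summaries only and differential-expression engines are
out of scope. It does **not** model scRNA-seq count noise (no
negative-binomial/dropout machinery), library-size effects, or correlated
genes; passing tests demonstrate correctness of the statistics under the
assumed sampling structure, not robustness to real single-cell artifacts.

Cluster experiments: per-cluster DEG counts are
round(intercept + slope·cells + ε), truncated at zero, with ε ~ N(0, sd).
Defaults: 2000 genes, 200 risk genes, intercept 10, slope 0.15, cells
800–1200 (expected counts ≈ 130–190), noise SD 18. The noise SD is chosen
as ≈ √(2E) at the default expected counts: the observed/expected
contingency-table residual implicitly assumes both rows are sampled, i.e.
count dispersion ≈ 2E, and the generator's role is to produce data with
the statistical structure the analysis assumes — with this choice all
per-cluster P values are null-calibrated (rejection ≈ 0.04–0.05 at
α = 0.05), whereas Poisson-scale noise would make the residual test
conservative (≈ 0.01). DEG genes are drawn without replacement with
risk-set members weighted by the cluster's planted odds ratio (1 = null;
∞ confines DEGs to the risk set); DEG P values are Uniform(0, threshold),
sufficient because downstream uses only thresholding and top-N order; the
up/down direction is a fair coin.

A planted *disease-associated* cluster shows signal in all four analyses,
as in the study design this emulates: risk-set enrichment at the planted
odds ratio (feeding both overlap analyses — the synthetic postmortem set
shares half its members with the risk set, related but not identical, as
real exome and postmortem sets are), a +2 SD heritability-score bonus on
risk genes, and an optional per-cluster DEG-count excess above the size
trend (default 60 in the recovery fixtures, ≈ 3 noise SDs, the magnitude
of a prominent deviation). With odds ratio 3 and ≥ 150 planted DEGs among
12 clusters, the planted cluster attains final rank 1 in ≈ 100% of
replicates; with the excess omitted the rank-sum pays a uniform-rank toll
on the excess analysis and recovery drops to ≈ 0.85.

Reversal experiments: mutant DEG fold changes are sign·(0.3 + |N(0, 0.4)|)
with the requested up/down split; the treatment effect is
s·λ·fc + N(0, noise) with s = −1 with the planted reversal probability
(default 0.9, the magnitude observed in the real pharmacological data),
damping λ = 0.8 and noise SD 0.05 — small relative to the minimum damped
fold change (0.24), so planted reversals are essentially never flipped by
noise and the observed fraction is an unbiased estimate of the planted
probability. A configurable fraction of genes receives mean expression at
half the floor to exercise the low-expression filter.

All generators are pure functions of their truth objects (seed included):
identical truth, identical bytes.

## Validation studies and sizes

`degrank.experiments` (shared by `analysis/04`, the acceptance tests and
`scripts/acceptance.py`) runs: null calibration over 60 replicates × 18
clusters = 1080 null cluster P values per statistic (and 1500 trivariate
normal replicates at n = 200 for Steiger's test), checked against
0.05 ± 3 binomial SEs; planted-cluster recovery over 100 replicates;
reversal-fraction recovery over 200 replicates at n = 400 DEGs. These
sizes give standard errors a few times smaller than the effects being
checked while keeping the whole suite around half a minute on one CPU.
The permutation stub uses 199 permutations in the replicated studies
(the add-one grid then contains 0.05 exactly, so the nominal level is
attainable) and 999 in single analyses.

## Numerical conventions

- Hypergeometric tails via the survival function at k−1 (inclusive tail).
- Expected regression counts floored at 0.5; the expected row of the 2×K
  table is rounded to integers (a count table needs integral cells; the
  construction is insensitive at the realistic count sizes).
- Discrete tests (hypergeometric, permutation) are conservative at fixed
  levels by construction; their null rejection sits at ≈ 0.039–0.047,
  inside the acceptance band but below 0.05 — inherent to discreteness,
  not an implementation artifact.
- P values of 0 are rejected by the Fisher combination; permutation
  sources must use add-one P values.
- All randomness flows from integer seeds through numpy Generators seeded
  with small-integer sequences; no global state is touched.

## Known limitations

- The residual construction's "both rows sampled" variance assumption is
  inherited from the emulated procedure; on data whose count dispersion is
  far from 2E its P values are mis-calibrated in the corresponding
  direction.
- The heritability stub is a stand-in interface exercising the pipeline's
  pluggable P-value slot; it is not an approximation of LD-score
  regression, and real analyses should supply external P values.
- The ortholog rule is exact upper-casing; genuine orthologs whose human
  symbol differs from the capitalized mouse symbol (renamed genes) are
  dropped, which is the reproducible but lossy behavior of the emulated
  procedure.
- Spearman concordance uses the asymptotic t approximation by default; the
  exact permutation P is limited to K ≤ 8 clusters.
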