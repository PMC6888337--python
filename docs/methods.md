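# Methods

`litsig` implements a literature-guided transcriptome analysis: expression
matrices are first reduced to genes whose co-occurrence with a set of query
terms (lipid and inflammation vocabulary in the motivating NASH
application) is over-represented in the literature, and only then tested
for differential expression. Restricting the testing burden to a few dozen
literature-supported genes instead of ~30,000 array features is the core
statistical idea: it trades genome-wide discovery for a large reduction in
the multiple-testing penalty on a biologically pre-filtered panel. The
stages downstream of the reduction — SAM, PCA, marker ROC, enrichment,
interaction-partner expansion and alteration-based survival stratification
— are standard, and this note records exactly how each is computed.

## Literature co-occurrence scoring

A corpus is a gene × term table of document co-occurrence counts plus a
document total `N`. For a query term set, gene `g` is scored with the
one-sided hypergeometric tail on the 2×2 document table: `k` = documents
pairing `g` with any query term, `K` = the gene marginal (row sum), `n` =
the query-term marginal, so `p = P[X ≥ k]`, `X ~ Hypergeom(N, K, n)`.
Benjamini–Hochberg correction runs across genes and the signature is the
set with `q < 0.05`. Counts are document counts (a document contributes
once per gene–term pair), gene symbols match case-insensitively, and ties
are always broken deterministically (count descending, then symbol). The
scoring statistic is a pluggable hook (`score_fn`), since co-occurrence
significance can be defined in several defensible ways; the hypergeometric
over-representation form is the package default.

Prioritization is a separate, simpler operation: candidate genes are
ranked by their raw count on one primary term (e.g. "liver"), ties broken
by the summed count over secondary terms (immunity/inflammation/progression
vocabulary), and the top-k table of (gene, term, count) triples is exported
in a circos-ready layout.

## SAM (two-class unpaired, permutation FDR)

The moderated statistic is `d_i = r_i / (s_i + s0)` with `r_i` the group
mean difference on the log2 scale and

    s_i = sqrt( [(1/n1 + 1/n2) / (n1 + n2 − 2)] · [SS_1(i) + SS_2(i)] ).

The fudge factor `s0` is selected from the percentile grid 0, 5, …, 100 of
`{s_i}`: for each candidate, genes are cut into up to 100 quantile bins of
`s_i`, the median absolute deviation of `d` is taken per bin, and the
candidate minimizing the coefficient of variation of those MADs wins (ties
to the smaller candidate). Below 100 genes the selection is noisy and the
package warns.

The null comes from B = 500 seeded label permutations by default (exact
enumeration of all `C(n, n1)` arrangements replaces sampling when B reaches
that count, with a warning). Expected order statistics `d̄_(i)` are the
mean of the sorted permuted `d`. `π0` is the interquartile estimate
`min(1, #{d_i within the permutation [q25, q75]} / 0.5m)`. For each Δ on a
200-point grid from 0 to `max|d_(i) − d̄_(i)|`, the upper cut is the first
sorted position (on the non-negative side) whose excess over `d̄` reaches
Δ and the lower cut the last such position on the non-positive side; all
genes beyond the cuts are called, and

    FDR(Δ) = π0 · median over permutations of false calls / #called.

The grid FDR is then replaced by its running minimum, which makes FDR(Δ)
non-increasing and is exactly the q-value convention: a gene's `q` is the
smallest FDR at which it is ever called, i.e. the monotonized FDR at the
largest Δ still calling it. The reported `delta` is the smallest grid
value with FDR ≤ the target (default 0.05); the `called` flag is the gene
set at that delta. The median (not the mean) of permutation false calls
keeps single outlier permutations from inflating the FDR. Per-gene fold
changes are reported on the linear scale with a sign convention (+2.0 for
a doubling, −2.0 for a halving); all statistics operate on log2 values.

## PCA and group discrimination

Samples are observations and genes variables; variables are centered and,
by default, scaled to unit variance (zero-variance genes are dropped with
a warning). The decomposition is the SVD of the standardized matrix; each
axis is oriented so its largest-|loading| gene loads positively, making
signs reproducible. The per-axis group-discrimination test is a one-way
ANOVA of the axis coordinates across sample groups, reported as η², F and
p — the correlation-ratio test that axis-description routines apply to
categorical variables, and the only standard reading that yields one group
p-value per axis. Axis contributors are genes whose standardized profile
correlates with the axis coordinates at BH q < 0.05, ranked by
|correlation|.

The heatmap-style misclassification rate clusters samples hierarchically
with distance 1 − Pearson correlation and average linkage (both
configurable), cuts the tree into k = #groups clusters and reports the
minimal fraction of misassigned samples over cluster→group assignments
(exhaustive for k ≤ 4, Hungarian assignment above). Correlation distance
compares expression *profiles*; groups differing only by a constant offset
across all genes are invisible to it by construction.

## Marker evaluation

AUC is the Mann–Whitney probability with mid-rank tie handling; when the
raw AUC is below 0.5 the direction-corrected value 1 − AUC is reported
with `direction="down"`, so discriminative down-regulated markers read the
same way as up-regulated ones. The confidence interval uses DeLong
placement-value variance (cross-checked against R's pROC to 7 decimals in
development); the normal-approximation interval is known to cover one or
two points below nominal in small samples because the AUC sampling
distribution is skewed. Two-group tests default to Welch's unequal-variance
t (the common R default) with a flag for the pooled-variance form;
multi-group reporting combines Kruskal–Wallis (tie-corrected chi-square
approximation), one-way ANOVA and Tukey HSD adjusted pairwise p-values.

## Enrichment

For a query of size `n` inside a universe of size `N`, a set of size `R`
with overlap `r` gets

    z = (r − nR/N) / sqrt( n (R/N)(1 − R/N)(N − n)/(N − 1) )

plus the exact one-sided hypergeometric p and BH q across sets. The
universe defaults to the annotation universe and should be intersected
with the measured genes (`restrict_universe`) to avoid inflating z with
unmeasurable genes. Sets are ingested as GMT; no ontology traversal is
performed — sets are taken as given. Significant terms export as a
bipartite gene–function edge list plus a node-attribute table (z on
function nodes) importable into Cytoscape-class tools.

## Network expansion and survival stratification

Interaction tables ingest as undirected graphs over uppercased symbols;
self-loops and duplicate (orientation-insensitive) edges are dropped and
counted. Partner expansion returns the lexicographically ordered first
neighbors of a seed gene (depth configurable, default 1), which feed a
second SAM pass through the same reduction machinery.

Alteration profiles are binary patient × gene calls with per-call class
labels (mutation/amplification/deletion/fusion/other). Because long-form
alteration exports list only altered patients, the cohort denominator must
be supplied from the survival records. Per-gene frequencies are rounded to
whole percent before the ≥ threshold comparison (default 4%), so a
14-of-353 = 3.97% gene counts as 4%, matching how such cutoffs are quoted
in practice. Stratification compares patients altered in ≥ 1 core gene
against patients altered only in non-core genes; alteration-free patients
are excluded, and a patient altered in both kinds belongs to the core
group. The `events_only` flag (default on, matching the
relapsed/progressed subgroup comparison this design reproduces) restricts
both groups to patients with an observed event; both readings are exposed
because cohort descriptions are often ambiguous on this point.

Kaplan–Meier is the product-limit estimator with simultaneous-event ties;
the median is the smallest time with S ≤ 0.5 (undefined if never reached).
The log-rank test accumulates observed-minus-expected events and
hypergeometric variances over distinct pooled event times into a 1-df
chi-square. Both match lifelines to ≥ 8 significant digits in the test
suite; lifelines is used only as the independent cross-check.

## Synthetic data: what it emulates, and what it does not

Every pipeline input has a generator with planted ground truth, one seed
per call and no global RNG state:

* **Corpus** — Poisson counts `count(g,t) ~ Poisson(N p_g q_t)` with
  heavy-tailed gene weights, the query terms carrying ~20% of the
  literature mass and one `background` column absorbing the rest, so a
  gene's row sum behaves like its full document count. Associated genes
  have their query-term rates multiplied by the enrichment factor (> 1),
  emulating genes whose lipid-term co-occurrence exceeds what their
  overall literature presence predicts. Under independence (no planted
  associations) the scorer's p-values are empirically uniform.
* **Expression** — gene baselines U(5, 10) on the log2 scale, Gaussian
  noise with sd `sigma` (default 0.5, the RMA-normalized regime), and a
  ±`effect` shift (sign drawn per gene) for the DE subset in the second
  group. Effect 1.0 ⇒ expected linear fold change 2.
* **Network** — Erdős–Rényi background plus a guaranteed hub–partner star.
* **Survival** — Bernoulli per-gene alterations; exponential event times
  with the hazard multiplied by the planted ratio for core-altered
  patients (the minimal model under which the log-rank test is exact);
  independent exponential censoring whose rate is chosen so a baseline
  patient is censored with probability `censor_rate`
  (`c = h0 · censor_rate/(1 − censor_rate)`; 0 and 1 degenerate to
  no-censoring and all-censored).

The default bundle mirrors the motivating study's shape: 500 measured
genes, 87 literature-associated, 25 differentially expressed (a subset of
the associated genes), sample groups of 24/24/23 (healthy-obese, NASH,
NAFL), 40 hub partners overlapping the DE genes, and a 353-patient cohort
with a 5-gene ≥ 4% alteration core (8% core rate, 1% background, hazard
ratio 4, baseline hazard 0.02/month, 30% censoring). The generators do
**not** simulate probe-level noise, batch effects, correlated gene blocks,
non-proportional hazards or informative censoring — passing tests
demonstrate the estimators' correctness and calibration under clean
conditions, not robustness to those real-data complications. Only the
designated (second) group is shifted, so three-group clustering has an
irreducible misclassification floor between the two unshifted groups; the
end-to-end checks therefore assess planted-truth recovery, not the
clustering error number.

## Numerical and design notes

* All orderings that affect output files are deterministic; two runs with
  the same config and seed produce byte-identical artifacts (TSV floats
  printed at %.10g).
* Pipeline stages cache on sha256 of inputs, parameters and outputs; a
  corrupted artifact re-runs its stage.
* Probe→gene collapse keeps the probe with the highest mean expression
  (deterministic and the common convention); averaging is available via
  `rule="mean"`. Printed fold changes can shift slightly under a
  different collapse rule.
* BH q-values are clipped to [0, 1]; exact hypergeometric tails come from
  scipy; degenerate cases (all scales zero, no events, single group) raise
  typed errors rather than returning NaN.
* Desk-scale simulation sizes in the test suite (e.g. 10 × 6 exhaustive
  SAM panels, 20-seed recovery runs, 1000-rep coverage simulations) were
  chosen so each property suite completes in seconds while leaving
  comfortable Monte-Carlo margins around its assertion bands.

## Known limitations

* Gene identity is plain symbol matching (uppercased); aliases, species
  mapping and probe ambiguity resolution are out of scope.
* The literature model treats counts as document counts under a
  conditional-independence null; mention-level counts or citation bias are
  not modeled, and the scoring statistic is declared, not inferred from
  any external tool.
* SAM here is the two-class unpaired variant only; published gene lists
  from other implementations are reproducible only up to implementation
  variance (s0 grid, permutation count, Δ-cut convention).
* The survival module implements two-group log-rank without covariate
  adjustment (no Cox regression) and assumes months as the time unit.
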