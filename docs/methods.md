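# Methods

`thermotol` re-implements, as a tested and reusable pipeline, a comparative
transcriptomic analysis contrasting high- (H) and low- (L) thermal-tolerance
rainbow trout against untreated controls (C) in two strains. The stages are:
within-strain differential expression with a filtered FDR, cross-strain
shared-gene accounting, consolidation of duplicated trout genes onto
mammalian orthologues, GO-slim overrepresentation by a backward-elimination
heterogeneity G-test, filtering rules for externally produced pathway and
upstream-regulator tables, and a per-function Functional Effects Group
(FE_g) score. A seeded synthetic-data generator with planted truth makes
every stage testable without external sequencing data.

## Synthetic data model

The generator emulates the study design: 2 strains x 3 groups (C, L, H) x 6
replicates. Gene counts are negative binomial with mean
`mu_gs = N_s * p_g * 2^(effect)` and variance `mu + phi * mu^2`; `phi = 0`
degenerates to Poisson. Relative abundances `p_g` are log-normal
(sigma = 1.2), gene lengths are log-uniform on [300, 10000] bp (needed only
for TPM/RPKM), and library sizes are log-normal with configurable mean and
CV. Defaults: 5000 genes, `phi = 0.1`, mean library size 2e6, CV 0.2 —
conventional bulk RNA-seq values at desk scale; the source experiment's
empirical dispersions and library sizes are not published, so these are
generic rather than fitted, and library sizes are scaled down from
sequencing-run depth to keep simulations fast while leaving per-gene counts
well above the expression filter.

Differential expression is planted per comparison: a fraction `frac_de` of
genes receive H-vs-C and L-vs-C log2 fold changes drawn as
`|N(lfc_mean, lfc_sd)|` with a random sign (50/50 up/down, floor 0.25);
half of the planted identities (configurable `shared_frac`) are common to
both strains with identical effects, to exercise the intersection logic.
H-vs-L truth is derived as the difference of the H and L effects. DE gene
blocks for different comparisons and strains are disjoint, which keeps the
planted truth unambiguous.

The orthologue map partitions genes into groups of 1 (singletons) or 2–3
copies (duplicated, probability `dup_fraction`), mimicking the salmonid
duplicate-gene complement. The duplicate structure is planned jointly with
the effect plan: a `discord_rate` fraction of duplicated orthologues is
constructed so that the copy with the largest |log2FC| is positive in one
strain and negative in the other, with both copies differentially expressed
in both strains — exactly the configuration the consolidation stage flags as
a cross-strain mismatch. Because concordant duplicates are built with
identical per-strain effects, the planted discordant set is recoverable
*exactly* from true fold changes, which the tests exploit. Duplicated
orthologues not chosen as discordant receive, with probability `frac_de`, a
common-sign shared effect on every copy (paralogues are often co-regulated),
so consolidation also sees realistic concordant duplicates. A null
experiment (`frac_de = 0`) plants no effects at all, including no
discordance.

GO-slim annotations draw Poisson(`terms_per_gene_mean`) distinct terms per
namespace (BP/CC/MF) per gene from a weighted universe of `n_terms` terms;
`enriched_terms` entries multiply one term's weight for genes whose planted
enhanced group matches, shifting that term's proportion from `1/n` to
`m/(n - 1 + m)` among target genes. Function associations link orthologues
with a known enhanced group to functions, drawing increase/decrease/affect
labels from `effect_mix_by_group`. Synthetic pathway/regulator tables stand
in for network-analysis exports so the pipeline can run end to end; their
z-scores are centred on the planted direction so that matches and mismatches
both occur.

What the generator does **not** emulate: batch effects beyond strain,
GC/length biases, isoform structure, correlated gene modules, read-level
noise, or the knowledge-base network inference behind pathway/regulator
z-scores. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated count model, not robustness to those real-data
phenomena.

## Differential expression

The original analysis used a proprietary commercial engine; here the
two-group test is a per-gene negative-binomial Wald test, chosen to be
standard and dependency-light:

* counts are normalized by library-size factors `f_s = N_s / mean(N)`;
* per-gene dispersion by method of moments from within-group variances
  (`Var(c/f) ≈ m/f + phi m^2`), averaged over the two groups, floored at
  1e-8 and shrunk 50/50 toward the global mean dispersion — the shrinkage
  stabilizes the n = 6 estimates enough for calibrated inference;
* log2FC from group means of normalized counts with a 0.5 pseudo-count;
* the Wald statistic on the difference of log means is referred to a t
  distribution rather than a normal, with degrees of freedom
  moment-matched to the shrunk dispersion estimator: shrinking by weight w
  toward the global mean scales the estimator's variance by `(1 - w)^2`,
  so the effective df are `(n_a + n_b - 2) / (1 - w)^2` — 40 at the default
  `w = 0.5` with 6 + 6 replicates. A plain normal reference is
  anti-conservative at this sample size and the raw `n_a + n_b - 2` df are
  conservative; the moment-matched reference keeps null p-values uniform.

Genes with mean normalized count below `filter_mean` (default 1.0) across
all samples are excluded *before* Benjamini–Hochberg correction — the
"filter on average gene expression" device — and carry a NaN q-value, never
significance. The filter is independent of the per-gene p-values, so it
changes power, not ranking. Significance defaults to q <= 0.01.

Null synthetic data give approximately uniform p-values
(Kolmogorov–Smirnov) and realized false-positive proportions near nominal;
planted 4-fold changes at `phi = 0.1` are recovered with a median estimated
log2FC of ~1.8–1.9 against a truth of 2.0 — the small attenuation is the
pseudo-count acting on moderately expressed genes and is the accepted cost
of a variance-stabilized estimate.

PCA is correlation-matrix PCA with samples as observations (genes centred
and scaled to unit variance); zero-variance genes are dropped with a warning
since scaling would divide by zero. By default the pipeline runs PCA on the
union of significant genes, in TPM units, and retains the smallest number of
components whose cumulative explained variance reaches the configurable
target (default 0.843).

Shared-DEG intersection records per-strain directions, flags
direction-discordant shared genes but retains them, ranks shared genes by
cross-strain average log2FC (ties broken by gene ID for determinism), and
emits Venn counts plus per-group upregulated proportions.

## Duplicate consolidation

"Highest gene expression level (either positive or negative)" is
implemented as the copy with maximum |log2FC| per strain (ties: larger raw
log2FC, then lexicographic gene ID). A duplicated orthologue whose selected
copies disagree in sign between strains is a mismatch — flagged, never
removed. Percentage rates round half-up to one decimal to match printed
style. Three denominators are reported because published accounts use
different ones: unique duplicated IDs, all mapped DEG records entering
consolidation, and unique mapped orthologue IDs. Mismatch comparison uses
the *selected* copies (the post-selection convention); comparing any copy
across strains would be an alternative reading, not implemented.

## GO-slim heterogeneity G-test with backward elimination

Counts per term per group (a gene with k terms contributes k counts) are
tested with the log-likelihood-ratio G-statistic, `G = 2 sum O ln(O/E)`,
df = n_terms − 1, chi-square reference; zero cells contribute 0. G is
additive over hierarchical row partitions: for any term,
`G_full = G_2x2(term vs pooled rest) + G_rest` exactly, which the suite
verifies to 1e-9. Backward elimination exploits this: while the overall test
is significant at alpha (default 0.05 — the stopping level is not published,
so it is a configurable choice) the term with the largest 2x2 partition G is
removed and recorded with its enrichment sign (positive percent difference =
overrepresented in the focal group); removing that term subtracts the
maximum possible amount from the residual G, so the residual decreases
monotonically. Ties break by |percent difference|, then term ID. If exactly
two significant terms remain, removing either leaves an untestable single
row; the more extreme term is recorded and the residual marked untestable.
No Williams correction by default (an optional flag), because the exact
partition additivity that justifies the greedy step holds only for the
uncorrected statistic. Namespaces are tested independently. Note that the
overall test gates elimination: an enrichment concentrated in one term can
be diluted below alpha by many homogeneous terms, which is inherent to the
procedure, not a defect.

## Pathways, regulators, FE_g

Directional pathways (z != 0) with −log10(p) < 1.3 (i.e. p > 0.05) are
filtered out; neutral pathways (z missing or 0) are retained only when
−log10(p) > 1.3. Upstream regulators are classified only if their orthologue
has a significant consolidated H-vs-L record; |z| >= 2.0 marks a major
regulator, and a match requires the predicted activation sign to agree with
the observed expression direction. Top-k lists (default 10) are produced
separately by |z| and by |log2FC| among matching regulators per group;
|log2FC| is used for the expression rank since each group's matches already
share a direction.

The FE_g score is reconstructed from its verbal description (the original
is in a deposited script): for each function and group g, over genes
enhanced in g,

    FE_g = (n_increase − n_decrease) / (n_increase + n_decrease + n_affect)

bounded in [−1, 1], antisymmetric under swapping increase/decrease labels.
The two-group comparison is a G-test on the 2 x 3 groups-by-categories table
(consistent with the G-tests used elsewhere in the pipeline), dropping
categories empty in both groups, with an exact conditional enumeration test
when any expected cell falls below 1 (and total count <= 500). Direction
calls: increased if FE_g > 0 and p <= alpha, decreased if FE_g < 0 and
p <= alpha, else indeterminate. Functions with no covered genes are skipped;
a function populated in one group only gets a score but no test. The
published z > ±1.6 functional-effects threshold applies to upstream network
scores consumed as input and is exposed as a filter, not recomputed.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeded per
  artifact from one user seed; identical parameters give bit-identical
  artifacts.
* BH correction uses `scipy.stats.false_discovery_control`; filtered-out
  genes carry NaN q-values as an explicit "undefined" sentinel.
* All ranking ties anywhere in the pipeline break lexicographically so that
  outputs are order-independent and diffable.
* `report.json` contains only derived summaries (no paths, no timestamps),
  making a rerun byte-identical; timings are logged to stderr only.
* Problem sizes in the test suite and acceptance script (hundreds to a few
  thousand genes, 200–2000 replicate tables) are chosen so the whole suite
  runs in well under a minute on one CPU while keeping Monte-Carlo standard
  errors small relative to the asserted bands.

## Known limitations

* The DE engine is a deliberately simple NB Wald test; it does not attempt
  to replicate any specific commercial or Bioconductor implementation, and
  its fold-change estimates are mildly attenuated by the pseudo-count.
* The exact enumeration fallback for the FE_g test is feasible only for
  small tables; large sparse tables fall back to the asymptotic G-test.
* The backward-elimination stopping rule tests at a fixed alpha per step
  with no multiplicity adjustment across steps or namespaces, matching the
  procedure it reproduces rather than a formally optimal testing strategy.
* Venn counts are emitted as JSON; no figures are drawn.
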