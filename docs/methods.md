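# Methods

This note documents the statistical procedures implemented in `coexhub`,
the choices made where the procedures were genuinely open, and what the
synthetic fixtures do and do not establish about real data.

## Co-expression matrix

Input is a gene × sample matrix of raw counts. Genes with zero reads in
every sample are removed first. Samples are transformed with log2(x + 1) —
the pseudocount of 1 is required because counts contain zeros, and it maps
zero counts to exactly zero so "expressed" (value > 0) keeps its meaning
after transformation. Quantile normalization then forces all samples onto
one empirical distribution: the reference is the across-sample mean of
sorted value vectors, each entry is replaced by the reference value at its
within-sample rank, and tied values receive the mean of the reference values
at the tied rank positions. This is the standard mean-rank dialect; the
implementation agrees with `limma::normalizeQuantiles(ties = TRUE)` to
better than 1e-10, which the test suite freezes as an oracle. Note the
reference minimum equals the mean of per-sample minima, so zeros stay zero
only when every sample contains at least one zero; prevalence is therefore
computed on the normalized values, where it is defined.

Pairwise Pearson correlations are computed densely (`numpy.corrcoef`).
The prevalence filter sets r(i, j) to exactly 0 unless at least one of the
two genes has normalized expression > 0 in at least θ of samples (default
θ = 0.3, exposed as a parameter). The rationale is that a pair of genes each
detected in only a handful of samples can show a high correlation driven
entirely by shared zeros. Genes that are constant after normalization get
r = 0 with every partner rather than NaN, which keeps downstream mean-PCC
sums well defined. The matrix is dense; at the ~60k-gene scale of a full
compendium a chunked implementation would be needed, but that is an
engineering concern, not a contract of this package, and the package targets
matrices that fit in memory.

## Gene-set association and p-values

The association statistic between a query gene and a gene set is the mean
of the query's correlations with the set members present in the matrix,
always excluding the query itself from the set. Significance is assessed
per term: the mean PCCs of **all** background genes with that term form the
term's null distribution, summarized by its mean μ and sample SD σ
(ddof = 1). The query's z = (mPCC − μ)/σ converts through the normal CDF
into p_right = 1 − Φ(z) and p_left = Φ(z), which sum to one by construction.
Per-term nulls are the point of the design: a large gene set has an
intrinsically narrower distribution of mean PCCs than a small one, so a
shared null would conflate set size with signal. An alternative null —
resampling random same-size sets per query — was considered and rejected
because it assigns each *query* rather than each *term* its own null and is
much more expensive; with a term-level null the background computation is a
single matrix product per term. Degenerate terms with σ = 0 are flagged and
reported with both tails at 0.5 rather than raising, so one pathological
term cannot abort a library scan. No multiple-testing correction is applied
across terms; rankings, not calibrated error rates, are the product.

Perturbation prioritization treats an up/down-labeled signature library the
same way: per signature, queries are ranked by mean PCC and the top k
(default 1000) retained; inverting the retained pairs gives each query an
ordered list of perturbations predicted to up- or downregulate it. The
default sort is mean PCC descending (up and down signatures have similar
sizes, making raw means comparable); sorting by right-tailed p-value is
available for report-style tables. Signature labels must end in an
up/down suffix separated by space, hyphen or underscore; anything else is
an error rather than a silent guess.

The differential-expression filter keeps records with |log2FC| > 0.5,
FDR < 0.05 and |z| > 1.645 jointly, splits them by fold-change sign, and
truncates each side to the top n (default 200) by |log2FC|, breaking ties
by smaller FDR and then gene name — the truncation key and tie rule are
choices of this package. Overlap significance between gene sets is the
right-tailed Fisher exact test over a user-supplied universe; when
benchmarking against a correlation matrix the natural universe is the
intersection of matrix genes and assay genes. AUROC uses the Mann–Whitney
rank identity with average ranks, which handles ties exactly
(P(pos > neg) + ½P(tie)).

## Network construction

The network around a seed gene contains the seed plus its n_top (default
100) most positively correlated genes. Edges initialize as the union over
nodes of each node's three highest-weight incident correlations within the
node set; edges below min_weight = 0.3 are dropped, except the seed's five
highest-weight edges, which are selected before any dropping and are exempt
from both the weight cut and pruning — the query gene must stay visible in
its own network. Pruning repeats: recompute degrees; every hub (degree >
10) loses its lowest-weight non-protected edge; if no hub exists, the single
globally lowest-weight non-protected edge is removed; stop when the average
degree (protected edges included) falls below 3 or only protected edges
remain. Hubs are re-identified each round — the alternative of freezing the
initial hub set can leave newly dense nodes unpruned. Every weight tie
breaks lexicographically on the sorted gene pair, which together with the
fixed iteration order makes the output byte-reproducible. Each round
removes at least one edge, so termination is guaranteed.

## Localization scoring

The gene universe is the intersection of correlation-matrix genes and
RCI-table genes, plus the queries. For each query, all other universe genes
are ranked by their correlation with the query, ascending, ties sharing the
mean position; ranks are scaled to [0, 1] so the strongest correlate scores
1. The raw localization sum multiplies each scaled rank by the gene's
measured CN RCI in a cell line — where a measurement exists — and adds them
up. Strongly correlated cytoplasmic genes (positive RCI) push the sum up,
correlated nuclear genes push it down; weakly and negatively correlated
genes still contribute, but with near-zero weight. Raw sums are min–max
normalized to [0, 1] **per cell line** across the scored queries and
shifted by −0.5, so scores read like RCIs: +0.5 maximally cytoplasmic,
−0.5 maximally nuclear. Normalization is per cell line because RCI gene
coverage (and hence the raw-sum scale) differs between cell lines; a global
min–max would let one wide cell line compress all others. A query's own
measured RCI is excluded from its sum: with self-correlation 1 the query
would otherwise inject its own label at maximal weight, corrupting the ROC
evaluation. Evaluation labels queries with measured RCI > +1 cytoplasmic
and < −1 nuclear, skips cell lines missing either class, and reports
pair-counting AUROC; reporting keeps the top five cell lines by AUROC.
With a single query min–max is degenerate and the score is fixed at 0 with
a warning.

## cis/trans assignment

A top correlate is cis when it shares the query's chromosome, trans
otherwise — chromosome identity only, no distance band, strand ignored.
The candidate pool is restricted to the requested partner class (all,
coding, lncRNA) **before** truncation to the top k (default 100) by signed
correlation, and partners without chromosome annotation are excluded from
numerator and denominator alike. Cohort summaries report mean ± sample SD
of the per-gene percentages; cis and trans always sum to exactly 100 per
gene and per aggregate.

## Sample labeling and expression profiles

Vocabularies and descriptions are normalized identically: lower-cased,
non-alphanumeric characters collapsed to spaces. Matching precedence is
cell type (labeled with its mapped tissue), then tissue name, then cell
line. Vocabulary entries shorter than five characters are word-boundary
anchored to avoid firing inside longer tokens; cell-line names of three or
fewer characters are searched as "<name> cell". A sample matching two
different labels at the same tier is left unlabeled and flagged ambiguous
for manual resolution — guessing would silently bias group statistics.
Groups below the minimum sample count (default 20; lowerable, e.g. to 10
for small cell-line cohorts) are dropped before any statistic is computed;
retained groups get per-gene five-number summaries plus the sample count.

## Synthetic data

The generator emulates the three external corpora the engine consumes.
Counts follow a latent-factor model: module genes share a per-sample
standard-normal factor with loading √ρ (default ρ = 0.9), giving expected
within-module correlation ρ on the latent log2 scale; gene baselines are
uniform on [2, 9] log2 units with latent SD 1.0, and counts are 2^latent
rounded to integers. Defaults are 500 genes × 200 samples with five
20-gene modules — large enough for stable correlation estimates, small
enough to run in seconds. Each module occupies one chromosome (so planted
partners are cis-enriched) and contains at least one lncRNA-flagged gene to
act as a query. Gene-set libraries contain each module's exact gene set
plus background terms rejection-sampled to contain no complete module. The
RCI table designates two modules — one cytoplasmic (+2), one nuclear (−2),
SD 0.2, 10% missingness over five cell lines — with all other genes near 0,
so the designated modules are the only localization signal; the
localization fixture uses two 100-gene modules with every gene
lncRNA-flagged, yielding 200 labeled queries. All randomness flows through
one seeded generator; a fixed seed reproduces every artifact bit-identically.

What passing on these fixtures shows: the pipeline's algebra and plumbing
are correct, planted signal of realistic strength is recovered, and results
are deterministic. What it does not show: robustness to the dispersion,
library-size variation, batch structure and context-specific co-expression
of real compendia — the latent-factor model has none of these — nor
anything about the biological validity of guilt-by-association itself.

## Numerical and scale choices

Correlations are clipped to [−1, 1] after `corrcoef` to absorb rounding.
Problem sizes throughout the tests and the reproduction script (300–500
genes, 120–200 samples, 20 corpora for the recovery rate) were chosen as the
smallest sizes at which the planted-signal statistics are stable; all
complete in seconds on one CPU. File formats are plain text (TSV, GMT,
JSON) except the optional HDF5 container for expression and correlation
matrices. GTF parsing goes through gffutils with an in-memory database;
Ensembl-style version suffixes are stripped from gene ids, and symbols fall
back to the stable id when no gene_name is annotated, with an optional
user-supplied alias table standing in for manual symbol curation, which is
not reproducible programmatically.

## Known limitations

Dense correlation matrices bound the practical gene count (~10⁴ on a
laptop). The text-search labeler is deliberately simple — substring
matching cannot resolve negations ("not liver") or abbreviations outside
its vocabulary. The localization score inherits every bias of the
underlying global correlation matrix, and per-term normal p-values are a
large-sample approximation: the background mean-PCC distributions are
roughly symmetric but not exactly normal, so tail p-values should be read
as rankings rather than calibrated probabilities.
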