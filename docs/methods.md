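# Methods

## The classification model

Given a query sequence *Q* (an OTU representative or single read) and a set
of candidate database hits, each hit's annotated taxon *T_i* — a leaf of the
reference taxonomy, typically a species or subspecies — is treated as a
hypothesis about the origin of *Q*. The likelihood of the hypothesis is the
alignment-based similarity of *Q* to the hit, normalised to [0, 1]:

    Pr(Q | T_i) = S(Q, T_i) / S(T_i, T_i)

where *S* is the global pairwise alignment score read off the multiple
alignment of the query with all retained hits, under the BLASTN-default DNA
scheme (match +1, mismatch −2, gap −2.5, linear gap costs). The denominator
— the hit aligned to itself — is the maximum score any sequence can achieve
against that hit, so a perfect match gives likelihood 1 and an alignment
with no shared residues gives 0. Ratios driven negative by mismatch- or
gap-heavy alignments are clamped to 0: the quantity is a degree of support,
and negative support carries no more information than none.

Bayes' rule converts likelihoods into a posterior over the candidate leaves:

    Pr(T_i | Q) = Pr(Q | T_i) Pr(T_i) / Σ_j Pr(Q | T_j) Pr(T_j)

with a uniform prior by default (it cancels; a non-uniform prior can be
supplied to `posterior_leaves` and `bootstrap_confidence` when some taxa are
a-priori more plausible). The posterior of an internal taxonomy node is the
sum of its descendant leaves' posteriors, so genus, family, … phylum
posteriors come from one summation primitive (`TaxonomyTree.sum_to_rank`).
Dissimilar hits are thereby penalised quantitatively rather than excluded
by a hard similarity cutoff, which is what makes the method insensitive to
how many marginal hits the candidate filter admits.

Likelihood adjustment for explicit sequencing-error models is left as a
hook: both posterior entry points accept externally computed likelihoods,
so an error-model-aware likelihood can be substituted without touching the
aggregation machinery.

## Candidate selection and alignment

Hits come either from a precomputed BLAST-style tabular file (12 standard
columns + `qlen`) or, for fixture- and benchmark-scale databases, from an
internal exhaustive search that globally aligns the query to every
reference (edlib) and synthesises equivalent hit rows, with the alignment
score under the scoring scheme standing in for the bit score. Retention
requires ≥95% identity and ≥95% query coverage (defaults), plus the
topPercent criterion: bit score within 10% (default) of the best hit.
One hit per subject is kept (highest bit score) so a redundant reference
cannot contribute twice; hits for the same leaf taxon are likewise reduced
to the single best-likelihood one before the posterior.

Only the matched subject region, plus 10 nt of flanking context on each
side (clamped at the reference ends, reverse-complemented for minus-strand
hits), enters the multiple alignment — queries are usually partial-length
marker sequences, and the padding absorbs small terminal overhangs. The
default aligner is an internal query-anchored star MSA: each subject is
aligned to the query with exact Needleman–Wunsch under the scoring scheme,
and the pairwise alignments are merged on query coordinates. Two properties
motivate this choice: the query row is reproduced exactly (no internal
query gaps), and each subject's score against the query over all columns of
the merged block equals its optimal pairwise score, because merge filler
columns are double-gap columns for every other subject and double-gap
columns score 0. An adapter for an external aligner binary (MAFFT or MUSCLE
command conventions) is available behind `backend="external"` for users who
prefer a classical progressive MSA; the downstream contract is on the
aligned block, not its producer.

Numerical details: terminal gap columns are scored as ordinary gaps (the
padding exists to make them rare; leaving them free would reward
truncation); `N` scores as a mismatch against everything including `N`
(ambiguity must never raise similarity); Needleman–Wunsch traceback ties
prefer diagonal, then gap-in-subject, then gap-in-query, making alignments
deterministic.

## Bootstrap confidence

Reliability of an assignment is the stability of the winning taxon under
column resampling. Each of 100 replicates (default) draws alignment columns
uniformly with replacement — as many draws as the query has bases —
recomputes every leaf likelihood and posterior on the drawn multiset, and
tallies the top-posterior leaf. A leaf's confidence is its winning fraction;
internal-node confidence is the sum over descendant leaves, so confidence
grows toward the root. Exact ties are split 1/k among the k tied leaves:
this keeps per-rank confidences summing to exactly 1 and makes the whole
procedure deterministic for a fixed seed. Replicates with all-zero
likelihoods degenerate to an all-way tie and are split uniformly. Each
query's generator is derived from `(seed, query index)`, so batch
composition and ordering cannot change any query's result.

At reporting time each canonical rank (superkingdom … species) is decided
independently: the top-confidence taxon at that rank is reported iff its
confidence reaches the threshold (default 0.8; 0.5 is the usual choice for
short reads), otherwise the rank is "unclassified". When resampling makes
the top-confidence and top-posterior taxon differ, confidence — the stated
reliability criterion — wins; posterior and then taxid break exact
confidence ties deterministically.

## The synthetic benchmark

`bayeslca.simulate` generates the study conditions end to end. A random
ancestral sequence is evolved down a configurable taxonomy (default: 2
phyla × 5 genera × 5 species = 50 species, 1000 nt); at each rank split
every child receives Binomial(L, d/2) substitutions, where *d* is the
configured per-rank divergence, so two siblings created at a split differ
by ≈ *d* (defaults: 5% between congeneric species, 15% between confamilial
genera, chosen so that within-genus species are distinctly more similar
than between-genus ones, as in real 16S data). Query reads are drawn from
random leaf species and receive Poisson(rate × length) substitutions
(default rate 1%, the upper range reported for Illumina MiSeq) at uniform
positions, each to a uniformly chosen different base. The error model is
substitution-only by design (`indel_rate` exists but defaults to 0), and
substitutions are Jukes–Cantor-uniform; a `subregion` window emulates
variable-region extraction without real primer coordinates.

Evaluation tallies, per rank and per taxon label, TP (truth and prediction
agree on the label), FN (truth carries it, prediction does not — including
"unclassified"), FP (prediction carries it, truth does not), TN (the rest),
summed over labels; precision, recall and F = 2PR/(P+R) follow, with
degenerate denominators mapping to 0.

What the simulator does *not* emulate: chimeras, indel sequencing errors,
rate heterogeneity along the gene, unbalanced taxon sampling, incomplete or
inconsistent reference annotation, and the conserved/variable block
structure of real 16S genes. Passing the end-to-end tests therefore shows
the machinery is correct and well-calibrated under clean phylogenetic
structure, not that real-database accuracy matches any particular figure.

## Test and benchmark scales

The end-to-end recovery check uses the default benchmark (50 species,
1000-nt references, 200 reads at 1% error, threshold 0.5) and requires
species-level F ≥ 0.9 and genus-level F ≥ 0.95 — conservative bounds, since
the synthetic database is better separated than real 16S collections. The
topPercent robustness check uses a closer benchmark (species split 3%,
identity/coverage filters at 90%) precisely so that congeneric hits are
admissible and the topPercent filter alone decides their inclusion; there
the Bayesian classifier's species-level F moves by < 0.05 between
topPercent 5% and 20%, while an equal-weight LCA baseline collapses to
genus-level assignments. Read-simulator calibration is checked on 10⁵
reads (mean mutations within 3 standard errors of the nominal rate).

## Known limitations

* The internal exhaustive search scales linearly in database size and is
  meant for small custom databases and simulations; large databases should
  supply a precomputed tabular hit file from a real search tool.
* The internal search considers the plus strand only; minus-strand handling
  is exercised through the hit-table path (`sstart > send`).
* Reference taxa whose lineage lacks a canonical rank are reported
  "unclassified" at that rank rather than interpolated.
* Queries are processed sequentially; per-query seeding guarantees that a
  future parallel executor cannot change results.
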