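# Methods

This note documents the models, conventions and design choices behind
`venomlgt`, and what the synthetic-data experiments do and do not show.

## Expression classification

The N99 threshold is read assembly-style: sort a sample's TPM vector in
descending order and take the TPM of the first gene at which the running
sum reaches 99% of the total — the same construction family as N50. A
plain 99th-percentile reading is available via `n99_mode: percentile`;
the two differ greatly on heavy-tailed expression data, and the
cumulative reading is the package default because it scales with library
composition rather than gene count. "Expressed" is strict inequality
above the threshold.

High expression uses a one-sided upper-tail Z-test on log2(TPM+1)
computed **among the sample's expressed genes only**: raw TPM is far too
heavy-tailed for a normal reference, and restricting to expressed genes
keeps the null population comparable across samples. Defaults: α = 0.01
for developmental stages, α = 0.05 for the venom gland (the VG sample is
sequenced separately and its calls feed a discovery filter rather than a
claim of significance). Zero variance among expressed genes produces no
calls with a warning rather than an error.

The specialization index is the venom-gland share of a gene's row-total
TPM — the simplest statistic on [0, 1] whose extremes mean "never
expressed in the VG" and "expressed only there". The tissue-specificity
index τ is available (`spec_index_mode: tau`) but is not the default
because τ conflates specialization toward *any* sample with
specialization toward the target.

Enrichment of gene sets among highly expressed genes uses the exact
hypergeometric tail evaluated in log space (gammaln sums +
log-sum-exp), with Bonferroni and Benjamini–Hochberg adjustments
reported side by side across samples.

## Rate estimation

Pairwise dN/dS is Nei–Gojobori (1986) counting on gap-free codon pair
alignments. Per-position synonymous site fractions exclude stop-creating
changes and renormalize over the remaining changes, so S + N equals the
alignment length exactly; difference counts average over all substitution
orderings that avoid stop codons (when every ordering is stop-blocked —
possible only for some 2–3-change codon pairs — each change is classified
directly against the current codon). Distances are Jukes–Cantor
corrected; p ≥ 3/4 yields an infinite-distance sentinel and the
`saturated` flag. ω conventions: Nd = 0 with dS > 0 gives ω = 0; dS = 0
gives ω undefined (`ds_zero`, excluded from pathway medians rather than
treated as ∞). Counting methods are deterministic and oracle-checkable;
they differ systematically from codon-model maximum likelihood (no
transition/transversion or codon-frequency weighting), which matters at
high divergence but not for the rank-and-threshold uses here.

The saturation filter removes pairs with dS strictly above 2 (a pair at
exactly 2 is retained). The pathway scan takes the median ω of each
pathway's genes (≥ 3 genes with defined ω required), z-scores each median
against the mean/SD of all pathway medians, and flags elevated pathways
at one-sided p < 0.01. The scan is over medians, not pooled gene values:
pathway gene counts vary by an order of magnitude and a pooled test would
be dominated by the large pathways. "Conserved" means median ω ≤ 0.02
(`conserved_eps`; "approximately zero" needs a number and 0.02 is well
below any plausible background).

K2P distances require nucleotide input — amino-acid letters that are not
IUPAC nucleotide codes are rejected — and exclude ambiguous or gapped
sites pairwise; out-of-domain logarithms return an infinite sentinel.

## The substitution simulator

`evolve_pair` is a proposal/acceptance scheme, not a matrix exponential:
single-nucleotide changes are proposed at uniform positions (transition
odds κ against each of the two transversions), stop-creating proposals
are rejected outright (matching the NG86 stop conventions above),
nonsynonymous proposals are accepted with relative probability ω, and
each branch runs until its expected synonymous divergence reaches half
the pairwise target. Realized substitution counts are recorded in the
truth record.

κ defaults to 1.0. The NG86 estimator weights the three possible changes
at a site equally; simulating with κ > 1 shifts realized substitutions
toward transitions (which are more often synonymous) and imposes a known
systematic ω bias of order 15–25% that reflects model mismatch, not an
estimator defect. With κ = 1 the proposal classes match the counting
convention, so estimator-recovery tests measure the estimator. κ remains
exposed for experiments that want the mismatch.

## Synthetic dataset: what it emulates

The default `SimConfig` builds a two-species catalog of 350 ortholog
pairs (278 background pairs at ω 0.15, 15 at ω 0.5 forming one elevated
pathway, 45 at ω 0.01 forming three conserved pathways, 12 saturated
pairs at target dS 3) plus 150 species-specific genes per species —
500 genes per species. Expression is log-normal TPM (median 5, σ = 1.5
on the natural log) over eight developmental stages plus one VG sample,
renormalized to 10^6 per column after planting; planted venom-specialized
genes get a fixed VG override and 100-fold suppressed stages; five genes
are expressed exclusively in P3 and AF. Ten genes are planted VPs (4–7
unique peptides of 8–25 aa drawn from their own protein and verified
absent from every other protein); non-VPs get 0–3 peptides. The genome is
2 Mb at GC 0.27 with ~10% of its length in 40 kb islands at GC 0.16, and
12 planted stop-free copies of the Lar-like CDS at nucleotide identities
0.70–0.95, one third on the reverse strand. Gene trees (50 LGT, 50
vertical) are rooted on bacterial outgroups. One gene (`spA0000`)
satisfies every Lar-like filter; its paralog pair evolves at ω 0.9
against a background where < 5% of ortholog pairs exceed the 95th
percentile bar. A nine-member species-B family carries a focal-exclusive
domain; one member peaks in the VG against the family's larval mode.

The transitive-locus construction deserves a note: the *intermediate*
planted locus is a seed homolog concatenated with a novel extension ORF,
and the *transitive* locus is a diverged copy of the extension alone. At
generation time the generator verifies (deterministically, by aligning)
that the transitive locus scores below the search threshold against the
seed and every other planted locus but well above it against its parent —
so discovery at iteration ≥ 2 is guaranteed by construction, not by luck.

What the generator does **not** emulate: indels (all pairs are gap-free
and equal length, so no aligner is needed upstream of the rate
estimator), rate heterogeneity across sites, read-level noise in TPM,
missed or decoy peptides, incomplete ortholog tables, or gene trees with
estimation error. Passing recovery tests therefore demonstrates that the
chain's logic is correct under its stated assumptions, not that it is
robust to upstream artifacts of real data.

## Homology search

Queries are aligned with Smith–Waterman (Biopython's C pairwise aligner)
under BLOSUM62 with affine gaps costing `gap_open + k·gap_extend` for a
gap of length k (defaults 11/1, the BLAST pairing). Frames are split at
stop codons, so alignments can never cross a stop; within each inter-stop
segment, hits are taken best-first with the remainder rescanned
(equivalent to masking). A raw score threshold (default 60) stands in for
an E-value cutoff: Karlin–Altschul calibration is deliberately out of
scope, and a fixed raw threshold keeps the search deterministic. At this
threshold a 2 Mb random genome yields a handful of spurious short hits
per query; almost all are removed by the 50 aa minimum locus length, and
the few that survive only add harmless extra loci.

Merged loci are extended to the enclosing open reading frame of their
best hit — a desk-scale stand-in for gene-structure assembly around a
seed alignment (no splice modeling). Locus peptides join the query set;
each query is scanned exactly once, which reaches the same fixpoint as
rescanning everything each round at a fraction of the cost. Iteration
stops when a round adds no locus or at `max_iter` (10), the latter
flagged unconverged. Coordinates are 0-based half-open on the forward
axis with an explicit strand.

The motif filter builds a position-frequency matrix (pseudocount 0.5)
from a user-supplied gap-light aligned block and scores loci by their
best sliding-window log-odds sum against a uniform background; the
default retention threshold is the weakest block member's own score, so
every block member passes by construction.

## LGT classification

The package turns a topological argument into an explicit rule: verdict
`lgt` requires that focal + metazoan tips are **not** monophyletic and
that the sister group of the smallest clade containing all focal tips is
at least 80% microbial (`min_microbial_sister`); monophyly alone gives
`vertical`; everything else is `ambiguous`. Trees are consumed rooted as
given (rooting on bacterial outgroups happens upstream and changes
monophyly answers, so no rerooting is attempted); branch lengths and
support values are ignored. `count_metazoan_clades` counts maximal
clades of only focal/metazoan tips that contain at least one metazoan
tip — a lower bound on independent acquisition events.

## Genome signatures

GC is computed as (G+C)/(A+C+G+T) over non-overlapping 10 kb windows
(window size config-exposed; 10 kb is conventional genome-scan
granularity and comfortably resolves 40 kb islands); windows over 50% N
are masked. Modes come from a Gaussian KDE with absolute bandwidth 0.02
evaluated on a 0.001 grid, local maxima at least 0.05 apart; each
window is assigned to its nearest mode and modes are reported
(location, mass), largest mass first. KDE peak-finding was chosen over
mixture fitting to avoid committing to component distributions.

Domain expansion is focal count / max other-species count; a domain
present only in the focal species is the tagged category `"exclusive"`
(and `"exclusive-elsewhere"` for the converse), never a floating-point
infinity, so TSV output stays lossless and sortable.

## Candidate integration

Filters form a cascade with per-filter evidence retained for every
VG-expressed gene, because the underlying argument is evidential: a
reviewer should be able to see which filter excluded a gene. Thresholds:
specialization ≥ 0.9 and paralog-pair ω percentile ≥ 95. At the synthetic
scale of 350 ortholog pairs a 99.9% percentile bar is not even
representable (the granularity is 1/350 ≈ 0.3%), so 95 is the default and
stricter values are a config change away. Ties in VG TPM break
lexicographically by gene id. Filters with missing inputs (no paralog
pair, no tree) are skipped for that gene with a logged warning —
disabling a filter can therefore only add candidates, never remove one.
Warm-like flags default to `family_min: 2` so that small test families
exercise the rule; a nine-copy family is the planted (and real-world
inspired) configuration.

## Problem sizes and determinism

The shipped study conditions (2 Mb genome, 500 genes per species, 100
gene trees, 100 estimator-recovery pairs per setting, 20 pathway-scan
replicates) were chosen so a complete discovery run finishes in a few
minutes on one CPU while leaving every planted structure recoverable at
its stated tolerance. One integer seed drives a hierarchical
per-component RNG stream (component name hashed into the stream), so
regenerating a dataset is byte-identical and adding a new component
never perturbs existing ones. Reports carry a config hash and no
timestamps; rerunning discovery on the same inputs reproduces the report
exactly.

## Known limitations

* NG86 counting underestimates ω at high divergence relative to ML codon
  models; the dS > 2 filter removes the worst cases but pairs near the
  boundary keep noisy estimates (a truly saturated 300-codon pair has a
  non-trivial chance of an estimated dS just below 2).
* The raw-score search threshold is not a significance statement; on
  larger genomes the spurious-locus rate grows linearly with target size.
* The LGT rule is topology-only and inherits any upstream rooting or
  tree-estimation error; it does not use branch support.
* Peptide matching is exact substring matching; I/L equivalence is off by
  default and no protein-inference parsimony is applied (shared peptides
  count for every protein, flagged).
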