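# Methods

This note documents the models, conventions, and numerical choices behind
tcrkit, in the spirit of a statistics package's methods appendix. It
describes what the code computes; every number quoted in the README is
printed by the code itself.

## Repertoire model and quality control

A clonotype is a (CDR3 amino-acid sequence, V gene, J gene, count) record;
a repertoire is an ordered list of clonotypes with frequencies derived
from counts (missing or zero counts default to 1 at ingestion so that
frequency-based statistics remain defined for sequence-only inputs).

QC applies five rules in a fixed order: (1) allele suffixes (`*NN`) are
stripped from gene symbols; (2) records lacking a V or J call are dropped
(skippable for CDR3-list inputs, which cannot carry gene calls); (3–4)
CDR3s must follow the IMGT junction convention — start with C, end with F
or W, contain only the 20 standard residues and no stop/frame marker
(`*`/`_`; in-frame status is operationalized at the amino-acid level since
inputs are protein sequences); (5) lengths outside 8–24 residues are
removed. Finally, identical CDR3s are merged into one clonotype that
**sums** the counts and keeps the gene pair of the most abundant
contributing record (ties: lexicographically smallest symbol). Summing
preserves clone-abundance mass, which the diversity statistics depend on;
the allele collapse must precede the merge or allele variants of one gene
would compete as distinct gene calls. The whole procedure is idempotent,
and the report satisfies `output = input − dropped − merged` by
construction. A record failing both a sequence rule and the length rule is
booked under the sequence-rule bucket; the length bucket counts records
whose only defect is length.

## Diversity and clonality

Renyi entropies are computed in log-space (`logsumexp` of
`alpha * log p`) so orders up to a few hundred do not underflow; alpha = 0,
1, and infinity are exact special cases (log richness, Shannon,
min-entropy). The default alpha grid is
{0, 0.25, 0.5, 1, 2, 4, 8, 16, 32, inf}, spanning the conventional
diversity-curve display; the default base is 2 (bits), exposed as a
parameter. Frequencies are clone-mass (count-weighted) by default; an
unweighted per-unique-sequence alternative is exposed.

Clonality is 1 − Shannon/log(N). A single-clonotype repertoire is defined
to have clonality 1: the evenness ratio is 0/0 there, and one clone is
maximal dominance. Clonality is 0 exactly when frequencies are even.

Sequence logos are position weight matrices with pseudocount 0 over the
20-letter alphabet. The top-100 logo never force-aligns variable-length
sequences: the top sequences are grouped by length and the modal-length
group's PWM is reported (ties to the shorter length), with all length
groups available.

## Similarity network

Clustering is length-stratified single-linkage under Hamming distance with
`max_intra_distance = 2`, consistent with the downstream "link if distance
< 3" rule, so network edges within clusters are exactly the brute-force
all-pairs thresholding (this equivalence is tested). Length stratification
makes the multiple alignment of a cluster the identity, so no aligner is
invoked; import hooks accept externally produced cluster tables (and, via
them, externally aligned variable-length groupings).

Node weight combines betweenness centrality (shortest-path, unweighted
edges) and degree. How to combine them is a free choice; we min-max scale
each within its connected component (a constant component maps to 0.5,
which is also what an isolated node receives) and take the equal-weight
convex sum, with the two coefficients exposed.

Communities come from walktrap (random-walk agglomeration) with walk
length 4, the algorithm's conventional default; the best-modularity cut is
taken. Walktrap is deterministic, so the seeded-determinism contract holds
trivially; the seed parameter is kept for stochastic plug-ins. Edgeless
graphs short-circuit to singleton communities. Community logos are
frequency-weighted PWMs; communities are single-length by construction
because they live inside length strata.

## Motif pipeline

3-mers are extracted with a stride-1 sliding window over unique CDR3s
(optionally clone-count-weighted), giving L−2 windows per sequence; the
feature universe is capped at 20^3 = 8000. The matrix pipeline advances
through tagged stages (raw → sample_filtered → prevalence_filtered →
mwu_filtered → normalized) and stage transitions are enforced, so filters
can only shrink the matrix.

The sample filter is rank-based: `ceil(n·q)` samples from each tail of the
total-motif-count ranking are removed (ties broken by sample id), so a
non-empty tail always removes at least one sample on small cohorts when
q > 0. The prevalence filter keeps motifs present in **strictly more
than** `min_frac` (default 0.5) of a disease group's samples. The
Mann–Whitney filter keeps motifs with two-sided p ≤ 0.05 against the
background group; per-sample counts are compared by default, with a
frequency option.

The Mann–Whitney implementation uses midranks; U counts x-over-y pairs
(ties half). For small samples (n·m ≤ 400 and at most 2·10^4 group
assignments, which covers all n, m ≤ 8) the two-sided p is exact by
enumeration of rank-subset assignments — the definition is
P(|U − nm/2| ≥ |u − nm/2|) under the permutation null, which handles ties
exactly. Beyond that the tie-corrected normal approximation with
continuity correction is used; enumerating, e.g., C(40,20) ≈ 1.4·10^11
assignments for two 20-sample groups is not tractable, and the
approximation error there is far below any decision threshold in the
pipeline. An all-constant comparison returns p = 1.

Z-scoring is per motif across samples with the population SD;
zero-variance columns become zeros. The column means and SDs are stored so
held-out samples are projected onto exactly the reference scale.

## Embedding

The default backend is a diffusion-map / potential-distance procedure:
Gaussian affinities with adaptive bandwidth (distance to the 5th
neighbour), symmetrization, row-normalization to a diffusion operator P,
t = 3 diffusion steps, potentials −log(P^t + 1e−12), and classical metric
scaling of the potential distances to 2-D. Eigenvector signs are fixed by
making the largest-magnitude entry positive, so the procedure is fully
deterministic; the backend seam accepts any callable with the same
signature (e.g. an external PHATE implementation), which is where the seed
matters. Out-of-sample projection is a Nystrom-style kernel average over
the 15 nearest reference samples (bandwidth = half the median neighbour
distance); an all-zero aligned vector returns the reference centroid with
a warning.

For two-disease cohorts without healthy controls, the discriminative
pipeline uses each disease's complement as its Mann–Whitney background and
(optionally) skips the depth filter — synthetic cohorts have uniform
sequencing depth, and a 20% tail trim would discard informative samples
for nothing.

## Annotation

"One mismatch" is Levenshtein distance ≤ 1 (substitution, insertion, or
deletion), matching fuzzy-search-engine semantics; a substitutions-only
(Hamming) mode is exposed. The index keys every reference sequence by
itself and its single-deletion variants; query-time candidates are the
union over the query's own deletion keys, each verified with an exact
distance check, so results equal a brute-force scan (tested against an
independent alignment library). Only the top 3000 clonotypes by frequency
are annotated by default (frequency ties broken lexicographically):
disease-associated clones are typically expanded, and the cap keeps batch
searches predictable. Enrichment counts **unique** annotated query
sequences per label.

## Synthetic data

The simulator emulates: IMGT-conformant CDR3s (C + uniform interior +
F/W, F:W at 4:1, lengths uniform on 8–24), Zipf(2.0) clone sizes truncated
below at 1 (reproducing the heavy-tailed clonal composition real
repertoires show; a geometric alternative is available), decaying-weight
V/J usage over realistic TRBV/TRBJ symbol sets, and group-specific motif
spike-ins that overwrite a random interior window so anchors survive.
Per-sample cohort seeds are drawn from one master generator, so cohorts
are reproducible end to end.

Default cohort signatures are 16 disjoint motifs per disease at insertion
probability 0.3. A disease signal carried by a single 3-mer out of 8000 is
unrealistically sparse — convergent antigen-driven expansions share many
overlapping windows — and after per-column z-scoring a one-column signal
is invisible against thousands of unit-variance noise columns, whatever
the effect size; a multi-motif signature is both the realistic and the
statistically meaningful regime.

What the simulator does **not** model: V(D)J recombination statistics
(junctional insertion/deletion profiles, positional amino-acid biases),
inter-sequence correlation within clonal lineages, sequencing error, or
depth variation between samples. Passing tests on synthetic cohorts
therefore demonstrate the pipeline's correctness and its sensitivity to
majority-prevalent, group-specific motif signals — not performance on real
disease cohorts, where signals are weaker and confounded.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: single
repertoires of 10^2–10^4 clones, cohorts of 20–60 samples of ~10^3 clones,
references of 2·10^3 records, chosen so each check completes in seconds
while still exercising the asymptotic regime of every algorithm (the
network and fuzzy-search oracles are exact set equalities, not
approximations). All randomness flows through explicit integer seeds; any
two runs with the same configuration and seed produce byte-identical
tables.

## Known limitations

- Beta chain only; no paired-chain or alpha-chain analysis.
- Hamming-based networks cannot link CDR3s of different lengths; the
  cluster import hook is the escape hatch.
- The diffusion backend is a faithful stand-in for the embedding contract
  but is not PHATE; fine-grained trajectory geometry may differ.
- No multiple-testing correction is applied in the motif Mann–Whitney
  filter (by design — it mirrors the stated per-motif threshold); with
  thousands of motifs the surviving set contains false positives, which
  the downstream embedding tolerates.
- Generation-probability modelling and peptide–TCR binding prediction are
  out of scope.
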