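# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Coordinates and neighborhood rules

Internally all gene coordinates are 0-based, half-open, so the intergenic
gap is `start(next) − end(prev)` with no ±1 bookkeeping; GFF3 input
(1-based, inclusive) is converted once on read, and the reader requires an
explicit dialect flag so an already-converted table can never be converted
twice.  Gaps are measured between annotated gene bounds (not translated
regions).

A neighborhood cluster is a maximal run of *consecutive* same-strand genes
with every successive gap ≤ 250 bp; overlapping genes (gap ≤ 0) always
join, and an interleaved opposite-strand gene terminates a run — the
positional-run reading matches the operon concept, where an inserted
antisense gene breaks co-transcription.  Divergent merging joins an
adjacent (left all-minus, right all-plus) cluster pair whose gap lies in
[200, 1000] bp — two transcription units sharing an upstream regulatory
region.  Both bounds are inclusive (pinned by tests), merging is applied
once left-to-right, and a merged mixed-strand cluster is never re-merged:
chains of alternating strand blocks are not a single regulatory unit.
Contigs are treated as linear; a per-contig circular flag exists but
origin-spanning neighborhoods are not computed.

## Protein families

A family is a connected component of the undirected similarity graph with
an edge where the best e-value (over both hit directions, duplicates
resolved by minimum e-value then maximum bitscore) is at or below the tier
cutoff.  The three default tiers, 1e-10 / 1e-50 / 1e-100, span permissive
to stringent homology; stricter tiers provably refine looser ones, which is
tested on random hit graphs.  Cluster ids are the lexicographically
smallest member id, so runs are reproducible regardless of input order.
Single-linkage components were chosen over centroid or MCL clustering
because the downstream score only needs a partition, and components are the
only partition that is order-independent and parameter-free at a fixed
cutoff.

## Conservation score

The score of a (focal, neighbor) family pair is the phylogenetic diversity
(total branch length of the minimal spanning subtree) of the supporting
genome set on a neighbor-joining tree, zero when at most one genome
supports the adjacency.  The genome tree is built from Jaccard distances on
shared family content at the modeling tier (default 1e-10); negative NJ
branch-length estimates are clamped to zero.  This definition has the three
properties the score needs: it is tree-based, zero exactly marks a
nonconserved neighborhood, and adding any genome to the supporting set can
only increase it.  One caveat: genomes with *identical* gene content sit at
distance zero, so a pair supported only by such duplicates scores zero
despite |S| = 2; the supporting-genome count is therefore reported next to
the score in all outputs.

Phylogenetic diversity is computed by edge bipartitions (an edge counts iff
both sides of its split contain supporting genomes), verified against an
independent path-union computation on random trees.

Raw scores are discretized to {0,1,2,3}: zero stays 0, and the strictly
positive training scores are cut at their empirical tertiles
(linear-interpolation quantiles), giving three equally populated positive
bins — the codomain forces exactly three.  With fewer than 3 distinct
positive scores the binning degenerates to the median with a warning.
Cutoffs are fitted on training scores only and serialized with the model.

## Features, labels, instances

Instances are annotated *proteins*, not families: homologous proteins share
a feature row but may carry different annotations, and collapsing them
would silently merge label sets.  Feature columns are the union of scored
neighbor families over the training instances; at prediction time unseen
columns are dropped (and counted) and missing ones zero-filled, keeping the
model dimensionality fixed.  Multiple homologs' neighborhoods are unioned
before scoring (the supporting set is defined over all members), rather
than aggregated by maximum afterwards.  GO labels are used flat, without
ontology-ancestor propagation.

## Learning

The feature selector is a multi-label ReliefF variant: over each instance
and its k = 10 nearest neighbors (Manhattan distance on features scaled by
the range 3), it accumulates the label dissimilarity dL = Hamming/|L|, the
per-feature difference diff_f = |Δx|/3, and their product; the weight
`W[f] = N_dYdF/N_dY − (N_dF − N_dYdF)/(M − N_dY)` is positive when a
feature varies together with the labels.  The exact update is pinned by a
literal-loop oracle test and by a planted-feature recovery property; ties
are broken by feature id.

BR, LP and RAkEL are implemented over a scikit-learn random forest
(default 300 trees, √p features per split).  LP classes are the distinct
observed labelsets; a label's score is the summed probability of the
classes containing it.  RAkEL samples m distinct k-subsets (default k = 3,
m = min(2|L|, C(|L|,k))) without replacement and averages member-marginal
scores.  Every member uses the same base-learner seed — members differ
only by their label subset — which makes the reduction identities
RAkEL(k=|L|, m=1) ≡ LP and RAkEL(k=1, full coverage) ≡ BR hold exactly and
testable to the last bit.  Degenerate cases (single-class label column,
single observed labelset, uncovered label) fall back to constant scorers
with warnings rather than errors, because cross-validation folds routinely
lose all positives of a rare label.

The binary mode is the single-label special case; it reports a
high-confidence flag at probability ≥ 0.8 (screening semantics) while 0.5
remains the ordinary decision threshold.

## Evaluation

F1max uses the inclusive comparison `score ≥ t` on the grid
t ∈ {0.0, 0.1, …, 1.0}, so t = 0 predicts every label; precision is
averaged over the m(t) proteins with at least one prediction and recall
over all n proteins; F1(t) is defined as 0 when m(t) = 0 or both averages
vanish.  The implementation is checked against a literal set-based
transcription on random fixtures to < 1e-12.

Nested CV uses shuffled unstratified folds (seeded); the inner 3-fold grid
search maximizes the mean inner-fold F1max with ties resolved in declared
grid order, feature selection runs inside each training split only, and an
assertion verifies that inner folds never contain outer-test instances.
The default grid covers n_trees ∈ {100, 300, 500}, mtry ∈ {√p, log2 p+1},
top-N ∈ {50, 100, 200, all}.

Wilcoxon comparisons drop zero differences, use the exact null for ≤ 25
nonzero pairs (correct under tied midranks) and the continuity-corrected
normal approximation above.  The annotation-transfer baseline transfers the
labels of the single best passing hit with percent identity / 100 as the
score.

## Networks and enrichment

The neighborhood network is a per-tier star graph; neighbor node area
scales linearly from 20 to 80 units with the raw conservation score
(rank-preserving; uniform minimal size when every neighbor is
nonconserved).  Enrichment is the one-sided hypergeometric upper tail with
Benjamini–Hochberg adjustment across tested terms; the background is all
GO-annotated proteins in the loaded database rather than all genes, which
avoids inflating enrichment with genes that could never carry an
annotation.  The choice of test and background is this package's own and
is stated in the output header.

## Synthetic benchmark

The generator plants conserved operons on a random binary genome phylogeny:
each operon is a same-strand block of families (within-block gaps uniform
in [10, 200] bp) placed in every genome of a clade covering ~60% of the
genomes by default; background families are singletons with gaps in
[400, 5000] bp, occasionally laid out as a divergent −/+ pair with a gap in
[200, 1000] bp to exercise the merge rule.  With probability `noise` (0.1)
a non-focal member is relocated into the background.  Within-family hits
get e-values ≤ 1e-121 so all three tiers recover families exactly;
cross-family decoys sit at ≥ 1e-4 and never form edges.  Focal-family
proteins carry their operon's GO labels (2 per operon from the 24-term
vocabulary).

Default conditions: 30 genomes, 400 families, 12 operons of size 4, one
contig per genome.  These sizes keep a full preprocessing + 5-fold RAkEL
cross-validation around a minute on one CPU while leaving ~200 instances
and ~36 informative features.

What passing shows: the pipeline recovers a planted
neighborhood→label signal (cross-validated F1max ≥ 0.9) and does not
hallucinate one (label-permuted control ≤ 0.5), and feature selection finds
the planted columns.  What it does not show: performance on real genomes,
where families blur at fixed cutoffs, neighborhoods decay with phylogenetic
distance, annotations are incomplete and biased, and homologous instances
leak between CV folds — the synthetic instances of one family are
duplicated across genomes, which makes the in-silico task considerably
easier than the biological one.  The generator also emits no sequence
evolution; FASTA output, where needed, is placeholder.

## Determinism

Every stochastic step (simulation, subset sampling, forests, folds,
subsampling in feature selection) takes an explicit seed; model files embed
seeds, bins, registries and vocabulary; `run-all` writes a provenance
record, and two runs with equal config and seed produce byte-identical
non-log outputs (tested).
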