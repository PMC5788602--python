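# Methods

This note records the model as implemented, the parameter choices that
matter, the numerical decisions, and what the synthetic benchmark does and
does not demonstrate.

## Model and assumptions

The predictor assumes that functionally similar miRNAs tend to associate
with phenotypically similar diseases, so association evidence can propagate
through similarity networks. All matrices are oriented diseases × miRNAs.

### Similarity construction

* **Semantic model 1.** For disease D with ancestor closure T(D), a term at
  minimum hop distance k from D contributes Δ^k (the recursive definition
  `D1_D(d) = Δ·max over children of d` reduces to this for Δ ≤ 1).
  Similarity is the shared contribution mass normalized by the two semantic
  values DV1. Pairs with an empty shared ancestry score 0; the diagonal is 1
  by construction.
* **Semantic model 2.** A term in c of the n disease DAGs contributes
  −log(c/n), identically for every disease containing it. The log base is
  configurable but cancels in the ratio, so the similarity is base-invariant
  (asserted in the tests). The DAG count runs over the full disease set of
  the DAG input, including each disease's own DAG.
* **GIP kernel.** Profiles are rows/columns of A; the bandwidth is
  β′ / (mean squared profile norm) with β′ = 1 by default. An all-zero A has
  no defined bandwidth and is rejected.
* **Integration.** SD takes (SS1+SS2)/2 where *both* diseases are DAG-
  annotated *and* SS1+SS2 > 0, otherwise GD. "Has semantic similarity" is
  thus read as "nonzero semantic score", so unannotated or fully disjoint
  pairs are rescued by the interaction-profile kernel. SR analogously takes
  MS where both miRNAs are covered and MS > 0. Integrated diagonals are
  forced to 1.

Δ defaults to 0.5, the conventional decay in the DAG-semantic-similarity
literature. Name normalization (lowercase, whitespace collapse) is applied
on input because the source databases disagree on casing; it can be
disabled per reader. Conversion of MeSH tree numbers to the child→parent
edge format is out of scope — the DAG file is the interface.

### RLS scoring

Scores are `SD(SD+λ_d I)^{-1} A` on the disease side and the analogous
expression with the miRNA profile of each disease on the miRNA side
(the label vector there is a *row* of A: that is the only reading under
which the dimensions of the closed form work out). λ_d = λ_r = 2. The
implementation solves linear systems rather than forming inverses and is
contract-tested to agree with the explicit-inverse formula to 1e-10.
Integrated similarity need not be positive semidefinite (the semantic
models are not kernels); the solve proceeds whenever (S+λI) is invertible
and a warning is logged past a condition estimate of 1e8. Because the hat
matrix depends only on the similarity, it is computed once and reused
across the many label matrices of spy rounds and super-layer scoring.

### Spy layer

Per round: ⌈0.10·|positives|⌉ spies (never fewer than 1) are zeroed, FS is
recomputed, and unknown pairs scoring *strictly below* the minimum spy
score are flagged (pairs tying the worst spy are conservatively kept
unlabeled). The reliable-negative set is the intersection over 200 rounds;
round r draws from substream (seed, r), so rounds are order-independent
and the whole procedure is bitwise reproducible. Two deliberate choices:
the score inside a round is the *combined* FS (consistent with the final
classifier), and similarity matrices are not rebuilt per round — spies
perturb labels, not similarities. A strict variant that re-derives the GIP
kernels with spies hidden in every round is available
(`spy_recompute_gip`), default off for tractability.

### Super-cluster layer

Distances are 1 − similarity. Ward linkage is implemented via the
Lance–Williams recurrence applied to these dissimilarities on the
squared-distance scale; merge ties go to the lexicographically smallest
cluster pair (clusters keyed by smallest member index), making the merge
sequence deterministic. The input is not necessarily Euclidean-embeddable;
the recurrence is applied as-is (documented caveat). The tree is cut at
0.70 × the maximum merge height by default (Ward heights are monotone, so
the retained merges are a prefix); an explicit cluster count is the
mutually exclusive alternative. The augmented matrices union each entity's
associations over clusters, then the k-NN filter (k = 5, neighbors by
integrated similarity, self excluded, ties by name) removes entries none
of the entity's neighbors support. The filter compares against the
*pre-filter* matrix, so it is order-independent, and it is applied
symmetrically on both the super-miRNA and super-disease sides. Neither the
cut fraction nor k is canonical; both are config-exposed and swept in the
tests. Super-layer scores are returned as plain arrays (their axes are
super entities, which the named score container cannot index).

### Two-layer score

`TS(d_i, m_j) = FSpy(d_i, m_j) · [S_sd_p(m_j) + S_sr_q(d_i)] / 2` with
p = cluster of d_i, q = cluster of m_j. With unit super scores TS reduces
to FSpy; with singleton clusters and the filter off, the super scores
reduce exactly to the basic RLS scores — both reductions are regression
tests.

## Evaluation protocols

* **Global LOOCV** hides one known association at a time, rebuilds the
  pipeline on the modified matrix, and ranks the hidden pair against all
  pairs unknown in the *original* matrix. By default the GIP kernels are
  recomputed for every held-out case (no leakage of the held-out label into
  the similarity); a `--fast` mode reuses the full-data kernels.
* **Local LOOCV** restricts the comparison set to the unknown pairs of the
  same disease; diseases with no candidate pairs are skipped and counted.
* **Reported AUC** is the mean over held-out cases of the fraction of
  candidates outranked, with ties counted one half (the Mann–Whitney
  reading). This makes global and local LOOCV coincide exactly on a
  single-disease instance. ROC polylines are built by sweeping a threshold
  over the normalized rank positions. The standalone `roc_auc` statistic is
  Mann–Whitney with midranks and equals the trapezoidal ROC area to 1e-12.
  Written candidate rankings use competition order with name tie-breaks;
  AUCs are reported to 4 decimals, growth rates to 2 (half-up).
* **k-fold CV** shuffles positives per repetition (substream (seed, rep)),
  splits them into k near-equal folds, hides each fold, and averages
  per-fold Mann–Whitney AUCs; the protocol reports mean ± std over
  repetitions. GIP similarity is always recomputed from the training
  matrix.

## Synthetic benchmark

The generator plants the minimal structure under which the model's
propagation assumption is true: diseases and miRNAs fall into latent
blocks; ground-truth associations are Bernoulli(0.6) within a block and
Bernoulli(0.05) across; 30% of true positives are hidden from the observed
matrix and recorded. The DAG forest gives same-block diseases a shared
subtree (depth 3, branching 2); the functional similarity is a 0.8/0.2
block matrix with truncated symmetric Gaussian noise (sd 0.05), clipped to
[0,1]. The default scale, 30 diseases × 40 miRNAs × 3 blocks, keeps full
global LOOCV with per-case kernel recomputation plus the 200-round spy
layer around tens of seconds, which is what the shipped benchmark and
acceptance script use; the 5-fold protocol is run at 10 repetitions there
for the same reason.

Passing on this benchmark shows the pipeline recovers planted structure
when its core assumption holds and that each layer behaves as specified.
It does not show performance on real HMDD data, whose degree distribution
is heavy-tailed, whose DAG annotation is partial, and whose similarity
sources carry correlated errors — none of which the generator mimics.
Published full-corpus reference AUCs are shipped as constants for
growth-rate arithmetic only.

## Degenerate inputs and edge cases

* Duplicate pairs collapse on read; malformed lines fail with their line
  number; an empty association file is an error.
* Similarity files may be asymmetric up to 1e-8 (repaired by averaging);
  beyond that they are rejected as corrupted. Symmetry is otherwise
  enforced at 1e-10.
* A cycle in the parent relation raises an error naming one cycle; diamond
  ancestry is counted once.
* Spy strategy requires ≥ 2 positives; fewer than 2 entities yields a
  single cluster with a warning; an all-known matrix produces an empty
  (header-only) ranking file.

## Known limitations

* Ward on non-Euclidean dissimilarities has no variance interpretation;
  it is used as a deterministic agglomeration rule.
* The spy threshold is a minimum over spies and thus sensitive to a single
  badly-scoring spy; the 200-round intersection compensates by
  construction but makes the reliable-negative set small and conservative.
* LOOCV rebuilds the pipeline per case; at full-corpus scale (hundreds of
  diseases and miRNAs) a global LOOCV run is a batch job, not interactive.
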