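# Methods

This note documents the models and procedures implemented in `kbalance`,
the parameter choices that matter, what the synthetic benchmarks do and
do not emulate, and the numerical conventions adopted where the design
was genuinely open.

## Feature extraction

A fragment of length L is featurized as the relative frequency of each
of the 4^k words of length k, counted over all L−k+1 sliding windows.
Windows containing any non-ACGT character are skipped and the
denominator is the count of *valid* windows, so profiles always lie on
the probability simplex regardless of ambiguity content; a record with
zero valid windows is flagged invalid and dropped (with a log message)
rather than silently zero-filled. Features are ordered lexicographically
with A < C < G < T and the ordering is stored in profile-file headers
and model fingerprints, so columns are stable across runs. No
reverse-complement canonicalization is applied: both strands' words are
separate features, giving D = 4^k dimensions exactly. The default k = 3
(64 features) balances signal and cost; k is capped at 8 by default
purely to guard against accidental memory blow-up (override `max_k` to
go higher deliberately).

## Feature-space balancing

Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `G` | 10 | grid cells per feature dimension, equidistant over [0, 1]; the last bin is closed so a value of exactly 1.0 is binned |
| `N` | 600 000 | target number of accepted training samples |
| `init_fraction` | 0.3 | fraction of N accepted unconditionally before the accept/reject phase |
| `escape_threshold` | 10 | consecutive rejections before one forced acceptance |
| `seed` | 0 | stream permutation seed |
| `stratified_init` | off | draw the initialization round-robin across class labels |

Design choices where more than one reading was defensible:

- **Candidates are drawn without replacement** (one random permutation
  of the input rows); a rejected sample is discarded permanently. This
  guarantees termination, forbids duplicate training rows, and makes
  "consecutive unsuccessful trials" well defined on a stream.
  With-replacement draws would be an alternative reading.
- **Initialization samples count** toward the budget N, toward cell
  counts, and toward `C_max`.
- **Initialization is uniform** over the training set by default, not
  class-stratified; `stratified_init=True` provides the stratified
  variant and a warning is emitted if a class is absent from the
  initialization sample.
- **Escape-hatch acceptances update cell counts and may raise `C_max`**,
  since `C_max` is defined as the highest count observed so far with no
  exception. The rejection counter is global (not per cell) and resets
  on any acceptance.
- **Cells are stored sparsely**, keyed by the exact tuple of bin indices
  (byte-encoded, collision-free). The conceptual grid has G^D cells and
  is never materialized; memory scales with occupied cells, which is
  bounded by the sample count.

Diagnostics record, for every cell occupied in the full input, the
occupancy before (`C_before`) and after (`C_after`) balancing, their
mean C̄ and the removal count ΔC = C_after − C_before ≤ 0, suitable for
a log-log removal-vs-density plot. On the imbalanced synthetic benchmark
the Spearman correlation between C_before and |ΔC| is ≈ 0.7: denser
cells lose proportionally more samples.

## Classifiers

All families are thin, seeded compositions of scikit-learn estimators
with hard-label majority voting; ties break toward the lowest index in
the model's sorted class list so predictions are reproducible.

- `bagged_trees` (default 100 learners): decision trees on bootstrap
  resamples; with one learner and bootstrapping off this reduces exactly
  to a single tree.
- `subspace_knn`, `subspace_discriminant` (default 30 learners):
  KNN (default 10 neighbours, Euclidean) or linear discriminant members,
  each on ⌈D/2⌉ feature dimensions drawn without replacement.
- `svm_linear` / `svm_gaussian` / `svm_polynomial`, `mlp` (one hidden
  layer of 512 units, early stopping): single models; inputs are
  standardized inside the model since these families are scale
  sensitive, whereas tree/KNN families consume the raw [0, 1] profiles.

These defaults are this package's own documented choices; no attempt is
made to replicate any other toolbox's default hyperparameters or
numerics. Models serialize with a format version and a feature-space
fingerprint (k, D, column ordering) and refuse feature matrices that do
not match it.

## Evaluation

Macro-average precision: the unweighted mean over classes of
TP_i/(TP_i+FP_i), with the class set taken as the union of true and
predicted labels (a model predicting an absent class must be
penalized). A class that is never predicted (TP+FP = 0) scores
precision 0 — the conservative convention — and is counted in
`n_undefined` so the drop-from-mean alternative can be recomputed from
the report.

## Synthetic benchmarks

The generator emits fixed-length sequences (default 1500 nt) from
first-order Markov chains over {A,C,G,T} — the minimal model whose
k-mer statistics are non-trivial and class-distinct for every k ≥ 1 and
whose stationary expectations are exactly computable, which keeps the
generator itself testable.

Each preset class is parameterized by a GC target and a homopolymer
persistence `a`: transition rows are `(1−a)·π + a·e_i`, i.e. the
previous base repeats with probability `a`, otherwise a fresh base is
drawn from the GC-determined composition π. π is stationary for any
`a`, so GC content is controlled exactly while persistence lengthens
homopolymer runs.

The presets encode two features of real genomic fragments that this
pipeline's behaviour hinges on:

- **Within-class GC heterogeneity.** Each class is a mixture of five
  sub-chains at GC offsets (−0.06 … +0.06, effective SD ≈ 0.033) around
  its target, emulating isochore-like GC variation along genomes. This
  makes adjacent classes genuinely overlap in feature space, as real
  phyla do — without it, classification is trivially perfect and no
  training-set curation could matter.
- **Local compositional autocorrelation.** Persistence (0.60/0.45
  alternating across classes) spreads homopolymer word frequencies over
  a range comparable to the grid's bin width, so the discretization is
  non-degenerate at k = 3, and gives adjacent classes run-length
  signatures that only k ≥ 2 features can see — which is why MAP at
  k = 3 exceeds MAP at k = 1 on these benchmarks.

`separated4` uses equal class weights at GC targets
0.30/0.43/0.57/0.70 (labels are superkingdom-like names); its classes
are separable to MAP ≈ 1 at k = 3. `blob_imbalanced` reuses the same
four classes but gives the GC-0.43 class 85% of the sampling weight,
producing one densely covered region of feature space — the pathology
balancing corrects. On it, training on the balanced subset (G=10,
N=800 of 2000) beats a size-matched random subset on a class-balanced
test set in median over seeds.

Not emulated: repeats, codon structure, horizontal transfer, sequencing
error, chimeras, and any higher-order dependence beyond first-order
chains. Passing benchmarks therefore demonstrate the pipeline's
mechanics and the direction of the balancing effect, not absolute
performance on real metagenomes.

## Pipeline and reproducibility

A run is a pure function of inputs and resolved configuration. One
master seed is fanned out via `numpy.random.SeedSequence.spawn` into
independent sub-seeds for synthesis, splitting, balancing, random
subsetting and training (each < 2^31), so stages can be rerun in
isolation; the resolved configuration and stage seeds are written next
to every run's artifacts. Balancing is fit on the training split only
and never applied to test data. Cross-validation uses stratified folds
(fold construction is otherwise unconstrained by the method), each
training fold balanced independently when balancing is enabled.

Experiment sizes used by the shipped tests and `scripts/acceptance.py`
(2 000–2 800 sequences, budgets of 800, 10 repetition seeds) are chosen
so the full battery completes in about a minute on one CPU while every
directional comparison is still decided by a comfortable margin; the
method itself streams, and the balancer's sparse grid has been run
unchanged at 10^5-sample scale.

## Known limitations

- Grid bins are fixed over [0, 1] per dimension. For large k, real
  profiles concentrate near the origin of every axis and few dimensions
  spread across bins; data whose per-dimension spread is far below 1/G
  will see little balancing effect (the grid degenerates to one cell).
  A per-dimension range normalization would be a natural extension.
- The balancer is order-sensitive by design (a stream, not a global
  optimization); different seeds give different, equally valid subsets.
- One model per taxonomic rank; no hierarchical consistency across
  ranks is enforced.
- MAP ignores recall entirely; a classifier can score well while
  leaving classes under-predicted (visible via `n_undefined` and
  per-class supports in the report).
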