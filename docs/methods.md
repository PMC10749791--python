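# Methods

This note records the model, the numerical and design choices behind
`metadti`, and what its synthetic benchmarks do and do not demonstrate.

## Data model

A heterogeneous network is a node catalog (id, type) plus directed typed
relations. Nodes are globally ordered by `(type, id)`; every matrix and
embedding row uses that ordering, which makes all downstream artifacts
byte-reproducible from the input files and a seed. Relation matrices
follow the receiver-row convention (`R[v, u] = 1` for an edge `u → v`), so
the matrix of `A→B` is exactly the transpose of `B→A`; same-type relations
are stored symmetrized. Multiple edge sets between one ordered type pair
(e.g. an interaction network and a thresholded similarity network) are
unioned into a single binary relation, because the search space assigns
one propagation mode per ordered type pair; weighted adjacency is out of
scope.

## Normalization

The graph convolution uses `D̃_r^{-1/2} (R + I) D̃_c^{-1/2}` with `D̃_r`,
`D̃_c` the row and column degree matrices of `R + I`. For a symmetric
relation both collapse to the familiar single-degree form. The self-loop
guarantees every degree ≥ 1, so the scaling is defined for arbitrary,
possibly rectangular-supported, cross-type relations. Entries of the
normalized matrix are finite and non-negative by construction; a dense
transcription of the formula agrees with the sparse implementation to
1e-10 in the tests.

## Initial features

`H⁰` is trained by node2vec on the directionless union of all relations:
15 walks per node of length 100 (`p = q = 1`, i.e. first-order walks;
biased second-order walks are supported but not default), then skip-gram
with negative sampling — window 5, 5 uniform negatives per positive,
5 epochs, dimension 64 to match the GCN hidden size so every weight
matrix is square. Negative sampling is uniform over nodes; the usual
unigram^0.75 table adds nothing at a few hundred nodes. The batched SGD
averages (rather than sums) the gradients a node accumulates within a
mini-batch: on small vocabularies a node can occur hundreds of times per
batch, and summed updates scale the effective step by that multiplicity
and diverge. Dead-end nodes terminate their walks early; nodes absent
from every walk keep their small random initialization with a warning.
A one-hot identity encoding is available as the ablation variant.

## Search space

For `T` propagation steps there are `T(T+1)/2` slots `(i, t)`. The
candidate catalog is every network relation plus IDENTITY and NULL; slot
position decides admissibility (chain slots below the top exclude NULL;
top-level slots are restricted to relations terminating at the role's
node type, C′, with IDENTITY/NULL re-admitted on top-level skip slots).
C′ is derived from relation typing rather than hard-coded, so networks
with different type sets get correct constraint sets automatically. The
drug-side and protein-side searches are independent, each with its own
significance tensor; prototypes of a jointly optimized two-role search
measured worse recovery and higher variance at this scale.

## Optimization

Significances `α` initialize uniformly in [0, 1]; `θ = softmax(α)` per
slot. Each search step:

1. samples one architecture — per slot, argmax-`θ` with probability
   `1 − p`, uniform otherwise, where `p` decays linearly from 0.1 to 0
   over the steps (ties break to the lowest catalog index, so runs are
   bit-reproducible);
2. takes one Adam step on the weights `ω` against the training loss of
   that sampled, discrete plan (so weight scales match final training);
3. takes one Adam step on `α` against the validation loss of the
   **mixture supernet**, in which every slot contributes the θ-weighted
   sum over all of its candidates (sharing the slot's weight matrix).
   Backpropagating through the mixture yields a dense gradient for every
   candidate of every slot each step.

The mixture-gradient estimator replaces a single-sample estimator
(θ-scaling only the sampled slot contribution) that proved too noisy on
desk-scale validation sets (~10 positive pairs): with it, planted-relation
recovery was near chance on some data conditions. During the first 20% of
steps `α` is frozen and architectures are sampled uniformly, so every
slot's weight matrix sees training before candidates are compared; with
exploration disabled entirely (`p0 = 0`) the warm-up is skipped and the
search is fully greedy. `α` takes larger Adam steps (0.02) than `ω`
(6e-3): with ~120 post-warm-up updates, steps at the weight learning rate
could not overcome the random initialization spread of `α`, leaving the
outcome dominated by initialization rather than data.

During a role's search the opposite side's features are the frozen `H⁰`
rows; after both searches the argmax meta-graphs are fixed and fresh
Glorot-initialized weights for both roles are retrained jointly on the
link loss (search-then-retrain). The optimizer is Adam throughout with
learning rate 6e-3, weight decay 1e-3 as an additive L2 gradient on the
weights, 150 epochs for both search and retraining, and a one-shot 0.2
learning-rate multiplier at the epoch midpoint (the natural reading of a
single stated "decay rate"; an exploration-decay reading is also
configurable). When a validation set is supplied, retraining returns the
weights of the epoch with the lowest per-pair validation loss — the
validation set's stated purpose is parameter tuning, and full-length
training at this data scale otherwise memorizes the training pairs.
Divergence (non-finite loss or states) aborts with a diagnostic rather
than returning garbage.

Gradients are derived analytically: reverse-mode through the GELU chain
(`gelu'(x) = Φ(x) + xφ(x)`, exact Gaussian form, no tanh approximation),
the sparse normalized adjacencies, and the bilinear logsigmoid loss
(stable via `softplus`); softmax Jacobians couple `α` to `θ`. Finite-
difference checks on weights, significances and loss gradients run in the
test suite.

## Evaluation protocol

Negatives are drawn uniformly without replacement from unknown
drug–protein pairs, `ratio` per positive, once per experiment. Both pools
are partitioned 60/20/20 (train/validation/test) per class,
independently re-drawn per repeat. Test ranking quality is AUROC
(rank-based, ties at half credit) and AUPRC (average precision, no
interpolation), via scikit-learn, with mean and best across repeats
reported; best-of-repeats is the headline convention for repeated
resampling. Meta-graph frequency analysis tallies each selected slot once
per meta-graph, reporting IDENTITY and NULL separately.

## Synthetic benchmark

The generator emulates a four-type biomedical network at desk scale: 50
drugs, 30 proteins, 15 diseases, 20 side-effects (115 nodes). Background
relations (drug–drug 0.02, protein–protein 0.02, drug–side-effect 0.03)
are Bernoulli noise; the planted rule is the two-hop path drug→disease→
protein at density 0.06 per hop, making a pair positive exactly when it
shares a disease (~79 expected positives). The densities were fixed by
two a-priori constraints: at least ~20 positives for stable splits, and
few enough (≤ 136 of 1500 pairs) that a 1:10 negative ratio remains
feasible. An optional noise fraction deletes true positives and promotes
an equal number of random non-pairs; the default is noise-free because
the planted rule is the recovery ground truth. Three-hop rules are
supported and exercise skip slots. Drug–protein edges are deliberately
not part of the propagation network (prototyping them as a
train-edges-only relation destabilized the desk-scale search), so there
is no route for label leakage through the graph.

What passing shows: the bilevel search can identify which typed relations
carry the generative signal, and the learned bilinear geometry ranks
held-out pairs far above chance, reproducibly under seeds. What it does
not show: performance on real pharmacological networks — the fixture has
independent-Bernoulli degrees, no similarity-derived edges, no
hub structure, and node2vec at 115 nodes already encodes much of the
two-hop signal, so absolute metric values do not transfer in either
direction.

Two desk-scale artifacts are worth naming. Held-out sets at ratio 1:1
contain ~15 positive and ~15 negative pairs, so a single AUROC estimate
carries a standard error of several hundredths, and run-to-run spread is
dominated by split noise. And the mean held-out AUROC rises measurably
(~0.84 → ~0.91) from ratio 1:1 to 1:10 simply because training sees ten
times more negative pairs; with thousands of positives this gradient
would vanish.

## Known limitations

No mini-batching, GPU paths or sparse-times-sparse fusion — full-batch
dense states are ample at desk scale. `T` is fixed per run, not searched.
One propagation mode per slot; parallel multi-relation slots are out of
scope. The skip-gram trainer is tuned for reproducibility and small
graphs, not for throughput on million-node networks.
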