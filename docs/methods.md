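# Methods

## Descriptor model

A DNA sequence of length L is viewed through its L−1 overlapping
dinucleotides, each scored by a physicochemical property index (16 real
values per index, canonical column order AA, AC, …, TT). DAC is the lagged
auto-covariance of one property's mean-centered profile; DCC the lagged
cross-covariance of an ordered property pair (φ₁ leads, φ₂ lags). Three
conventions are load-bearing and verified by the worked example and by
brute-force oracles in the test suite:

* the profile mean counts repeated dinucleotides with multiplicity (the
  worked example's two CA steps both contribute);
* the denominator is L − lag − 1, which equals the number of summands;
* DCC(φ, φ, lag) reduces exactly to DAC(φ, lag).

The combined DACC vector is laid out DAC block first (property outer, lag
inner/fastest), then the DCC block over ordered pairs in property order,
again lag fastest — N²·LAG entries. The layout is arbitrary but fixed, so
feature matrices are reproducible column-for-column; labels follow the
grammar `DAC|φ|lag` and `DCC|φ1|φ2|lag`.

Full precision is the contract; printed three-decimal reference values are
matched within ±0.0005 except where the source's own printed value embeds
rounded intermediates (the cross-covariance example: rounded means −0.449
and 0.109 give 0.2407 ≈ 0.241, full precision gives 0.24048, which rounds
to 0.240).

## Property tables, deduplication, DBSCAN screening

Property tables load from CSV/TSV in either orientation (properties as rows
or as columns). Values are used exactly as supplied; an optional z-scoring
flag exists but defaults off so published example values reproduce
bit-exactly.

Equivalent properties — 16-value vectors pairwise equal within a tolerance,
default exact — are collapsed to one uniformly-random representative per
connected component of the equivalence graph. The retained count is
therefore seed-independent even though the retained identity is not.

Screening treats each property as a point in 16-dimensional value space and
clusters with DBSCAN under a schedule of parameter rounds of increasing
strictness. For each cluster of size M, with threshold N (default 5):
0 < M ≤ N keeps the cluster; N < M ≤ 6N samples N members; M > 6N
reclusters the cluster's points with the next round's parameters, and after
the last round samples 2N. Noise points are kept by default (policy flag),
on the reading that density outliers are exactly the hard-to-replace,
informative indices. Interval endpoints are closed on the right, matching
the rule statement.

DBSCAN itself is the classic order-deterministic formulation, implemented in
the package so the border-point tie policy is fixed: a point is core when
its closed eps-ball (point included) holds ≥ minPts points; seeds expand in
input order, so a border point reachable from several clusters joins the
first cluster that reaches it. Euclidean distance is the default metric (the
choice is open; the metric is injectable). The default round schedule is
eps ∈ {4.0, 3.0, 2.0, 1.5} at minPts = 4 — no published values exist for
this step, so the schedule is a documented, fully overridable default; the
47-property outcome of the original screening depends on unpublished
parameters and random draws and is explicitly not a reproduction target.
Correctness is anchored by an O(n²) density-reachability closure oracle and
a cross-check against scikit-learn's DBSCAN (noise sets and core-point
partitions agree; border ties are compared only where the policy determines
them).

## Feature selection

The selection step is a deliberately pluggable stand-in for external
feature-ranking toolchains: three base rankers — one-way ANOVA F statistic,
mutual information on 8-quantile-discretized columns, and variance of
min-max-scaled columns — each rank all features, and rankings merge by Borda
count. Borda ties break on the raw scores, then on input column order, so
the result is deterministic, invariant to row shuffling and (for distinct
scores) to column order. Constant columns rank last with a warning.
`select_top` keeps the top-k set but preserves the matrix's own column
order, making top-k sets nested in k and k = all an identity. The canonical
operating point reduces the 11,045-column DACC matrix to 791 columns; an
externally produced ranking file can be ingested verbatim instead.

## k-mer embeddings

Sequences tokenize into overlapping k-mers (stride 1; L − k + 1 tokens;
k = 3 default, so the 3-mer vocabulary is at most 64). The embedding trainer
is word2vec in numpy: CBOW (context mean predicts center) and skip-gram
(each context token predicts the center) with hierarchical softmax (Huffman
tree over frequency-sorted vocabulary, deterministic tie-breaking) or
negative sampling (unigram^0.75 noise distribution, 5 negatives). Dynamic
windows shrink uniformly to 1..window per center, as in the original
implementation. Updates are applied per sentence as a vectorized mini-batch
— a deliberate departure from strictly sequential SGD that changes no
convergence property at this corpus scale and keeps the trainer fast in
numpy. The learning rate decays linearly across epochs from 0.025 to 1e-4
of itself. Training is single-threaded and bit-deterministic per seed.

Defaults: CBOW + hierarchical softmax, min_count 5, window 5, dimension 200
(the winning cell of the published parameter grid; the dimension is implied
by the 198 × 200 encoding of a 200-bp sequence). Epochs default to 50,
suited to corpora of a few hundred sequences. Out-of-vocabulary tokens
(possible at min_count 5 on small corpora) encode as zero rows with a mask
flag. Embeddings are trained on the training split only by default, to keep
cross-validation leak-free; models persist in the word2vec text format.

## Attention Bi-LSTM

The recurrent head is a numpy implementation with manual backpropagation
through time, verified against finite differences and a scalar-by-scalar
step oracle. The cell is the standard LSTM (gates σ(W·[h, x] + b), candidate
tanh, h = o ⊙ tanh(C)); forget-gate biases initialize to 1 and weights
uniformly at ±1/√(d+H). The bidirectional encoder sums forward and backward
hidden states elementwise. Self-attention pooling uses the mean hidden state
as a single pooled query with dot-product similarities — the simplest
reading of "query, key and value are all the hidden sequence"; per-position
query attention is a possible extension, not currently implemented. A single
dense layer with sigmoid completes the model; decisions threshold at 0.5.

Training: Adam (lr 1e-3), batch 32, ≤ 50 epochs with early stopping on the
MCC of a 15% stratified validation split (patience 8), binary cross-entropy
loss. Hidden size defaults to 128; the planted-signal test suite uses hidden
32 and embedding dimension 16, which separates the synthetic task well
within seconds. Batches require equal-length sequences (true for fixed-length
benchmark-style data); OOV positions contribute zero input rows.

The identification head is a scikit-learn random forest (500 trees, √p
features per split, seeded) over the DACC matrix, optionally after screening
and top-k selection.

## Synthetic data: what it emulates and what it does not

The generator emulates the shape of enhancer benchmarks: fixed-length
(default 200 bp) sequences in an exact 2:1:1
non-enhancer : strong : weak ratio (a 400-sequence set mirrors the
independent-test shape). Class signal is planted through first-order Markov
chains whose transition weights follow a per-class dinucleotide weight map,
so the signal lives exactly where DACC features (and low-order k-mer
statistics) look. Default weights encode CpG/GC-step enrichment —
strong enhancers {CG 5, GC 5, CC 2, GG 2}, weak {CG 2, GC 2, CC 1.5,
GG 1.5}, background uniform — mimicking the GC- and CpG-rich character of
active enhancers, with strong > weak so the strong/weak task is learnable.
These weights produce a clearly separable planted signal (Bayes accuracy
well above the tested bounds), by construction.

What the generator does not emulate: positional structure (motifs, TF
binding-site grammar), long-range dependencies, sequence redundancy/homology
between records, and genomic background composition. Passing tests
therefore demonstrate that the pipeline recovers planted
dinucleotide/composition signal end-to-end — not that it attains any
particular accuracy on real enhancer benchmarks, which additionally depend
on external data and the original screening's unpublished parameters.

## Numerical and protocol choices

* Covariance identities (shift invariance of centered products, s² / s
  scaling, DCC→DAC reduction) are property-tested against brute-force
  oracles at 1e-12.
* MCC is defined as 0 with a degeneracy flag when its denominator vanishes.
* Positive class: "enhancer" for identification, "strong_enhancer" for
  classification.
* Cross-validation is stratified 5-fold with seeded shuffling (stratification
  chosen because of the 2:1:1 imbalance); all fitting, including embedding
  training and feature ranking, happens inside training folds via
  per-fold pipeline factories.
* All randomness (generation, sampling draws in screening and
  deduplication, embedding and network training, fold shuffling) flows from
  explicit integer seeds; training is single-threaded for bit
  reproducibility.
* Non-ACGT residues are a hard error naming the record and position, with an
  opt-in drop policy; sequences are used single-strand, with no
  reverse-complement augmentation.

## Known limitations

* The multi-round screening reproduces the published *rules*, not the
  published 47-index outcome (unpublished parameters).
* The selection module is a transparent stand-in, not a reimplementation of
  any particular external ranking toolkit; it performs single-shot top-k
  truncation rather than iterated re-ranking.
* The Bi-LSTM head requires equal-length inputs per batch; variable-length
  corpora would need padding/packing, not currently implemented.
* Embedding quality at the default min_count 5 degrades on very small
  corpora (OOV zero rows); lower min_count for toy data.
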