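# Methods

## The representation

A DNA sequence `S` of length `L` over {A, C, G, T} is summarized by two
tensors that together form its *gapped pattern graph* (GPG):

- **Vertex features** — a length-`4^k` vector; entry `i` is the frequency
  of k-mer `i` in `S`. K-mers are indexed lexicographically with
  A < C < G < T read as base-4 digits.
- **Pair features** — a `4^k × 4^k × B` tensor; entry `(s, t, b)` is the
  frequency of the gapped pattern `s·x·t` (k-mer `s`, then an arbitrary
  spacer `x`, then k-mer `t`) with `|x|` falling in gap bin `b`. With the
  default identity binning, `B = d+1` and bin `g` holds exactly the
  gap-`g` occurrences, for gaps up to the maximum `d`.

All `4^k` vertices and `4^(2k)` ordered pairs are always materialized
(zeros where absent), so every sequence maps to tensors of identical
shape; this is what lets a downstream network consume sequences of wildly
different lengths. Spaced patterns are the point: a SNP inside the gap
does not disturb the pattern at all, and small indels move an occurrence
between neighboring gap lengths rather than destroying it.

Defaults are `k = 3`, `d = 2`, identity binning, normalized counts.

### Counting rules and normalization

Counting is windowed and vectorized (`O(dL)` per sequence): any window
overlapping a non-ACGT character (N or another ambiguity code) contributes
nothing to the counts — this applies to the k-mer windows *and* to the gap
characters of a pair window, so only genuine clean substrings are counted.
Sequences are used strand-as-given; no reverse-complement
canonicalization is applied.

Normalized mode divides vertex counts by the total number of k-mer
windows, `L − k + 1`. For pair features the denominator is per gap
length, `max(1, L − 2k − g + 1)` — the number of possible `s·x·t` windows
at gap `g` — applied *before* any gap binning, so a binned entry is a sum
of per-gap normalized frequencies. The per-gap denominator mirrors the
vertex rule; it is a package choice, since only the vertex denominator
has a canonical definition. Normalizing an already-normalized graph
raises rather than silently renormalizing. Denominators always use the
full sequence length even when ambiguity characters removed some windows
(simple and testable; the alternative — counting only clean windows —
changes nothing in clean data).

## The network

Edge features cannot ride through a standard vertex-centred graph
convolution, so each of the `4^(2k)` ordered pairs is reified as a
*pair vertex* holding the `B`-dimensional gap profile, connected in both
directions to its two constituent k-mer vertices (one neighbor when
`s = t`). This bipartite topology depends only on `k`; all sequences
share it, and both directions of mean aggregation are precomputed as
row-stochastic sparse matrices.

One convolution level is a two-step update with learned matrices
`W1, B1, W2, B2` and ReLU activation:

    h_u' = relu(B1 h_u + W1 · mean{h_v : v ∈ N(u)})      (k-mers first)
    h_v' = relu(B2 h_v + W2 · mean{h_u' : u ∈ N(v)})     (pairs second)

The pair step deliberately consumes the *already updated* k-mer features
`h_u'`. After `l` levels (default 2) the pair features are concatenated in
lexicographic pair-index order into a `(4^(2k), hidden)` array and reduced
by a small 1-D CNN head: two convolutions over the pair axis
(channels hidden→16→8, kernel 8, stride 4, ReLU), then the concatenation
of a per-channel global max-pool with the flattened feature map, linearly
projected to the embedding (default 64 dimensions). A softmax MLP
(default hidden sizes 64, 32) maps the embedding to class probabilities;
auxiliary per-sequence feature vectors (e.g. gene density or protein
presence/absence profiles), when configured, are concatenated to the
embedding at the first MLP layer. Head and MLP shapes are package
defaults in the stated architecture family and are fully configurable.

**Input scaling.** Normalized frequencies live on a `1/4^(2k)` scale,
far below the scale of freshly initialized weights and biases, which
stalls optimization. The model therefore feeds *enrichment ratios* to the
first layer: each feature divided by its uniform-background expectation
(`1/4^k` per vertex, `bin_width/4^(2k)` per pair bin). This is a fixed,
data-independent diagonal rescaling — the graph itself still stores plain
normalized frequencies — and it is applied identically to the no-GCN
ablation model. It can be disabled via `ModelConfig(input_scale=False)`.

**Ablation model.** The no-GCN control flattens the pair-feature tensor
and feeds it directly to a fully connected network with the same hidden
sizes and the same training loop, skipping graph convolutions and the CNN
head.

The whole network is plain float64 NumPy with hand-written
backpropagation, validated in the test suite against finite differences
and against a dense neighbor-list oracle of the two-step layer. Forward
passes are bit-deterministic; weight initialization is uniform fan-in
scaling from the model seed.

## Training

Mini-batch Adam (learning rate default 1e-4, the value used for the
original large-scale tasks; the bundled synthetic experiments use 1e-3
because they take only a few hundred optimizer steps) on the batch-mean
cross-entropy, with a 1e-12 probability floor inside the log. Class
imbalance is handled by sampling training records with replacement with
probability proportional to the inverse of their class frequency, which
equalizes expected class draws. Splits are stratified 80/10/10 by
default, deterministic per seed, with largest-remainder rounding. Model
selection keeps the weights with the best validation loss; early stopping
uses a default patience of 10 epochs. Grid search trains one model per
cell (any set of `ModelConfig` fields), selects the best validation
accuracy (macro-F1 optional), breaking ties in favor of the first cell.
When a window length `w > 0` is set, sequences are cut into
non-overlapping length-`w` windows, each encoded as its own graph
carrying its parent's label — the mode used for integration-site-style
tasks.

## Attribution

The contribution of a set of gapped patterns is measured by occlusion at
the feature level: the addressed pair entries are zeroed (vertex features
and all other entries untouched, no renormalization — keeping the
perturbation local), and the score is the mean absolute difference
between the class-probability vectors before and after, averaged over an
evaluation set. Occluding features rather than re-encoding
pattern-deleted sequences keeps the perturbation exactly aligned with
what the model consumes. Each score is compared to a baseline: the mean
over `R = 10` repeats of the same measurement with equally many patterns
drawn uniformly without replacement. A motif (IUPAC consensus) is mapped
to its pattern set by enumerating every in-motif decomposition `s·x·t`
with `|x| ≤ d`, expanding ambiguity codes in the two k-mer windows only
(gap characters are unconstrained), and is called *informative* when its
contribution strictly exceeds its baseline.

## Synthetic data

The generator emulates small genome-classification studies: i.i.d.
background sequences with configurable base composition and length range;
class-specific signatures (concrete gapped patterns or IUPAC motifs)
overwritten at random non-overlapping positions — substitution rather
than insertion, so the length distribution carries no label information;
per-position SNP noise (substitution to a uniformly different base) and
indel noise (deletion or single-base insertion, 50/50); and optional
class-conditional Bernoulli auxiliary features emulating protein
presence/absence profiles.

The default study conditions are two classes × 100 sequences of length
1000 at uniform composition with 1% SNP noise and a **pair-swap** design:
class 0 plants `ACG··TGA` and `GTC··CAT` (gap exactly 2, random gap
characters, 4 copies of each per sequence), class 1 plants `ACG··CAT` and
`GTC··TGA`. Both classes contain the same left k-mers, right k-mers and
junction contexts in aggregate; only the *pairing* at gap 2 differs, so
single-k-mer statistics are uninformative by construction and the task
isolates exactly what gapped pairs add. Four copies keeps the planted
count (~4) well above the background expectation of any single gap-2
pair (~0.24 in 1000 bp) while leaving the task non-trivial under noise.

What the generator does not emulate: phylogenetic correlation between
sequences, realistic genome composition and repeat structure, and
train/test distribution shift. Passing the bundled experiments therefore
shows that the implementation learns and attributes planted spaced
signals under noise — not that it matches real-genome performance.

## Numerical and design notes

- Gap binning must tile `{0, …, d}` exactly; the identity binning is the
  default for small `d`. Binned entries are sums of normalized per-gap
  entries (mass-conserving).
- Mean over a singleton neighbor set (self-pairs `s = s`) is the neighbor
  itself, as forced by the definition.
- Checkpoints are NPZ containers holding the config JSON plus every
  weight tensor; save/load round-trips bit-exactly.
- Empty or too-short sequences produce all-zero graphs without error;
  `k ≤ 0`, `d < 0`, non-covering bins, ratio sets not summing to 1, and
  shape mismatches raise typed errors.
- The bundled experiments use deliberately small problem sizes (200
  sequences of 1 kb, hidden width 16, ≤60 epochs) chosen so the full
  study runs on a laptop-class single core in a couple of minutes.

## Known limitations

- The pair-swap design cannot *fully* blind a gap-free model: a planted
  contiguous `s·x·t` span also shifts some overlapping gap-0 pairs (e.g.
  the pair `(Gxx, TGA)` at gap 0 inside `ACG·xx·TGA`), each weakly, so a
  `d = 0` model can recover part of the signal and the margin between the
  full model and its controls varies with the seed at test sets of 20
  sequences.
- Occlusion scores on a saturated classifier are small in absolute terms
  (most predictions sit near 0 or 1 and removing one of several redundant
  informative entries moves them little); only their comparison against
  matched baselines is meaningful.
- Memory grows as `16^k`; `k ≤ 8` is enforced and `k = 3` is the
  practical default.
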