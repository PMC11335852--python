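# Methods

## Model

A word's grounded representation is a linear image of its textual embedding:
`g = t · M`, with `M` a d × c matrix and *no bias term*, so grounding is
exactly a matrix product and is linear by construction. During training a
caption `S = [w_1 … w_n]` is mapped token-by-token through the frozen
textual table and `M`, the grounded sequence is summarized by a *bridge*
encoder into one vector, and that vector must predict the caption's image
feature vector `I` (an opaque, precomputed CNN activation vector; any
dimension is accepted). The loss is the mean squared error taken over all
batch × D_img elements. Both the textual embedding table and the image
vectors are frozen; the trainable parameters are `M`, the encoder weights
θ, and (when the encoder's output dimension differs from D_img) a final
linear projection head.

The zero-shot step is the point of the design: after training, the encoder
is discarded and `M` alone maps *every* vocabulary word — including words
never seen in captions and abstract words that are rarely depictable — into
the grounded space. Keeping `M` linear deliberately restricts how much the
visual signal can deform the textual space; this is what lets abstract
words inherit grounding through their textual geometry (indirect
grounding) instead of being forced toward image statistics.

### Bridges

- **word_level** — stop words are removed from each caption (packaged
  ~120-entry closed-class list, `stopwords.py`), the image vectors are
  PCA-reduced to dimension c when c ≠ D_img (PCA fit on the training split
  only), and `M` is the ordinary least-squares regression of each remaining
  word occurrence's (reduced) image vector on its textual vector. OLS is
  used because this mode *is* a linear regression; the solution is the
  exact minimizer of the same MSE the other bridges descend.
- **bow** — mean of the grounded token vectors → tanh hidden layer →
  linear map to D_img. Order invariant by construction.
- **lstm** (reference) / **gru** — single- or multi-layer recurrent
  encoders; the final time-step's top-layer hidden state is the prediction.
  The reference configuration uses 2048 LSTM units so the hidden state is
  itself the image prediction; a projection head is inserted automatically
  whenever `encoder_units ≠ D_img`.
- **transformer** — tokens are linearly lifted to the hidden size, summed
  with sinusoidal position encodings (the fixed sine/cosine scheme; the
  choice of positional scheme was open and fixed for determinism),
  contextualized by stacked post-norm self-attention blocks (16 heads by
  default), mean-pooled and projected to D_img.

### Nonlinear ablations

`activation ∈ {linear, relu, leaky_relu}` applies the chosen activation
after `t · M`; `activation_layers = 2` stacks a second activated c × c
matrix. These variants let images deform the word space beyond a linear
map, trading textual (abstract) structure for visual (concrete) structure.
Whether such layers carry biases was an open detail; they are bias-free
here so that `ground(0) = 0` holds for every variant.

## Training

Mini-batch stochastic optimization with NAdam (default learning rate 1e-3;
Adam and SGD available). Reference schedule: batch 256, at most 20 epochs,
early stopping with patience 5 — training halts after `patience`
consecutive epochs without a new validation-loss minimum and the
best-epoch parameters are restored. Within a batch, captions are grouped
by length so each group forms a dense tensor; no padding or masking is
needed. Captions that become empty after vocabulary filtering are excluded
from batches. Initial LSTM/GRU states default to zeros for bitwise
reproducibility (a learned-initial-state switch exists); weights use a
seeded Glorot-uniform fan-based initialization. Given identical config and
seed, runs are bitwise identical.

The MSE normalizer is the total element count (batch × D_img), i.e. the
standard per-element MSE; alternative normalizations only rescale the
gradient and are absorbed by the learning rate.

Desk-scale corpora need a different schedule than 100k-caption corpora:
throughout the tests, the acceptance script and the examples, runs on
~2,000 captions use batch 64, learning rate 3e-3, up to 300 epochs with
patience 20, which reaches the noise floor of the synthetic generative
process in well under a minute per run. This is the package's own sizing
choice for small corpora, stated here once; the reference defaults remain
the config defaults.

### Numerical core

No deep-learning framework is a dependency: the encoders and the
concreteness MLP run on a compact reverse-mode autodiff engine over numpy
arrays (`autodiff.py`), implementing exactly the required operator set.
Every operator is verified against central finite differences in the test
suite, and the LSTM/GRU forward passes are additionally checked against
hand-rolled step-by-step recurrence oracles.

## Preprocessing

Captions are lowercased, ASCII punctuation characters are *deleted in
place* (not replaced by spaces: `co-pilot's` → `copilots`), and tokens are
split on whitespace. The training vocabulary keeps the `top_k` (default
10,000) most frequent caption tokens, ties broken lexicographically for
determinism, and is intersected with the embedding table before training
(the truncation count is taken before intersection; the alternative order
was unspecified and this one keeps `top_k` a property of the corpus alone).

## Evaluation

Pairs are scored by cosine similarity and correlated with human scores via
Spearman's ρ (scipy, average ranks for ties), reported ×100. Pairs with an
out-of-vocabulary word are skipped and counted, never zero-filled. Each
benchmark is min–max normalized to [0, 1] before pooling; pooled duplicates
are kept as distinct records with per-pair provenance (the alternative —
deduplication — was unspecified; retention preserves each source's
weighting). Pair concreteness is the mean of the two words' ratings, over
the intersection with the rating norm; pair concreteness is standardized
with the *population* standard deviation (switchable) and partitioned into
four σ-bins with boundaries `x ≤ −1`, `−1 < x ≤ 0`, `0 < x < 1`, `x ≥ 1` —
the extreme bins are inclusive, following the convention that `x ≥ σ` is
highly concrete and `x ≤ −σ` highly abstract. The "Mean" column across
benchmarks is the unweighted arithmetic mean of per-benchmark ρ×100.

The paired significance test between two embedding tables compares, over
the pairs both can score, the per-pair absolute error `|cosine − x_in|`
(squared error via a flag) with a two-sided paired t-test. The exact
operand of such comparisons is underdetermined in general; absolute error
against the normalized human score is the package's definition, and the
degenerate all-zero-difference case returns (t = 0, p = 1) by convention.

Concreteness prediction: words present in both the table and the norm are
shuffled by seed into 10 near-equal folds; targets are standardized
ratings; models are an OLS linear regression and a 512/100 MLP with batch
normalization (running statistics at inference) and dropout 0.2 (off at
inference), ReLU activations, 50 epochs of NAdam at 1e-3 on batches of 64
— the MLP's activation, dropout rate and training length were unspecified
and are fixed defaults. Fold ρ is computed per fold and averaged (not
pooled).

## Synthetic worlds

`make_world` plants a full-rank alignment `M*` (d × c) over an iid Gaussian
embedding table and a projection `P` (c × D_img). Captions are uniform
random token sequences (default lengths 4–12, a realistic caption-length
band); the image vector is `P`-projected *mean* of the tokens' planted
grounded vectors plus Gaussian noise (default sd 0.05). Composition is a
token mean on purpose: it is encoder-agnostic, makes the linear + BoW
bridge well specified with a closed-form optimum, and asks the recurrent
bridges only to match it. Benchmark "human" scores are cosines of planted
grounded vectors plus noise; concreteness ratings are a fixed linear
functional of the textual vectors plus noise. Every generator is a pure
function of its seed and arguments.

What the generators do *not* emulate: realistic language (no Zipfian token
distribution, no syntax), correlated image features, anisotropic embedding
geometry, and rating-scale bounded noise. Consequently, passing tests
establish the *mechanics* — recovery, linearity, contracts, reproducibility
— not performance claims about real embeddings, captions or human norms.

## Numerical choices and degenerate inputs

- Cosine of a zero vector, constant-score correlation/normalization/
  standardization, and sub-2-pair correlations raise typed errors instead
  of returning NaN.
- Duplicate words in an embedding file keep the first occurrence; duplicate
  rating rows keep the last; both are logged.
- Nearest-neighbor ties are broken lexicographically.
- Embedding files are written with 8 significant digits, so read∘write
  round-trips to 1e-6.
- `word_level` uses SVD-based least squares (`lstsq`), which also handles
  rank-deficient designs; PCA uses the full SVD solver for determinism.

## Known limitations

- Trained with a nonlinear bridge, `M` is identified only up to an
  invertible c × c transform absorbed by the encoder; cosine similarities
  in the learned grounded space therefore approach but do not exactly
  reproduce the planted space's cosines even at zero noise.
- The autodiff engine is single-threaded numpy; it is sized for
  desk-scale experiments, not for 100k-caption corpora with 2048-unit
  LSTMs.
- Transformer and multi-layer recurrent bridges are functional and tested
  for contracts and gradients, but no claim is made that the default small
  schedules train them to competitive quality.
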