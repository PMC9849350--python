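# Methods

## Scope and design

`capsite` implements a sequence-only per-residue classifier for
protein–protein binding sites: two per-residue feature channels, a deep
memory capsule network per channel, a softmax fusion head, and an
asymmetric-bagging ensemble for the class imbalance inherent to
interface annotation (positives are 10–18% of residues in the benchmark
regime this package targets). Protein language models and PSI-BLAST are
*producers* of inputs, not components: embeddings are consumed as opaque
L × D matrices and PSSMs are parsed from the standard ASCII layout. The
public surface is a statsmodels-style pair — `BindingSiteModel` (data +
configuration) whose `fit()` returns `BindingSiteResults` (members,
training history, `predict`/`evaluate`/`summary`, directory
save/load) — with a thin CLI over it.

## Feature channels

**MBF.** Per residue: 20 positional log-odds scores, 7 physical
descriptors (steric/graph index, polarizability, normalized van der Waals
volume, hydrophobicity, isoelectric point, helix and sheet probability; the
reduced parameter set of Meiler et al. 2001, shipped as
`data/residue_descriptors.tsv` with provenance in its header) and 3
physicochemical descriptors (atom count, net side-chain charge at pH 7,
side-chain hydrogen-bond donor+acceptor count). The 30-dim base vectors are
stacked over a sliding window (default n = 25, step 1, centre residue is
the target), giving L × 750. Window positions beyond either end contribute
zero vectors — zero padding keeps one row per residue and marks "no
residue" unambiguously. Unknown residues (`X`, and any non-standard letter
mapped to it) get zero descriptor vectors so matrix shapes never change.
A descriptor registry (`features.EXTRA_DESCRIPTORS`) lets extra per-residue
descriptors be appended without code changes. Parsed PSSM values are used
as-is (no sigmoid or min-max rescaling by default).

**Embedding.** L × D (default D = 1024) consumed unmodified and *not*
windowed — the recurrent encoder supplies context for this channel.

## Network

Per channel, parallel bidirectional recurrent stacks with different hidden
sizes (default [64, 128]; the desk-scale tests use smaller) run over the
residue sequence; per position, forward and backward states of all stacks
are concatenated (width 2·Σh). The memory cell uses three sigmoid gates on
`[h_{t−1}, m_t]` — forget `f_t`, input-rate `r_t`, output `g_t` — with
state `M_t = f_t∗M_{t−1} + r_t∗tanh(W_M·[h_{t−1}, m_t]+b_M)` and emitted
hidden state `h_t = O_t = g_t∗tanh(M_t)`; there is no separate hidden-state
recurrence beyond `O_t`.

The encoder output is sliced into input capsules of dimension
`caps_in_dim` (default 8; the encoder width must be divisible by it —
checked at configuration time). Routing by agreement runs a fixed number of
iterations (default 3, the standard setting for this layer type): couplings
from a max-shifted softmax over zero-initialized logits, weighted vote
sums, the squash nonlinearity (ε-guarded at 1e−12 so `squash(0) = 0`), and
logit updates by the vote–output inner product. Training backpropagates
through the unrolled routing iterations.

Flattened capsule outputs of the channels are concatenated and standardized
**layer-wise** (per residue, across features; ε = 1e−6) — a stateless
choice that behaves identically at train and test time, with `none` and
`l2` available — then classified by a dense softmax head.

## Training

Weighted cross-entropy, Adam (lr 1e−3), Glorot-uniform initialization,
tanh activations. Up to 100 epochs with early stopping (patience 10) on
the validation loss, restoring the best epoch's weights. The validation
split is 20%, stratified at residue level and seeded; sequences are always
processed whole — the split only selects which residues enter the train or
validation loss, so windows and recurrent context are never broken.
Gradient updates are made per minibatch of 8 proteins (configurable;
`None` = full batch). All numerics run in float64 on an in-repo
reverse-mode autodiff tape; the tape's gradients are verified against
central finite differences in the test suite, so the training loop is
correct by construction rather than by convention.

## Imbalance strategies

`none` (baseline), `cost_sensitive` (class weights inversely proportional
to class frequency), `oversample` (minority residues duplicated to parity,
with replacement), `undersample` (majority residues reduced to parity,
without replacement), and `ensemble`. The asymmetric-bagging plan shuffles
the training-split negatives with the seed and cuts them into consecutive
blocks of the positive-set size; the final short block is topped up by
seeded sampling from already-used negatives so every bag is exactly
balanced (a short last bag is available via `pad_last=False`). Member m
trains on all training positives plus bag m, initialized from seed
`base_seed + m`; all members share one validation split. Member softmax
outputs are summed class-wise and divided by the member count — the raw
sum exceeds 1, and the division is order-preserving, so decisions are
identical while reported scores stay in [0, 1]. A combined score exactly at
the 0.5 threshold is called positive (favouring recall in a screening
tool). `max_members` trains only the first bags of the full plan — the
plan itself always covers every negative.

The bagging rationale — variance σ²/n for n independent members, degrading
to σ²/n + ((n−1)/n)ρσ² under correlation ρ — is checked empirically by
`variance_reduction_check` on equicorrelated toy predictors.

## Evaluation

TPR, TNR, Pre, ACC, F1 and MCC from the 2×2 table at a configurable
threshold (default 0.5; `match_prevalence=True` instead thresholds at the
score quantile that calls as many positives as the labels contain — both
conventions appear in the interaction-site literature, and the threshold
used is always reported). Scores equal to the threshold are positive. Any
zero-denominator metric is reported as 0 with a logged note so degenerate
folds never crash. AUROC uses the Mann–Whitney midrank formulation (ties
count ½). AP is the exact step summation over descending distinct-score
thresholds with R₀ = 0 — no interpolation, which is why it agrees with the
step-wise definition to machine precision and is preferred here over
trapezoidal PR-AUC.

## Synthetic data

The generator emulates the statistical regime the method assumes, not real
biology:

* lengths uniform in [50, 80] (default 30 proteins); binding sites planted
  as contiguous segments of 3–12 residues (interface patches, not i.i.d.
  labels) until the positive fraction is within ±2 points of the 12%
  default target — never overshooting the upper bound;
* sequences drawn from UniProt-like background frequencies; when the
  signal is on, binding segments carry a short motif (default `WRHY`,
  20% substitution rate), so the sequence-derived MBF channel is
  informative; with `signal_strength = 0` no motif is planted and labels
  are independent of both channels — a true null;
* embeddings: a fixed random projection of local one-hot windows plus
  `signal_strength` times a unit offset direction on positive residues,
  plus Gaussian noise (σ = 0.5). The projection and offset derive from a
  `representation_seed` kept separate from the dataset seed and constant by
  default: a language model is the same function for every protein, so
  train and held-out datasets must share one representation map;
* PSSMs: per position, multinomially perturbed counts around the true
  residue are turned into a substitution-probability matrix against
  background, scored with the log-odds formula, scaled ×10 and rounded to
  integers (the PSI-BLAST ASCII convention), so write→parse round-trips are
  exact.

What passing tests on this generator do **not** show: performance on real
proteins. Real embeddings are not Gaussian around two class means, real
interfaces correlate with structure the generator ignores, and real PSSMs
encode homology depth. The synthetic results certify the machinery —
feature plumbing, optimization, ensemble logic, metrics — and the *ordering*
of strategies, not absolute benchmark numbers.

## Problem sizes and defaults used in the shipped runs

The recovery runs (test suite and acceptance script) use 30 training and
~30 held-out proteins (~2,000 residues each side), a single bidirectional
stack of hidden size 16, 16 output capsules of dimension 4, 2 routing
iterations, at most 40 epochs, and a 2-member ensemble; the
strategy-ordering comparison uses 16 proteins of length 40–60 over 5 seeds
with 3-member ensembles. These sizes are this package's declared desk-scale
study conditions; the published-scale defaults (hidden [64, 128], 32
capsules of dimension 10, 3 routing iterations, 100 epochs, full bag
coverage) remain the configuration defaults.

## Known limitations

* Full-batch recurrent processing pads all proteins in a minibatch to the
  longest length; extremely heterogeneous lengths waste compute.
* The identity of the "eleven" descriptors sometimes mentioned alongside
  the three documented feature groups is unresolved; the package ships the
  documented 30 dimensions and leaves extensions to the descriptor
  registry.
* Routing iteration count, the agreement update, and the fusion
  normalization are declared design choices where the method description
  is silent; all are configurable.
* No GPU path; the NumPy implementation is sized for desk-scale data, not
  proteome-wide inference.
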