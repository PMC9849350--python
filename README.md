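# capsite

Per-residue prediction of protein–protein interaction (PPI) binding sites
with an ensemble deep memory capsule network.

## The problem

Residues that sit at protein–protein interfaces are the functional currency
of cellular pathways, but experimentally mapped binding sites cover only a
sliver of known proteins, and in the benchmark datasets used for this task
binding residues are a 10–18% minority. `capsite` is a sequence-only
classifier for this setting, aimed at computational biologists who want a
trainable, inspectable implementation of the method rather than a black-box
web service. Every component — feature encoding, the network, the
imbalance machinery, the evaluation suite — is exercisable end-to-end on
seeded synthetic data, with no pretrained language model, PSI-BLAST run or
external dataset required.

## The model

Each protein is encoded into two channels:

* **MBF** (multi-source biological features): per residue, 20 PSSM log-odds
  values (`score(a,b) = log10(M(a,b)/p_a p_b)`, parsed from PSI-BLAST ASCII
  profiles), 7 physical descriptors and 3 physicochemical descriptors,
  stacked over a sliding window of n = 25 residues centred on the target —
  an L × 750 matrix;
* **embedding**: an opaque L × 1024 per-residue matrix from a protein
  language model (ProtT5-style), consumed as-is.

Each channel passes through a *deep memory* encoder — parallel
bidirectional recurrent stacks with different hidden sizes, whose gates are

```
f_t = σ(W_f·[h_{t−1}, m_t] + b_f)        (forget)
r_t = σ(W_r·[h_{t−1}, m_t] + b_r)        (input rate)
M̃_t = tanh(W_M·[h_{t−1}, m_t] + b_M)     (candidate state)
M_t = f_t ∗ M_{t−1} + r_t ∗ M̃_t
g_t = σ(W_g·[h_{t−1}, m_t] + b_g)        (output)
h_t = O_t = g_t ∗ tanh(M_t)
```

— then a capsule layer with routing by agreement: votes ĉ_{j|i} = W_ij c_i,
couplings o_ij = softmax_j(b_ij), pre-activations s_j = Σ_i o_ij ĉ_{j|i},
outputs v_j = (‖s_j‖²/(1+‖s_j‖²)) · s_j/‖s_j‖, and logit updates
b_ij += ⟨ĉ_{j|i}, v_j⟩. Channel outputs are concatenated, standardized, and
classified by a dense softmax head.

Class imbalance is handled by **asymmetric bagging**: all positive residues
are kept in every bag, the negatives are partitioned (without replacement)
into ⌈|S_n|/|S_p|⌉ subsets of exactly |S_p|, one network is trained per bag,
and member softmax outputs are combined class-wise. Single-model baselines
(cost-sensitive weights, random over-/under-sampling) are selectable.
Evaluation reports TPR, TNR, Pre, ACC, F1, MCC, AUROC (Mann–Whitney) and
average precision AP = Σ_n (R_n − R_{n−1}) P_n.

The network and its training loop are implemented in NumPy on a small
in-repo reverse-mode autodiff tape (gradient-checked against finite
differences in the test suite).

## Worked example

```python
from capsite import BindingSiteModel, ModelConfig, SimConfig, simulate_dataset
from capsite.model import bundles_from_dataset

cfg = ModelConfig(hidden_sizes=(16,), caps_in_dim=8, caps_count=16, caps_dim=4,
                  routing_iters=2, epochs=40, patience=8, seed=7)
train = simulate_dataset(SimConfig(seed=11))     # 30 proteins, 12% positives
test = simulate_dataset(SimConfig(seed=1111))    # held-out proteins

model = BindingSiteModel.from_dataset(train, cfg, strategy="ensemble",
                                      max_members=2)
results = model.fit()
print(results.summary())
print(results.evaluate(bundles_from_dataset(test, cfg)))
```

prints

```
Binding-site prediction model
=============================================
strategy:            ensemble
channels:            mbf, embedding
window size (MBF):   25
recurrent stacks:    [16] (bidirectional)
capsules:            16 x dim 4, 2 routing iterations
members:             2
seed:                7
negative partition:  7 balanced bags of 202
member 0: 19 epochs, best val loss 0.1870
member 1: 22 epochs, best val loss 0.1557

residues evaluated: 1852
decision threshold: 0.5
TPR: 0.9791
TNR: 0.9560
...
AUROC: 0.9942
AP: 0.9665
```

The summary shows the fitted configuration and the per-member early-stopped
training; the report shows held-out performance. AP (0.97) against a 0.13
positive fraction and AUROC 0.99 mean the planted binding-site signal is
recovered almost perfectly; on a zero-signal dataset the same pipeline
returns AUROC ≈ 0.5.

The same pipeline is available from the shell:

```bash
capsite simulate --out data/ --seed 11
capsite train --data data/ --out model/ --strategy ensemble --max-members 2
capsite predict --model model/ --fasta data/proteins.fasta \
    --pssm-dir data/pssm --embeddings data/embeddings.npz --out pred.tsv
capsite evaluate --predictions pred.tsv --fasta data/proteins.fasta \
    --labels data/labels.txt
capsite sweep-window --data data/ --out sweep.tsv   # window-size experiment
```

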