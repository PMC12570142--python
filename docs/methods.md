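# Methods

This note records the methodological choices of `smilesclm` in one place:
what each stage computes, with which conventions, and why.

## Corpus curation

Raw SMILES are standardized in a fixed order: parse → strip stereochemistry
(the model has no stereo tokens) → keep the largest fragment (desalting; ties
broken by lexicographically smallest canonical SMILES) → neutralize simple
charged groups by proton transfer (atoms whose charge is balanced by a bonded
counter-charge, e.g. charge-separated nitro, are left as drawn) → reject
molecules containing metals, no carbon, or elements outside
{H, C, N, O, F, Cl, Br, I, P, S} → reject molecules with residual net charge →
canonical SMILES. Duplicates are collapsed on canonical SMILES (first
occurrence kept), then canonical-string lengths outside the empirical
5%/95% quantiles are trimmed. Every input molecule is accounted for: the
curation report's rejection counts plus the output size always equal the
input size, and this conservation is asserted.

## Tokenization

SMILES are kekulized before splitting, so aromatic lowercase tokens never
enter the vocabulary, and then split with the standard atom-wise regex:
bracket atoms, two-letter halogens, ring-closure digits and `%nn` pairs,
bonds and branch parentheses each form one token. Joining the tokens
reproduces the kekulized string character for character, which is enforced.
The vocabulary reserves `<PAD>` (id 0, excluded from the loss), `^` (begin)
and `$` (end); remaining tokens are sorted lexicographically, so the mapping
is deterministic and corpus-order invariant. There is no silent unknown
token: encoding raises, naming every out-of-vocabulary token.

## Model

A decoder-only Transformer in pure NumPy with hand-written backprop:
embeddings + fixed sinusoidal positional encodings, 4 post-norm blocks
(causal multi-head self-attention, then a ReLU feed-forward network of width
300), d_model 100, 4 heads, dropout 0.15, untied output head. Attention
weights beyond the causal frontier are re-set to exactly zero after the
softmax, so causality holds to machine precision, not just to mask scale.

Two head-dimension conventions are supported. The default (`per_head_dmodel`)
gives every head d_model-dimensional queries/keys/values; with the tuned
configuration this totals just under one million trainable parameters at a
~50-token vocabulary. `split_dmodel` (d_model // n_heads per head) is
provided for comparability with other codebases.

Initialization is Glorot-uniform with the residual-path projections (attention
output and second FFN matrix) scaled by 1/√(2·n_layers), the standard
deep-residual scheme that starts the stack near-identity. All gradients are
verified against central finite differences in float64 in the test suite.

## Training

Teacher-forced next-token prediction with masked cross-entropy. The corpus is
split 80/20 into train/validation, stratified by token length. Batches are
built inside length buckets (sequences sorted by length, consecutive groups)
to minimize padding; batch order is reshuffled each epoch. Each epoch, every
molecule is independently replaced with probability 0.1 by a randomized
(non-canonical) SMILES rendering; renderings that introduce out-of-vocabulary
tokens fall back to the canonical form.

Optimization: Adam under the Noam schedule
`lr = d_model^-0.5 · min(step^-0.5, step · warmup^-1.5)`, global-norm
gradient clipping at 1.0, validation-plateau learning-rate halving, early
stopping, and restoration of the best-validation weights.

Fine-tuning reuses pretrained weights with a frozen vocabulary (target
molecules introducing unseen tokens raise an error naming them), a constant
learning rate of 5e-5 and batch 32, with early stopping on an internal 10%
validation split.

### Desk-scale schedule

The full-scale defaults (batch 128, warmup 4000, up to 300 epochs) assume
corpora of 10^5–10^6 molecules. On a ~500-molecule corpus they collapse to a
few hundred optimizer steps, all inside warmup, and the model never sharpens.
Desk-scale runs therefore use batch 8 and warmup 2000, giving ~1500 steps in
30 epochs with a peak learning rate comparable to the full-scale schedule's.
This is a scaling choice of this package (the full-scale configuration was
tuned over batch sizes {32, 64, 128}). Residual seed-to-seed variance is
real at this corpus size: sampling validity at temperature 1.0 typically
lands between 0.80 and 0.95.

## Generation

Autoregressive sampling from `^`, one draw per step from
`softmax(logits / τ)`, until `$` or the length cap. Strings that never emit
`$` are flagged truncated and count as invalid. The sampler advances
sequences in fixed chunks of 200 to bound memory. Temperature 1.0 samples the
model distribution unchanged; 0.6 is the preset for structurally complex
target corpora. The sampling process is exactly normalized — enumerating all
terminated and truncated strings on a toy vocabulary sums to probability 1 —
which the acceptance suite verifies.

## Leakage-safe splitting

Two stages: (1) a Bemis–Murcko scaffold group split — molecules sharing a
scaffold are co-assigned, whole groups go to the holdout until it is as close
to the target fraction as group granularity allows; acyclic molecules share
one empty-scaffold group; (2) sphere exclusion — every holdout candidate with
maximum Tanimoto similarity ≥ 0.6 (Morgan radius 2, 2048 bits) to any
training molecule is removed. The recorded maximum cross-partition similarity
is re-computable by a brute-force audit, and the no-leakage invariant is
asserted property-style in the tests.

## Metrics

- **Quality**: validity (valid / sampled), uniqueness (unique canonical /
  valid), novelty (unique ∉ training set / unique), as percentages.
- **Property profile**: MW, logP, ring count, H-bond donors/acceptors,
  rotatable bonds, QED, synthetic accessibility (RDKit contrib SA scorer),
  Lipinski rule-of-five, PAINS flags — all consumed from RDKit, never
  re-implemented. Per-property distributional fidelity via the
  Kolmogorov–Smirnov statistic and a binned, smoothed KL divergence.
- **Fréchet distance** between Gaussian fits of molecular embeddings,
  computed on equal-size resampled subsets (3 repetitions, mean ± sd) to
  avoid set-size bias. The default embedding is a 10-dimensional
  physicochemical descriptor vector; the featurizer is pluggable. The
  published neural-embedding variant of this metric requires reference
  network weights unavailable offline, so the package names the metric what
  it is: a descriptor-space Fréchet distance.
- **Similarity/diversity**: SNN (mean nearest-neighbor Tanimoto to a
  reference), IntDiv1/IntDiv2 (1 − power-mean pairwise similarity over
  ordered pairs, self-pairs included — the standard benchmarking convention),
  recovery rate (holdout molecules with a generated neighbor ≥ 0.6), scaffold
  recovery.
- **Scaffold diversity**: greedy first-fit clustering of unique scaffolds
  (Morgan radius 3) in a canonical order (descending frequency, ties
  lexicographic), with the Shannon entropy of cluster populations (SDI, bits).
  The empty acyclic-scaffold sentinel forms its own cluster.
- **Chemical-space projection**: 2-D UMAP (Jaccard metric) fitted on
  train + generated fingerprints; holdout molecules are only transformed,
  never used for fitting.

## Reproducibility

One global seed fans out into per-component seeds via a stable SHA-256
derivation, so any pipeline stage can be re-run in isolation with its exact
seed. Every CLI command writes a manifest with its configuration, seed,
package versions and input hashes. End-to-end runs can be specified as one
YAML configuration (`smilesclm run`), whose blocks mirror the stage
dataclasses and reject unknown keys. `scripts/acceptance.py` recomputes all
headline quantities from scratch for any given seed.
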