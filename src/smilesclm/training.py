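"""Pretraining and fine-tuning loops.

Training is teacher-forced next-token prediction with the masked
cross-entropy of :mod:`smilesclm.model`.  Batches are built inside length
buckets to minimize padding; batch order is reshuffled every epoch.  During
pretraining the Noam warmup/decay schedule drives Adam; validation loss is
monitored continuously for early stopping and plateau-triggered learning-rate
reduction.  Fine-tuning reuses the pretrained weights and frozen vocabulary
with a small constant learning rate.

SMILES augmentation: each epoch, every molecule is independently replaced by
a randomized (non-canonical, chemically equivalent) rendering with probability
``augment_prob``; renderings that introduce out-of-vocabulary tokens fall back
to the canonical form.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

from .model import ClmConfig, TransformerLM, lr_schedule
from .tokenizer import (TokenVocabulary, UnknownTokenError, encode,
                        randomize_smiles, tokenize)


@dataclass
class TrainingConfig:
    """Optimization hyperparameters.

    Pretraining defaults: up to 300 epochs, batch 128, Noam schedule with
    4000 warmup steps, 10% augmentation.  Fine-tuning: up to 100 epochs,
    batch 32, constant learning rate 5e-5.
    """

    batch_size: int = 128
    max_epochs: int = 300
    warmup_steps: int = 4000
    augment_prob: float = 0.10
    early_stop_patience: int = 10
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    grad_clip_norm: float = 1.0
    fine_tune_lr: float = 5e-5
    fine_tune_batch_size: int = 32
    fine_tune_max_epochs: int = 100
    split_fraction: float = 0.8
    seed: int = 0
    min_corpus_size: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if not 0 <= self.augment_prob <= 1:
            raise ValueError("augment_prob must be in [0, 1]")
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ValueError("patience values must be >= 1")
        if not 0 < self.plateau_factor <= 1:
            raise ValueError("plateau_factor must be in (0, 1]")
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be > 0")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss", "lr"])
            for i, (tl, vl, lr) in enumerate(zip(self.train_loss, self.val_loss, self.lr), 1):
                w.writerow([i, tl, vl, lr])


def split_train_val(corpus: list[str], fraction: float, seed: int,
                    n_bins: int = 5) -> tuple[list[str], list[str]]:
    """Random train/validation split stratified by token length.

    Molecules are binned by token-length quantile; each bin is split
    ``fraction : 1-fraction`` with a seeded shuffle, so both subsets preserve
    the length distribution.  Deterministic for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1) — both subsets must be non-empty")
    if len(corpus) < 2:
        raise ValueError("corpus must contain at least 2 molecules")
    lengths = np.array([len(tokenize(s)) for s in corpus])
    edges = np.quantile(lengths, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, lengths, side="left")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        rng.shuffle(idx)
        k = int(round(fraction * len(idx)))
        k = min(max(k, 0), len(idx))
        train.extend(corpus[i] for i in idx[:k])
        val.extend(corpus[i] for i in idx[k:])
    if not train or not val:  # tiny corpora: force at least one molecule per side
        allidx = rng.permutation(len(corpus))
        k = max(1, min(len(corpus) - 1, int(round(fraction * len(corpus)))))
        train = [corpus[i] for i in allidx[:k]]
        val = [corpus[i] for i in allidx[k:]]
    return train, val


def make_batches(sequences: list[list[int]], batch_size: int,
                 epoch_seed: int) -> list[list[int]]:
    """Group sequences of similar length into batches and return the batches
    (lists of sequence indices) in a seeded random order.

    Every sequence appears exactly once; sequences are sorted by length so the
    per-batch padding never exceeds the batch's length spread.
    """
    if len(sequences) == 0:
        raise ValueError("make_batches requires at least one sequence")
    order = sorted(range(len(sequences)), key=lambda i: (len(sequences[i]), i))
    batches = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
    rng = np.random.default_rng(epoch_seed)
    rng.shuffle(batches)
    return batches


def _pad_batch(seqs: list[list[int]], pad_id: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Teacher-forcing arrays: inputs seq[:-1], targets seq[1:], pad mask."""
    T = max(len(s) for s in seqs) - 1
    B = len(seqs)
    x = np.full((B, T), pad_id, dtype=np.int64)
    y = np.full((B, T), pad_id, dtype=np.int64)
    m = np.zeros((B, T), dtype=np.float64)
    for i, s in enumerate(seqs):
        n = len(s) - 1
        x[i, :n] = s[:-1]
        y[i, :n] = s[1:]
        m[i, :n] = 1.0
    return x, y, m


class AdamOptimizer:
    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for k, p in params.items():
            gk = grads[k].astype(p.dtype)
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            p -= (lr * corr) * self.m[k] / (np.sqrt(self.v[k]) + self.eps)


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so their global L2 norm is at most
    ``max_norm``; returns the pre-clip norm."""
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                              for g in grads.values())))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


def _encode_corpus(corpus: list[str], vocab: TokenVocabulary) -> list[list[int]]:
    out = []
    unknown: set[str] = set()
    for smi in corpus:
        toks = tokenize(smi)
        missing = [t for t in toks if t not in vocab]
        if missing:
            unknown.update(missing)
            continue
        out.append(encode(toks, vocab, add_bos=True, add_eos=True))
    if unknown:
        raise UnknownTokenError(sorted(unknown))
    return out


def _eval_loss(model: TransformerLM, seqs: list[list[int]], pad_id: int,
               batch_size: int = 256) -> float:
    total, n = 0.0, 0
    for batch in make_batches(seqs, batch_size, epoch_seed=0):
        x, y, m = _pad_batch([seqs[i] for i in batch], pad_id)
        logits = model.forward(x, train=False)
        mx = logits.max(-1, keepdims=True)
        logp = logits - (mx + np.log(np.exp(logits - mx).sum(-1, keepdims=True)))
        picked = np.take_along_axis(logp, y[..., None], -1)[..., 0]
        total += float(-(picked * m).sum())
        n += int(m.sum())
    return total / max(n, 1)


def _run_loop(model: TransformerLM, vocab: TokenVocabulary,
              train_smiles: list[str], val_smiles: list[str],
              config: TrainingConfig, *, batch_size: int, max_epochs: int,
              constant_lr: float | None) -> tuple[dict[str, np.ndarray], TrainingHistory]:
    rng = np.random.default_rng(config.seed)
    train_seqs_canonical = _encode_corpus(train_smiles, vocab)
    val_seqs = _encode_corpus(val_smiles, vocab)
    pad_id = vocab.pad_id
    opt = AdamOptimizer(model.params)
    history = TrainingHistory()
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    since_best = 0
    since_plateau = 0
    lr_mult = 1.0
    step = 0

    for epoch in range(1, max_epochs + 1):
        # per-epoch augmentation: independent Bernoulli draw per molecule
        seqs = []
        for smi, canonical_seq in zip(train_smiles, train_seqs_canonical):
            if config.augment_prob > 0 and rng.random() < config.augment_prob:
                try:
                    rand = randomize_smiles(smi, rng)
                    seqs.append(encode(tokenize(rand), vocab, add_bos=True, add_eos=True))
                    continue
                except Exception:  # OOV rendering or parse hiccup: keep canonical
                    pass
            seqs.append(canonical_seq)

        epoch_losses = []
        lr_now = 0.0
        for batch in make_batches(seqs, batch_size,
                                  epoch_seed=int(rng.integers(2 ** 31))):
            step += 1
            if constant_lr is None:
                lr_now = lr_schedule(step, model.config.d_model, config.warmup_steps) * lr_mult
            else:
                lr_now = constant_lr * lr_mult
            x, y, m = _pad_batch([seqs[i] for i in batch], pad_id)
            loss, grads = model.loss_and_grad(x, y, m, train=True, rng=rng)
            clip_gradients(grads, config.grad_clip_norm)
            opt.step(model.params, grads, lr_now)
            epoch_losses.append(loss)

        val_loss = _eval_loss(model, val_seqs, pad_id)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.lr.append(lr_now)

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            since_best = 0
            since_plateau = 0
        else:
            since_best += 1
            since_plateau += 1
            if since_plateau >= config.plateau_patience:
                lr_mult *= config.plateau_factor
                since_plateau = 0
            if since_best >= config.early_stop_patience:
                history.stop_reason = "early_stop"
                break

    model.params = best_params
    return best_params, history


def train(model: TransformerLM, corpus: list[str], vocab: TokenVocabulary,
          config: TrainingConfig) -> tuple[dict[str, np.ndarray], TrainingHistory]:
    """Pretrain on a curated corpus with the Noam schedule.

    The corpus is split ``split_fraction : 1-split_fraction`` into train and
    validation subsets stratified by token length; the returned weights are
    those of the best validation epoch.
    """
    if len(corpus) < config.min_corpus_size:
        raise ValueError(
            f"corpus of {len(corpus)} below minimum size {config.min_corpus_size}")
    tr, va = split_train_val(corpus, config.split_fraction, config.seed)
    return _run_loop(model, vocab, tr, va, config,
                     batch_size=config.batch_size, max_epochs=config.max_epochs,
                     constant_lr=None)


def fine_tune(model: TransformerLM, target_corpus: list[str],
              vocab: TokenVocabulary, config: TrainingConfig,
              val_fraction: float = 0.10) -> tuple[dict[str, np.ndarray], TrainingHistory]:
    """Adapt a pretrained model to a small target corpus.

    Constant learning rate (``fine_tune_lr``), batch ``fine_tune_batch_size``,
    early stopping on an internal validation split (default 10% of the target
    corpus).  The vocabulary is frozen: any target molecule introducing an
    unseen token raises :class:`UnknownTokenError` listing the tokens.
    """
    if len(target_corpus) == 0:
        raise ValueError("empty fine-tuning corpus")
    _encode_corpus(target_corpus, vocab)  # fail fast on vocabulary gaps
    tr, va = split_train_val(target_corpus, 1.0 - val_fraction, config.seed)
    return _run_loop(model, vocab, tr, va, config,
                     batch_size=config.fine_tune_batch_size,
                     max_epochs=config.fine_tune_max_epochs,
                     constant_lr=config.fine_tune_lr)
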