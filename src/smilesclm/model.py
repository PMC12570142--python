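"""Decoder-only Transformer for SMILES, in pure NumPy.

The network is the classic autoregressive decoder stack: token embeddings plus
fixed sinusoidal positional encodings, four post-norm blocks of causal
multi-head self-attention and a position-wise feed-forward network, and an
untied linear output head.  Forward and backward passes are written explicitly
(no autodiff framework), which keeps the model dependency-free and makes the
gradient amenable to direct finite-difference verification.

Two head-dimension conventions are supported:

* ``per_head_dmodel`` (default): every head projects to ``d_model`` query/key/
  value dimensions, so the concatenated head output has ``n_heads * d_model``
  columns.  With the default configuration (d_model=100, 4 heads, 4 layers,
  FFN 300) this yields just under a million trainable parameters.
* ``split_dmodel``: the usual ``d_model // n_heads`` per head, provided for
  comparability with other codebases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

_NEG_INF = -1e9  # additive mask surrogate; softmax of it underflows to exactly 0


@dataclass
class ClmConfig:
    """Architecture hyperparameters (defaults are the tuned configuration)."""

    vocab_size: int
    max_len: int = 128
    d_model: int = 100
    n_layers: int = 4
    n_heads: int = 4
    d_ffn: int = 300
    dropout: float = 0.15
    head_dim_convention: Literal["per_head_dmodel", "split_dmodel"] = "per_head_dmodel"

    def __post_init__(self) -> None:
        for name in ("vocab_size", "max_len", "d_model", "n_layers", "n_heads", "d_ffn"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.head_dim_convention == "split_dmodel" and self.d_model % self.n_heads:
            raise ValueError("split_dmodel requires d_model divisible by n_heads")

    @property
    def d_head(self) -> int:
        if self.head_dim_convention == "per_head_dmodel":
            return self.d_model
        return self.d_model // self.n_heads


def positional_encoding(max_len: int, d_model: int, dtype=np.float64) -> np.ndarray:
    """Fixed sinusoidal positional-encoding matrix of shape (max_len, d_model).

    ``PE[pos, 2i] = sin(pos / 10000^(2i/d_model))`` and
    ``PE[pos, 2i+1] = cos(pos / 10000^(2i/d_model))``; no trainable state.
    """
    if max_len < 1 or d_model < 1:
        raise ValueError("max_len and d_model must be >= 1")
    pos = np.arange(max_len, dtype=np.float64)[:, None]
    i = np.arange(0, d_model, 2, dtype=np.float64)[None, :]
    angles = pos / np.power(10000.0, i / d_model)
    pe = np.zeros((max_len, d_model), dtype=np.float64)
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles[:, : (d_model // 2)]) if d_model % 2 else np.cos(angles)
    return pe.astype(dtype)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / np.sum(e, axis=axis, keepdims=True)


def causal_mask(t: int, dtype=np.float64) -> np.ndarray:
    """Additive (t, t) mask: 0 where key <= query position, -inf surrogate above."""
    m = np.zeros((t, t), dtype=dtype)
    m[np.triu_indices(t, k=1)] = _NEG_INF
    return m


def causal_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                     scale_dim: int, mask: np.ndarray | None = None) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k) + M) V with exact zeros beyond the causal
    frontier (weights are re-masked after the softmax).

    ``q, k, v`` may carry leading batch/head axes; the last two axes are
    (positions, dim).
    """
    if q.shape[-1] != k.shape[-1] or k.shape[-2] != v.shape[-2]:
        raise ValueError(f"incompatible attention shapes {q.shape} {k.shape} {v.shape}")
    t = q.shape[-2]
    if mask is None:
        mask = causal_mask(t, dtype=q.dtype)
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(scale_dim) + mask
    w = _softmax(scores, axis=-1)
    w = np.where(mask < 0, 0.0, w)  # enforce exact zeros on disallowed pairs
    return w @ v


def masked_loss(scores: np.ndarray, target_ids: np.ndarray,
                pad_mask: np.ndarray) -> float:
    """Mean cross-entropy of the target token over non-padding positions.

    ``scores``: (..., T, V) unnormalized logits; ``target_ids``: (..., T) int;
    ``pad_mask``: (..., T) with 1 on real tokens and 0 on padding.
    """
    pad_mask = np.asarray(pad_mask, dtype=float)
    n = pad_mask.sum()
    if n == 0:
        raise ValueError("masked_loss: all positions are padding")
    logp = scores - _logsumexp(scores)
    picked = np.take_along_axis(logp, np.asarray(target_ids)[..., None], axis=-1)[..., 0]
    return float(-(picked * pad_mask).sum() / n)


def _logsumexp(x: np.ndarray) -> np.ndarray:
    m = np.max(x, axis=-1, keepdims=True)
    return m + np.log(np.sum(np.exp(x - m), axis=-1, keepdims=True))


def lr_schedule(step: int, d_model: int, warmup_steps: int) -> float:
    """Noam learning-rate schedule:
    ``d_model^-0.5 * min(step^-0.5, step * warmup_steps^-1.5)``.

    Increases linearly during warmup, decays as 1/sqrt(step) afterwards, and is
    continuous (and maximal) at ``step == warmup_steps``.
    """
    if step < 1:
        raise ValueError("lr_schedule is defined for step >= 1")
    if warmup_steps < 1:
        raise ValueError("warmup_steps must be >= 1")
    return d_model ** -0.5 * min(step ** -0.5, step * warmup_steps ** -1.5)


def count_parameters(config: ClmConfig) -> int:
    """Exact trainable-scalar count for the documented conventions: untied
    output head, two layer-norms per block, biases on every projection."""
    d, h, dh, f, v = (config.d_model, config.n_heads, config.d_head,
                      config.d_ffn, config.vocab_size)
    embed = v * d
    attn = 3 * (d * h * dh + h * dh) + (h * dh * d + d)
    ln = 2 * 2 * d
    ffn = d * f + f + f * d + d
    head = d * v + v
    return embed + config.n_layers * (attn + ln + ffn) + head


class TransformerLM:
    """The trainable model: parameter store plus explicit forward/backward.

    Parameters are float arrays in a flat dict; `forward` caches every
    intermediate needed by `backward`.  Dropout (inverted, applied to the
    embedding+PE sum, the attention weights and the FFN output) is active only
    when a ``rng`` is passed with ``train=True``.
    """

    def __init__(self, config: ClmConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        self.pe = positional_encoding(config.max_len, config.d_model, dtype=self.dtype)
        self.params = self._init_params(np.random.default_rng(seed))
        self._cache: dict | None = None

    # -- parameters -----------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c = self.config
        d, hdh, f, v = c.d_model, c.n_heads * c.d_head, c.d_ffn, c.vocab_size

        def glorot(fan_in, fan_out):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=(fan_in, fan_out)).astype(self.dtype)

        p: dict[str, np.ndarray] = {"embed": (rng.standard_normal((v, d)) * 0.02).astype(self.dtype)}
        for l in range(c.n_layers):
            p[f"l{l}.Wq"], p[f"l{l}.Wk"], p[f"l{l}.Wv"] = (glorot(d, hdh) for _ in range(3))
            p[f"l{l}.bq"] = np.zeros(hdh, self.dtype)
            p[f"l{l}.bk"] = np.zeros(hdh, self.dtype)
            p[f"l{l}.bv"] = np.zeros(hdh, self.dtype)
            # residual-path projections scaled down so the stacked blocks start
            # near-identity (standard deep-residual initialization)
            p[f"l{l}.Wo"] = glorot(hdh, d) / np.sqrt(2.0 * c.n_layers)
            p[f"l{l}.bo"] = np.zeros(d, self.dtype)
            p[f"l{l}.ln1_g"] = np.ones(d, self.dtype)
            p[f"l{l}.ln1_b"] = np.zeros(d, self.dtype)
            p[f"l{l}.W1"] = glorot(d, f)
            p[f"l{l}.b1"] = np.zeros(f, self.dtype)
            p[f"l{l}.W2"] = glorot(f, d) / np.sqrt(2.0 * c.n_layers)
            p[f"l{l}.b2"] = np.zeros(d, self.dtype)
            p[f"l{l}.ln2_g"] = np.ones(d, self.dtype)
            p[f"l{l}.ln2_b"] = np.zeros(d, self.dtype)
        p["Wout"] = glorot(d, v)
        p["bout"] = np.zeros(v, self.dtype)
        return p

    def n_parameters(self) -> int:
        return sum(a.size for a in self.params.values())

    # -- layer norm ------------------------------------------------------
    @staticmethod
    def _ln_forward(x, g, b, eps=1e-5):
        mu = x.mean(-1, keepdims=True)
        var = x.var(-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        return g * xhat + b, (xhat, inv)

    @staticmethod
    def _ln_backward(dy, g, cache):
        xhat, inv = cache
        dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        db = dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * g
        dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(-1, keepdims=True))
        return dx, dg, db

    # -- forward ---------------------------------------------------------
    def forward(self, ids: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits of shape (B, T, V); position t depends only on ids[:, :t+1]."""
        c = self.config
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        B, T = ids.shape
        if T > c.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {c.max_len}")
        if ids.max() >= c.vocab_size:
            raise ValueError("token id out of range")
        p = self.params
        drop = c.dropout if (train and rng is not None and c.dropout > 0) else 0.0

        def dropout(x):
            if drop == 0.0:
                return x, None
            m = (rng.random(x.shape) >= drop).astype(x.dtype) / (1.0 - drop)
            return x * m, m

        cache: dict = {"ids": ids, "drop": drop, "layers": []}
        x = p["embed"][ids] + self.pe[:T]
        x, m_emb = dropout(x)
        cache["m_emb"] = m_emb
        mask = causal_mask(T, dtype=self.dtype)
        H, dh = c.n_heads, c.d_head
        scale = 1.0 / np.sqrt(dh)
        for l in range(c.n_layers):
            lc: dict = {"x_in": x}
            q = x @ p[f"l{l}.Wq"] + p[f"l{l}.bq"]  # (B,T,H*dh)
            k = x @ p[f"l{l}.Wk"] + p[f"l{l}.bk"]
            v = x @ p[f"l{l}.Wv"] + p[f"l{l}.bv"]
            qh = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)  # (B,H,T,dh)
            kh = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            s = (qh @ kh.swapaxes(-1, -2)) * scale + mask
            a = _softmax(s, axis=-1)
            a = np.where(mask < 0, 0.0, a)
            a_d, m_att = dropout(a)
            oh = a_d @ vh  # (B,H,T,dh)
            o = oh.transpose(0, 2, 1, 3).reshape(B, T, H * dh)
            attn_out = o @ p[f"l{l}.Wo"] + p[f"l{l}.bo"]
            r1 = x + attn_out
            x1, ln1c = self._ln_forward(r1, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            u = x1 @ p[f"l{l}.W1"] + p[f"l{l}.b1"]
            relu = np.maximum(u, 0.0)
            fout = relu @ p[f"l{l}.W2"] + p[f"l{l}.b2"]
            fout_d, m_ffn = dropout(fout)
            r2 = x1 + fout_d
            x2, ln2c = self._ln_forward(r2, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            lc.update(qh=qh, kh=kh, vh=vh, a=a, a_d=a_d, m_att=m_att, o=o,
                      ln1c=ln1c, x1=x1, u=u, relu=relu, m_ffn=m_ffn, ln2c=ln2c)
            cache["layers"].append(lc)
            x = x2
        cache["x_final"] = x
        logits = x @ p["Wout"] + p["bout"]
        self._cache = cache
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits")
        return logits

    # -- loss + gradient -------------------------------------------------
    def loss_and_grad(self, ids: np.ndarray, targets: np.ndarray,
                      pad_mask: np.ndarray, train: bool = True,
                      rng: np.random.Generator | None = None
                      ) -> tuple[float, dict[str, np.ndarray]]:
        logits = self.forward(ids, train=train, rng=rng)
        pad_mask = np.asarray(pad_mask, dtype=logits.dtype)
        n = pad_mask.sum()
        if n == 0:
            raise ValueError("all positions are padding")
        probs = _softmax(logits, axis=-1)
        logp = logits - _logsumexp(logits)
        picked = np.take_along_axis(logp, np.asarray(targets)[..., None], -1)[..., 0]
        loss = float(-(picked * pad_mask).sum() / n)
        dlogits = probs.copy()
        np.put_along_axis(
            dlogits, np.asarray(targets)[..., None],
            np.take_along_axis(dlogits, np.asarray(targets)[..., None], -1) - 1.0, -1)
        dlogits *= (pad_mask / n)[..., None]
        return loss, self.backward(dlogits)

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss wrt every parameter, given d(loss)/d(logits).
        Must follow a `forward` call (uses the cached activations)."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        c, p, cache = self.config, self.params, self._cache
        ids = cache["ids"]
        B, T = ids.shape
        H, dh = c.n_heads, c.d_head
        scale = 1.0 / np.sqrt(dh)
        g: dict[str, np.ndarray] = {}

        x_final = cache["x_final"]
        g["Wout"] = x_final.reshape(-1, c.d_model).T @ dlogits.reshape(-1, c.vocab_size)
        g["bout"] = dlogits.sum((0, 1))
        dx = dlogits @ p["Wout"].T

        for l in reversed(range(c.n_layers)):
            lc = cache["layers"][l]
            # ln2
            dr2, g[f"l{l}.ln2_g"], g[f"l{l}.ln2_b"] = self._ln_backward(
                dx, p[f"l{l}.ln2_g"], lc["ln2c"])
            dfout = dr2 if lc["m_ffn"] is None else dr2 * lc["m_ffn"]
            dx1 = dr2.copy()
            # ffn
            g[f"l{l}.W2"] = lc["relu"].reshape(-1, c.d_ffn).T @ dfout.reshape(-1, c.d_model)
            g[f"l{l}.b2"] = dfout.sum((0, 1))
            drelu = dfout @ p[f"l{l}.W2"].T
            du = drelu * (lc["u"] > 0)
            g[f"l{l}.W1"] = lc["x1"].reshape(-1, c.d_model).T @ du.reshape(-1, c.d_ffn)
            g[f"l{l}.b1"] = du.sum((0, 1))
            dx1 += du @ p[f"l{l}.W1"].T
            # ln1
            dr1, g[f"l{l}.ln1_g"], g[f"l{l}.ln1_b"] = self._ln_backward(
                dx1, p[f"l{l}.ln1_g"], lc["ln1c"])
            dattn_out = dr1
            dx_res = dr1.copy()
            # output projection
            g[f"l{l}.Wo"] = lc["o"].reshape(-1, H * dh).T @ dattn_out.reshape(-1, c.d_model)
            g[f"l{l}.bo"] = dattn_out.sum((0, 1))
            do = dattn_out @ p[f"l{l}.Wo"].T  # (B,T,H*dh)
            doh = do.reshape(B, T, H, dh).transpose(0, 2, 1, 3)  # (B,H,T,dh)
            # attention weights
            da_d = doh @ lc["vh"].swapaxes(-1, -2)  # (B,H,T,T)
            dvh = lc["a_d"].swapaxes(-1, -2) @ doh
            da = da_d if lc["m_att"] is None else da_d * lc["m_att"]
            a = lc["a"]
            ds = a * (da - (da * a).sum(-1, keepdims=True))
            dqh = (ds @ lc["kh"]) * scale
            dkh = (ds.swapaxes(-1, -2) @ lc["qh"]) * scale
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, H * dh)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, H * dh)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, H * dh)
            x_in = lc["x_in"]
            flat = x_in.reshape(-1, c.d_model).T
            g[f"l{l}.Wq"] = flat @ dq.reshape(-1, H * dh)
            g[f"l{l}.Wk"] = flat @ dk.reshape(-1, H * dh)
            g[f"l{l}.Wv"] = flat @ dv.reshape(-1, H * dh)
            g[f"l{l}.bq"] = dq.sum((0, 1))
            g[f"l{l}.bk"] = dk.sum((0, 1))
            g[f"l{l}.bv"] = dv.sum((0, 1))
            dx = (dx_res + dq @ p[f"l{l}.Wq"].T + dk @ p[f"l{l}.Wk"].T
                  + dv @ p[f"l{l}.Wv"].T)

        if cache["m_emb"] is not None:
            dx = dx * cache["m_emb"]
        g["embed"] = np.zeros_like(p["embed"])
        np.add.at(g["embed"], ids.reshape(-1), dx.reshape(-1, c.d_model))
        return g

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint archive with the config embedded."""
        meta = asdict(self.config)
        np.savez(path, __config__=np.array([repr(meta)]),
                 **{k: v for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "TransformerLM":
        import ast
        with np.load(path, allow_pickle=False) as data:
            meta = ast.literal_eval(str(data["__config__"][0]))
            model = cls(ClmConfig(**meta))
            for k in model.params:
                model.params[k] = data[k]
                model.dtype = data[k].dtype
        return model
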