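"""Miniature decoder transformer in pure NumPy.

The architecture is a standard pre-norm transformer: token embedding (plus
an additive positional table for the learnable/fixed schemes), ``n_layers``
blocks of multi-head self-attention and a GELU feed-forward (4x expansion),
a final layer norm, and an untied output projection. Four positional
encodings are supported (rotary, learnable, fixed sinusoidal, relative
shared-bias-per-offset) together with causal or bidirectional (MLM)
attention and an optional sliding attention window.

Forward and backward passes are written by hand against NumPy arrays; with
fixed seeds every score is bit-reproducible on CPU. Desk-scale defaults
(4 layers x 128 dims) train in minutes on one core; the production-scale
20 x 1856 configuration is expressible but never required.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

POSITIONAL_ENCODINGS = ("rotary", "learnable", "fixed", "relative")
OBJECTIVES = ("causal", "mlm")

_GELU_C = np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 4
    d_model: int = 128
    n_heads: int = 4
    vocab_size: int = 9
    context_length: int = 1024
    objective: str = "causal"
    mask_rate: float = 0.15
    positional_encoding: str = "rotary"
    attention_window: int | None = None  # None = dense
    ffn_mult: int = 4
    seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )
        if self.vocab_size > 16:
            raise ValueError("vocab_size must be <= 16")
        if not 0.0 < self.mask_rate < 1.0:
            raise ValueError("mask_rate must lie in (0, 1)")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if self.positional_encoding not in POSITIONAL_ENCODINGS:
            raise ValueError(
                f"positional_encoding must be one of {POSITIONAL_ENCODINGS}"
            )
        if self.attention_window is not None:
            if not 1 <= self.attention_window <= self.context_length:
                raise ValueError("attention_window must lie in [1, context_length]")
        if self.n_layers < 1 or self.d_model < 1 or self.context_length < 2:
            raise ValueError("n_layers, d_model, context_length must be positive")
        if self.positional_encoding == "rotary" and (self.d_model // self.n_heads) % 2:
            raise ValueError("rotary encoding requires an even head dimension")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads


def parameter_count(config: ModelConfig) -> int:
    """Closed-form parameter count for the declared layer layout."""
    d, v, L, f = config.d_model, config.vocab_size, config.context_length, config.ffn_mult
    per_layer = (
        4 * (d * d + d)  # q, k, v, o projections with bias
        + 2 * 2 * d  # two layer norms (gain + bias)
        + d * (f * d) + f * d  # ffn in
        + (f * d) * d + d  # ffn out
    )
    if config.positional_encoding == "relative":
        per_layer += config.n_heads * (2 * L - 1)
    total = v * d + config.n_layers * per_layer + 2 * d + d * v + v
    if config.positional_encoding == "learnable":
        total += L * d
    return total


def _gelu(x):
    # tanh approximation (the form used by most transformer stacks)
    return 0.5 * x * (1.0 + np.tanh(_GELU_C * (x + 0.044715 * x * x * x)))


def _gelu_grad(x):
    inner = _GELU_C * (x + 0.044715 * x * x * x)
    t = np.tanh(inner)
    dinner = _GELU_C * (1.0 + 3 * 0.044715 * x * x)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner


def _sinusoidal(L: int, d: int, dtype) -> np.ndarray:
    pos = np.arange(L)[:, None]
    i = np.arange(d // 2)[None, :]
    ang = pos / (10000.0 ** (2 * i / d))
    table = np.zeros((L, d))
    table[:, 0::2] = np.sin(ang)
    table[:, 1::2] = np.cos(ang)
    return table.astype(dtype)


def _rotary_tables(L: int, dh: int, dtype):
    pos = np.arange(L)[:, None]
    inv = 1.0 / (10000.0 ** (np.arange(dh // 2)[None, :] * 2.0 / dh))
    ang = pos * inv
    return np.cos(ang).astype(dtype), np.sin(ang).astype(dtype)


def _rotate(x, cos, sin):
    # x: (B, H, L, dh); tables: (L, dh/2)
    x1, x2 = x[..., 0::2], x[..., 1::2]
    out = np.empty_like(x)
    out[..., 0::2] = x1 * cos - x2 * sin
    out[..., 1::2] = x1 * sin + x2 * cos
    return out


def _rotate_back(d, cos, sin):
    d1, d2 = d[..., 0::2], d[..., 1::2]
    out = np.empty_like(d)
    out[..., 0::2] = d1 * cos + d2 * sin
    out[..., 1::2] = -d1 * sin + d2 * cos
    return out



def _outer(x, d):
    """sum_b,l x[b,l,:]^T d[b,l,:] via one BLAS call."""
    return x.reshape(-1, x.shape[-1]).T @ d.reshape(-1, d.shape[-1])

class TransformerLM:
    """Decoder transformer with hand-written forward/backward passes."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        d, v, L = config.d_model, config.vocab_size, config.context_length
        f = config.ffn_mult * d
        std = 0.02

        def w(*shape):
            return rng.normal(0.0, std, size=shape).astype(self.dtype)

        p: dict[str, np.ndarray] = {"tok_emb": w(v, d)}
        if config.positional_encoding == "learnable":
            p["pos_emb"] = w(L, d)
        for i in range(config.n_layers):
            p[f"l{i}.ln1.g"] = np.ones(d, self.dtype)
            p[f"l{i}.ln1.b"] = np.zeros(d, self.dtype)
            for name in ("q", "k", "v", "o"):
                p[f"l{i}.W{name}"] = w(d, d)
                p[f"l{i}.b{name}"] = np.zeros(d, self.dtype)
            if config.positional_encoding == "relative":
                p[f"l{i}.rel_bias"] = np.zeros((config.n_heads, 2 * L - 1), self.dtype)
            p[f"l{i}.ln2.g"] = np.ones(d, self.dtype)
            p[f"l{i}.ln2.b"] = np.zeros(d, self.dtype)
            p[f"l{i}.W1"] = w(d, f)
            p[f"l{i}.b1"] = np.zeros(f, self.dtype)
            p[f"l{i}.W2"] = w(f, d)
            p[f"l{i}.b2"] = np.zeros(d, self.dtype)
        p["lnf.g"] = np.ones(d, self.dtype)
        p["lnf.b"] = np.zeros(d, self.dtype)
        p["head.W"] = w(d, v)
        p["head.b"] = np.zeros(v, self.dtype)
        self.params = p
        self._fixed_table = (
            _sinusoidal(L, d, self.dtype) if config.positional_encoding == "fixed" else None
        )
        self._cache: dict | None = None

    # -- masks ------------------------------------------------------------

    def attention_mask(self, L: int) -> np.ndarray:
        """Boolean (L, L) matrix of allowed (query, key) pairs."""
        i = np.arange(L)[:, None]
        j = np.arange(L)[None, :]
        w = self.config.attention_window
        if self.config.objective == "causal":
            allowed = j <= i
            if w is not None:
                allowed &= j > i - w
        else:
            allowed = np.ones((L, L), dtype=bool)
            if w is not None:
                allowed &= np.abs(i - j) < w
        return allowed

    # -- forward ----------------------------------------------------------

    def _ln(self, x, g, b, eps=1e-5):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        return xhat * g + b, (xhat, inv, g)

    def _ln_back(self, dy, cache):
        xhat, inv, g = cache
        dxhat = dy * g
        dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        db = dy.sum(axis=tuple(range(dy.ndim - 1)))
        m = dxhat.mean(axis=-1, keepdims=True)
        mx = (dxhat * xhat).mean(axis=-1, keepdims=True)
        dx = (dxhat - m - xhat * mx) * inv
        return dx, dg, db

    def forward(
        self,
        token_ids: np.ndarray,
        collect_hidden: bool = False,
        collect_scores: bool = False,
    ) -> np.ndarray:
        """Logits of shape (B, L', vocab); caches activations for backward."""
        cfg = self.config
        tokens = np.atleast_2d(np.asarray(token_ids, dtype=np.int64))
        if tokens.max(initial=0) >= cfg.vocab_size or tokens.min(initial=0) < 0:
            raise ValueError("token id out of vocabulary range")
        B, L = tokens.shape
        if L > cfg.context_length:
            raise ValueError(f"input length {L} exceeds context_length")
        p = self.params
        x = p["tok_emb"][tokens]
        if cfg.positional_encoding == "learnable":
            x = x + p["pos_emb"][:L]
        elif cfg.positional_encoding == "fixed":
            x = x + self._fixed_table[:L]
        H, dh = cfg.n_heads, cfg.head_dim
        scale = 1.0 / np.sqrt(dh)
        allowed = self.attention_mask(L)
        cos = sin = None
        if cfg.positional_encoding == "rotary":
            cos, sin = _rotary_tables(L, dh, self.dtype)
        cache = {
            "tokens": tokens,
            "allowed": allowed,
            "cos": cos,
            "sin": sin,
            "layers": [],
            "hidden": [x.copy()] if collect_hidden else None,
            "attn_scores": [],
        }

        def heads(t):  # (B, L, d) -> (B, H, L, dh)
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        def unheads(t):  # inverse
            return t.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

        for i in range(cfg.n_layers):
            lc: dict = {"x_in": x}
            h, lc["ln1"] = self._ln(x, p[f"l{i}.ln1.g"], p[f"l{i}.ln1.b"])
            lc["h"] = h
            q = heads(h @ p[f"l{i}.Wq"] + p[f"l{i}.bq"])
            k = heads(h @ p[f"l{i}.Wk"] + p[f"l{i}.bk"])
            v = heads(h @ p[f"l{i}.Wv"] + p[f"l{i}.bv"])
            if cfg.positional_encoding == "rotary":
                q = _rotate(q, cos, sin)
                k = _rotate(k, cos, sin)
            s = (q @ k.transpose(0, 1, 3, 2)) * scale
            if cfg.positional_encoding == "relative":
                off = np.arange(L)[None, :] - np.arange(L)[:, None] + cfg.context_length - 1
                s = s + p[f"l{i}.rel_bias"][:, off]
                lc["off"] = off
            if collect_scores:
                cache["attn_scores"].append(s.copy())
            s = np.where(allowed, s, -np.inf)
            s = s - s.max(axis=-1, keepdims=True)
            e = np.exp(s)
            a = e / e.sum(axis=-1, keepdims=True)
            o = a @ v
            attn = unheads(o) @ p[f"l{i}.Wo"] + p[f"l{i}.bo"]
            x = x + attn
            lc.update(q=q, k=k, v=v, a=a, o=o)
            lc["x_mid"] = x
            h2, lc["ln2"] = self._ln(x, p[f"l{i}.ln2.g"], p[f"l{i}.ln2.b"])
            lc["h2"] = h2
            z = h2 @ p[f"l{i}.W1"] + p[f"l{i}.b1"]
            g = _gelu(z)
            x = x + g @ p[f"l{i}.W2"] + p[f"l{i}.b2"]
            lc["z"] = z
            lc["g"] = g
            cache["layers"].append(lc)
            if collect_hidden:
                cache["hidden"].append(x.copy())
        xf, cache["lnf"] = self._ln(x, p["lnf.g"], p["lnf.b"])
        cache["xf"] = xf
        logits = xf @ p["head.W"] + p["head.b"]
        self._cache = cache
        return logits

    def hidden_states(self, token_ids: np.ndarray) -> list[np.ndarray]:
        """Per-layer residual-stream states: entry 0 is the post-embedding
        representation, entry i the output of block i (n_layers + 1 total)."""
        self.forward(token_ids, collect_hidden=True)
        return self._cache["hidden"]

    def attention_score_matrices(self, token_ids: np.ndarray) -> list[np.ndarray]:
        """Pre-mask, pre-softmax attention scores per layer (B, H, L, L)."""
        self.forward(token_ids, collect_scores=True)
        return self._cache["attn_scores"]

    # -- backward ---------------------------------------------------------

    def backward(
        self, dlogits: np.ndarray | None = None, d_hidden_final: np.ndarray | None = None
    ) -> dict[str, np.ndarray]:
        """Gradients for every parameter given dLoss/dlogits (and/or a
        gradient flowing directly into the final layer-norm output)."""
        if self._cache is None:
            raise RuntimeError("forward must run before backward")
        cfg = self.config
        p = self.params
        c = self._cache
        tokens = c["tokens"]
        B, L = tokens.shape
        H, dh = cfg.n_heads, cfg.head_dim
        scale = 1.0 / np.sqrt(dh)
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dxf = np.zeros_like(c["xf"])
        if dlogits is not None:
            dlogits = dlogits.astype(self.dtype, copy=False)
            grads["head.W"] += _outer(c["xf"], dlogits)
            grads["head.b"] += dlogits.sum(axis=(0, 1))
            dxf += dlogits @ p["head.W"].T
        if d_hidden_final is not None:
            dxf += d_hidden_final.astype(self.dtype, copy=False)
        dx, dg, db = self._ln_back(dxf, c["lnf"])
        grads["lnf.g"] += dg
        grads["lnf.b"] += db

        def heads(t):
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        def unheads(t):
            return t.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

        for i in reversed(range(cfg.n_layers)):
            lc = c["layers"][i]
            # ffn
            dgel = dx @ p[f"l{i}.W2"].T
            grads[f"l{i}.W2"] += _outer(lc["g"], dx)
            grads[f"l{i}.b2"] += dx.sum(axis=(0, 1))
            dz = dgel * _gelu_grad(lc["z"])
            grads[f"l{i}.W1"] += _outer(lc["h2"], dz)
            grads[f"l{i}.b1"] += dz.sum(axis=(0, 1))
            dh2 = dz @ p[f"l{i}.W1"].T
            dmid, dg, db = self._ln_back(dh2, lc["ln2"])
            grads[f"l{i}.ln2.g"] += dg
            grads[f"l{i}.ln2.b"] += db
            dx = dx + dmid
            # attention
            dattn = dx
            do_heads = heads(dattn @ p[f"l{i}.Wo"].T)
            grads[f"l{i}.Wo"] += _outer(unheads(lc["o"]), dattn)
            grads[f"l{i}.bo"] += dattn.sum(axis=(0, 1))
            da = do_heads @ lc["v"].transpose(0, 1, 3, 2)
            dv = lc["a"].transpose(0, 1, 3, 2) @ do_heads
            tmp = (da * lc["a"]).sum(axis=-1, keepdims=True)
            ds = lc["a"] * (da - tmp)
            if cfg.positional_encoding == "relative":
                ds_sum = ds.sum(axis=0)  # (H, L, L)
                off = lc["off"]
                for h_i in range(H):
                    grads[f"l{i}.rel_bias"][h_i] += np.bincount(
                        off.ravel(),
                        weights=ds_sum[h_i].ravel(),
                        minlength=2 * cfg.context_length - 1,
                    ).astype(self.dtype)
            dq = (ds @ lc["k"]) * scale
            dk = (ds.transpose(0, 1, 3, 2) @ lc["q"]) * scale
            if cfg.positional_encoding == "rotary":
                dq = _rotate_back(dq, c["cos"], c["sin"])
                dk = _rotate_back(dk, c["cos"], c["sin"])
            dq_flat, dk_flat, dv_flat = unheads(dq), unheads(dk), unheads(dv)
            h = lc["h"]
            dh_total = np.zeros_like(h)
            for name, dmat in (("q", dq_flat), ("k", dk_flat), ("v", dv_flat)):
                grads[f"l{i}.W{name}"] += _outer(h, dmat)
                grads[f"l{i}.b{name}"] += dmat.sum(axis=(0, 1))
                dh_total += dmat @ p[f"l{i}.W{name}"].T
            dxin, dg, db = self._ln_back(dh_total, lc["ln1"])
            grads[f"l{i}.ln1.g"] += dg
            grads[f"l{i}.ln1.b"] += db
            dx = dx + dxin
        if cfg.positional_encoding == "learnable":
            grads["pos_emb"][:L] += dx.sum(axis=0)
        np.add.at(grads["tok_emb"], tokens, dx)
        return grads

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        np.savez_compressed(path, **self.params)
        with open(path + ".json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)

    @classmethod
    def load(cls, path) -> "TransformerLM":
        path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        with open(path + ".json") as fh:
            config = ModelConfig(**json.load(fh))
        model = cls(config)
        data = np.load(path)
        for k in model.params:
            model.params[k] = data[k]
        return model


def build_model(config: ModelConfig) -> TransformerLM:
    """Seeded construction; same config (incl. seed) gives identical weights."""
    return TransformerLM(config)


def predict_logits(model: TransformerLM, token_ids: np.ndarray) -> np.ndarray:
    """Per-slot vocabulary scores under the model's objective and mask."""
    return model.forward(token_ids)


@dataclass
class CorruptedContext:
    token_ids: np.ndarray
    target_slots: np.ndarray
    target_ids: np.ndarray


def mlm_corrupt(context, config: ModelConfig, seed: int, acgt_ids=None, mask_id=3):
    """BERT-style corruption of one packed context.

    Selects exactly round(mask_rate * n_maskable) nucleotide slots (without
    replacement, seeded) and applies the 80/10/10 recipe: 80% become the
    MASK token, 10% a random nucleotide, 10% stay unchanged. Returns None
    when no slots would be selected (the context is skipped).
    """
    rng = np.random.default_rng(seed)
    tokens = np.asarray(context.token_ids, dtype=np.int64).copy()
    nuc_ids = np.asarray(acgt_ids if acgt_ids is not None else [4, 5, 6, 7])
    maskable = np.flatnonzero(np.asarray(context.loss_mask) & np.isin(tokens, nuc_ids))
    n_sel = int(round(config.mask_rate * len(maskable)))
    if n_sel == 0:
        return None
    sel = rng.choice(maskable, size=n_sel, replace=False)
    target_ids = tokens[sel].copy()
    u = rng.random(n_sel)
    mask_slots = sel[u < 0.8]
    random_slots = sel[(u >= 0.8) & (u < 0.9)]
    tokens[mask_slots] = mask_id
    if random_slots.size:
        tokens[random_slots] = rng.choice(nuc_ids, size=random_slots.size)
    return CorruptedContext(token_ids=tokens, target_slots=sel, target_ids=target_ids)
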