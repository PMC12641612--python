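"""Weighted next-token / MLM pretraining and evaluation.

Training uses plain AdamW with a fixed learning rate (no schedule — at desk
scale schedules add nothing but state). A two-phase loop first trains on a
reference-genome corpus, then mixes in a second corpus (subject reads or a
diverged genome) by drawing each phase-2 batch from it with probability
``mix_ratio``. Evaluation is next-token accuracy over nucleotide targets,
optionally restricted to variant-supporting slots, plus a generic ablation
grid runner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TransformerLM, mlm_corrupt
from .packing import PackedContext
from .tokenizer import TokenVocabulary

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    steps_phase1: int = 200
    steps_phase2: int = 0
    batch_size: int = 8
    learning_rate: float = 3e-3
    weight_decay: float = 0.01
    mix_ratio: float = 0.5  # fraction of phase-2 batches drawn from corpus B
    subset_fraction: float = 1.0  # fraction of corpus B made available
    seed: int = 0
    # optional early stop on a held-out accuracy target (used e.g. for
    # memorization checks); None disables
    eval_every: int = 0
    stop_accuracy: float | None = None

    def validate(self) -> None:
        if not 0.0 <= self.mix_ratio <= 1.0:
            raise ValueError("mix_ratio must lie in [0, 1]")
        if not 0.0 < self.subset_fraction <= 1.0:
            raise ValueError("subset_fraction must lie in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EvalResult:
    dataset: str
    next_token_accuracy: float
    n_scored_slots: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.next_token_accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.n_scored_slots <= 0:
            raise ValueError("n_scored_slots must be positive")


@dataclass
class TrainTrace:
    losses: list[float] = field(default_factory=list)
    phase_boundary: int = 0
    corpus_log: list[str] = field(default_factory=list)  # "A"/"B" per batch
    stopped_early_at: int | None = None


def weighted_loss(scores: np.ndarray, targets: np.ndarray, weights: np.ndarray):
    """Weighted mean cross-entropy: sum(w * CE) / sum(w).

    ``scores`` (n, V) are unnormalized logits; slots with weight 0 do not
    contribute. Returns (loss, dscores) so training can reuse the softmax.
    """
    scores = np.asarray(scores, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    if scores.shape[0] != targets.shape[0] or targets.shape != weights.shape:
        raise ValueError("scores, targets, weights shapes disagree")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    wsum = weights.sum()
    if wsum == 0:
        raise ValueError("all weights are zero")
    s = scores - scores.max(axis=1, keepdims=True)
    logz = np.log(np.exp(s).sum(axis=1))
    ce = logz - s[np.arange(len(targets)), targets]
    loss = float((weights * ce).sum() / wsum)
    probs = np.exp(s - logz[:, None])
    dscores = probs * weights[:, None]
    dscores[np.arange(len(targets)), targets] -= weights
    dscores /= wsum
    return loss, dscores


class AdamW:
    def __init__(self, params, lr, weight_decay=0.01, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = *betas, eps
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, p in params.items():
            g = grads[k].astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            upd = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if self.wd and p.ndim >= 2:  # decay matrices only
                upd = upd + self.wd * p.astype(np.float64)
            params[k] = (p.astype(np.float64) - self.lr * upd).astype(p.dtype)


def _stack(corpus: list[PackedContext]):
    return (
        np.stack([c.token_ids for c in corpus]),
        np.stack([c.weights for c in corpus]),
        np.stack([c.loss_mask for c in corpus]),
    )


def _causal_batch_loss(model: TransformerLM, tokens, weights):
    """Forward + backward for one causal batch; returns loss and grads."""
    logits = model.forward(tokens)
    B, L, V = logits.shape
    tgt = tokens[:, 1:].reshape(-1)
    w = weights[:, 1:].reshape(-1)
    flat = logits[:, :-1, :].reshape(-1, V)
    loss, dflat = weighted_loss(flat, tgt, w)
    dlogits = np.zeros_like(logits)
    dlogits[:, :-1, :] = dflat.reshape(B, L - 1, V)
    grads = model.backward(dlogits=dlogits)
    return loss, grads


def _mlm_batch_loss(model: TransformerLM, contexts, vocab: TokenVocabulary, seed):
    corrupted = []
    for j, ctx in enumerate(contexts):
        cc = mlm_corrupt(
            ctx, model.config, seed + j, acgt_ids=vocab.acgt_ids, mask_id=vocab.mask_id
        )
        if cc is not None:
            corrupted.append((cc, ctx))
    if not corrupted:
        raise ValueError("no maskable contexts in MLM batch")
    tokens = np.stack([cc.token_ids for cc, _ in corrupted])
    logits = model.forward(tokens)
    V = logits.shape[-1]
    rows, cols, tgts, ws = [], [], [], []
    for b, (cc, ctx) in enumerate(corrupted):
        rows.extend([b] * len(cc.target_slots))
        cols.extend(cc.target_slots)
        tgts.extend(cc.target_ids)
        ws.extend(np.asarray(ctx.weights)[cc.target_slots])
    flat = logits[rows, cols, :]
    loss, dflat = weighted_loss(flat, np.asarray(tgts), np.asarray(ws, dtype=np.float64))
    dlogits = np.zeros_like(logits)
    np.add.at(dlogits, (rows, cols), dflat.astype(dlogits.dtype))
    grads = model.backward(dlogits=dlogits)
    return loss, grads


def train_two_phase(
    model: TransformerLM,
    corpus_a: list[PackedContext],
    corpus_b: list[PackedContext] | None,
    config: TrainConfig,
    vocab: TokenVocabulary | None = None,
    eval_contexts: list[PackedContext] | None = None,
) -> TrainTrace:
    """Phase 1 samples only corpus A; phase 2 draws each batch from corpus B
    with probability ``mix_ratio`` (over the ``subset_fraction`` of B made
    available). Fully reproducible for a fixed config seed."""
    config.validate()
    if not corpus_a:
        raise ValueError("corpus A is empty")
    if config.steps_phase2 > 0 and config.mix_ratio > 0 and not corpus_b:
        raise ValueError("phase 2 with mix_ratio > 0 requires a non-empty corpus B")
    if model.config.objective == "mlm" and vocab is None:
        raise ValueError("MLM training requires the vocabulary")
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.params, config.learning_rate, config.weight_decay)
    trace = TrainTrace(phase_boundary=config.steps_phase1)

    avail_b: list[PackedContext] = []
    if corpus_b:
        n_avail = max(1, int(round(config.subset_fraction * len(corpus_b))))
        idx = rng.permutation(len(corpus_b))[:n_avail]
        avail_b = [corpus_b[i] for i in sorted(idx)]

    tok_a, w_a, _ = _stack(corpus_a)
    tok_b, w_b = (None, None)
    if avail_b:
        tok_b, w_b, _ = _stack(avail_b)

    total = config.steps_phase1 + config.steps_phase2
    for step in range(total):
        in_phase2 = step >= config.steps_phase1
        use_b = in_phase2 and avail_b and rng.random() < config.mix_ratio
        trace.corpus_log.append("B" if use_b else "A")
        tok, w, pool = (tok_b, w_b, avail_b) if use_b else (tok_a, w_a, corpus_a)
        pick = rng.integers(0, len(pool), size=config.batch_size)
        if model.config.objective == "causal":
            loss, grads = _causal_batch_loss(model, tok[pick], w[pick])
        else:
            loss, grads = _mlm_batch_loss(
                model, [pool[i] for i in pick], vocab, seed=config.seed * 100_003 + step
            )
        opt.step(model.params, grads)
        trace.losses.append(loss)
        if (
            config.eval_every
            and config.stop_accuracy is not None
            and eval_contexts
            and (step + 1) % config.eval_every == 0
        ):
            acc = next_token_accuracy(model, eval_contexts, vocab=vocab).next_token_accuracy
            if acc >= config.stop_accuracy:
                trace.stopped_early_at = step + 1
                break
    return trace


def next_token_accuracy(
    model: TransformerLM,
    contexts: list[PackedContext],
    vocab: TokenVocabulary | None = None,
    restrict_mask: list[np.ndarray] | None = None,
    dataset: str = "eval",
    batch_size: int = 16,
) -> EvalResult:
    """Accuracy of the argmax nucleotide prediction for each nucleotide slot.

    A slot t >= 1 is scored when its token is one of the four bases and its
    loss mask is set; the prediction comes from the logits at slot t-1, with
    the argmax restricted to the A/C/G/T token ids (N is an ambiguity symbol,
    not a base call, so it is excluded from targets and candidates alike).
    ``restrict_mask`` (per-context boolean arrays) optionally narrows scoring
    further, e.g. to variant-supporting slots.
    """
    if model.config.objective != "causal":
        raise ValueError("next-token accuracy is defined for causal models")
    from .tokenizer import build_vocab

    vocab = vocab or build_vocab()
    nuc = np.asarray(vocab.acgt_ids)
    correct = 0
    scored = 0
    for lo in range(0, len(contexts), batch_size):
        chunk = contexts[lo : lo + batch_size]
        tokens = np.stack([c.token_ids for c in chunk])
        mask = np.stack([c.loss_mask for c in chunk])
        logits = model.forward(tokens)
        sub = logits[:, :-1, :][:, :, nuc]
        pred = nuc[np.argmax(sub, axis=-1)]
        tgt = tokens[:, 1:]
        ok = mask[:, 1:] & np.isin(tgt, nuc)
        if restrict_mask is not None:
            extra = np.stack([m for m in restrict_mask[lo : lo + batch_size]])
            ok &= extra[:, 1:]
        correct += int((pred[ok] == tgt[ok]).sum())
        scored += int(ok.sum())
    if scored == 0:
        raise ValueError("no scorable slots")
    return EvalResult(dataset, correct / scored, scored)


def mlm_accuracy(
    model: TransformerLM,
    contexts: list[PackedContext],
    vocab: TokenVocabulary,
    seed: int = 0,
    dataset: str = "eval",
) -> EvalResult:
    """Masked-token recovery accuracy for MLM models (the analogue of
    next-token accuracy under the bidirectional objective)."""
    nuc = np.asarray(vocab.acgt_ids)
    correct = scored = 0
    for j, ctx in enumerate(contexts):
        cc = mlm_corrupt(ctx, model.config, seed + j, acgt_ids=vocab.acgt_ids, mask_id=vocab.mask_id)
        if cc is None:
            continue
        logits = model.forward(cc.token_ids[None, :])[0]
        sub = logits[cc.target_slots][:, nuc]
        pred = nuc[np.argmax(sub, axis=-1)]
        correct += int((pred == cc.target_ids).sum())
        scored += len(cc.target_slots)
    if scored == 0:
        raise ValueError("no scorable slots")
    return EvalResult(dataset, correct / scored, scored)


def variant_slot_masks(contexts: list[PackedContext], ref) -> list[np.ndarray]:
    """Per-context boolean masks marking slots whose token differs from the
    reference base at the slot's genomic position (variant-supporting slots)."""
    from .tokenizer import build_vocab

    vocab = build_vocab()
    base_id = {b: vocab.symbol_to_id[b] for b in "ACGT"}
    masks = []
    for ctx in contexts:
        m = np.zeros(len(ctx.token_ids), dtype=bool)
        nuc = ctx.loss_mask & (np.asarray(ctx.positions) >= 0)
        for slot in np.flatnonzero(nuc):
            contig = ctx.contig_names[int(ctx.contig_index[slot])]
            refbase = ref.sequence(contig)[int(ctx.positions[slot])]
            m[slot] = int(ctx.token_ids[slot]) != base_id[refbase]
        masks.append(m)
    return masks


def run_ablation_grid(axes: dict[str, list], runner, base: dict | None = None) -> pd.DataFrame:
    """Train/evaluate one cell per combination of axis values.

    ``runner(cell)`` receives a dict of axis values (merged over ``base``)
    and returns {eval_set_name: accuracy}. Failures are recorded per cell
    and the grid continues. The result is long-format: one row per
    (cell, eval set)."""
    names = list(axes)
    rows = []

    def product(i, cell):
        if i == len(names):
            yield dict(cell)
            return
        for v in axes[names[i]]:
            cell[names[i]] = v
            yield from product(i + 1, cell)
        cell.pop(names[i], None)

    for cell in product(0, {}):
        full = {**(base or {}), **cell}
        try:
            results = runner(full)
            for eval_name, acc in results.items():
                rows.append({**cell, "eval_set": eval_name, "accuracy": acc, "error": None})
        except Exception as exc:  # record and continue
            log.warning("grid cell %s failed: %s", cell, exc)
            rows.append({**cell, "eval_set": None, "accuracy": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)


def render_matrix(df: pd.DataFrame, row_axis: str) -> str:
    """Pivot a grid result into a text matrix (rows: axis, cols: eval set)."""
    pivot = df.dropna(subset=["eval_set"]).pivot_table(
        index=row_axis, columns="eval_set", values="accuracy"
    )
    return pivot.to_string(float_format=lambda v: f"{100 * v:.2f}")
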