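"""Downstream variant-classification evaluation.

Benchmarks follow the variant-centered pattern: a fixed-length reference
window around each variant with the alternate allele substituted in
(positives) and windows at random non-variant positions left intact
(controls). Datasets are split 70/12/18 (train/validation/test), classifier
heads are fine-tuned end to end and scored with the Matthews correlation
coefficient, and frozen per-layer embeddings are probed with a small MLP
under stratified 10-fold cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core import ReferenceGenome, VariantTable
from .model import TransformerLM
from .pretrain import AdamW, weighted_loss
from .tokenizer import TokenVocabulary, build_vocab, encode_array


@dataclass(frozen=True)
class DatasetRecord:
    sequence: str
    label: int
    origin: str  # "variant:<contig>:<pos>:<ref>><alt>" or "control:<contig>:<pos>"


@dataclass
class ClassificationDataset:
    records: list[DatasetRecord]

    def __post_init__(self) -> None:
        if self.records:
            lens = {len(r.sequence) for r in self.records}
            if len(lens) != 1:
                raise ValueError("all sequences must have equal length")
            labels = sorted({r.label for r in self.records})
            if len(labels) < 2:
                raise ValueError("dataset must contain at least two classes")
            if labels != list(range(len(labels))):
                raise ValueError("labels must be dense from 0")

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    def subset(self, idx) -> "ClassificationDataset":
        ds = ClassificationDataset.__new__(ClassificationDataset)
        ds.records = [self.records[i] for i in idx]
        return ds


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.70
    validation: float = 0.12
    test: float = 0.18
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if min(self.train, self.validation, self.test) <= 0:
            raise ValueError("split fractions must be positive")
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def build_variant_benchmark(
    variants: VariantTable,
    ref: ReferenceGenome,
    window: int,
    controls: int,
    seed: int = 0,
) -> ClassificationDataset:
    """One positive record per variant plus seeded control windows.

    Positive: the reference window centered on the variant position with the
    alternate allele substituted at the variant position; near contig edges
    the window is shifted inward (the variant then sits off-center, never
    padded). Controls: intact reference windows centered on random
    non-variant positions. Labels: control = 0, variant classes = 1..K in
    sorted label order.
    """
    lengths = ref.lengths()
    if window > min(lengths.values()):
        raise ValueError("window exceeds the smallest contig")
    half = window // 2
    var_positions = variants.positions()
    var_labels = sorted({r.label for r in variants})
    label_id = {lab: i + 1 for i, lab in enumerate(var_labels)}

    def window_start(contig: str, pos: int) -> int:
        start = pos - half
        return max(0, min(start, lengths[contig] - window))

    records = []
    for r in variants:
        seq = ref.sequence(r.contig)
        if r.position >= len(seq):
            raise ValueError(f"variant position {r.contig}:{r.position} absent from ref")
        if seq[r.position] != r.ref_allele:
            raise ValueError(
                f"variant {r.contig}:{r.position}: ref allele mismatch"
            )
        s = window_start(r.contig, r.position)
        chars = list(seq[s : s + window])
        chars[r.position - s] = r.alt_allele
        records.append(
            DatasetRecord(
                "".join(chars),
                label_id[r.label],
                f"variant:{r.contig}:{r.position}:{r.ref_allele}>{r.alt_allele}",
            )
        )

    rng = np.random.default_rng(seed)
    names = ref.names
    n_placed = 0
    while n_placed < controls:
        contig = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(0, lengths[contig]))
        if (contig, pos) in var_positions:
            continue
        s = window_start(contig, pos)
        records.append(
            DatasetRecord(ref.sequence(contig)[s : s + window], 0, f"control:{contig}:{pos}")
        )
        n_placed += 1
    return ClassificationDataset(records)


def split_dataset(ds: ClassificationDataset, spec: SplitSpec):
    """Disjoint (train, validation, test) with sizes round(f*n), remainder
    to test; stratified per class when enabled."""
    spec.validate()
    n = len(ds)
    if n < 10:
        raise ValueError("dataset too small to split")
    rng = np.random.default_rng(spec.seed)
    labels = ds.labels()

    def cut(idx: np.ndarray):
        m = len(idx)
        n_tr = round(spec.train * m)
        n_va = round(spec.validation * m)
        if n_tr < 1 or n_va < 1 or m - n_tr - n_va < 1:
            raise ValueError("a class is too small for stratified splitting")
        shuffled = idx[rng.permutation(m)]
        return shuffled[:n_tr], shuffled[n_tr : n_tr + n_va], shuffled[n_tr + n_va :]

    if spec.stratified:
        tr, va, te = [], [], []
        for cls in np.unique(labels):
            a, b, c = cut(np.flatnonzero(labels == cls))
            tr.append(a), va.append(b), te.append(c)
        tr, va, te = (np.sort(np.concatenate(x)) for x in (tr, va, te))
    else:
        tr, va, te = cut(np.arange(n))
    return ds.subset(tr), ds.subset(va), ds.subset(te)


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation from 2x2 confusion counts; 0 when any
    denominator factor vanishes (degenerate predictions)."""
    if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
        raise ValueError("counts must be non-negative with a positive total")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_from_predictions(y_true, y_pred) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return mcc(tp, fp, fn, tn)


# ---------------------------------------------------------------------------
# Embeddings, fine-tuning, probing


def _tokenize_batch(sequences: list[str], vocab: TokenVocabulary) -> np.ndarray:
    rows = [np.concatenate(([vocab.bos_id], encode_array(s, vocab))) for s in sequences]
    return np.stack(rows)


def _pool(hidden: np.ndarray, tokens: np.ndarray, pad_id: int) -> np.ndarray:
    """Mean over non-PAD slots: (B, L, d) -> (B, d)."""
    keep = (tokens != pad_id).astype(hidden.dtype)
    return (hidden * keep[:, :, None]).sum(axis=1) / keep.sum(axis=1, keepdims=True)


def extract_layer_embeddings(
    model: TransformerLM,
    sequences: list[str],
    layer_index: int,
    vocab: TokenVocabulary | None = None,
    batch_size: int = 32,
) -> np.ndarray:
    """Mean-pooled residual-stream embeddings at one layer (frozen backbone).

    Layer 0 is the post-embedding representation; layer i the output of
    block i. Deterministic; the backbone is never modified.
    """
    if not 0 <= layer_index <= model.config.n_layers:
        raise ValueError(
            f"layer_index {layer_index} out of range [0, {model.config.n_layers}]"
        )
    vocab = vocab or build_vocab()
    out = []
    for lo in range(0, len(sequences), batch_size):
        tokens = _tokenize_batch(sequences[lo : lo + batch_size], vocab)
        hidden = model.hidden_states(tokens)[layer_index]
        out.append(_pool(hidden, tokens, vocab.pad_id))
    return np.concatenate(out, axis=0)


@dataclass(frozen=True)
class FinetuneConfig:
    steps: int = 400
    batch_size: int = 16
    learning_rate: float = 3e-4
    eval_every: int = 50
    freeze_backbone: bool = False
    seed: int = 0


@dataclass
class FinetuneResult:
    test_mcc: float
    best_val_mcc: float
    head: dict = field(repr=False, default_factory=dict)
    val_trace: list[float] = field(default_factory=list)


def _head_predict(model, head, sequences, vocab, batch_size=32):
    preds = []
    for lo in range(0, len(sequences), batch_size):
        tokens = _tokenize_batch(sequences[lo : lo + batch_size], vocab)
        model.forward(tokens)
        pooled = _pool(model._cache["xf"], tokens, vocab.pad_id)
        preds.append(np.argmax(pooled @ head["W"] + head["b"], axis=1))
    return np.concatenate(preds)


def finetune_classifier(
    model: TransformerLM,
    ds: ClassificationDataset,
    spec: SplitSpec,
    config: FinetuneConfig,
    vocab: TokenVocabulary | None = None,
) -> FinetuneResult:
    """Linear head on mean-pooled final-layer states, full fine-tuning.

    The backbone is updated unless ``freeze_backbone``; the checkpoint with
    the best validation MCC is kept and the test MCC is computed once on it.
    Binary tasks only (MCC is the selection metric).
    """
    vocab = vocab or build_vocab()
    train, val, test = split_dataset(ds, spec)
    y_train = train.labels()
    n_classes = int(ds.labels().max()) + 1
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")
    if n_classes != 2:
        raise ValueError("finetune_classifier supports binary tasks")
    rng = np.random.default_rng(config.seed)
    d = model.config.d_model
    head = {
        "W": rng.normal(0, 0.02, size=(d, n_classes)).astype(model.dtype),
        "b": np.zeros(n_classes, dtype=model.dtype),
    }
    opt_head = AdamW(head, config.learning_rate, weight_decay=0.0)
    opt_body = None if config.freeze_backbone else AdamW(
        model.params, config.learning_rate, weight_decay=0.01
    )
    seqs = train.sequences()
    best = {"mcc": -2.0, "head": None, "params": None}
    result = FinetuneResult(test_mcc=0.0, best_val_mcc=-2.0)

    def evaluate(split):
        pred = _head_predict(model, head, split.sequences(), vocab)
        return mcc_from_predictions(split.labels(), pred)

    for step in range(config.steps):
        pick = rng.integers(0, len(seqs), size=config.batch_size)
        tokens = _tokenize_batch([seqs[i] for i in pick], vocab)
        model.forward(tokens)
        pooled = _pool(model._cache["xf"], tokens, vocab.pad_id)
        logits = pooled @ head["W"] + head["b"]
        loss, dlogits = weighted_loss(
            logits, y_train[pick], np.ones(len(pick))
        )
        dlogits = dlogits.astype(model.dtype)
        ghead = {
            "W": pooled.T @ dlogits,
            "b": dlogits.sum(axis=0),
        }
        dpooled = dlogits @ head["W"].T
        keep = (tokens != vocab.pad_id).astype(model.dtype)
        d_hidden = (
            dpooled[:, None, :] * keep[:, :, None] / keep.sum(axis=1)[:, None, None]
        )
        if opt_body is not None:
            grads = model.backward(d_hidden_final=d_hidden)
            opt_body.step(model.params, grads)
        opt_head.step(head, ghead)
        if (step + 1) % config.eval_every == 0 or step + 1 == config.steps:
            val_mcc = evaluate(val)
            result.val_trace.append(val_mcc)
            if val_mcc > best["mcc"]:
                best.update(
                    mcc=val_mcc,
                    head={k: v.copy() for k, v in head.items()},
                    params={k: v.copy() for k, v in model.params.items()},
                )
    if best["head"] is not None:
        head = best["head"]
        model.params = best["params"]
    result.best_val_mcc = best["mcc"]
    result.head = head
    pred = _head_predict(model, head, test.sequences(), vocab)
    result.test_mcc = mcc_from_predictions(test.labels(), pred)
    return result


@dataclass
class ProbeReport:
    per_layer_mcc: dict[int, list[float]]
    folds: int

    def __post_init__(self) -> None:
        for layer, vals in self.per_layer_mcc.items():
            if len(vals) != self.folds:
                raise ValueError(f"layer {layer}: expected {self.folds} folds")
            if any(not -1.0 <= v <= 1.0 for v in vals):
                raise ValueError("MCC out of [-1, 1]")

    def median(self, layer: int) -> float:
        return float(np.median(self.per_layer_mcc[layer]))


def probe_layers(
    model: TransformerLM,
    ds: ClassificationDataset,
    folds: int = 10,
    seed: int = 0,
    vocab: TokenVocabulary | None = None,
    hidden_width: int = 64,
) -> ProbeReport:
    """Stratified k-fold CV of a two-layer MLP probe on each layer's frozen
    mean-pooled embeddings (layers 0..n_layers). The backbone is read-only."""
    vocab = vocab or build_vocab()
    labels = ds.labels()
    if len(np.unique(labels)) != 2:
        raise ValueError("probing supports binary tasks")
    counts = np.bincount(labels)
    if counts.min() < folds:
        raise ValueError("each class needs at least `folds` members")
    sequences = ds.sequences()
    report: dict[int, list[float]] = {}
    for layer in range(model.config.n_layers + 1):
        emb = extract_layer_embeddings(model, sequences, layer, vocab=vocab)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_mcc = []
        for tr_idx, te_idx in skf.split(emb, labels):
            # raw embedding scales vary by orders of magnitude across layers;
            # standardization keeps the probe's optimizer in a workable regime
            clf = make_pipeline(
                StandardScaler(),
                MLPClassifier(
                    hidden_layer_sizes=(hidden_width,),
                    max_iter=500,
                    random_state=seed,
                    n_iter_no_change=10,
                    tol=1e-4,
                ),
            )
            clf.fit(emb[tr_idx], labels[tr_idx])
            fold_mcc.append(mcc_from_predictions(labels[te_idx], clf.predict(emb[te_idx])))
        report[layer] = fold_mcc
    return ProbeReport(per_layer_mcc=report, folds=folds)
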