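"""Benchmark construction, splitting, MCC, fine-tuning, and probing."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from exolm import simdata, tasks
from exolm.core import VariantRecord, VariantTable
from exolm.model import ModelConfig, TransformerLM
from exolm.tasks import (
    ClassificationDataset,
    DatasetRecord,
    FinetuneConfig,
    SplitSpec,
    build_variant_benchmark,
    extract_layer_embeddings,
    finetune_classifier,
    mcc,
    probe_layers,
    split_dataset,
)

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


def _variant_at(ref, pos, label="v"):
    seq = ref.sequence("contig0")
    alt = "A" if seq[pos] != "A" else "G"
    return VariantRecord("contig0", pos, seq[pos], alt, label=label)


# -- benchmark construction -------------------------------------------------


def test_positive_window_centers_the_alt_allele(tiny_ref):
    rec = _variant_at(tiny_ref, 1000)
    ds = build_variant_benchmark(VariantTable([rec]), tiny_ref, window=11, controls=1, seed=0)
    seq = tiny_ref.sequence("contig0")
    pos_rec = [r for r in ds.records if r.label == 1][0]
    want = seq[995:1000] + rec.alt_allele + seq[1001:1006]
    assert pos_rec.sequence == want


def test_cardinality_and_labels(tiny_ref):
    variants = VariantTable([_variant_at(tiny_ref, p) for p in range(100, 1100, 100)])
    ds = build_variant_benchmark(variants, tiny_ref, window=11, controls=5, seed=0)
    assert len(ds) == 15
    assert sorted({r.label for r in ds.records}) == [0, 1]


def test_edge_windows_shift_inward(tiny_ref):
    rec = _variant_at(tiny_ref, 2)
    ds = build_variant_benchmark(VariantTable([rec]), tiny_ref, window=11, controls=1, seed=0)
    pos_rec = [r for r in ds.records if r.label == 1][0]
    assert len(pos_rec.sequence) == 11
    seq = tiny_ref.sequence("contig0")
    assert pos_rec.sequence == seq[0:2] + rec.alt_allele + seq[3:11]


def test_controls_are_leak_free(tiny_ref):
    variants = VariantTable([_variant_at(tiny_ref, p) for p in range(100, 600, 100)])
    ds = build_variant_benchmark(variants, tiny_ref, window=21, controls=50, seed=1)
    seq = tiny_ref.sequence("contig0")
    for r in ds.records:
        if r.label == 0:
            _, contig, pos = r.origin.split(":")
            start = min(max(0, int(pos) - 10), 2000 - 21)
            assert r.sequence == seq[start : start + 21]  # reference intact


def test_variant_position_absent_errors(tiny_ref):
    bad = VariantTable([VariantRecord("contig0", 5000, "A", "G")])
    with pytest.raises(ValueError):
        build_variant_benchmark(bad, tiny_ref, window=11, controls=0, seed=0)


# -- splitting --------------------------------------------------------------


def test_split_sizes_70_12_18():
    recs = [DatasetRecord("ACGT", i % 2, str(i)) for i in range(10_000)]
    tr, va, te = split_dataset(ClassificationDataset(recs), SplitSpec(stratified=False, seed=0))
    assert (len(tr), len(va), len(te)) == (7000, 1200, 1800)


def test_split_is_seeded_partition():
    recs = [DatasetRecord("ACGT", i % 2, str(i)) for i in range(500)]
    ds = ClassificationDataset(recs)
    a = split_dataset(ds, SplitSpec(seed=4))
    b = split_dataset(ds, SplitSpec(seed=4))
    for x, y in zip(a, b):
        assert [r.origin for r in x.records] == [r.origin for r in y.records]
    origins = [r.origin for part in a for r in part.records]
    assert sorted(origins) == sorted(r.origin for r in recs)  # disjoint union


def test_stratified_split_preserves_balance():
    recs = [DatasetRecord("ACGT", 0, f"a{i}") for i in range(250)] + [
        DatasetRecord("ACGT", 1, f"b{i}") for i in range(250)
    ]
    tr, va, te = split_dataset(ClassificationDataset(recs), SplitSpec(seed=1))
    for part in (tr, va, te):
        labels = part.labels()
        assert abs((labels == 0).sum() - (labels == 1).sum()) <= 1


def test_split_errors():
    small = ClassificationDataset([DatasetRecord("A", i % 2, str(i)) for i in range(6)])
    with pytest.raises(ValueError, match="too small"):
        split_dataset(small, SplitSpec())
    lop = ClassificationDataset(
        [DatasetRecord("A", 0, str(i)) for i in range(20)]
        + [DatasetRecord("A", 1, "x"), DatasetRecord("A", 1, "y")]
    )
    with pytest.raises(ValueError, match="class"):
        split_dataset(lop, SplitSpec())
    with pytest.raises(ValueError, match="sum to 1"):
        SplitSpec(train=0.5, validation=0.2, test=0.2).validate()


# -- MCC --------------------------------------------------------------------


def test_mcc_examples():
    assert mcc(tp=50, fp=0, fn=0, tn=50) == 1.0
    assert mcc(tp=50, fp=50, fn=0, tn=0) == 0.0  # all predictions one class
    want = (40 * 45 - 10 * 5) / np.sqrt((40 + 10) * (40 + 5) * (45 + 10) * (45 + 5))
    assert mcc(tp=40, fp=10, fn=5, tn=45) == pytest.approx(want, rel=1e-12)


def test_mcc_agrees_with_sklearn_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        tp, fp, fn, tn = (int(x) for x in rng.integers(0, 30, 4))
        if tp + fp + fn + tn == 0:
            continue
        y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        assert mcc(tp, fp, fn, tn) == pytest.approx(
            matthews_corrcoef(y_true, y_pred), abs=1e-12
        )


# -- embeddings / fine-tuning / probing -------------------------------------


@pytest.fixture(scope="module")
def toy_backbone():
    return TransformerLM(
        ModelConfig(n_layers=2, d_model=32, n_heads=2, vocab_size=9, context_length=64, seed=1)
    )


def _center_rule_dataset(n_per_class=100, window=9, seed=0):
    """Label decided by the single base at the window center."""
    rng = np.random.default_rng(seed)
    half = window // 2

    def win(center):
        s = "".join(rng.choice(list("ACGT"), size=window))
        return s[:half] + center + s[half + 1 :]

    recs = [DatasetRecord(win("A"), 1, f"v{i}") for i in range(n_per_class)] + [
        DatasetRecord(win("G"), 0, f"c{i}") for i in range(n_per_class)
    ]
    return ClassificationDataset(recs)


def _composition_dataset(n_per_class=30, length=40, seed=0):
    """GC-rich vs AT-rich sequences: linearly separable from pooled input."""
    rng = np.random.default_rng(seed)

    def seq(gc):
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list("ACGT"), p=p, size=length))

    recs = [DatasetRecord(seq(0.15), 0, f"c{i}") for i in range(n_per_class)] + [
        DatasetRecord(seq(0.85), 1, f"v{i}") for i in range(n_per_class)
    ]
    return ClassificationDataset(recs)


def test_embedding_shapes_layer_range_and_determinism(toy_backbone):
    seqs = ["ACGTACGT", "ACGTACGT", "GGGGCCCC"]
    for layer in range(toy_backbone.config.n_layers + 1):
        emb = extract_layer_embeddings(toy_backbone, seqs, layer)
        assert emb.shape == (3, 32)
    assert (emb[0] == emb[1]).all()  # identical sequences, identical vectors
    with pytest.raises(ValueError, match="layer_index"):
        extract_layer_embeddings(toy_backbone, seqs, 3)


def test_finetune_learns_center_base_rule():
    ds = _center_rule_dataset()
    model = TransformerLM(
        ModelConfig(n_layers=2, d_model=32, n_heads=2, vocab_size=9, context_length=16, seed=2)
    )
    res = finetune_classifier(
        model, ds, SplitSpec(seed=0), FinetuneConfig(steps=500, batch_size=32, seed=0)
    )
    assert res.test_mcc > 0.9


def test_finetune_on_random_labels_sits_near_zero():
    rng = np.random.default_rng(7)
    ds = _center_rule_dataset(n_per_class=150, seed=3)
    shuffled = rng.permutation(ds.labels())
    ds = ClassificationDataset(
        [DatasetRecord(r.sequence, int(l), r.origin) for r, l in zip(ds.records, shuffled)]
    )
    model = TransformerLM(
        ModelConfig(n_layers=2, d_model=32, n_heads=2, vocab_size=9, context_length=16, seed=2)
    )
    res = finetune_classifier(
        model, ds, SplitSpec(seed=0), FinetuneConfig(steps=200, batch_size=32, seed=0)
    )
    # permutation-null band ~ 2.5 / sqrt(n_test) at n_test = 54
    assert abs(res.test_mcc) < 0.35


def test_freeze_flag_controls_backbone_updates():
    ds = _center_rule_dataset(n_per_class=30, seed=5)
    for freeze in (True, False):
        model = TransformerLM(
            ModelConfig(n_layers=1, d_model=16, n_heads=2, vocab_size=9, context_length=16, seed=2)
        )
        before = {k: v.copy() for k, v in model.params.items()}
        finetune_classifier(
            model, ds, SplitSpec(seed=0),
            FinetuneConfig(steps=10, batch_size=8, freeze_backbone=freeze, seed=0),
        )
        unchanged = all((model.params[k] == before[k]).all() for k in before)
        assert unchanged == freeze


def test_probe_report_shape_and_frozen_backbone(toy_backbone):
    ds = _composition_dataset(n_per_class=15)
    before = {k: v.copy() for k, v in toy_backbone.params.items()}
    report = probe_layers(toy_backbone, ds, folds=3, seed=0)
    assert set(report.per_layer_mcc) == {0, 1, 2}
    assert all(len(v) == 3 for v in report.per_layer_mcc.values())
    assert all((toy_backbone.params[k] == before[k]).all() for k in before)


def test_probe_separates_separable_fixture(toy_backbone):
    report = probe_layers(toy_backbone, _composition_dataset(), folds=10, seed=0)
    for layer in range(3):
        assert report.median(layer) > 0.95


def test_probe_requires_enough_members_per_class(toy_backbone):
    ds = _composition_dataset(n_per_class=5)
    with pytest.raises(ValueError, match="folds"):
        probe_layers(toy_backbone, ds, folds=10, seed=0)
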