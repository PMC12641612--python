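"""Packing strategies against hand oracles; shape and conservation laws."""

import numpy as np
import pytest

from exolm import packing
from exolm.packing import PackingConfig, load_shard, save_shard
from exolm.tokenizer import encode

from conftest import make_read


def _reads_at(ref, starts, length=151, contig="toy"):
    seq = ref.sequence(contig)
    return [
        make_read(contig, s, seq[s : s + length], read_id=f"r{i:03d}")
        for i, s in enumerate(starts)
    ]


def _layout_oracle(reads, vocab, L):
    """Independent layout oracle: BOS + (read + SEP)* + PAD, greedy fill."""
    contexts, cur = [], [vocab.bos_id]
    for r in reads:
        toks = encode(r.bases, vocab)
        if len(cur) + len(toks) + 1 > L:
            contexts.append(cur + [vocab.pad_id] * (L - len(cur)))
            cur = [vocab.bos_id]
        cur += toks + [vocab.sep_id]
    if len(cur) > 1:
        contexts.append(cur + [vocab.pad_id] * (L - len(cur)))
    return contexts


def test_single_read_layout(toy_ref, vocab):
    [read] = _reads_at(toy_ref, [0], length=151)
    cfg = PackingConfig("consecutive", 1024)
    [ctx] = packing.pack_consecutive([read], vocab, cfg)
    assert len(ctx) == 1024
    assert ctx.token_ids[0] == vocab.bos_id
    assert list(ctx.token_ids[1:152]) == encode(read.bases, vocab)
    assert ctx.token_ids[152] == vocab.sep_id
    assert (ctx.token_ids[153:] == vocab.pad_id).all()
    # positions/coordinates bookkeeping
    assert list(ctx.positions[1:152]) == list(range(151))
    assert ctx.positions[0] == -1 and ctx.positions[152] == -1


def test_consecutive_matches_layout_oracle(toy_ref, vocab):
    reads = _reads_at(toy_ref, [5, 30, 60, 100, 140, 0, 200, 220, 180, 240], length=40)
    cfg = PackingConfig("consecutive", context_length=100)
    got = packing.pack_consecutive(reads, vocab, cfg)
    ordered = sorted(reads, key=lambda r: (r.contig, r.start, r.read_id))
    want = _layout_oracle(ordered, vocab, 100)
    assert [list(c.token_ids) for c in got] == want


def test_empty_read_list(vocab):
    assert packing.pack_consecutive([], vocab, PackingConfig("consecutive", 1024)) == []


def test_oversized_read_rejected(toy_ref, vocab):
    reads = _reads_at(toy_ref, [0], length=151)
    # a 151-bp read exactly fills L=153 (BOS + read + SEP) ...
    [ctx] = packing.pack_consecutive(reads, vocab, PackingConfig("consecutive", 153))
    assert ctx.token_ids[-1] == vocab.sep_id
    # ... but overflows L=152
    with pytest.raises(ValueError, match="capacity"):
        packing.pack_consecutive(reads, vocab, PackingConfig("consecutive", 152))


@pytest.mark.parametrize("strategy", ["consecutive", "random", "spaced"])
def test_read_id_conservation(toy_ref, vocab, strategy):
    reads = _reads_at(toy_ref, [0, 10, 20, 30, 100, 150, 200, 249], length=30)
    cfg = PackingConfig(strategy, context_length=80, seed=3)
    contexts = packing.pack(reads, toy_ref, vocab, cfg)
    packed = sorted(rid for c in contexts for rid in c.read_ids)
    assert packed == sorted(r.read_id for r in reads)


def test_random_is_seeded_and_explores_orders(toy_ref, vocab):
    reads = _reads_at(toy_ref, [0, 60], length=30)
    cfg = PackingConfig("random", 100, seed=5)
    a = packing.pack_random(reads, vocab, cfg)
    b = packing.pack_random(reads, vocab, cfg)
    assert [list(c.token_ids) for c in a] == [list(c.token_ids) for c in b]
    orders = {
        tuple(packing.pack_random(reads, vocab, PackingConfig("random", 100, seed=s))[0].read_ids)
        for s in range(1, 21)
    }
    assert orders == {("r000", "r001"), ("r001", "r000")}


def test_spaced_rejects_overlap_within_context(toy_ref, vocab):
    r1, r2 = _reads_at(toy_ref, [0, 100], length=151)
    # overlap by 51 bp
    r1, r2 = _reads_at(toy_ref, [0, 100], length=151)
    ctxs = packing.pack_spaced([r1, r2], vocab, PackingConfig("spaced", 400))
    assert len(ctxs) == 2  # second read carried to the next pass
    disjoint = _reads_at(toy_ref, [0, 200], length=151)
    ctxs = packing.pack_spaced(disjoint, vocab, PackingConfig("spaced", 400))
    assert len(ctxs) == 1 and len(ctxs[0].read_ids) == 2


def test_spaced_contexts_are_pairwise_disjoint(toy_ref, vocab):
    rng = np.random.default_rng(8)
    starts = sorted(int(s) for s in rng.integers(0, 360, size=30))
    reads = _reads_at(toy_ref, starts, length=40)
    contexts = packing.pack_spaced(reads, vocab, PackingConfig("spaced", 200))
    by_id = {r.read_id: r for r in reads}
    packed_ids = []
    for ctx in contexts:
        intervals = [(by_id[i].start, by_id[i].end) for i in ctx.read_ids]
        for (s1, e1) in intervals:
            for (s2, e2) in intervals:
                if (s1, e1) != (s2, e2):
                    assert e1 <= s2 or e2 <= s1, "overlap within a context"
        packed_ids += list(ctx.read_ids)
    assert sorted(packed_ids) == sorted(r.read_id for r in reads)


def test_overlap_merge_lengths_and_majority(toy_ref, vocab):
    seq = toy_ref.sequence("toy")
    # two agreeing reads overlapping by 10 bp -> one 292-bp segment
    a = make_read("toy", 0, seq[0:151], read_id="a")
    b = make_read("toy", 141, seq[141:292], read_id="b")
    ctxs = packing.pack_overlapping([a, b], toy_ref, vocab, PackingConfig("overlapping", 512))
    nuc = ctxs[0].positions[ctxs[0].positions >= 0]
    assert len(nuc) == 292

    # disagreement at one position: 2 reads vs 1 -> majority base wins
    pos = 50
    wrong = "A" if seq[pos] != "A" else "C"
    c = make_read("toy", 0, seq[0:151], read_id="c")
    d = make_read("toy", 10, seq[10:161], read_id="d")
    mut = list(seq[20:171])
    mut[pos - 20] = wrong
    e = make_read("toy", 20, "".join(mut), read_id="e")
    [ctx] = packing.pack_overlapping([c, d, e], toy_ref, vocab, PackingConfig("overlapping", 512))
    slot = int(np.flatnonzero(ctx.positions == pos)[0])
    assert ctx.token_ids[slot] == vocab.symbol_to_id[seq[pos]]  # 2:1 keeps ref base


def test_overlap_tiling_reconstructs_donor(toy_ref, vocab):
    seq = toy_ref.sequence("toy")
    # 20 error-free reads tiling 0..400 with overlaps -> merged = donor slice
    starts = list(range(0, 380, 20))
    reads = [make_read("toy", s, seq[s : s + 21], read_id=f"t{s:03d}") for s in starts]
    ctxs = packing.pack_overlapping(reads, toy_ref, vocab, PackingConfig("overlapping", 512))
    text = "".join(
        vocab.id_to_symbol[int(t)]
        for c in ctxs
        for t, p in zip(c.token_ids, c.positions)
        if p >= 0
    )
    assert text == seq[0:381]


def test_reference_packing_chunks_and_positions(vocab):
    from exolm.core import ReferenceGenome

    rng = np.random.default_rng(1)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
    ref = ReferenceGenome([("c0", seq)])
    ctxs = packing.pack_reference(ref, vocab, PackingConfig("reference", 1024))
    assert len(ctxs) == 10  # ceil(10000 / 1022)
    text = "".join(
        vocab.id_to_symbol[int(t)]
        for c in ctxs
        for t, p in zip(c.token_ids, c.positions)
        if p >= 0
    )
    assert text == seq
    assert list(ctxs[0].positions[1:10]) == list(range(9))


def test_context_shape_and_mask_invariants(toy_ref, vocab):
    reads = _reads_at(toy_ref, [0, 40, 80, 120], length=30)
    for strategy in packing.STRATEGIES:
        cfg = PackingConfig(strategy, 100, seed=2)
        for ctx in packing.pack(reads, toy_ref, vocab, cfg):
            assert len(ctx) == 100
            is_pad = ctx.token_ids == vocab.pad_id
            is_bos = ctx.token_ids == vocab.bos_id
            assert (ctx.loss_mask == ~(is_pad | is_bos)).all()
            assert (ctx.weights[~ctx.loss_mask] == 0).all()
            assert (ctx.weights[ctx.loss_mask] == 1).all()


def test_consecutive_positions_monotone_within_context(toy_ref, vocab):
    reads = _reads_at(toy_ref, [0, 10, 25, 60, 90, 130], length=30)
    for ctx in packing.pack_consecutive(reads, vocab, PackingConfig("consecutive", 120)):
        pos = ctx.positions[ctx.positions >= 0]
        # read starts ascend; within-read positions ascend
        starts = [pos[i] for i in range(len(pos)) if i == 0 or pos[i] < pos[i - 1]]
        assert starts == sorted(starts)


def test_shard_round_trip(tmp_path, toy_ref, vocab):
    reads = _reads_at(toy_ref, [0, 40, 80], length=30)
    cfg = PackingConfig("consecutive", 100)
    ctxs = packing.pack_consecutive(reads, vocab, cfg)
    save_shard(ctxs, tmp_path / "shard", cfg)
    back = load_shard(tmp_path / "shard")
    assert len(back) == len(ctxs)
    for a, b in zip(ctxs, back):
        assert (a.token_ids == b.token_ids).all()
        assert (a.positions == b.positions).all()
        assert (a.loss_mask == b.loss_mask).all()
        assert (a.weights == b.weights).all()
        assert a.contig_names == b.contig_names
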