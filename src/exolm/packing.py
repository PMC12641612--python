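"""Assemble 151-bp reads into fixed-length token contexts.

Five preparations of the same underlying reads are supported:

* ``consecutive`` — reads in ascending genomic order;
* ``random`` — a seeded uniform shuffle of each contig's reads;
* ``spaced`` — greedy non-overlapping selection, repeated in passes, so each
  context covers spread-out positions;
* ``overlapping`` — maximal overlapping/abutting read chains merged into
  contiguous consensus segments (majority base, ties to the reference);
* ``reference`` — the reference genome itself, chunked.

Every context is laid out as ``BOS, tokens..., SEP-terminated units, PAD``;
a read is never split across contexts (merged segments are instead split at
the payload capacity). Contexts never mix contigs. The loss mask is False
exactly on PAD and BOS slots; weights default to 1 there and 0 elsewhere
(see :mod:`exolm.weighting` for the dynamic alternative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import AlignedRead, ReferenceGenome
from .tokenizer import TokenVocabulary, encode_array

STRATEGIES = ("consecutive", "random", "spaced", "overlapping", "reference")


@dataclass(frozen=True)
class PackingConfig:
    strategy: str = "consecutive"
    context_length: int = 1024
    seed: int = 0

    def validate(self, read_length: int = 1) -> None:
        """Oversized reads are also rejected per unit at pack time; passing
        the corpus read length here fails fast before packing starts."""
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; one of {STRATEGIES}")
        if self.context_length < read_length + 2:
            raise ValueError(
                f"context_length {self.context_length} < read_length + 2"
            )


@dataclass
class PackedContext:
    """One fixed-length training window with per-slot metadata.

    ``contig_index`` indexes into ``contig_names`` (-1 for slots with no
    genomic coordinate); ``positions`` holds 0-based reference coordinates
    (-1 for structural tokens).
    """

    token_ids: np.ndarray
    contig_index: np.ndarray
    positions: np.ndarray
    loss_mask: np.ndarray
    weights: np.ndarray
    contig_names: tuple[str, ...] = ()
    read_ids: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        L = len(self.token_ids)
        for name in ("contig_index", "positions", "loss_mask", "weights"):
            if len(getattr(self, name)) != L:
                raise ValueError(f"{name} length != context length {L}")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.token_ids)


class _ContextBuilder:
    def __init__(self, vocab: TokenVocabulary, L: int, contig_names: tuple[str, ...]):
        self.vocab = vocab
        self.L = L
        self.names = contig_names
        self.reset()

    def reset(self):
        self.tokens = [self.vocab.bos_id]
        self.cidx = [-1]
        self.pos = [-1]
        self.read_ids: list[str] = []

    def fits(self, n: int) -> bool:
        return len(self.tokens) + n + 1 <= self.L

    def add_unit(self, token_ids: np.ndarray, contig_i: int, start: int, read_id: str | None):
        self.tokens.extend(int(t) for t in token_ids)
        self.cidx.extend([contig_i] * len(token_ids))
        self.pos.extend(range(start, start + len(token_ids)))
        self.tokens.append(self.vocab.sep_id)
        self.cidx.append(-1)
        self.pos.append(-1)
        if read_id is not None:
            self.read_ids.append(read_id)

    def flush(self) -> PackedContext | None:
        if len(self.tokens) <= 1:
            return None
        pad = self.L - len(self.tokens)
        tok = np.array(self.tokens + [self.vocab.pad_id] * pad, dtype=np.int64)
        cidx = np.array(self.cidx + [-1] * pad, dtype=np.int64)
        pos = np.array(self.pos + [-1] * pad, dtype=np.int64)
        mask = (tok != self.vocab.pad_id) & (tok != self.vocab.bos_id)
        ctx = PackedContext(
            token_ids=tok,
            contig_index=cidx,
            positions=pos,
            loss_mask=mask,
            weights=mask.astype(np.float64),
            contig_names=self.names,
            read_ids=tuple(self.read_ids),
        )
        self.reset()
        return ctx


def _pack_units(units, vocab, config, contig_names) -> list[PackedContext]:
    """Pack (tokens, contig_i, start, read_id) units greedily in order."""
    L = config.context_length
    b = _ContextBuilder(vocab, L, contig_names)
    out: list[PackedContext] = []
    current_contig = None
    for tokens, ci, start, rid in units:
        if len(tokens) > L - 2:
            raise ValueError(
                f"unit of {len(tokens)} tokens exceeds capacity {L - 2}"
            )
        if (current_contig is not None and ci != current_contig) or not b.fits(len(tokens)):
            ctx = b.flush()
            if ctx is not None:
                out.append(ctx)
        current_contig = ci
        b.add_unit(tokens, ci, start, rid)
    ctx = b.flush()
    if ctx is not None:
        out.append(ctx)
    return out


def _read_units(reads, vocab, contig_names):
    index = {n: i for i, n in enumerate(contig_names)}
    for r in reads:
        yield encode_array(r.bases, vocab), index[r.contig], r.start, r.read_id


def _contig_names(reads) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for r in reads:
        seen.setdefault(r.contig, None)
    return tuple(sorted(seen))


def pack_consecutive(reads, vocab, config: PackingConfig) -> list[PackedContext]:
    """Reads in ascending (contig, start) order, no splitting."""
    config.validate()
    names = _contig_names(reads)
    ordered = sorted(reads, key=lambda r: (r.contig, r.start, r.read_id))
    return _pack_units(_read_units(ordered, vocab, names), vocab, config, names)


def pack_random(reads, vocab, config: PackingConfig) -> list[PackedContext]:
    """Seeded uniform shuffle within each contig's read set."""
    config.validate()
    names = _contig_names(reads)
    rng = np.random.default_rng(config.seed)
    ordered: list[AlignedRead] = []
    for name in names:
        group = sorted(
            (r for r in reads if r.contig == name),
            key=lambda r: (r.start, r.read_id),
        )
        perm = rng.permutation(len(group))
        ordered.extend(group[i] for i in perm)
    return _pack_units(_read_units(ordered, vocab, names), vocab, config, names)


def pack_spaced(reads, vocab, config: PackingConfig) -> list[PackedContext]:
    """Greedy left-to-right non-overlapping passes until all reads are placed.

    Within each pass a read is selected only if its interval does not overlap
    the previously selected read's interval; skipped reads go to the next
    pass. Contexts are flushed between passes so intervals inside any one
    context are pairwise disjoint.
    """
    config.validate()
    names = _contig_names(reads)
    out: list[PackedContext] = []
    for ci, name in enumerate(names):
        pending = sorted(
            (r for r in reads if r.contig == name),
            key=lambda r: (r.start, r.read_id),
        )
        while pending:
            selected, leftover = [], []
            last_end = -1
            for r in pending:
                if r.start >= last_end:
                    selected.append(r)
                    last_end = r.end
                else:
                    leftover.append(r)
            out.extend(
                _pack_units(_read_units(selected, vocab, names), vocab, config, names)
            )
            pending = leftover
    return out


def _merge_chain(chain: list[AlignedRead], refseq: str) -> tuple[int, str]:
    """Consensus over one overlapping/abutting chain: majority, ties -> ref."""
    start = chain[0].start
    end = max(r.end for r in chain)
    counts = np.zeros((5, end - start), dtype=np.int64)
    lut = {b: i for i, b in enumerate("ACGTN")}
    for r in chain:
        for i, b in enumerate(r.bases):
            counts[lut[b], r.start - start + i] += 1
    best = counts.max(axis=0)
    merged = []
    for j in range(end - start):
        winners = [i for i in range(5) if counts[i, j] == best[j]]
        refbase = refseq[start + j]
        if len(winners) > 1 and lut[refbase] in winners:
            merged.append(refbase)
        else:
            merged.append("ACGTN"[winners[0]])
    return start, "".join(merged)


def pack_overlapping(reads, ref: ReferenceGenome, vocab, config: PackingConfig) -> list[PackedContext]:
    """Merge overlapping/abutting reads into maximal consensus segments.

    Segments longer than the payload capacity (L - 2) are split at capacity
    boundaries; segments are then packed consecutively.
    """
    config.validate()
    names = _contig_names(reads)
    cap = config.context_length - 2
    units = []
    for ci, name in enumerate(names):
        refseq = ref.sequence(name)
        group = sorted(
            (r for r in reads if r.contig == name),
            key=lambda r: (r.start, r.read_id),
        )
        chain: list[AlignedRead] = []
        chain_end = -1
        flushable = []
        for r in group:
            if chain and r.start > chain_end:
                flushable.append(chain)
                chain = []
            chain.append(r)
            chain_end = max(chain_end, r.end)
        if chain:
            flushable.append(chain)
        for ch in flushable:
            start, seq = _merge_chain(ch, refseq)
            for off in range(0, len(seq), cap):
                piece = seq[off : off + cap]
                units.append((encode_array(piece, vocab), ci, start + off, None))
    return _pack_units(units, vocab, config, names)


def pack_reference(ref: ReferenceGenome, vocab, config: PackingConfig) -> list[PackedContext]:
    """Chunk each reference contig into (L - 2)-base windows."""
    config.validate()
    cap = config.context_length - 2
    units = []
    for ci, (name, seq) in enumerate(ref.contigs):
        for off in range(0, len(seq), cap):
            units.append((encode_array(seq[off : off + cap], vocab), ci, off, None))
    names = tuple(n for n, _ in ref.contigs)
    return _pack_units(units, vocab, config, names)


def pack(reads, ref, vocab, config: PackingConfig) -> list[PackedContext]:
    """Dispatch on ``config.strategy``."""
    if config.strategy == "consecutive":
        return pack_consecutive(reads, vocab, config)
    if config.strategy == "random":
        return pack_random(reads, vocab, config)
    if config.strategy == "spaced":
        return pack_spaced(reads, vocab, config)
    if config.strategy == "overlapping":
        return pack_overlapping(reads, ref, vocab, config)
    if config.strategy == "reference":
        return pack_reference(ref, vocab, config)
    raise ValueError(f"unknown strategy {config.strategy!r}")


# ---------------------------------------------------------------------------
# Shard serialization


def save_shard(contexts: list[PackedContext], path, config: PackingConfig | None = None) -> None:
    """Columnar .npz shard plus a JSON sidecar with config and contig names."""
    if not contexts:
        raise ValueError("refusing to write an empty shard")
    path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    names = contexts[0].contig_names
    np.savez_compressed(
        path,
        token_ids=np.stack([c.token_ids for c in contexts]),
        contig_index=np.stack([c.contig_index for c in contexts]),
        positions=np.stack([c.positions for c in contexts]),
        loss_mask=np.stack([c.loss_mask for c in contexts]),
        weights=np.stack([c.weights for c in contexts]),
    )
    sidecar = {
        "contig_names": list(names),
        "n_contexts": len(contexts),
        "config": None if config is None else vars(config).copy(),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_shard(path) -> list[PackedContext]:
    path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    names = tuple(sidecar["contig_names"])
    data = np.load(path)
    return [
        PackedContext(
            token_ids=data["token_ids"][i],
            contig_index=data["contig_index"][i],
            positions=data["positions"][i],
            loss_mask=data["loss_mask"][i],
            weights=data["weights"][i],
            contig_names=names,
        )
        for i in range(data["token_ids"].shape[0])
    ]
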