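"""Dynamic inverse-frequency loss weights.

Training on raw pileups lets the reference allele dominate: at a typical
position the non-reference allele is a small minority, so an unweighted
cross-entropy pushes the model toward always predicting the reference base.
The dynamic mode counteracts this by weighting each nucleotide slot by the
inverse relative frequency of its allele in the pileup at its position,

    u(p, a) = (c(p, a) / d(p) + eps) ** (-alpha),

clipped to [1/clip_max, clip_max] and rescaled so the mean weight over all
loss-masked slots in the corpus is exactly 1 (keeping the loss scale
comparable to uniform weighting). alpha = 0 reproduces uniform weights;
SEP slots (no genomic coordinate) enter the normalization with raw weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlignedRead, ReferenceGenome
from .packing import PackedContext
from .tokenizer import TokenVocabulary

_ALLELES = "ACGTN"


@dataclass(frozen=True)
class WeightingConfig:
    mode: str = "uniform"
    alpha: float = 1.0
    clip_max: float = 100.0
    epsilon: float = 1e-6

    def validate(self) -> None:
        if self.mode not in ("uniform", "dynamic"):
            raise ValueError(f"mode must be 'uniform' or 'dynamic', got {self.mode!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.clip_max < 1:
            raise ValueError("clip_max must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


class PileupTable:
    """Per-(contig, position) allele counts over A/C/G/T/N."""

    def __init__(self, contig_lengths: dict[str, int]):
        self.counts = {
            name: np.zeros((5, ln), dtype=np.int64) for name, ln in contig_lengths.items()
        }

    def depth(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=0)

    def allele_count(self, contig: str, position: int, allele: str) -> int:
        return int(self.counts[contig][_ALLELES.index(allele), position])

    def max_depth(self, contig: str | None = None, interior: int = 0) -> int:
        """Maximum depth; ``interior`` trims that many bp from each contig end."""
        best = 0
        for name, c in self.counts.items():
            if contig is not None and name != contig:
                continue
            d = c.sum(axis=0)
            if interior:
                d = d[interior:-interior] if len(d) > 2 * interior else d[:0]
            if d.size:
                best = max(best, int(d.max()))
        return best


def build_pileup(reads: list[AlignedRead], ref: ReferenceGenome) -> PileupTable:
    """Tally read bases per reference position."""
    table = PileupTable(ref.lengths())
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_ALLELES):
        lut[ord(b)] = i
    for r in reads:
        counts = table.counts[r.contig]
        idx = lut[np.frombuffer(r.bases.encode(), dtype=np.uint8)]
        np.add.at(counts, (idx, np.arange(r.start, r.end)), 1)
    return table


def compute_weights(
    contexts: list[PackedContext],
    pileup: PileupTable,
    config: WeightingConfig,
    vocab: TokenVocabulary,
) -> list[PackedContext]:
    """Fill the per-slot weights of each context in place (and return them).

    Uniform mode assigns 1 to every loss-masked slot. Dynamic mode applies
    the inverse-frequency formula to nucleotide slots, gives SEP slots raw
    weight 1, and normalizes the corpus mean over loss-masked slots to 1.
    PAD/BOS slots always keep weight 0.
    """
    config.validate()
    if config.mode == "uniform" or config.alpha == 0.0:
        for ctx in contexts:
            ctx.weights = ctx.loss_mask.astype(np.float64)
        return contexts

    id_to_allele = {vocab.symbol_to_id[a]: i for i, a in enumerate(_ALLELES)}
    raw_all: list[np.ndarray] = []
    nuc_total = 0.0
    nuc_count = 0
    for ctx in contexts:
        raw = ctx.loss_mask.astype(np.float64)  # SEP slots stay at 1
        nuc = ctx.loss_mask & (ctx.positions >= 0)
        for slot in np.flatnonzero(nuc):
            ci = int(ctx.contig_index[slot])
            contig = ctx.contig_names[ci]
            p = int(ctx.positions[slot])
            counts = pileup.counts[contig]
            d = counts[:, p].sum()
            if d == 0:
                raise ValueError(
                    f"slot {slot}: position {contig}:{p} absent from pileup"
                )
            a = id_to_allele[int(ctx.token_ids[slot])]
            freq = counts[a, p] / d
            u = (freq + config.epsilon) ** (-config.alpha)
            raw[slot] = min(max(u, 1.0 / config.clip_max), config.clip_max)
            nuc_total += raw[slot]
            nuc_count += 1
        raw_all.append(raw)

    if nuc_count == 0:
        raise ValueError("no nucleotide slots in corpus")
    # normalize nucleotide slots to mean 1; SEP slots are already exactly 1,
    # so the corpus mean over all loss-masked slots is exactly 1 as well
    scale = nuc_count / nuc_total
    for ctx, raw in zip(contexts, raw_all):
        w = raw.copy()
        nuc = ctx.loss_mask & (ctx.positions >= 0)
        w[nuc] *= scale
        w[~ctx.loss_mask] = 0.0
        ctx.weights = w
    return contexts
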