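"""k-fold read-set reduction that keeps variant evidence.

Redundant reads (deep coverage, few informative positions) dominate raw
short-read data. The filter ranks reads globally by (carries-a-variant,
mean base quality, read id) and keeps the top ceil(n/k); a repair pass then
guarantees that every position supported by a non-reference base in the
input is still supported in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np

log = logging.getLogger(__name__)

from .core import AlignedRead, ReferenceGenome


@dataclass(frozen=True)
class FiltrationConfig:
    reduction_factor: int = 8
    preserve_variants: bool = True

    def validate(self) -> None:
        if self.reduction_factor < 1:
            raise ValueError("reduction_factor must be >= 1")


def score_read(read: AlignedRead, ref: ReferenceGenome) -> tuple[bool, float]:
    """(carries any non-reference base, mean Phred quality)."""
    seq = ref.sequence(read.contig)
    if read.end > len(seq):
        raise ValueError(
            f"read {read.read_id} overhangs contig {read.contig} "
            f"({read.end} > {len(seq)})"
        )
    variant_flag = read.bases != seq[read.start : read.end]
    return variant_flag, float(np.mean(read.qualities))


def _mismatch_sites(read: AlignedRead, refseq: str):
    """(position, alt base) pairs where the read differs from the reference."""
    window = refseq[read.start : read.end]
    return [
        (read.start + i, b) for i, (b, r) in enumerate(zip(read.bases, window)) if b != r
    ]


def filter_reads(
    reads: list[AlignedRead], ref: ReferenceGenome, config: FiltrationConfig
) -> list[AlignedRead]:
    """Retain exactly ceil(n/k) reads, preferring variant carriers and quality.

    With ``preserve_variants`` on, (position, alt) evidence observed in the
    input is kept observable in the output where the quota allows: missing
    carriers are swapped in for the lowest-ranked retained reads that carry
    no variant. The retained count is never grown — the k-fold reduction is
    the primary contract — so in mismatch-dense regimes (deep coverage with
    sequencing errors) some singleton error sites are necessarily lost;
    :func:`filtration_report` counts what survived.
    """
    config.validate()
    k = config.reduction_factor
    if not reads:
        return []
    if k == 1:
        return list(reads)

    scored = []
    for r in reads:
        flag, q = score_read(r, ref)
        scored.append((r, flag, q))
    # rank: variant carriers first, then higher quality, then read id
    ranked = sorted(scored, key=lambda t: (not t[1], -t[2], t[0].read_id))
    n_keep = ceil(len(reads) / k)
    kept = ranked[:n_keep]
    dropped = ranked[n_keep:]

    if config.preserve_variants:
        refseqs = {name: seq for name, seq in ref.contigs}
        covered: set[tuple[str, int, str]] = set()
        for r, flag, _ in kept:
            if flag:
                for p, b in _mismatch_sites(r, refseqs[r.contig]):
                    covered.add((r.contig, p, b))
        # reads outside the kept slice whose evidence is otherwise lost
        rescue: list[AlignedRead] = []
        for r, flag, _ in dropped:
            if not flag:
                continue
            sites = {(r.contig, p, b) for p, b in _mismatch_sites(r, refseqs[r.contig])}
            if sites - covered:
                rescue.append(r)
                covered |= sites
        # swap rescues in for the lowest-ranked non-variant kept reads;
        # cardinality stays ceil(n/k) even if some evidence cannot fit
        if rescue:
            swappable = [i for i in range(len(kept) - 1, -1, -1) if not kept[i][1]]
            for r, slot in zip(rescue, swappable):
                kept[slot] = (r, True, 0.0)
            if len(rescue) > len(swappable):
                log.debug(
                    "filter_reads: %d variant-evidence reads could not be "
                    "retained within the quota",
                    len(rescue) - len(swappable),
                )

    out = [r for r, _, _ in kept]
    out.sort(key=lambda r: (r.contig, r.start, r.read_id))
    return out


def filtration_report(
    reads_in: list[AlignedRead], reads_out: list[AlignedRead], ref: ReferenceGenome
) -> dict:
    """Summary row for the TSV report emitted by the CLI stage."""
    refseqs = {name: seq for name, seq in ref.contigs}

    def sites(rs):
        out = set()
        for r in rs:
            for p, b in _mismatch_sites(r, refseqs[r.contig]):
                out.add((r.contig, p, b))
        return out

    n_in, n_out = len(reads_in), len(reads_out)
    return {
        "n_in": n_in,
        "n_out": n_out,
        "fold": (n_in / n_out) if n_out else float("nan"),
        "n_variant_positions_preserved": len(sites(reads_in) & sites(reads_out)),
    }
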