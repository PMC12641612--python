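"""Core domain types shared across the toolkit.

Coordinates are 0-based half-open everywhere in memory; 1-based coordinates
appear only at SAM/VCF format boundaries (see :mod:`exolm.alignio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEOTIDES = ("A", "C", "G", "T")
READ_ALPHABET = ("A", "C", "G", "T", "N")


@dataclass(frozen=True)
class AlignedRead:
    """One aligned short read (substitutions only, no clips or indels).

    ``start`` is the 0-based reference coordinate of the first base; the read
    covers the half-open interval ``[start, start + len(bases))``.
    """

    read_id: str
    contig: str
    start: int
    bases: str
    qualities: tuple[int, ...]
    mapping_quality: int = 60
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("read bases must be non-empty")
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} qualities"
            )
        if self.start < 0:
            raise ValueError(f"read {self.read_id}: negative start {self.start}")
        bad = set(self.bases) - set(READ_ALPHABET)
        if bad:
            raise ValueError(f"read {self.read_id}: invalid bases {sorted(bad)}")

    @property
    def end(self) -> int:
        return self.start + len(self.bases)


@dataclass
class ReferenceGenome:
    """An ordered collection of named contigs over {A, C, G, T}."""

    contigs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for name, seq in self.contigs:
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - set(NUCLEOTIDES)
            if bad:
                raise ValueError(f"contig {name!r} contains non-ACGT symbols {sorted(bad)}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    def sequence(self, name: str) -> str:
        for n, s in self.contigs:
            if n == name:
                return s
        raise KeyError(f"unknown contig {name!r}")

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.contigs}


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    label: str = "."


@dataclass
class VariantTable:
    """Single-base substitution records, sorted by (contig, position)."""

    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        key = [(r.contig, r.position) for r in self.records]
        if key != sorted(key):
            raise ValueError("variant records must be sorted by (contig, position)")
        for r in self.records:
            if len(r.ref_allele) != 1 or len(r.alt_allele) != 1:
                raise ValueError("only single-base substitutions are supported")
            if r.ref_allele == r.alt_allele:
                raise ValueError(
                    f"{r.contig}:{r.position}: alt allele equals ref allele"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def positions(self) -> set[tuple[str, int]]:
        return {(r.contig, r.position) for r in self.records}
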