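"""FASTA / SAM / VCF input and output.

SAM and VCF handling stands on :mod:`pysam`; FASTA on Biopython's SeqIO.
In memory everything is 0-based half-open; POS fields are converted at the
boundary. Records outside this toolkit's scope (unmapped, secondary,
clipped/indel CIGARs, multi-allelic or indel VCF rows) are skipped and
counted, never fatal: the training recipe consumes matched bases only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pysam
from Bio import SeqIO

from .core import AlignedRead, ReferenceGenome, VariantRecord, VariantTable

log = logging.getLogger(__name__)

_ALLOWED_FASTA = set("ACGTN")


class FastaParseError(ValueError):
    pass


def read_fasta(path) -> ReferenceGenome:
    """Load a FASTA file, uppercasing and normalizing U -> T.

    Raises :class:`FastaParseError` naming the offending line for any
    symbol outside A/C/G/T/N (N is tolerated on input but forbidden in
    references, so it is rejected here too — references are clean).
    """
    path = Path(path)
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - set("ACGT")
        if bad:
            line = _find_bad_line(path, rec.id, bad)
            raise FastaParseError(
                f"{path}: contig {rec.id!r} contains invalid symbol(s) "
                f"{sorted(bad)} at line {line}"
            )
        contigs.append((rec.id, seq))
    if not contigs:
        raise FastaParseError(f"{path}: no FASTA records found")
    return ReferenceGenome(contigs)


def _find_bad_line(path: Path, contig: str, bad: set[str]) -> int:
    inside = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if raw.startswith(">"):
            inside = raw[1:].split()[0] == contig if len(raw) > 1 else False
            continue
        if inside and (set(raw.upper().replace("U", "T")) & bad):
            return lineno
    return -1


def write_fasta(genome: ReferenceGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SkipCounts:
    """Tally of records excluded while reading alignments."""

    unmapped: int = 0
    secondary_or_supplementary: int = 0
    complex_cigar: int = 0
    out_of_scope_variant: int = 0

    @property
    def total(self) -> int:
        return (
            self.unmapped
            + self.secondary_or_supplementary
            + self.complex_cigar
            + self.out_of_scope_variant
        )


def _sam_header(genome_lengths: dict[str, int], subjects: list[str]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in genome_lengths.items()],
        "RG": [{"ID": s, "SM": s} for s in subjects],
    }


def write_alignments(reads: list[AlignedRead], genome_lengths: dict[str, int], path) -> None:
    """Write coordinate-sorted SAM with @SQ lines and one @RG per subject."""
    subjects = sorted({r.subject_id for r in reads}) or ["S0"]
    header = pysam.AlignmentHeader.from_dict(_sam_header(genome_lengths, subjects))
    ordered = sorted(reads, key=lambda r: (r.contig, r.start, r.read_id))
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.query_sequence = r.bases
            a.flag = 0
            a.reference_id = out.get_tid(r.contig)
            a.reference_start = r.start
            a.mapping_quality = r.mapping_quality
            a.cigarstring = f"{len(r.bases)}M"
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qualities)
            )
            a.set_tag("RG", r.subject_id)
            out.write(a)


def read_alignments(path, skip_counts: SkipCounts | None = None):
    """Iterate :class:`AlignedRead` from a SAM (or BAM) file.

    Unmapped, secondary/supplementary, and non-single-match-CIGAR records
    are skipped; totals go to ``skip_counts`` and a debug log line.
    """
    counts = skip_counts if skip_counts is not None else SkipCounts()
    with pysam.AlignmentFile(str(path), check_sq=True) as fh:
        for rec in fh:
            if rec.is_unmapped:
                counts.unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                counts.secondary_or_supplementary += 1
                continue
            cig = rec.cigartuples
            if cig is None or len(cig) != 1 or cig[0][0] != 0:  # single M run only
                counts.complex_cigar += 1
                continue
            yield AlignedRead(
                read_id=rec.query_name,
                contig=rec.reference_name,
                start=rec.reference_start,
                bases=rec.query_sequence.upper(),
                qualities=tuple(int(q) for q in rec.query_qualities),
                mapping_quality=rec.mapping_quality,
                subject_id=rec.get_tag("RG") if rec.has_tag("RG") else "S0",
            )
    if counts.total:
        log.debug("read_alignments(%s): skipped %d records", path, counts.total)


# ---------------------------------------------------------------------------
# VCF


def write_variants(table: VariantTable, genome_lengths: dict[str, int], path) -> None:
    """Write single-base substitutions as VCF v4.2 with the label in INFO."""
    header = pysam.VariantHeader()
    for name, ln in genome_lengths.items():
        header.contigs.add(name, length=ln)
    header.info.add("LABEL", 1, "String", "Record label")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in table:
            rec = out.new_record(
                contig=r.contig,
                start=r.position,  # pysam converts to 1-based POS on write
                stop=r.position + 1,
                alleles=(r.ref_allele, r.alt_allele),
            )
            rec.info["LABEL"] = r.label or "."
            out.write(rec)


def read_variants(path, skip_counts: SkipCounts | None = None) -> VariantTable:
    """Read a VCF; multi-allelic and indel rows are skipped with a count."""
    counts = skip_counts if skip_counts is not None else SkipCounts()
    records = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                counts.out_of_scope_variant += 1
                continue
            label = rec.info.get("LABEL", ".")
            if isinstance(label, tuple):
                label = label[0]
            records.append(
                VariantRecord(rec.contig, rec.start, rec.ref, alts[0], label=str(label))
            )
    records.sort(key=lambda r: (r.contig, r.position))
    return VariantTable(records)
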