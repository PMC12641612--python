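"""Synthetic exome-style data: reference genomes, donor genomes, aligned reads.

The simulator emulates the character of real short-read exome data without
any downloads: 151-bp substitution-only reads, per-position coverage bounded
in [1, 180], roughly 1-2 non-reference bases per read (variants plus rare
sequencing errors), integer Phred qualities, multi-subject cohorts, and a
diverged second genome standing in for a multispecies corpus.

Every operation is deterministic given its seed; per-subject sub-seeds are
derived with :class:`numpy.random.SeedSequence` so cohort members are
independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import NUCLEOTIDES, AlignedRead, ReferenceGenome, VariantRecord, VariantTable

_BASES = np.array(list(NUCLEOTIDES))
_TILE = 1000  # bp; coverage targets are redrawn per tile


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror short-read exome sequencing: 151-bp reads, depth between
    1 and 180 reads per position, ~1e-3 substitution and base-error rates
    (so a typical read carries ~1-2 non-reference bases), Phred qualities
    centred on 30, and a 15%-diverged second genome.
    """

    n_contigs: int = 1
    contig_length: int = 100_000
    read_length: int = 151
    coverage_min: int = 1
    coverage_max: int = 180
    variant_rate: float = 1e-3
    base_error_rate: float = 1e-3
    quality_mean: float = 30.0
    quality_sd: float = 5.0
    divergence: float = 0.15
    n_subjects: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.contig_length < 1:
            raise ValueError("contig_length must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.coverage_min < 1:
            raise ValueError("coverage_min must be >= 1")
        if self.coverage_max < self.coverage_min:
            raise ValueError("coverage_max must be >= coverage_min")
        for name in ("variant_rate", "base_error_rate", "divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _subject_seed(master_seed: int, subject_index: int) -> np.random.SeedSequence:
    # Deterministic per-subject stream derived from (master seed, index).
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(subject_index,))


def simulate_reference(config: SimConfig) -> ReferenceGenome:
    """Draw a uniform-random A/C/G/T genome with the configured shape."""
    config.validate()
    rng = _rng(config.seed)
    contigs = []
    for i in range(config.n_contigs):
        seq = "".join(_BASES[rng.integers(0, 4, size=config.contig_length)])
        contigs.append((f"contig{i}", seq))
    return ReferenceGenome(contigs)


def _mutate(sequence: str, rate: float, rng: np.random.Generator):
    """Substitute each base independently with probability ``rate``.

    Returns the mutated sequence and the sorted array of mutated positions.
    A drawn substitution always changes the base (uniform over the three
    alternatives).
    """
    n = len(sequence)
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(n) < rate)
    if hit.size:
        old = arr[hit]
        # offset 1..3 from the current base, cyclic over ACGT
        offsets = rng.integers(1, 4, size=hit.size)
        base_idx = np.searchsorted(_BASES.astype("S1"), old)
        arr[hit] = _BASES.astype("S1")[(base_idx + offsets) % 4]
    return arr.tobytes().decode(), hit


def apply_variants(
    ref: ReferenceGenome, rate: float, seed: int
) -> tuple[ReferenceGenome, VariantTable]:
    """Create a donor genome by substituting bases at the given per-bp rate."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = _rng(seed)
    donor_contigs = []
    records = []
    for name, seq in ref.contigs:
        mutated, hits = _mutate(seq, rate, rng)
        donor_contigs.append((name, mutated))
        for p in hits:
            records.append(
                VariantRecord(name, int(p), seq[p], mutated[p], label="simulated")
            )
    return ReferenceGenome(donor_contigs), VariantTable(records)


def simulate_diverged_genome(
    ref: ReferenceGenome, divergence: float, seed: int
) -> ReferenceGenome:
    """A second species stand-in: the reference with substitution-only drift."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = _rng(seed)
    contigs = []
    for name, seq in ref.contigs:
        mutated, _ = _mutate(seq, divergence, rng)
        contigs.append((name, mutated))
    return ReferenceGenome(contigs)


def _coverage_starts(length: int, read_length: int, cfg: SimConfig, rng) -> np.ndarray:
    """Read start positions whose pileup depth stays inside the configured band.

    A target depth is drawn uniformly per 1-kb tile; a left-to-right sweep
    then tops coverage up to the local target at each start position. Old
    reads decay over at most one read length after a tile transition, so the
    depth at any position at least ``read_length`` from the contig ends is
    bounded by [coverage_min, coverage_max] by construction.
    """
    last_start = length - read_length
    if last_start < 0:
        raise ValueError(
            f"contig of length {length} is shorter than read_length {read_length}"
        )
    n_tiles = last_start // _TILE + 1
    targets = rng.integers(cfg.coverage_min, cfg.coverage_max + 1, size=n_tiles)
    starts: list[int] = []
    # diff array of coverage deltas from already-placed reads
    expiry = np.zeros(last_start + read_length + 2, dtype=np.int64)
    cover = 0
    for p in range(last_start + 1):
        cover += expiry[p]
        want = targets[p // _TILE]
        if cover < want:
            add = int(want - cover)
            starts.extend([p] * add)
            cover += add
            expiry[p + read_length] -= add
    return np.asarray(starts, dtype=np.int64)


def simulate_reads(
    donor: ReferenceGenome, ref: ReferenceGenome, config: SimConfig, subject_id: str = "S0"
) -> list[AlignedRead]:
    """Emit aligned reads from the donor genome with per-base errors.

    Reads are placed only where they fit entirely inside a contig, carry
    reference coordinates (the donor shares coordinates with the reference),
    and are returned coordinate-sorted.
    """
    config.validate()
    if donor.names != ref.names or donor.lengths() != ref.lengths():
        raise ValueError("donor and reference must share contig names and lengths")
    rng = _rng(config.seed)
    L = config.read_length
    reads: list[AlignedRead] = []
    for name, dseq in donor.contigs:
        if len(dseq) < L:
            raise ValueError(
                f"contig {name!r} (length {len(dseq)}) shorter than read_length {L}"
            )
        starts = _coverage_starts(len(dseq), L, config, rng)
        darr = np.frombuffer(dseq.encode(), dtype="S1")
        for i, s in enumerate(starts):
            bases = darr[s : s + L].copy()
            if config.base_error_rate > 0:
                err = np.flatnonzero(rng.random(L) < config.base_error_rate)
                if err.size:
                    idx = np.searchsorted(_BASES.astype("S1"), bases[err])
                    shift = rng.integers(1, 4, size=err.size)
                    bases[err] = _BASES.astype("S1")[(idx + shift) % 4]
            quals = np.clip(
                np.rint(rng.normal(config.quality_mean, config.quality_sd, size=L)),
                2,
                40,
            ).astype(int)
            reads.append(
                AlignedRead(
                    read_id=f"{subject_id}:{name}:r{i}",
                    contig=name,
                    start=int(s),
                    bases=bases.tobytes().decode(),
                    qualities=tuple(int(q) for q in quals),
                    subject_id=subject_id,
                )
            )
    reads.sort(key=lambda r: (r.contig, r.start, r.read_id))
    return reads


def simulate_cohort(
    ref: ReferenceGenome, config: SimConfig
) -> list[tuple[str, list[AlignedRead], VariantTable]]:
    """Independent donor + read draws for each subject under derived sub-seeds."""
    config.validate()
    cohort = []
    for i in range(config.n_subjects):
        ss = _subject_seed(config.seed, i)
        var_seed, read_seed = ss.spawn(2)
        subject = f"S{i}"
        donor, variants = apply_variants(ref, config.variant_rate, var_seed)
        sub_cfg = replace(config, seed=read_seed)
        reads = simulate_reads(donor, ref, sub_cfg, subject_id=subject)
        cohort.append((subject, reads, variants))
    return cohort
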