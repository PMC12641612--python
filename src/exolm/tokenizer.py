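"""Nucleotide tokenization with a fixed 9-symbol vocabulary.

One token per base plus four structural symbols, well inside the 16-symbol
budget a 4-bit token dictionary allows. Contig identity is carried as
context metadata, not as tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PAD = "PAD"
BOS = "BOS"
SEP = "SEP"
MASK = "MASK"

_SYMBOLS = (PAD, BOS, SEP, MASK, "A", "C", "G", "T", "N")
MAX_VOCAB = 16


@dataclass(frozen=True)
class TokenVocabulary:
    symbol_to_id: dict
    id_to_symbol: dict

    def __len__(self) -> int:
        return len(self.symbol_to_id)

    @property
    def pad_id(self) -> int:
        return self.symbol_to_id[PAD]

    @property
    def bos_id(self) -> int:
        return self.symbol_to_id[BOS]

    @property
    def sep_id(self) -> int:
        return self.symbol_to_id[SEP]

    @property
    def mask_id(self) -> int:
        return self.symbol_to_id[MASK]

    @property
    def nucleotide_ids(self) -> tuple[int, ...]:
        """Ids of A, C, G, T, N — a contiguous block."""
        return tuple(self.symbol_to_id[s] for s in ("A", "C", "G", "T", "N"))

    @property
    def acgt_ids(self) -> tuple[int, ...]:
        return tuple(self.symbol_to_id[s] for s in "ACGT")


def build_vocab() -> TokenVocabulary:
    """The fixed, versioned vocabulary; PAD is always id 0."""
    s2i = {s: i for i, s in enumerate(_SYMBOLS)}
    assert len(s2i) <= MAX_VOCAB
    return TokenVocabulary(symbol_to_id=s2i, id_to_symbol={i: s for s, i in s2i.items()})


def encode(sequence: str, vocab: TokenVocabulary) -> list[int]:
    """Map a nucleotide string to token ids, one per character."""
    out = []
    for i, ch in enumerate(sequence):
        tid = vocab.symbol_to_id.get(ch)
        if tid is None or ch in (PAD, BOS, SEP, MASK):
            raise ValueError(f"unknown character {ch!r} at index {i}")
        out.append(tid)
    return out


def encode_array(sequence: str, vocab: TokenVocabulary) -> np.ndarray:
    """Vectorized :func:`encode` for long sequences."""
    lut = np.full(256, -1, dtype=np.int64)
    for ch in "ACGTN":
        lut[ord(ch)] = vocab.symbol_to_id[ch]
    arr = lut[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        bad = int(np.flatnonzero(arr < 0)[0])
        raise ValueError(f"unknown character {sequence[bad]!r} at index {bad}")
    return arr


def decode(ids, vocab: TokenVocabulary) -> str:
    """Inverse of encode; structural tokens render as bracketed markers."""
    parts = []
    for tid in ids:
        sym = vocab.id_to_symbol.get(int(tid))
        if sym is None:
            raise ValueError(f"token id {tid} not in vocabulary (size {len(vocab)})")
        parts.append(f"[{sym}]" if sym in (PAD, BOS, SEP, MASK) else sym)
    return "".join(parts)


def save_vocab(vocab: TokenVocabulary, path) -> None:
    with open(path, "w") as fh:
        for sym, tid in sorted(vocab.symbol_to_id.items(), key=lambda kv: kv[1]):
            fh.write(f"{sym}\t{tid}\n")


def load_vocab(path) -> TokenVocabulary:
    s2i = {}
    with open(path) as fh:
        for line in fh:
            sym, tid = line.split("\t")
            s2i[sym] = int(tid)
    return TokenVocabulary(symbol_to_id=s2i, id_to_symbol={i: s for s, i in s2i.items()})
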