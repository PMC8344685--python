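"""Integer encoding of peptide sequences for the convolutional channel.

Each of the 20 amino acids maps to a distinct code in 1..20 (alphabetical,
A=1 ... Y=20) and sequences are right-padded with 0 to a fixed length of
210 residues, sized to exceed the longest peptide in the benchmark data.
The specific letter order is immaterial to the embedding layer that
consumes these codes, but is fixed here for reproducibility and can be
overridden through :class:`AlphabetMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import AMINO_ACIDS, LabelledDataset

#: Fixed padded length of every encoded sequence.
DEFAULT_MAX_LEN = 210


@dataclass(frozen=True)
class AlphabetMap:
    """Bijection from the 20 amino-acid letters to codes 1..20; 0 is padding."""

    letter_to_code: dict[str, int] = field(
        default_factory=lambda: {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
    )

    def __post_init__(self) -> None:
        codes = sorted(self.letter_to_code.values())
        if sorted(self.letter_to_code) != sorted(AMINO_ACIDS) or codes != list(range(1, 21)):
            raise ValueError("alphabet map must be a bijection from the 20 letters onto 1..20")

    @property
    def code_to_letter(self) -> dict[int, str]:
        return {c: a for a, c in self.letter_to_code.items()}


DEFAULT_ALPHABET = AlphabetMap()


@dataclass(frozen=True)
class EncodedSequence:
    """Fixed-length integer code vector for one peptide."""

    codes: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1:
            raise ValueError("codes must be a 1-D vector")
        n = self.source_length
        if not 0 < n <= codes.size:
            raise ValueError(f"source_length {n} outside (0, {codes.size}]")
        if not (np.all((codes[:n] >= 1) & (codes[:n] <= 20)) and np.all(codes[n:] == 0)):
            raise ValueError("codes must be 1..20 over the sequence and 0 over the padding")


def encode(
    sequence: str,
    alphabet: AlphabetMap = DEFAULT_ALPHABET,
    max_len: int = DEFAULT_MAX_LEN,
) -> EncodedSequence:
    """Encode an alphabet-clean peptide as codes padded with zeros to ``max_len``.

    Sequences longer than ``max_len`` are an error — truncation would
    silently change the peptide.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    if len(sequence) > max_len:
        raise ValueError(
            f"sequence length {len(sequence)} exceeds max_len {max_len}; refusing to truncate"
        )
    codes = np.zeros(max_len, dtype=np.int64)
    try:
        codes[: len(sequence)] = [alphabet.letter_to_code[a] for a in sequence.upper()]
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from None
    return EncodedSequence(codes=codes, source_length=len(sequence))


def decode(encoded: EncodedSequence, alphabet: AlphabetMap = DEFAULT_ALPHABET) -> str:
    """Invert :func:`encode`, recovering the original peptide string."""
    codes = np.asarray(encoded.codes)
    if np.any((codes < 0) | (codes > 20)):
        bad = codes[(codes < 0) | (codes > 20)][0]
        raise ValueError(f"code {int(bad)} outside the valid range 0..20")
    lookup = alphabet.code_to_letter
    return "".join(lookup[int(c)] for c in codes[: encoded.source_length])


def encode_dataset(
    dataset: LabelledDataset,
    alphabet: AlphabetMap = DEFAULT_ALPHABET,
    max_len: int = DEFAULT_MAX_LEN,
) -> np.ndarray:
    """Encode every record, returning an ``(n_records, max_len)`` int matrix."""
    out = np.zeros((len(dataset), max_len), dtype=np.int64)
    for i, rec in enumerate(dataset):
        out[i] = encode(rec.sequence, alphabet=alphabet, max_len=max_len).codes
    return out
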