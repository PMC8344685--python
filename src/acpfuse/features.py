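"""Handcrafted composition descriptors: AAC, DPC and CKSAAGP.

Three classical descriptor families over a peptide of length ``L``:

* **AAC** — amino acid composition, ``f(a) = N(a) / L`` for each of the 20
  letters (20 features).
* **DPC** — dipeptide composition, ``D(r, s) = N_rs / (L - 1)`` for each
  ordered letter pair (400 features).
* **CKSAAGP** — composition of k-spaced amino-acid group pairs. The 20
  letters are partitioned into five physicochemical groups — aliphatic
  G1 = {G,A,V,L,M,I}, aromatic G2 = {F,Y,W}, positively charged
  G3 = {K,R,H}, negatively charged G4 = {D,E}, uncharged G5 = {S,T,C,P,N,Q}
  — and for each gap k = 0..5 the frequency of each ordered group pair
  separated by exactly k residues is computed over its ``L - k - 1``
  possible positions (25 pairs x 6 gaps = 150 features).

Feature columns have a fixed, documented order: AAC alphabetical, DPC
row-major alphabetical (AA, AC, ..., YY), CKSAAGP gap-major then pair order
G1G1, G1G2, ..., G5G5, with names like ``G3XXG1`` where each ``X`` is one
intervening residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .sequence_io import AMINO_ACIDS, LabelledDataset

#: Descriptor scheme identifiers and their dimensionalities (at kmax = 5).
SCHEME_DIMS = {"AAC": 20, "DPC": 400, "CKSAAGP": 150}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_KMAX = 5


@dataclass(frozen=True)
class GroupScheme:
    """Partition of the 20 amino acids into five physicochemical groups."""

    groups: dict[str, str] = field(
        default_factory=lambda: {
            "G1": "GAVLMI",  # aliphatic
            "G2": "FYW",     # aromatic
            "G3": "KRH",     # positive charge
            "G4": "DE",      # negative charge
            "G5": "STCPNQ",  # uncharged
        }
    )

    def __post_init__(self) -> None:
        pooled = "".join(self.groups.values())
        if sorted(pooled) != sorted(AMINO_ACIDS):
            raise ValueError("groups must partition the 20 amino-acid letters exactly")

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def group_index(self) -> dict[str, int]:
        """Letter -> group position (0-based, in label order)."""
        return {aa: gi for gi, members in enumerate(self.groups.values()) for aa in members}


DEFAULT_GROUPS = GroupScheme()


@dataclass(frozen=True)
class FeatureVector:
    """A named, ordered descriptor vector for one peptide."""

    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.names) != values.size:
            raise ValueError("names and values length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.scheme)


def aac_names() -> tuple[str, ...]:
    return tuple(AMINO_ACIDS)


def dpc_names() -> tuple[str, ...]:
    return tuple(r + s for r in AMINO_ACIDS for s in AMINO_ACIDS)


def cksaagp_names(kmax: int = DEFAULT_KMAX, scheme: GroupScheme = DEFAULT_GROUPS) -> tuple[str, ...]:
    labels = scheme.labels
    return tuple(
        f"{gi}{'X' * k}{gj}" for k in range(kmax + 1) for gi in labels for gj in labels
    )


def _codes(sequence: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[a] for a in sequence), dtype=np.int64, count=len(sequence))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from None


def aac(sequence: str) -> FeatureVector:
    """Amino acid composition: per-letter frequency, summing to 1."""
    if not sequence:
        raise ValueError("AAC undefined for an empty sequence")
    counts = np.bincount(_codes(sequence), minlength=20)
    return FeatureVector("AAC", aac_names(), counts / len(sequence))


def dpc(sequence: str) -> FeatureVector:
    """Dipeptide composition: adjacent ordered pair frequency over L-1 pairs."""
    if len(sequence) < 2:
        raise ValueError("DPC requires a sequence of length >= 2")
    c = _codes(sequence)
    counts = np.bincount(c[:-1] * 20 + c[1:], minlength=400)
    return FeatureVector("DPC", dpc_names(), counts / (len(sequence) - 1))


def cksaagp(
    sequence: str,
    kmax: int = DEFAULT_KMAX,
    scheme: GroupScheme = DEFAULT_GROUPS,
    permissive: bool = False,
) -> FeatureVector:
    """Composition of k-spaced amino-acid group pairs for k = 0..kmax.

    Each 25-entry block for gap k holds the frequencies of the ordered group
    pairs (residue at p, residue at p+k+1) over the L-k-1 valid positions.
    Sequences shorter than ``kmax + 2`` leave some block with no valid pair;
    by default that is an error, under ``permissive=True`` such blocks are
    emitted as zeros.
    """
    if kmax < 0:
        raise ValueError("kmax must be non-negative")
    L = len(sequence)
    if L < kmax + 2 and not permissive:
        raise ValueError(
            f"CKSAAGP with kmax={kmax} requires length >= {kmax + 2}, got {L}"
        )
    if L == 0:
        raise ValueError("CKSAAGP undefined for an empty sequence")
    # group index per residue, via the letter codes
    lookup = np.empty(20, dtype=np.int64)
    gmap = scheme.group_index()
    for aa, i in _AA_INDEX.items():
        lookup[i] = gmap[aa]
    gidx = lookup[_codes(sequence)]

    blocks = []
    for k in range(kmax + 1):
        n_pairs = L - k - 1
        if n_pairs <= 0:
            blocks.append(np.zeros(25))
            continue
        pair_idx = gidx[: L - k - 1] * 5 + gidx[k + 1 :]
        blocks.append(np.bincount(pair_idx, minlength=25) / n_pairs)
    return FeatureVector("CKSAAGP", cksaagp_names(kmax, scheme), np.concatenate(blocks))


_SCHEME_FUNCS = {"AAC": aac, "DPC": dpc, "CKSAAGP": cksaagp}


def featurize(sequence: str, scheme: str, **kwargs) -> FeatureVector:
    """Compute one descriptor family (``AAC``, ``DPC`` or ``CKSAAGP``)."""
    try:
        func = _SCHEME_FUNCS[scheme.upper()]
    except KeyError:
        raise ValueError(f"unknown descriptor scheme {scheme!r}; use one of {list(SCHEME_DIMS)}")
    return func(sequence, **kwargs)


def feature_names(scheme: str, kmax: int = DEFAULT_KMAX) -> tuple[str, ...]:
    scheme = scheme.upper()
    if scheme == "AAC":
        return aac_names()
    if scheme == "DPC":
        return dpc_names()
    if scheme == "CKSAAGP":
        return cksaagp_names(kmax)
    raise ValueError(f"unknown descriptor scheme {scheme!r}")


def featurize_dataset(
    dataset: LabelledDataset,
    scheme: str,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Featurize every record: ``(matrix, labels, column names)``.

    Row order follows dataset order. A record violating the scheme's length
    precondition raises an error naming the record.
    """
    rows = []
    for rec in dataset:
        try:
            rows.append(featurize(rec.sequence, scheme, **kwargs).values)
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from None
    X = np.vstack(rows)
    y = np.asarray(dataset.labels, dtype=np.int64)
    return X, y, feature_names(scheme, kwargs.get("kmax", DEFAULT_KMAX))


def feature_frame(dataset: LabelledDataset, scheme: str, **kwargs) -> pd.DataFrame:
    """Featurize into a DataFrame with ``id`` and ``label`` leading columns."""
    X, y, names = featurize_dataset(dataset, scheme, **kwargs)
    frame = pd.DataFrame(X, columns=list(names))
    frame.insert(0, "label", y)
    frame.insert(0, "id", dataset.ids)
    return frame
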