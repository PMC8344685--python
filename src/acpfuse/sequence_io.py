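"""Reading, validating and writing peptide sequence sets.

Peptides are plain FASTA records over the 20 standard amino-acid letters.
Labelled datasets are assembled from a positives file and a negatives file
(label 1 = anticancer peptide, 0 = non-ACP, fixed everywhere in this
package), or from a single FASTA plus an ``id<TAB>label`` sidecar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid letters, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Residue policies for non-standard letters (X, B, Z, U, O, gaps, ...).
RESIDUE_POLICIES = ("strict", "skip")


@dataclass
class PeptideRecord:
    """One identified peptide sequence with an optional binary label."""

    id: str
    sequence: str
    label: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def is_standard(self) -> bool:
        """True if the sequence is non-empty and uses only the 20 letters."""
        return bool(self.sequence) and set(self.sequence) <= _AA_SET

    def invalid_residues(self) -> set[str]:
        return set(self.sequence) - _AA_SET


@dataclass
class LabelledDataset:
    """An ordered collection of labelled peptides with unique ids."""

    records: list[PeptideRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.label not in (0, 1):
                raise ValueError(f"record {rec.id!r} has no binary label")
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[int]:
        return [int(r.label) for r in self.records]  # type: ignore[arg-type]

    def subset(self, indices: Sequence[int], provenance: str = "") -> "LabelledDataset":
        return LabelledDataset(
            [self.records[i] for i in indices],
            provenance or f"subset of: {self.provenance}",
        )


def read_fasta(
    path: str | Path,
    label: int | None = None,
    policy: str = "strict",
) -> list[PeptideRecord]:
    """Read peptide records from a FASTA file.

    Sequences are upper-cased before validation. Records containing letters
    outside the 20-letter alphabet are an error under ``policy="strict"``
    (the default: every descriptor and the integer encoding are defined only
    over the 20 standard residues) or dropped, with a logged count, under
    ``policy="skip"``.
    """
    if policy not in RESIDUE_POLICIES:
        raise ValueError(f"unknown residue policy {policy!r}; use one of {RESIDUE_POLICIES}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")

    records: list[PeptideRecord] = []
    skipped: list[str] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rec = PeptideRecord(
            id=entry.id,
            sequence=str(entry.seq),
            label=label,
            description=entry.description,
        )
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        if not rec.is_standard():
            bad = ",".join(sorted(rec.invalid_residues())) or "<empty sequence>"
            if policy == "strict":
                raise ValueError(
                    f"record {rec.id!r} in {path} contains non-standard residue(s): {bad}"
                )
            skipped.append(rec.id)
            continue
        records.append(rec)
    if skipped:
        logger.warning(
            "skipped %d record(s) with non-standard residues in %s: %s",
            len(skipped), path, ", ".join(skipped),
        )
    if not records:
        raise ValueError(f"zero parseable records in {path}")
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records as single-line-sequence FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_label_sidecar(path: str | Path) -> dict[str, int]:
    """Read an ``id<TAB>label`` file mapping record ids to 0/1 labels."""
    labels: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rec_id, _, value = line.partition("\t")
        if not value:
            raise ValueError(f"malformed sidecar line (need id<TAB>label): {line!r}")
        labels[rec_id] = int(value)
    return labels


def build_dataset(
    positives: Sequence[PeptideRecord],
    negatives: Sequence[PeptideRecord],
    provenance: str = "",
) -> LabelledDataset:
    """Concatenate positive (label 1) and negative (label 0) records.

    Ids must be unique across the two sets; class counts are recorded in the
    dataset provenance.
    """
    if not positives:
        raise ValueError("positives collection is empty")
    if not negatives:
        raise ValueError("negatives collection is empty")
    collisions = {r.id for r in positives} & {r.id for r in negatives}
    if collisions:
        raise ValueError(f"id collision between positive and negative sets: {sorted(collisions)}")
    records = [
        PeptideRecord(r.id, r.sequence, 1, r.description) for r in positives
    ] + [
        PeptideRecord(r.id, r.sequence, 0, r.description) for r in negatives
    ]
    info = f"{len(positives)} positives + {len(negatives)} negatives"
    if provenance:
        info = f"{provenance} ({info})"
    return LabelledDataset(records, provenance=info)


def load_dataset(
    positives_path: str | Path,
    negatives_path: str | Path,
    policy: str = "strict",
) -> LabelledDataset:
    """Read a positives FASTA and a negatives FASTA into one labelled dataset."""
    pos = read_fasta(positives_path, label=1, policy=policy)
    neg = read_fasta(negatives_path, label=0, policy=policy)
    return build_dataset(pos, neg, provenance=f"{positives_path} + {negatives_path}")
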