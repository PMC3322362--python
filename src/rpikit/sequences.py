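"""Sequence and pair-list I/O.

Reads protein and RNA sequences from FASTA, canonicalizes them
(case-folding; DNA-style ``T`` mapped to ``U`` in RNA), and reads/writes
the two-column tab-delimited pair lists used to describe interacting
RNA-protein pairs.  Non-standard letters (ambiguity codes such as ``N``,
``X``, ``B``, ``Z``, or selenocysteine ``U`` in proteins) are kept in the
sequence string but flagged invalid; downstream k-mer encoders skip any
window that touches them rather than discarding the whole sequence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from Bio import SeqIO

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
RNA_ALPHABET = frozenset("ACGU")

Moltype = Literal["protein", "rna"]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input or duplicate record identifiers."""


class PairFormatError(ValueError):
    """Raised for malformed pair lists or unresolvable identifiers."""


def canonicalize(seq: str, moltype: Moltype) -> str:
    """Upper-case a raw sequence; for RNA, additionally map T to U.

    Canonicalization is idempotent.  Letters outside the canonical
    alphabet are preserved verbatim (and flagged by :func:`valid_mask`).
    """
    s = seq.upper()
    if moltype == "rna":
        s = s.replace("T", "U")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein or RNA sequence with a declared molecule type."""

    id: str
    seq: str
    moltype: Moltype

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.moltype not in ("protein", "rna"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        object.__setattr__(self, "seq", canonicalize(self.seq, self.moltype))

    def __len__(self) -> int:
        return len(self.seq)

    def valid_mask(self) -> list[bool]:
        """Per-position validity: True where the letter is in the canonical alphabet."""
        alpha = PROTEIN_ALPHABET if self.moltype == "protein" else RNA_ALPHABET
        return [c in alpha for c in self.seq]

    def is_fully_valid(self) -> bool:
        return all(self.valid_mask())


@dataclass(frozen=True)
class InteractionPair:
    """One labeled (protein, RNA) pair referencing records by id."""

    protein_id: str
    rna_id: str
    label: Literal["positive", "negative", "unlabeled"] = "unlabeled"

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative", "unlabeled"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class PairDataset:
    """A collection of sequence records plus the labeled pairs over them.

    ``sequences`` maps record id to :class:`SequenceRecord`; every pair
    must reference an existing protein and RNA record of the right
    molecule type.
    """

    sequences: dict[str, SequenceRecord] = field(default_factory=dict)
    pairs: list[InteractionPair] = field(default_factory=list)
    metadata: dict[str, object] = field(default_factory=dict)

    def add_sequence(self, record: SequenceRecord) -> None:
        existing = self.sequences.get(record.id)
        if existing is not None and existing != record:
            raise ValueError(f"conflicting records for id {record.id!r}")
        self.sequences[record.id] = record

    def add_pair(self, pair: InteractionPair) -> None:
        self._check_ref(pair.protein_id, "protein")
        self._check_ref(pair.rna_id, "rna")
        if any(
            p.protein_id == pair.protein_id and p.rna_id == pair.rna_id
            for p in self.pairs
        ):
            raise ValueError(
                f"duplicate pair ({pair.protein_id!r}, {pair.rna_id!r})"
            )
        self.pairs.append(pair)

    def _check_ref(self, seq_id: str, moltype: Moltype) -> None:
        rec = self.sequences.get(seq_id)
        if rec is None:
            raise KeyError(f"pair references unknown sequence id {seq_id!r}")
        if rec.moltype != moltype:
            raise ValueError(
                f"sequence {seq_id!r} has moltype {rec.moltype}, expected {moltype}"
            )

    def protein(self, pair: InteractionPair) -> SequenceRecord:
        return self.sequences[pair.protein_id]

    def rna(self, pair: InteractionPair) -> SequenceRecord:
        return self.sequences[pair.rna_id]

    def records(self, moltype: Moltype) -> list[SequenceRecord]:
        return [r for r in self.sequences.values() if r.moltype == moltype]

    def subset(self, pairs: Iterable[InteractionPair]) -> "PairDataset":
        """New dataset holding the given pairs and only the sequences they reference."""
        pairs = list(pairs)
        keep = {p.protein_id for p in pairs} | {p.rna_id for p in pairs}
        return PairDataset(
            sequences={k: v for k, v in self.sequences.items() if k in keep},
            pairs=pairs,
            metadata=dict(self.metadata),
        )

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for p in self.pairs:
            self._check_ref(p.protein_id, "protein")
            self._check_ref(p.rna_id, "rna")
            key = (p.protein_id, p.rna_id)
            if key in seen:
                raise ValueError(f"duplicate pair {key!r}")
            seen.add(key)


def read_fasta(path: str | Path, moltype: Moltype) -> list[SequenceRecord]:
    """Read a FASTA file into canonicalized records, preserving order.

    Raises :class:`FastaFormatError` on text before the first header or
    on duplicate identifiers.
    """
    path = Path(path)
    text = path.read_text()
    # Bio.SeqIO silently ignores leading junk before the first '>'; catch it.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise FastaFormatError(
                f"{path}: line {lineno}: expected FASTA header before sequence data"
            )
        break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), moltype=moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _dataset_from_records(
    proteins: Iterable[SequenceRecord], rnas: Iterable[SequenceRecord]
) -> PairDataset:
    ds = PairDataset()
    for rec in proteins:
        ds.add_sequence(rec)
    for rec in rnas:
        ds.add_sequence(rec)
    return ds


def read_pairs(
    path: str | Path,
    dialect: Literal["id_pairs", "seq_pairs"] = "seq_pairs",
    sequences: Mapping[str, SequenceRecord] | None = None,
) -> PairDataset:
    """Read a two- or three-column tab-delimited pair list.

    Columns are protein, RNA, and an optional label
    (``positive``/``negative``/``unlabeled``; absent means unlabeled).
    In the ``seq_pairs`` dialect the first two columns hold raw
    sequences and anonymous identifiers ``P<row>``/``R<row>`` are
    assigned from the 1-based row number; identical sequences in
    different rows keep distinct ids.  In the ``id_pairs`` dialect the
    columns hold identifiers that must resolve against ``sequences``
    (e.g. records loaded from FASTA beforehand).
    """
    path = Path(path)
    ds = PairDataset()
    if dialect == "id_pairs":
        if sequences is None:
            raise ValueError("id_pairs dialect requires a sequence collection")
        for rec in sequences.values():
            ds.add_sequence(rec)
    missing: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line == "":
                continue
            cols = line.split("\t")
            if len(cols) not in (2, 3):
                raise PairFormatError(
                    f"{path}: line {lineno}: expected 2 or 3 tab-separated columns, "
                    f"got {len(cols)}"
                )
            label = cols[2] if len(cols) == 3 else "unlabeled"
            if label not in ("positive", "negative", "unlabeled"):
                raise PairFormatError(
                    f"{path}: line {lineno}: unknown label {label!r}"
                )
            if dialect == "seq_pairs":
                prot = SequenceRecord(f"P{lineno}", cols[0], "protein")
                rna = SequenceRecord(f"R{lineno}", cols[1], "rna")
                ds.add_sequence(prot)
                ds.add_sequence(rna)
                ds.add_pair(InteractionPair(prot.id, rna.id, label))
            else:
                pid, rid = cols[0], cols[1]
                for sid in (pid, rid):
                    if sid not in ds.sequences:
                        missing.append(f"line {lineno}: {sid}")
                if missing:
                    continue
                ds.add_pair(InteractionPair(pid, rid, label))
    if missing:
        raise PairFormatError(
            f"{path}: unresolvable sequence ids: " + "; ".join(missing)
        )
    ds.metadata["source"] = str(path)
    ds.metadata["dialect"] = dialect
    return ds


def write_pairs(dataset: PairDataset, path: str | Path, labels: bool = True) -> None:
    """Write the pair list as tab-delimited id columns (plus label if requested).

    Identifiers may not contain the tab delimiter.  A read_pairs round
    trip in the ``id_pairs`` dialect reproduces the pair list exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        for p in dataset.pairs:
            for sid in (p.protein_id, p.rna_id):
                if "\t" in sid:
                    raise ValueError(f"id {sid!r} contains the tab delimiter")
            row = [p.protein_id, p.rna_id] + ([p.label] if labels else [])
            fh.write("\t".join(row) + "\n")
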