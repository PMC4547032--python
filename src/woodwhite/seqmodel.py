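"""Core sequence and specimen data model.

Holds the domain types shared by the whole toolkit — specimens, per-locus
alignments anchored to a reference coordinate system, and restriction-enzyme
specifications — together with the readers and writers for their on-disk
formats (aligned FASTA, tab-separated specimen and enzyme tables).

Reference coordinates are 1-based inclusive throughout the public API; the
alignment column index is 0-based internal bookkeeping.  For the standard
mitochondrial COI barcode fragment used in *Leptidea* work, column 0 of the
trimmed 631-position alignment corresponds to position 1526 of the
*Drosophila yakuba* mitochondrial reference (X03240).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data import IUPACData

__all__ = [
    "GAP",
    "UNAMBIGUOUS_BASES",
    "IUPAC_BASES",
    "AMBIGUITY_SETS",
    "Specimen",
    "LocusAlignment",
    "EnzymeSpec",
    "load_locus_alignment",
    "write_locus_alignment",
    "map_reference_position",
    "map_column_index",
    "load_specimen_table",
    "load_enzyme_library",
]

GAP = "-"
#: The four unambiguous nucleotides.
UNAMBIGUOUS_BASES = frozenset("ACGT")
#: All IUPAC nucleotide codes (including ambiguity codes), upper case.
IUPAC_BASES = frozenset(IUPACData.ambiguous_dna_letters.upper())
#: IUPAC code -> set of unambiguous bases it denotes (e.g. "R" -> {"A","G"}).
AMBIGUITY_SETS: Mapping[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if code != "X"
}

_ALLOWED_CHARS = IUPAC_BASES | {GAP}


def _validate_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _ALLOWED_CHARS
    if bad:
        raise ValueError(
            f"sequence {name!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class Specimen:
    """A collected individual, e.g. ``L12`` of Table-1 style metadata.

    ``species_label`` is a short group label (``s``/``j``/``a``/``m`` in the
    reference dataset) or ``"unknown"``.
    """

    id: str
    sex: str = "unknown"
    species_label: str = "unknown"
    collection_date: _dt.date | None = None
    accessions: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("specimen id must be non-empty")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r}")


@dataclass
class LocusAlignment:
    """An aligned set of sequences for a single locus.

    ``sequences`` maps specimen (or allele) id to an aligned nucleotide
    string over A/C/G/T, IUPAC ambiguity codes and ``-`` gaps.  ``ref_start``
    anchors column 0 to a 1-based reference coordinate.
    """

    locus_name: str
    sequences: dict[str, str]
    ref_start: int = 1
    ref_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"alignment {self.locus_name!r} is empty")
        if self.ref_start < 1:
            raise ValueError("ref_start must be >= 1")
        self.sequences = {
            sid: _validate_sequence(seq, sid) for sid, seq in self.sequences.items()
        }
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"ragged alignment {self.locus_name!r}: lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise ValueError(f"alignment {self.locus_name!r} has zero length")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def ref_end(self) -> int:
        """Last reference position covered (1-based inclusive)."""
        return self.ref_start + self.length - 1

    def to_column(self, ref_pos: int) -> int:
        return map_reference_position(self, ref_pos)

    def to_reference(self, column: int) -> int:
        return map_column_index(self, column)

    def column_states(self, ref_pos: int) -> dict[str, str]:
        col = self.to_column(ref_pos)
        return {sid: seq[col] for sid, seq in self.sequences.items()}

    def subset(self, ids: Iterable[str]) -> "LocusAlignment":
        ids = list(ids)
        missing = [i for i in ids if i not in self.sequences]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return LocusAlignment(
            self.locus_name,
            {i: self.sequences[i] for i in ids},
            ref_start=self.ref_start,
            ref_id=self.ref_id,
        )

    def write_fasta(self, path: str | Path) -> None:
        write_locus_alignment(self, path)


def map_reference_position(aln: LocusAlignment, ref_pos: int) -> int:
    """Map a 1-based reference position to a 0-based alignment column."""
    if not (aln.ref_start <= ref_pos <= aln.ref_end):
        raise ValueError(
            f"reference position {ref_pos} outside "
            f"[{aln.ref_start}, {aln.ref_end}] for locus {aln.locus_name!r}"
        )
    return ref_pos - aln.ref_start


def map_column_index(aln: LocusAlignment, column: int) -> int:
    """Inverse of :func:`map_reference_position`."""
    if not (0 <= column < aln.length):
        raise ValueError(f"column {column} outside [0, {aln.length - 1}]")
    return aln.ref_start + column


def load_locus_alignment(
    path: str | Path, locus_name: str, ref_start: int = 1, ref_id: str = ""
) -> LocusAlignment:
    """Read an aligned FASTA file into a :class:`LocusAlignment`.

    Sequences are upper-cased; duplicate record ids and ragged (unequal
    length) alignments are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    return LocusAlignment(locus_name, sequences, ref_start=ref_start, ref_id=ref_id)


def write_locus_alignment(aln: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


def load_specimen_table(path: str | Path) -> list[Specimen]:
    """Read a specimen metadata TSV (columns: id, sex, species_label, date)."""
    df = _read_tsv(path)
    required = {"id", "sex", "species_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    specimens = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["id"].strip()
        if sid in seen:
            raise ValueError(f"duplicate specimen id {sid!r}")
        seen.add(sid)
        date = None
        raw_date = str(row.get("date", "")).strip()
        if raw_date:
            date = _dt.date.fromisoformat(raw_date)
        specimens.append(
            Specimen(
                id=sid,
                sex=row["sex"].strip() or "unknown",
                species_label=row["species_label"].strip() or "unknown",
                collection_date=date,
            )
        )
    return specimens


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction endonuclease: IUPAC recognition sequence plus the cut
    offset (bases 5' of the cut on the top strand, e.g. C^CGG -> offset 1)."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", self.recognition.upper())
        if not (4 <= len(self.recognition) <= 8):
            raise ValueError(
                f"{self.name}: recognition length must be 4-8, "
                f"got {len(self.recognition)}"
            )
        bad = set(self.recognition) - IUPAC_BASES
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(self.recognition)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        return str(Seq(self.recognition).reverse_complement()) == self.recognition


def load_enzyme_library(path: str | Path) -> list[EnzymeSpec]:
    """Read an enzyme TSV with columns name, recognition, cut_offset."""
    df = _read_tsv(path)
    required = {"name", "recognition", "cut_offset"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"enzyme table missing columns: {sorted(missing)}")
    specs: list[EnzymeSpec] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        name = row["name"].strip()
        if name in seen:
            raise ValueError(f"duplicate enzyme name {name!r}")
        seen.add(name)
        specs.append(EnzymeSpec(name, row["recognition"].strip(), int(row["cut_offset"])))
    return specs
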