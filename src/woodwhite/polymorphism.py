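"""Polymorphic-site tables and diagnostic-site classification.

Given an aligned locus for two (or more) taxon groups, this module collapses
identical sequences into haplotypes, tabulates the polymorphic columns
(a site matrix in the style of a "polymorphic positions" results table),
classifies each column as *diagnostic* — both groups fixed, for different
states — or *shared*, compares carrier-weighted majority-rule group
consensuses, and annotates coding substitutions (codon number, codon
position, synonymy) under an explicit genetic code.

The reverse operation :func:`reconstruct_alleles` rebuilds full-length
allele sequences from a site matrix (all unlisted columns identical),
which is how compact published site tables are turned back into analysable
alignments.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .seqmodel import (
    AMBIGUITY_SETS,
    GAP,
    UNAMBIGUOUS_BASES,
    LocusAlignment,
)

__all__ = [
    "Haplotype",
    "SiteTable",
    "SubstitutionAnnotation",
    "build_site_table",
    "classify_sites",
    "consensus_difference_count",
    "group_consensus",
    "annotate_coding_substitution",
    "reconstruct_alleles",
    "expand_to_specimens",
    "GENETIC_CODES",
]

#: Genetic-code aliases -> NCBI translation table ids.  COI is translated
#: with the invertebrate mitochondrial code, nuclear genes (e.g. histone H1)
#: with the standard code.
GENETIC_CODES = {
    "standard": 1,
    "invertebrate_mitochondrial": 5,
}

DIAGNOSTIC = "diagnostic"
SHARED = "shared"


@dataclass
class Haplotype:
    """A distinct allele: its states at the polymorphic positions and the
    specimens carrying it."""

    allele_id: str
    states: dict[int, str]
    carrier_specimens: list[str]

    def __post_init__(self) -> None:
        if not self.carrier_specimens:
            raise ValueError(f"haplotype {self.allele_id!r} has no carriers")

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_specimens)


@dataclass
class SiteTable:
    """Polymorphic positions x alleles matrix for one locus.

    ``positions`` are 1-based reference coordinates in ascending order;
    ``haplotypes`` hold the per-allele states and carrier lists;
    ``group_assignment`` maps allele id to a taxon-group label ("unknown"
    when carriers are unlabelled or mixed); ``flagged_positions`` are
    columns containing a gap or ambiguity code in some allele — they are
    retained in the matrix but excluded from diagnostic classification.
    ``classification`` is filled by :func:`classify_sites`.
    """

    locus: str
    positions: list[int]
    haplotypes: list[Haplotype]
    group_assignment: dict[str, str]
    flagged_positions: list[int] = field(default_factory=list)
    classification: dict[int, str] = field(default_factory=dict)
    ref_start: int = 1
    ref_id: str = ""
    specimen_grouping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = sorted(self.positions)
        for hap in self.haplotypes:
            missing = set(self.positions) - set(hap.states)
            if missing:
                raise ValueError(
                    f"allele {hap.allele_id!r} lacks states at {sorted(missing)}"
                )
        if not self.specimen_grouping:
            # fall back to the allele-level assignment: every carrier of an
            # allele inherits that allele's group label
            self.specimen_grouping = {
                sid: self.group_assignment.get(hap.allele_id, "unknown")
                for hap in self.haplotypes
                for sid in hap.carrier_specimens
            }

    @property
    def allele_ids(self) -> list[str]:
        return [h.allele_id for h in self.haplotypes]

    @property
    def carrier_counts(self) -> dict[str, int]:
        return {h.allele_id: h.n_carriers for h in self.haplotypes}

    def states_at(self, pos: int) -> dict[str, str]:
        return {h.allele_id: h.states[pos] for h in self.haplotypes}

    def group_carrier_count(self, hap: Haplotype, group: str) -> int:
        return sum(
            1
            for sid in hap.carrier_specimens
            if self.specimen_grouping.get(sid, "unknown") == group
        )

    def alleles_in_group(self, group: str) -> list[Haplotype]:
        """Haplotypes carried by at least one specimen of ``group`` — an
        allele shared between groups belongs to both."""
        return [h for h in self.haplotypes if self.group_carrier_count(h, group) > 0]

    def to_frame(self) -> pd.DataFrame:
        """Positions-by-alleles matrix with group and flag annotation rows
        mirrored as columns."""
        data = {
            h.allele_id: [h.states[p] for p in self.positions] for h in self.haplotypes
        }
        df = pd.DataFrame(data, index=pd.Index(self.positions, name="position"))
        df["flag"] = [
            self.classification.get(
                p, "excluded" if p in self.flagged_positions else ""
            )
            for p in self.positions
        ]
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_site_table(
    aln: LocusAlignment, grouping: Mapping[str, str] | None = None
) -> SiteTable:
    """Collapse an alignment to haplotypes and tabulate polymorphic columns.

    ``grouping`` maps specimen id to group label; unlisted specimens are
    "unknown".  A haplotype's group is the common label of its carriers,
    "unknown" when carriers disagree.  Columns where any sequence carries a
    gap or an IUPAC ambiguity code are flagged (retained in the matrix,
    excluded from diagnostic classification downstream).
    """
    grouping = dict(grouping or {})
    if not aln.sequences:
        raise ValueError("empty alignment")

    # Collapse identical sequences, keeping first-seen order of carriers.
    by_seq: dict[str, list[str]] = {}
    for sid, seq in aln.sequences.items():
        by_seq.setdefault(seq, []).append(sid)

    polymorphic: list[int] = []
    flagged: list[int] = []
    unique_seqs = list(by_seq)
    for col in range(aln.length):
        states = {seq[col] for seq in unique_seqs}
        if len(states) > 1:
            pos = aln.ref_start + col
            polymorphic.append(pos)
            if states - UNAMBIGUOUS_BASES:
                flagged.append(pos)

    haplotypes = []
    group_assignment = {}
    for n, (seq, carriers) in enumerate(by_seq.items(), start=1):
        allele_id = f"{aln.locus_name}-{n}"
        states = {pos: seq[pos - aln.ref_start] for pos in polymorphic}
        haplotypes.append(Haplotype(allele_id, states, carriers))
        labels = {grouping.get(c, "unknown") for c in carriers}
        group_assignment[allele_id] = labels.pop() if len(labels) == 1 else "unknown"

    return SiteTable(
        locus=aln.locus_name,
        positions=polymorphic,
        haplotypes=haplotypes,
        group_assignment=group_assignment,
        flagged_positions=flagged,
        ref_start=aln.ref_start,
        ref_id=aln.ref_id,
        specimen_grouping={
            sid: grouping.get(sid, "unknown") for sid in aln.sequences
        },
    )


def _group_state_sets(table: SiteTable, group: str, pos: int) -> set[str]:
    return {h.states[pos] for h in table.alleles_in_group(group)}


def _check_groups(table: SiteTable, *groups: str) -> None:
    for g in groups:
        if not table.alleles_in_group(g):
            raise ValueError(f"no alleles assigned to group {g!r}")


def classify_sites(
    table: SiteTable, group_a: str, group_b: str
) -> tuple[dict[int, str], int]:
    """Classify each polymorphic position as diagnostic or shared.

    A position is *diagnostic* iff each group is fixed for a single state
    and the two states differ (disjoint singleton state sets).  Positions
    flagged for gaps/ambiguity are excluded from classification.  Updates
    ``table.classification`` in place and returns it with the diagnostic
    count.
    """
    _check_groups(table, group_a, group_b)
    classification: dict[int, str] = {}
    for pos in table.positions:
        if pos in table.flagged_positions:
            continue
        sa = _group_state_sets(table, group_a, pos)
        sb = _group_state_sets(table, group_b, pos)
        diagnostic = len(sa) == 1 and len(sb) == 1 and sa.isdisjoint(sb)
        classification[pos] = DIAGNOSTIC if diagnostic else SHARED
    table.classification = classification
    n_diagnostic = sum(1 for v in classification.values() if v == DIAGNOSTIC)
    return classification, n_diagnostic


_IUPAC_FOR_SET = {bases: code for code, bases in AMBIGUITY_SETS.items()}


def group_consensus(
    table: SiteTable,
    group: str,
    pos: int,
    weighted: bool = True,
    prefer: str | None = None,
) -> str:
    """Majority-rule consensus state of one group at one position.

    Alleles are weighted by carrier counts (``weighted=True``, the default)
    or equally.  Ties are broken toward ``prefer`` (conventionally the other
    group's consensus state — the conservative choice that minimises
    apparent between-group differences) when that state is among the tied
    ones, else the IUPAC ambiguity code for the tied states is returned.
    """
    counts: Counter[str] = Counter()
    for hap in table.alleles_in_group(group):
        counts[hap.states[pos]] += (
            table.group_carrier_count(hap, group) if weighted else 1
        )
    if not counts:
        raise ValueError(f"no alleles in group {group!r}")
    best = max(counts.values())
    top = sorted(state for state, n in counts.items() if n == best)
    if len(top) == 1:
        return top[0]
    if prefer is not None and prefer in top:
        return prefer
    return _IUPAC_FOR_SET.get(frozenset(top), "N")


def consensus_difference_count(
    table: SiteTable, group_a: str, group_b: str, weighted: bool = True
) -> tuple[int, list[int], dict[int, tuple[str, str]]]:
    """Count positions where the two groups' majority consensuses differ.

    Builds carrier-weighted majority-rule consensuses per group (ties
    resolved toward the other group's state when possible, else to an
    ambiguity code) and reports the positions where both consensus states
    are unambiguous nucleotides and differ.  Returns
    ``(count, positions, {pos: (state_a, state_b)})``.
    """
    _check_groups(table, group_a, group_b)
    differing: dict[int, tuple[str, str]] = {}
    for pos in table.positions:
        if pos in table.flagged_positions:
            continue
        # First pass without preference to obtain each side's plain majority,
        # then re-resolve ties toward the other side's state.
        ca0 = group_consensus(table, group_a, pos, weighted=weighted)
        cb0 = group_consensus(table, group_b, pos, weighted=weighted)
        ca = group_consensus(table, group_a, pos, weighted=weighted, prefer=cb0)
        cb = group_consensus(table, group_b, pos, weighted=weighted, prefer=ca0)
        if (
            ca in UNAMBIGUOUS_BASES
            and cb in UNAMBIGUOUS_BASES
            and ca != cb
        ):
            differing[pos] = (ca, cb)
    positions = sorted(differing)
    return len(positions), positions, differing


@dataclass(frozen=True)
class SubstitutionAnnotation:
    """A coding-sequence substitution located within its codon.

    ``codon_number = ceil(pos / 3)``; ``codon_position = ((pos - 1) % 3) + 1``.
    ``synonymous`` is ``None`` (undetermined) unless the codon context was
    available; ``aa_change`` is e.g. ``"A116T"`` for non-synonymous changes.
    """

    cds_position: int
    ref_base: str
    alt_base: str
    codon_number: int
    codon_position: int
    synonymous: bool | None
    aa_change: str | None


def annotate_coding_substitution(
    cds_length: int,
    pos: int,
    ref: str,
    alt: str,
    genetic_code: str | int = "standard",
    cds_sequence: str | None = None,
) -> SubstitutionAnnotation:
    """Annotate a substitution at 1-based CDS position ``pos``.

    Synonymy is determined only when the full reference CDS (``cds_sequence``)
    is supplied, since it needs the two codon-context bases; otherwise the
    codon coordinates are reported and ``synonymous`` is ``None``.
    """
    if cds_length % 3 != 0:
        raise ValueError(f"cds_length {cds_length} is not a multiple of 3")
    if not (1 <= pos <= cds_length):
        raise ValueError(f"position {pos} outside [1, {cds_length}]")
    ref, alt = ref.upper(), alt.upper()
    for base, which in ((ref, "ref"), (alt, "alt")):
        if base not in UNAMBIGUOUS_BASES:
            raise ValueError(f"{which} base {base!r} is not an unambiguous nucleotide")

    codon_number = math.ceil(pos / 3)
    codon_position = (pos - 1) % 3 + 1

    synonymous: bool | None = None
    aa_change: str | None = None
    if cds_sequence is not None:
        cds_sequence = cds_sequence.upper()
        if len(cds_sequence) != cds_length:
            raise ValueError("cds_sequence length disagrees with cds_length")
        if cds_sequence[pos - 1] != ref:
            raise ValueError(
                f"cds_sequence has {cds_sequence[pos - 1]!r} at position {pos}, "
                f"expected ref base {ref!r}"
            )
        table_id = (
            GENETIC_CODES[genetic_code]
            if isinstance(genetic_code, str)
            else int(genetic_code)
        )
        CodonTable.unambiguous_dna_by_id[table_id]  # validates the id
        start = (codon_number - 1) * 3
        codon = cds_sequence[start : start + 3]
        mutant = codon[: codon_position - 1] + alt + codon[codon_position:]
        aa_ref = str(Seq(codon).translate(table=table_id))
        aa_alt = str(Seq(mutant).translate(table=table_id))
        synonymous = aa_ref == aa_alt
        if not synonymous:
            aa_change = f"{aa_ref}{codon_number}{aa_alt}"

    return SubstitutionAnnotation(
        cds_position=pos,
        ref_base=ref,
        alt_base=alt,
        codon_number=codon_number,
        codon_position=codon_position,
        synonymous=synonymous,
        aa_change=aa_change,
    )


def reconstruct_alleles(
    table: SiteTable, length: int, backbone: str = "A"
) -> LocusAlignment:
    """Rebuild full-length allele sequences from a site matrix.

    All columns not listed in the table are identical across alleles — either
    taken from ``backbone`` (a full-length sequence) or filled with a single
    base (``backbone`` of length 1).  Pairwise difference counts between the
    reconstructed alleles therefore depend only on the table.
    """
    if len(backbone) == 1:
        backbone_seq = backbone.upper() * length
    else:
        backbone_seq = backbone.upper()
        if len(backbone_seq) != length:
            raise ValueError(
                f"backbone length {len(backbone_seq)} != requested length {length}"
            )
    last = table.ref_start + length - 1
    out_of_range = [p for p in table.positions if not table.ref_start <= p <= last]
    if out_of_range:
        raise ValueError(
            f"positions {out_of_range} outside [{table.ref_start}, {last}]"
        )
    sequences = {}
    for hap in table.haplotypes:
        chars = list(backbone_seq)
        for pos, state in hap.states.items():
            chars[pos - table.ref_start] = state
        sequences[hap.allele_id] = "".join(chars)
    return LocusAlignment(
        table.locus, sequences, ref_start=table.ref_start, ref_id=table.ref_id
    )


def expand_to_specimens(aln: LocusAlignment, table: SiteTable) -> LocusAlignment:
    """Replicate each allele sequence once per carrier specimen, so that
    per-specimen-pair statistics (the averaging unit of distance summaries)
    can be computed from an allele-level alignment."""
    sequences = {}
    for hap in table.haplotypes:
        if hap.allele_id not in aln.sequences:
            raise KeyError(f"allele {hap.allele_id!r} missing from alignment")
        for sid in hap.carrier_specimens:
            sequences[sid] = aln.sequences[hap.allele_id]
    return LocusAlignment(
        aln.locus_name, sequences, ref_start=aln.ref_start, ref_id=aln.ref_id
    )
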