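"""In-silico CAPS (PCR-RFLP) marker design and genotype calling.

A CAPS marker genotypes a diagnostic SNP by digesting a PCR amplicon with a
restriction endonuclease whose recognition site is gained or lost between
two taxa, and reading the fragment pattern on an agarose gel.  This module
scans linear amplicon sequences for IUPAC-degenerate recognition sites
(both strands for non-palindromic enzymes), predicts digestion fragment
patterns, decides whether two patterns are distinguishable under an
explicit gel model (minimum detectable fragment size, minimum resolvable
size difference), selects markers that are fixed within each group and
distinguishable between groups, and calls genotypes from observed fragment
lists.

Templates are linear (PCR products); overlapping sites all cut; ambiguity
codes in the *template* never match a recognition site — the conservative
choice that avoids phantom markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .seqmodel import AMBIGUITY_SETS, UNAMBIGUOUS_BASES, EnzymeSpec

__all__ = [
    "GelModel",
    "DigestPattern",
    "CapsMarker",
    "scan_recognition_sites",
    "digest",
    "patterns_distinguishable",
    "design_caps_markers",
    "call_caps_genotype",
    "AMBIGUOUS",
]

logger = logging.getLogger(__name__)

#: Returned by :func:`call_caps_genotype` when no (or more than one) expected
#: pattern matches the observation.
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class GelModel:
    """What an agarose gel can resolve.

    ``min_detectable_fragment``: fragments shorter than this run off or are
    too faint to see (bp).  ``min_resolvable_difference``: two fragments
    closer in size than this co-migrate (bp).
    """

    min_detectable_fragment: int = 50
    min_resolvable_difference: int = 20

    def __post_init__(self) -> None:
        if self.min_detectable_fragment < 0 or self.min_resolvable_difference < 0:
            raise ValueError("gel model thresholds must be >= 0")

    def detectable(self, fragments: Iterable[int]) -> tuple[int, ...]:
        return tuple(
            sorted(f for f in fragments if f >= self.min_detectable_fragment)
        )


@dataclass(frozen=True)
class DigestPattern:
    """Result of digesting one linear template: the multiset of fragment
    lengths and the 0-based cut coordinates."""

    fragment_lengths: tuple[int, ...]
    cut_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fragment_lengths", tuple(sorted(self.fragment_lengths))
        )
        object.__setattr__(self, "cut_positions", tuple(sorted(self.cut_positions)))
        if any(f <= 0 for f in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")

    @property
    def total_length(self) -> int:
        return sum(self.fragment_lengths)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


def _site_matches(seq: str, start: int, recognition: str) -> bool:
    for offset, code in enumerate(recognition):
        base = seq[start + offset]
        # Template ambiguity codes never match (conservative).
        if base not in UNAMBIGUOUS_BASES:
            return False
        if base not in AMBIGUITY_SETS[code]:
            return False
    return True


def scan_recognition_sites(seq: str, enzyme: EnzymeSpec) -> list[int]:
    """0-based top-strand start positions of all recognition-site matches.

    IUPAC codes in the *recognition sequence* are expanded; for
    non-palindromic enzymes the reverse complement of the recognition
    sequence is scanned too and hits are reported in top-strand coordinates.
    Overlapping matches are all reported.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if any(c not in UNAMBIGUOUS_BASES for c in set(seq)):
        logger.warning(
            "template for %s contains ambiguity codes or gaps; such positions "
            "never match a recognition site",
            enzyme.name,
        )
    patterns = [enzyme.recognition]
    if not enzyme.is_palindromic:
        patterns.append(str(Seq(enzyme.recognition).reverse_complement()))
    hits: set[int] = set()
    k = len(enzyme.recognition)
    for pattern in patterns:
        for start in range(len(seq) - k + 1):
            if _site_matches(seq, start, pattern):
                hits.add(start)
    return sorted(hits)


def digest(seq: str, enzyme: EnzymeSpec) -> DigestPattern:
    """Digest a linear template, cutting every recognition site.

    Top-strand matches cut at ``site_start + cut_offset``; bottom-strand
    matches of non-palindromic enzymes cut at the complementary offset.
    Cuts falling exactly on a template end would create zero-length
    fragments and are dropped with a warning.  Fragment lengths always sum
    to the template length.
    """
    seq = seq.upper()
    k = len(enzyme.recognition)
    rc = str(Seq(enzyme.recognition).reverse_complement())
    cuts: set[int] = set()
    for start in range(len(seq) - k + 1):
        if _site_matches(seq, start, enzyme.recognition):
            cuts.add(start + enzyme.cut_offset)
        if not enzyme.is_palindromic and _site_matches(seq, start, rc):
            cuts.add(start + k - enzyme.cut_offset)
    boundary = {c for c in cuts if c <= 0 or c >= len(seq)}
    if boundary:
        warnings.warn(
            f"{enzyme.name}: cut(s) at template boundary dropped: {sorted(boundary)}",
            stacklevel=2,
        )
    cuts -= boundary
    ordered = sorted(cuts)
    edges = [0, *ordered, len(seq)]
    fragments = tuple(b - a for a, b in zip(edges, edges[1:]))
    return DigestPattern(fragment_lengths=fragments, cut_positions=tuple(ordered))


def _match_fragments(
    frags_a: Sequence[int], frags_b: Sequence[int], tolerance: int
) -> tuple[int, int]:
    """Greedy size-ordered matching of two fragment multisets.

    Two fragments match when their sizes differ by less than ``tolerance``
    (they would co-migrate).  Returns the count of unmatched fragments on
    each side.  Sorted greedy matching is optimal here because the match
    relation is an interval condition on sorted sizes.
    """
    a = sorted(frags_a)
    b = sorted(frags_b)
    i = j = 0
    matched = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) < tolerance:
            matched += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return len(a) - matched, len(b) - matched


def patterns_distinguishable(
    p1: DigestPattern, p2: DigestPattern, gel: GelModel | None = None
) -> tuple[bool, int]:
    """Decide whether two fragment patterns can be told apart on a gel.

    Only detectable fragments count; the patterns are distinguishable iff
    some detectable fragment of one has no counterpart within the gel's
    resolvable difference in the other.  The score is the total number of
    such unmatched fragments (both sides) — shared fragments, like a common
    fragment flanking the polymorphic site, contribute nothing.
    """
    gel = gel or GelModel()
    da = gel.detectable(p1.fragment_lengths)
    db = gel.detectable(p2.fragment_lengths)
    ua, ub = _match_fragments(da, db, max(gel.min_resolvable_difference, 1))
    score = ua + ub
    return score > 0, score


@dataclass(frozen=True)
class CapsMarker:
    """A locus/enzyme combination whose digestion pattern separates two
    taxon groups."""

    locus: str
    enzyme: EnzymeSpec
    expected_patterns: Mapping[str, DigestPattern]
    distinguishability: int
    fixed_within_groups: bool
    supporting_positions: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "locus": self.locus,
            "enzyme": self.enzyme.name,
            "recognition": self.enzyme.recognition,
            "patterns": {
                g: list(p.fragment_lengths) for g, p in self.expected_patterns.items()
            },
            "score": self.distinguishability,
            "supporting_positions": list(self.supporting_positions),
        }


def _uniform_pattern(
    seqs: Sequence[str], enzyme: EnzymeSpec
) -> DigestPattern | None:
    patterns = [digest(s, enzyme) for s in seqs]
    first = patterns[0]
    if all(p.fragment_lengths == first.fragment_lengths for p in patterns[1:]):
        return first
    return None


def _differing_site_positions(
    seq_a: str, seq_b: str, enzyme: EnzymeSpec, ref_start: int
) -> set[int]:
    """Reference positions covered by recognition sites gained or lost
    between two aligned sequences."""
    sites_a = set(scan_recognition_sites(seq_a, enzyme))
    sites_b = set(scan_recognition_sites(seq_b, enzyme))
    span = len(enzyme.recognition)
    covered: set[int] = set()
    for start in sites_a ^ sites_b:
        covered.update(range(ref_start + start, ref_start + start + span))
    return covered


def design_caps_markers(
    group_a_seqs: Sequence[str],
    group_b_seqs: Sequence[str],
    enzymes: Sequence[EnzymeSpec],
    gel: GelModel | None = None,
    locus: str = "locus",
    labels: tuple[str, str] = ("A", "B"),
    diagnostic_positions: Iterable[int] | None = None,
    ref_start: int = 1,
) -> list[CapsMarker]:
    """Screen an enzyme library for CAPS markers separating two groups.

    A marker is emitted for an enzyme iff the digestion pattern is identical
    within each group (fixed — a polymorphic pattern cannot genotype) and
    the two group patterns are distinguishable under the gel model.  Markers
    are ranked by distinguishability score (descending), then total fragment
    count (ascending — simpler gels first), then enzyme name.  When the two
    groups share an alignment and ``diagnostic_positions`` (1-based
    reference coordinates) are supplied, each marker is annotated with the
    diagnostic positions falling inside gained/lost recognition sites.
    """
    if not enzymes:
        raise ValueError("empty enzyme library")
    if not group_a_seqs or not group_b_seqs:
        raise ValueError("both groups need at least one sequence")
    gel = gel or GelModel()
    diagnostic_positions = set(diagnostic_positions or ())

    markers: list[CapsMarker] = []
    for enzyme in enzymes:
        pat_a = _uniform_pattern(group_a_seqs, enzyme)
        pat_b = _uniform_pattern(group_b_seqs, enzyme)
        if pat_a is None or pat_b is None:
            logger.info(
                "%s: digestion pattern polymorphic within a group; skipped",
                enzyme.name,
            )
            continue
        ok, score = patterns_distinguishable(pat_a, pat_b, gel)
        if not ok:
            continue
        supporting: tuple[int, ...] = ()
        if diagnostic_positions and len(group_a_seqs[0]) == len(group_b_seqs[0]):
            covered = _differing_site_positions(
                group_a_seqs[0], group_b_seqs[0], enzyme, ref_start
            )
            supporting = tuple(sorted(diagnostic_positions & covered))
        markers.append(
            CapsMarker(
                locus=locus,
                enzyme=enzyme,
                expected_patterns={labels[0]: pat_a, labels[1]: pat_b},
                distinguishability=score,
                fixed_within_groups=True,
                supporting_positions=supporting,
            )
        )
    markers.sort(
        key=lambda m: (
            -m.distinguishability,
            sum(p.n_fragments for p in m.expected_patterns.values()),
            m.enzyme.name,
        )
    )
    return markers


def call_caps_genotype(
    observed: Sequence[int], marker: CapsMarker, gel: GelModel | None = None
) -> str:
    """Assign an observed fragment list to one of the marker's groups.

    The observation matches an expected pattern when every detectable
    expected fragment has an observed counterpart within the gel's
    resolvable difference and vice versa.  Returns the unique matching
    group label, or :data:`AMBIGUOUS` when zero or several match.
    """
    if any(f <= 0 for f in observed):
        raise ValueError("observed fragments must be positive")
    gel = gel or GelModel()
    obs = gel.detectable(observed)
    matches = []
    for label, pattern in marker.expected_patterns.items():
        exp = gel.detectable(pattern.fragment_lengths)
        ua, ub = _match_fragments(obs, exp, max(gel.min_resolvable_difference, 1))
        if ua == 0 and ub == 0:
            matches.append(label)
    return matches[0] if len(matches) == 1 else AMBIGUOUS


def markers_to_frame(markers: Sequence[CapsMarker]) -> pd.DataFrame:
    """Flat report table for a ranked marker list."""
    rows = []
    for m in markers:
        row = {
            "locus": m.locus,
            "enzyme": m.enzyme.name,
            "recognition": m.enzyme.recognition,
            "score": m.distinguishability,
            "supporting_positions": ",".join(map(str, m.supporting_positions)),
        }
        for g, p in m.expected_patterns.items():
            row[f"fragments_{g}"] = "+".join(map(str, p.fragment_lengths))
        rows.append(row)
    return pd.DataFrame(rows)
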