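"""Multilocus genotype assembly, mito-nuclear concordance and infection
prevalence.

Hybridisation between two species leaves a signature: a specimen whose
maternally inherited mitochondrial marker says one species while its
biparental nuclear markers say the other.  With markers that are perfectly
diagnostic, the rate of such discordant specimens estimates the rate of
(recent, maternal-side) introgression; zero observed discordance bounds it
from above via an exact binomial interval.

The same module computes endosymbiont (*Wolbachia*) infection prevalence
with Wilson score intervals, from per-specimen records or pre-tabulated
counts, and a sex-ratio binomial test (a skewed sex ratio among infected
hosts would point at male-killing strains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .seqmodel import LocusAlignment

__all__ = [
    "UNTYPED",
    "MultilocusGenotype",
    "ConcordanceReport",
    "InfectionRecord",
    "assemble_multilocus",
    "concordance_report",
    "infection_prevalence",
    "prevalence_from_counts",
    "call_by_diagnostic_states",
    "sex_ratio_test",
]

UNTYPED = "untyped"
AMBIGUOUS = "ambiguous"


@dataclass
class MultilocusGenotype:
    """Per-specimen taxon calls across loci.

    ``concordant`` is ``True``/``False`` only when at least two loci gave a
    non-ambiguous call; otherwise ``None`` (untestable).  Ambiguous calls
    reduce power but never count as conflict.
    """

    specimen_id: str
    calls: dict[str, str]
    concordant: bool | None = field(init=False)
    consensus_label: str | None = field(init=False)

    def __post_init__(self) -> None:
        informative = [
            c for c in self.calls.values() if c not in (AMBIGUOUS, UNTYPED)
        ]
        if len(informative) >= 2:
            self.concordant = len(set(informative)) == 1
        else:
            self.concordant = None
        self.consensus_label = (
            informative[0] if informative and len(set(informative)) == 1 else None
        )


def assemble_multilocus(
    calls: Mapping[str, Mapping[str, str]] | pd.DataFrame,
) -> list[MultilocusGenotype]:
    """Combine per-locus genotype tables into per-specimen records.

    ``calls`` is either ``{locus: {specimen: label}}`` or a long-format
    DataFrame with columns ``specimen``, ``locus``, ``call``.  Specimens
    missing from a locus are marked untyped; duplicate conflicting calls
    for the same specimen x locus are an error.
    """
    table: dict[str, dict[str, str]] = {}
    if isinstance(calls, pd.DataFrame):
        required = {"specimen", "locus", "call"}
        if missing := required - set(calls.columns):
            raise ValueError(f"call table missing columns: {sorted(missing)}")
        per_locus: dict[str, dict[str, str]] = {}
        for _, row in calls.iterrows():
            locus_calls = per_locus.setdefault(str(row["locus"]), {})
            sid, call = str(row["specimen"]), str(row["call"])
            if sid in locus_calls and locus_calls[sid] != call:
                raise ValueError(
                    f"conflicting duplicate call for {sid} at {row['locus']}: "
                    f"{locus_calls[sid]!r} vs {call!r}"
                )
            locus_calls[sid] = call
        table = per_locus
    else:
        table = {loc: dict(m) for loc, m in calls.items()}
    if not table:
        raise ValueError("no loci supplied")

    specimens: list[str] = []
    for locus_calls in table.values():
        for sid in locus_calls:
            if sid not in specimens:
                specimens.append(sid)
    return [
        MultilocusGenotype(
            specimen_id=sid,
            calls={locus: table[locus].get(sid, UNTYPED) for locus in table},
        )
        for sid in specimens
    ]


@dataclass(frozen=True)
class ConcordanceReport:
    n_concordant: int
    n_discordant: int
    n_untestable: int
    discordant_specimens: tuple[str, ...]
    rate: float | None
    rate_upper_bound: float | None
    confidence: float

    def to_dict(self) -> dict:
        return {
            "concordant": self.n_concordant,
            "discordant": self.n_discordant,
            "untestable": self.n_untestable,
            "discordant_specimens": list(self.discordant_specimens),
            "discordance_rate": self.rate,
            "rate_upper_bound": self.rate_upper_bound,
            "confidence": self.confidence,
        }


def concordance_report(
    genotypes: Sequence[MultilocusGenotype], confidence: float = 0.95
) -> ConcordanceReport:
    """Tally concordant/discordant/untestable specimens.

    ``rate = discordant / (concordant + discordant)`` (``None`` when no
    specimen is testable) with a one-sided exact binomial (Clopper-Pearson)
    upper bound at the given confidence — informative precisely when zero
    discordance is observed.
    """
    if not genotypes:
        raise ValueError("no genotypes")
    concordant = [g for g in genotypes if g.concordant is True]
    discordant = [g for g in genotypes if g.concordant is False]
    untestable = [g for g in genotypes if g.concordant is None]
    n_tested = len(concordant) + len(discordant)
    rate = upper = None
    if n_tested:
        rate = len(discordant) / n_tested
        # One-sided exact upper bound: the upper end of a two-sided
        # Clopper-Pearson interval with alpha doubled.
        _, upper = proportion_confint(
            len(discordant), n_tested, alpha=2 * (1 - confidence), method="beta"
        )
        upper = float(upper)
    return ConcordanceReport(
        n_concordant=len(concordant),
        n_discordant=len(discordant),
        n_untestable=len(untestable),
        discordant_specimens=tuple(g.specimen_id for g in discordant),
        rate=rate,
        rate_upper_bound=upper,
        confidence=confidence,
    )


def call_by_diagnostic_states(
    aln: LocusAlignment, diagnostic_states: Mapping[int, Mapping[str, str]]
) -> dict[str, str]:
    """Genotype every sequence in an alignment from diagnostic sites.

    ``diagnostic_states`` maps reference position -> {group label: fixed
    base}.  A specimen is called for the single group whose bases match at
    every diagnostic position; anything else (mixture, unresolved bases) is
    ambiguous.  This mimics what a CAPS assay or diagnostic-site inspection
    of a sequence does.
    """
    if not diagnostic_states:
        raise ValueError("no diagnostic states supplied")
    labels = sorted({g for states in diagnostic_states.values() for g in states})
    calls = {}
    for sid, seq in aln.sequences.items():
        matching = []
        for label in labels:
            if all(
                seq[aln.to_column(pos)] == states[label]
                for pos, states in diagnostic_states.items()
                if label in states
            ):
                matching.append(label)
        calls[sid] = matching[0] if len(matching) == 1 else AMBIGUOUS
    return calls


@dataclass(frozen=True)
class InfectionRecord:
    specimen_id: str
    group: str
    sex: str = "unknown"
    infected: str = "untested"  # positive / negative / untested

    def __post_init__(self) -> None:
        if self.infected not in ("positive", "negative", "untested"):
            raise ValueError(f"invalid infection state {self.infected!r}")


def prevalence_from_counts(
    positive: int, tested: int, confidence: float = 0.95
) -> dict:
    """Prevalence (as a percentage, one decimal) with a Wilson score
    interval, from pre-tabulated screening counts."""
    if tested <= 0:
        raise ValueError("tested count must be positive")
    if not 0 <= positive <= tested:
        raise ValueError("positive count outside [0, tested]")
    low, high = proportion_confint(
        positive, tested, alpha=1 - confidence, method="wilson"
    )
    return {
        "tested": tested,
        "positive": positive,
        "prevalence": positive / tested,
        "prevalence_pct": round(100 * positive / tested, 1),
        "wilson_low": float(low),
        "wilson_high": float(high),
    }


def infection_prevalence(
    records: Sequence[InfectionRecord],
    by: tuple[str, ...] = ("group",),
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-group infection prevalence from per-specimen screening records.

    Untested specimens are excluded.  ``by`` selects the grouping keys
    (any of ``group``, ``sex``).  Raises if a resulting group has zero
    tested specimens overall.
    """
    tested = [r for r in records if r.infected != "untested"]
    if not tested:
        raise ValueError("no tested records")
    df = pd.DataFrame(
        {
            "specimen_id": r.specimen_id,
            "group": r.group,
            "sex": r.sex,
            "positive": r.infected == "positive",
        }
        for r in tested
    )
    rows = []
    for keys, sub in df.groupby(list(by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        rec = prevalence_from_counts(
            int(sub["positive"].sum()), len(sub), confidence=confidence
        )
        rows.append({**dict(zip(by, keys)), **rec})
    return pd.DataFrame(rows)


def sex_ratio_test(records: Sequence[InfectionRecord]) -> dict:
    """Exact binomial test of the male:female ratio among infected
    specimens against 1:1 (male-killing endosymbionts skew it)."""
    infected = [r for r in records if r.infected == "positive"]
    males = sum(1 for r in infected if r.sex == "male")
    females = sum(1 for r in infected if r.sex == "female")
    n = males + females
    if n == 0:
        raise ValueError("no infected specimens with known sex")
    result = stats.binomtest(males, n, 0.5)
    return {"males": males, "females": females, "p_value": float(result.pvalue)}
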