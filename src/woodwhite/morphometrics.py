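"""Morphometric discrimination of near-sibling species.

Group descriptive statistics, two-sample t criteria, phi association of
binary characters with the molecular species assignment, and overlap/hiatus
analysis of measurements.

The measured characters are the classical *Leptidea* genitalic diagnostics:
saccus length S and valve length V (males, mm), their ratio S/V, and ductus
bursae length D (females, mm); binary characters score saccus curvature,
general size and two wing-pattern traits as 0/1 classes.

Three t-statistic variants are provided because published summary tables do
not always state the formula behind a printed t: the classic pooled-variance
t, Welch's unequal-variance t, and Welch's formula applied to means/SDs
first rounded to two decimals — the variant that reproduces values computed
from a rounded summary table rather than from raw measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MEASUREMENTS",
    "BINARY_TRAITS",
    "MorphoRecord",
    "GroupSummary",
    "TTestResult",
    "PhiResult",
    "GapResult",
    "round_half_up",
    "load_morpho_table",
    "records_to_frame",
    "trait_group_summary",
    "two_sample_t",
    "phi_coefficient",
    "phi_from_counts",
    "gap_analysis",
]

MEASUREMENTS = ("S", "V", "S_over_V", "D")
BINARY_TRAITS = (
    "saccus_curvature",
    "general_size",
    "hindwing_suffusion",
    "forewing_apex",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13), the convention of printed
    report tables, as opposed to Python's banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MorphoRecord:
    """One specimen's morphometric data.

    Males carry S and V (D absent), females carry D.  ``S_over_V`` defaults
    to the computed ratio but may be given explicitly — measurement tables
    often list a per-specimen ratio rounded independently of S and V.
    ``binary_traits`` maps trait name -> 0/1 score.
    """

    specimen_id: str
    sex: str
    molecular_label: str
    S: float | None = None
    V: float | None = None
    D: float | None = None
    S_over_V: float | None = None
    binary_traits: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.S_over_V is None and self.S is not None and self.V is not None:
            self.S_over_V = self.S / self.V
        for name in ("S", "V", "D"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{self.specimen_id}: {name} must be > 0")
        if self.sex == "male" and self.D is not None:
            raise ValueError(f"{self.specimen_id}: males carry no ductus measure")
        if self.sex == "female" and (self.S is not None or self.V is not None):
            raise ValueError(f"{self.specimen_id}: females carry no S/V measures")
        if self.binary_traits:
            bad = {k: v for k, v in self.binary_traits.items() if v not in (0, 1)}
            if bad:
                raise ValueError(f"{self.specimen_id}: non-binary trait scores {bad}")


def records_to_frame(records: Sequence[MorphoRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.specimen_id,
            "sex": r.sex,
            "molecular_label": r.molecular_label,
            "S": r.S,
            "V": r.V,
            "S_over_V": r.S_over_V,
            "D": r.D,
        }
        for t in BINARY_TRAITS:
            row[t] = (r.binary_traits or {}).get(t)
        rows.append(row)
    return pd.DataFrame(rows)


def load_morpho_table(path: str | Path) -> list[MorphoRecord]:
    """Read a morphometric TSV (columns id, sex, molecular_label, S, V, D
    and the binary traits; empty cells allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "sex", "molecular_label"}
    if missing := required - set(df.columns):
        raise ValueError(f"morphometric table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        def _num(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        traits = {}
        for t in BINARY_TRAITS:
            v = row.get(t)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                traits[t] = int(v)
        records.append(
            MorphoRecord(
                specimen_id=str(row["id"]),
                sex=str(row["sex"]),
                molecular_label=str(row["molecular_label"]),
                S=_num("S"),
                V=_num("V"),
                D=_num("D"),
                S_over_V=_num("S_over_V"),
                binary_traits=traits or None,
            )
        )
    return records


def _trait_values(records: Sequence[MorphoRecord], trait: str) -> dict[str, list[float]]:
    if trait not in MEASUREMENTS:
        raise ValueError(f"unknown measurement {trait!r}; expected one of {MEASUREMENTS}")
    by_group: dict[str, list[float]] = {}
    for r in records:
        value = getattr(r, trait)
        if value is not None:
            by_group.setdefault(r.molecular_label, []).append(float(value))
    return by_group


@dataclass(frozen=True)
class GroupSummary:
    group: str
    trait: str
    n: int
    mean: float
    sd: float | None  # sample SD (n-1); undefined for n == 1

    def rounded(self, ndigits: int = 2) -> "GroupSummary":
        return GroupSummary(
            self.group,
            self.trait,
            self.n,
            round_half_up(self.mean, ndigits),
            None if self.sd is None else round_half_up(self.sd, ndigits),
        )


def trait_group_summary(
    records: Sequence[MorphoRecord],
    trait: str,
    pooled_label: str = "both",
) -> list[GroupSummary]:
    """Mean and sample SD of one measurement per molecular group, plus a
    pooled row over all groups (the 'both species' line of a summary
    table).  Values are returned at full precision; use
    :meth:`GroupSummary.rounded` for report formatting."""
    by_group = _trait_values(records, trait)
    if not by_group:
        raise ValueError(f"no records carry trait {trait!r}")
    summaries = []
    for group, values in by_group.items():
        arr = np.asarray(values)
        summaries.append(
            GroupSummary(
                group=group,
                trait=trait,
                n=len(arr),
                mean=float(arr.mean()),
                sd=float(arr.std(ddof=1)) if len(arr) > 1 else None,
            )
        )
    pooled = np.concatenate([np.asarray(v) for v in by_group.values()])
    summaries.append(
        GroupSummary(
            group=pooled_label,
            trait=trait,
            n=len(pooled),
            mean=float(pooled.mean()),
            sd=float(pooled.std(ddof=1)) if len(pooled) > 1 else None,
        )
    )
    return summaries


@dataclass(frozen=True)
class TTestResult:
    trait: str
    method: str
    t: float
    df: float
    p: float


def _welch_from_stats(m1, s1, n1, m2, s2, n2):
    se2 = s1**2 / n1 + s2**2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / (
        (s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def two_sample_t(
    group_a: Sequence[float] | GroupSummary,
    group_b: Sequence[float] | GroupSummary,
    method: str = "welch",
    trait: str = "",
) -> TTestResult:
    """Two-sample t statistic by one of three documented methods.

    ``pooled``
        classic equal-variance t, df = nA + nB - 2;
    ``welch``
        unequal-variance t with Welch-Satterthwaite df;
    ``welch_on_rounded_summaries``
        Welch's formula applied to means and SDs first rounded half-up to
        two decimals — reproduces t values computed from a rounded summary
        table.

    Raw samples or :class:`GroupSummary` objects are accepted; the
    summary-only route supports ``pooled`` and ``welch`` variants through
    :func:`scipy.stats.ttest_ind_from_stats`.
    """

    def as_stats(g):
        if isinstance(g, GroupSummary):
            if g.n < 2 or g.sd is None:
                raise ValueError("summary needs n >= 2 and a defined SD")
            return g.mean, g.sd, g.n
        arr = np.asarray(list(g), dtype=float)
        if len(arr) < 2:
            raise ValueError("each group needs at least 2 observations")
        return float(arr.mean()), float(arr.std(ddof=1)), len(arr)

    m1, s1, n1 = as_stats(group_a)
    m2, s2, n2 = as_stats(group_b)

    if method == "pooled":
        res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        df = n1 + n2 - 2
        t, p = float(res.statistic), float(res.pvalue)
    elif method == "welch":
        t, df, p = _welch_from_stats(m1, s1, n1, m2, s2, n2)
    elif method == "welch_on_rounded_summaries":
        t, df, p = _welch_from_stats(
            round_half_up(m1), round_half_up(s1), n1,
            round_half_up(m2), round_half_up(s2), n2,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return TTestResult(trait=trait, method=method, t=float(t), df=float(df), p=float(p))


@dataclass(frozen=True)
class PhiResult:
    trait: str
    counts: tuple[int, int, int, int]  # a, b, c, d of the 2x2 table
    phi: float
    chi_square: float
    p: float


def phi_from_counts(a: int, b: int, c: int, d: int, trait: str = "") -> PhiResult:
    """Phi (mean-square contingency) coefficient of a 2x2 table.

    ``phi = |ad - bc| / sqrt((a+b)(c+d)(a+c)(b+d))`` (absolute-value
    convention), with the uncorrected chi-square ``phi**2 * n`` and its
    1-df p-value.  Any zero marginal total is degenerate.
    """
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError(f"degenerate 2x2 margin in {(a, b, c, d)}")
    phi = abs(a * d - b * c) / math.sqrt(math.prod(margins))
    chi2 = phi**2 * n
    return PhiResult(
        trait=trait,
        counts=(a, b, c, d),
        phi=phi,
        chi_square=chi2,
        p=float(stats.chi2.sf(chi2, df=1)),
    )


def phi_coefficient(
    records: Sequence[MorphoRecord],
    trait: str,
    groups: tuple[str, str] | None = None,
) -> PhiResult:
    """Association between a binary character and the molecular species.

    Builds the species x trait 2x2 count table (rows: the two molecular
    groups, columns: trait scores 1/0) and applies :func:`phi_from_counts`.
    """
    scored = [
        r
        for r in records
        if r.binary_traits is not None and trait in r.binary_traits
    ]
    if not scored:
        raise ValueError(f"no records scored for {trait!r}")
    labels = sorted({r.molecular_label for r in scored})
    if groups is None:
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 groups, found {labels}")
        groups = (labels[0], labels[1])
    ga, gb = groups
    a = sum(1 for r in scored if r.molecular_label == ga and r.binary_traits[trait] == 1)
    b = sum(1 for r in scored if r.molecular_label == ga and r.binary_traits[trait] == 0)
    c = sum(1 for r in scored if r.molecular_label == gb and r.binary_traits[trait] == 1)
    d = sum(1 for r in scored if r.molecular_label == gb and r.binary_traits[trait] == 0)
    return phi_from_counts(a, b, c, d, trait=trait)


@dataclass(frozen=True)
class GapResult:
    """Outcome of the overlap/hiatus analysis of one measurement.

    When the ranges of the two groups do not overlap, ``gap`` is ``True``
    and ``interval`` is (max of the lower-mean group, min of the
    higher-mean group) — any threshold inside it classifies the sample
    without error.  Otherwise ``interval`` is the overlapping range.
    """

    trait: str
    gap: bool
    interval: tuple[float, float]
    lower_group: str
    upper_group: str


def gap_analysis(
    records: Sequence[MorphoRecord], trait: str, groups: tuple[str, str] | None = None
) -> GapResult:
    by_group = _trait_values(records, trait)
    if groups is None:
        labels = sorted(by_group)
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 groups, found {labels}")
        groups = (labels[0], labels[1])
    va, vb = by_group.get(groups[0]), by_group.get(groups[1])
    if not va or not vb:
        raise ValueError(f"both groups need values for {trait!r}")
    # Order by group mean.
    if np.mean(va) <= np.mean(vb):
        lower_group, lower = groups[0], va
        upper_group, upper = groups[1], vb
    else:
        lower_group, lower = groups[1], vb
        upper_group, upper = groups[0], va
    lo_max, hi_min = max(lower), min(upper)
    if lo_max < hi_min:
        return GapResult(trait, True, (lo_max, hi_min), lower_group, upper_group)
    return GapResult(trait, False, (hi_min, lo_max), lower_group, upper_group)
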