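"""Packaged reference dataset: the published tables of the four-species
sympatric *Leptidea* study sample, transcribed verbatim.

The dataset comprises 70 specimens of *L. sinapis* (label ``s``),
*L. juvernica* (``j``), *L. amurensis* (``a``) and *L. morsei* (``m``):

* the specimen/collection/infection table (70 rows);
* the COI polymorphic-site matrix — six alleles over 631 aligned positions
  (reference coordinates 1526-2156 on the *D. yakuba* mitochondrial
  genome), 21 variable positions listed, all other columns identical;
* male genital measurements (saccus S, valve V, ratio S/V; 28 specimens)
  with their three-locus CAPS calls;
* female ductus bursae lengths (18 specimens) with CAPS calls;
* binary external/genitalic characters of the same males;
* *Wolbachia* wsp screening totals (the united *sinapis* + *juvernica*
  screen includes 15 specimens absent from the specimen table, so the
  printed totals are stored alongside the per-specimen rows);
* the conventional three-enzyme CAPS library (HpaII C^CGG, AluI AG^CT,
  HindIII A^AGCTT).

Everything is embedded as tab-separated text and exposed through loader
functions returning the package's domain objects.
"""

from __future__ import annotations

import io
from functools import lru_cache

import pandas as pd

from .concordance import InfectionRecord
from .morphometrics import BINARY_TRAITS, MorphoRecord
from .polymorphism import Haplotype, SiteTable, reconstruct_alleles
from .seqmodel import EnzymeSpec, LocusAlignment, Specimen

__all__ = [
    "COI_REF_START",
    "COI_LENGTH",
    "specimen_frame",
    "specimens",
    "coi_site_table",
    "coi_allele_alignment",
    "amurensis_coi_site_table",
    "male_morphometrics_frame",
    "female_morphometrics_frame",
    "binary_trait_frame",
    "morpho_records",
    "caps_call_frame",
    "infection_records",
    "wsp_screen_counts",
    "default_enzyme_library",
]

#: COI fragment anchoring: column 0 = reference position 1526; 631 columns.
COI_REF_START = 1526
COI_LENGTH = 631
COI_REF_ID = "X03240"

_SPECIMEN_TSV = """\
id	sex	date	species_label	coi_accession	h1_accession	wolbachia	wsp_allele
L1	male	2010-06-05	s			-
L2	male	2010-06-05	j			+
L3	male	2010-06-05	j			+
L4	male	2010-06-05	s			+
L5	male	2010-06-05	j			+
L6	male	2010-06-05	s			+
L7	male	2010-06-06	s			+
L8	male	2010-06-06	j			+
L9	male	2010-06-06	j			+
L10	male	2010-06-05	j	HG969218	LN606440	+
L11	male	2011-05-29	j	HG969219		+
L12	male	2011-05-29	j	HG969220	LN606441	+	wsp-10
L13	male	2011-05-29	j	HG969221		+
L14	male	2011-05-29	j	HG969222		+
L15	male	2011-05-29	s	HG969223	LN606442	+
L16	male	2011-05-29	s	HG969224	LN606443	+	wsp-687
L17	male	2011-05-29	s	HG969225	LN606444	+	wsp-10
L18	male	2011-05-29	s	HG969226		+
L19	male	2012-05-13	j	HG969227		+
L20	male	2012-05-13	j			+
L21	male	2012-05-13	j			+
L22	male	2012-05-13	s			+
L23	male	2012-05-13	s			+
L24	male	2012-05-14	j			+
L25	male	2012-05-14	s			+
L26	male	2012-05-15	s			-
L27	male	2012-05-15	j			+
L28	male	2012-05-15	j			+
L29	female	2010-05-29	j			+
L30	female	2010-06-05	j			+
L31	female	2010-06-05	j			+
L32	female	2010-06-05	j			+
L33	female	2010-06-05	j			+
L34	female	2010-06-05	s			-
L35	female	2010-06-05	j			+
L36	female	2010-06-06	j			+
L37	female	2010-06-06	s			+
L38	female	2010-06-06	j			+
L39	female	2012-05-13	j			+
L40	female	2012-05-13	j			+
L41	female	2012-05-13	j			+
L42	female	2012-05-13	j			+
L43	female	2012-05-14	s			+
L44	female	2012-05-14	s			+
L45	female	2012-05-14	j			+
L46	female	2012-05-14	s			+
L47	male	2010-05-29	a	HG969228		+
L48	male	2010-05-29	a	HG969229		+
L49	male	2011-05-26	a	HG969230		+
L50	male	2011-05-26	a	HG969231	LN606445	+
L51	male	2011-05-29	a	HG969232		+
L52	male	2011-05-29	a	HG969233		+
L53	male	2011-05-29	a	HG969234		+
L54	female	2010-05-28	a	HG969235		+
L55	female	2010-05-28	a	HG969236		+
L56	female	2011-05-26	a	HG969237		+
L57	female	2011-05-26	a	HG969238		+
L58	female	2011-05-26	a	HG969239	LN606446	+	wsp-10
L59	female	2011-05-29	a	HG969240		+
L60	male	2010-05-29	m	HG969241	LN606447	+
L61	male	2011-05-29	m	HG969242		+
L62	male	2011-05-29	m	HG969243		+
L63	male	2011-05-29	m	HG969244		+
L64	male	2011-05-29	m	HG969245		+
L65	male	2011-05-29	m	HG969246		+
L66	female	2010-05-29	m	HG969247		+
L67	female	2011-05-26	m	HG969248	LN606448	+	wsp-686
L68	female	2011-05-29	m	HG969249		+
L69	female	2011-05-29	m	HG969250		+
L70	female	2011-05-29	m	HG969251		+
"""

#: COI polymorphic-site matrix: six alleles in two groups (j1-j3, s1-s3).
#: Carriers per allele: j1 = L10,L11,L14; j2 = L12,L13; j3 = L19;
#: s1 = L15; s2 = L16,L17; s3 = L18.
_COI_SITE_TSV = """\
position	j1	j2	j3	s1	s2	s3
1530	T	T	T	C	C	C
1587	A	A	A	A	G	G
1599	C	C	C	T	T	T
1615	A	G	G	G	G	G
1624	A	A	A	G	G	G
1659	T	T	T	C	C	C
1674	G	G	G	G	A	A
1686	T	C	C	C	C	C
1720	C	C	C	T	T	T
1854	C	C	C	T	T	T
1860	A	A	A	G	G	G
1914	T	T	T	C	C	C
1917	C	C	T	T	T	T
1926	C	C	C	T	T	T
1947	A	A	A	G	G	G
1959	C	C	C	T	T	T
2076	T	T	T	T	T	A
2103	C	C	C	T	T	T
2121	T	T	T	A	A	A
2133	G	G	G	A	A	A
2148	C	C	C	T	T	T
"""

_COI_CARRIERS = {
    "j1": ["L10", "L11", "L14"],
    "j2": ["L12", "L13"],
    "j3": ["L19"],
    "s1": ["L15"],
    "s2": ["L16", "L17"],
    "s3": ["L18"],
}

_MALE_MORPHO_TSV = """\
id	coi	its2	cad	S	V	S_over_V
L1	s	s	s	0.60	0.88	0.69
L2	j	j	j	0.83	0.73	1.14
L3	j	j	j	0.80	0.78	1.03
L4	s	s	s	0.63	0.80	0.78
L5	j	j	j	0.78	0.70	1.11
L6	s	s	s	0.45	0.70	0.64
L7	s	s	s	0.60	0.88	0.69
L8	j	j	j	0.88	0.70	1.25
L9	j	j	j	0.75	0.70	1.07
L10	j	j	j	0.60	0.75	0.80
L11	j	j	j	0.73	0.78	0.94
L12	j	j	j	0.75	0.75	1.00
L13	j	j	j	0.83	0.75	1.10
L14	j	j	j	0.90	0.80	1.13
L15	s	s	s	0.70	0.88	0.80
L16	s	s	s	0.55	0.88	0.63
L17	s	s	s	0.68	0.95	0.71
L18	s	s	s	0.68	0.93	0.73
L19	j	j	j	0.65	0.73	0.90
L20	j	j	j	0.95	0.75	1.27
L21	j	j	j	0.83	0.65	1.27
L22	s	s	s	0.68	0.85	0.79
L23	s	s	s	0.63	0.78	0.81
L24	j	j	j	0.80	0.95	0.84
L25	s	s	s	0.70	0.83	0.85
L26	s	s	s	0.63	0.75	0.83
L27	j	j	j	0.88	0.88	1.00
L28	j	j	j	0.98	0.80	1.22
"""

_FEMALE_MORPHO_TSV = """\
id	coi	its2	cad	D
L29	j	j	j	1.00
L30	j	j	j	1.10
L31	j	j	j	0.83
L32	j	j	j	0.78
L33	j	j	j	0.95
L34	s	s	s	0.60
L35	j	j	j	1.00
L36	j	j	j	0.95
L37	s	s	s	0.60
L38	j	j	j	0.88
L39	j	j	j	0.85
L40	j	j	j	1.23
L41	j	j	j	0.75
L42	j	j	j	1.25
L43	s	s	s	0.55
L44	s	s	s	0.55
L45	j	j	j	0.90
L46	s	s	s	0.60
"""

_BINARY_TRAIT_TSV = """\
id	molecular_label	saccus_curvature	general_size	hindwing_suffusion	forewing_apex
L1	s	1	0	0	0
L2	j	1	1	1	1
L3	j	1	1	1	1
L4	s	1	0	1	1
L5	j	1	1	1	1
L6	s	0	0	0	0
L7	s	0	1	1	1
L8	j	1	1	1	0
L9	j	1	1	1	0
L10	j	1	0	1	1
L11	j	1	1	1	1
L12	j	1	1	1	0
L13	j	1	1	1	1
L14	j	1	1	1	1
L15	s	1	0	0	1
L16	s	1	1	0	1
L17	s	0	1	0	0
L18	s	0	0	0	0
L19	j	1	1	1	1
L20	j	1	1	1	1
L21	j	1	1	1	0
L22	s	1	0	0	0
L23	s	0	0	0	0
L24	j	1	1	1	1
L25	s	0	0	0	0
L26	s	1	1	1	0
L27	j	0	0	1	0
L28	j	1	0	1	0
"""

#: wsp screening totals.  The united s+j screen covers 61 specimens (the 46
#: table rows plus 15 screened-only specimens); per-species-group totals as
#: printed.
_WSP_COUNTS = {
    ("sinapis+juvernica", "male"): (38, 42),
    ("sinapis+juvernica", "female"): (18, 19),
    ("amurensis", "both"): (13, 13),
    ("morsei", "both"): (11, 11),
}

_ENZYME_TSV = """\
name	recognition	cut_offset
HpaII	CCGG	1
AluI	AGCT	2
HindIII	AAGCTT	1
"""


def _frame(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text), sep="\t")


@lru_cache(maxsize=None)
def specimen_frame() -> pd.DataFrame:
    return _frame(_SPECIMEN_TSV)


def specimens() -> list[Specimen]:
    out = []
    for _, row in specimen_frame().iterrows():
        accessions = {}
        if isinstance(row["coi_accession"], str) and row["coi_accession"].strip():
            accessions["COI"] = row["coi_accession"].strip()
        if isinstance(row["h1_accession"], str) and row["h1_accession"].strip():
            accessions["H1"] = row["h1_accession"].strip()
        out.append(
            Specimen(
                id=row["id"],
                sex=row["sex"],
                species_label=row["species_label"],
                accessions=accessions or None,
            )
        )
    return out


def coi_site_table() -> SiteTable:
    """The six-allele COI polymorphic-site matrix (21 listed positions)."""
    df = _frame(_COI_SITE_TSV)
    haplotypes = []
    group_assignment = {}
    for allele, carriers in _COI_CARRIERS.items():
        states = {int(row["position"]): row[allele] for _, row in df.iterrows()}
        haplotypes.append(Haplotype(allele, states, list(carriers)))
        group_assignment[allele] = allele[0]  # j or s
    return SiteTable(
        locus="COI",
        positions=[int(p) for p in df["position"]],
        haplotypes=haplotypes,
        group_assignment=group_assignment,
        ref_start=COI_REF_START,
        ref_id=COI_REF_ID,
    )


def coi_allele_alignment(backbone: str = "A") -> LocusAlignment:
    """The six COI alleles reconstructed to full 631-position sequences
    (identical outside the listed polymorphic columns)."""
    return reconstruct_alleles(coi_site_table(), COI_LENGTH, backbone=backbone)


def amurensis_coi_site_table() -> SiteTable:
    """The *L. amurensis* COI sample: 13 specimens, two alleles differing
    only at position 1969 (T in 12 specimens, A in L57)."""
    t_carriers = [
        "L47", "L48", "L49", "L50", "L51", "L52", "L53",
        "L54", "L55", "L56", "L58", "L59",
    ]
    haplotypes = [
        Haplotype("a-1969T", {1969: "T"}, t_carriers),
        Haplotype("a-1969A", {1969: "A"}, ["L57"]),
    ]
    return SiteTable(
        locus="COI",
        positions=[1969],
        haplotypes=haplotypes,
        group_assignment={"a-1969T": "a", "a-1969A": "a"},
        ref_start=COI_REF_START,
        ref_id=COI_REF_ID,
    )


@lru_cache(maxsize=None)
def male_morphometrics_frame() -> pd.DataFrame:
    return _frame(_MALE_MORPHO_TSV)


@lru_cache(maxsize=None)
def female_morphometrics_frame() -> pd.DataFrame:
    return _frame(_FEMALE_MORPHO_TSV)


@lru_cache(maxsize=None)
def binary_trait_frame() -> pd.DataFrame:
    return _frame(_BINARY_TRAIT_TSV)


def morpho_records() -> list[MorphoRecord]:
    """All 46 morphometric records (28 males with S/V and binary traits,
    18 females with D), labelled by their concordant molecular calls."""
    traits = binary_trait_frame().set_index("id")
    records = []
    for _, row in male_morphometrics_frame().iterrows():
        trow = traits.loc[row["id"]]
        records.append(
            MorphoRecord(
                specimen_id=row["id"],
                sex="male",
                molecular_label=row["coi"],
                S=float(row["S"]),
                V=float(row["V"]),
                S_over_V=float(row["S_over_V"]),
                binary_traits={t: int(trow[t]) for t in BINARY_TRAITS},
            )
        )
    for _, row in female_morphometrics_frame().iterrows():
        records.append(
            MorphoRecord(
                specimen_id=row["id"],
                sex="female",
                molecular_label=row["coi"],
                D=float(row["D"]),
            )
        )
    return records


def caps_call_frame() -> pd.DataFrame:
    """Long-format CAPS calls: 46 specimens x {COI, ITS2, CAD}."""
    rows = []
    for frame in (male_morphometrics_frame(), female_morphometrics_frame()):
        for _, row in frame.iterrows():
            for locus, col in (("COI", "coi"), ("ITS2", "its2"), ("CAD", "cad")):
                rows.append(
                    {"specimen": row["id"], "locus": locus, "call": row[col]}
                )
    return pd.DataFrame(rows)


def infection_records() -> list[InfectionRecord]:
    """Per-specimen *Wolbachia* screening states from the specimen table."""
    out = []
    for _, row in specimen_frame().iterrows():
        state = {"+": "positive", "-": "negative"}.get(
            str(row["wolbachia"]).strip(), "untested"
        )
        out.append(
            InfectionRecord(
                specimen_id=row["id"],
                group=row["species_label"],
                sex=row["sex"],
                infected=state,
            )
        )
    return out


def wsp_screen_counts() -> dict[tuple[str, str], tuple[int, int]]:
    """Printed screening totals: (positive, tested) per (group, sex).

    The united *sinapis* + *juvernica* sample totals 56/61 over both sexes.
    """
    return dict(_WSP_COUNTS)


def default_enzyme_library() -> list[EnzymeSpec]:
    """HpaII (C^CGG), AluI (AG^CT) and HindIII (A^AGCTT) — the enzymes that
    genotype COI, ITS2 and CAD respectively in this species pair."""
    df = _frame(_ENZYME_TSV)
    return [
        EnzymeSpec(row["name"], row["recognition"], int(row["cut_offset"]))
        for _, row in df.iterrows()
    ]
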