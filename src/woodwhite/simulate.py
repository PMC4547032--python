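"""Synthetic two-species study generator.

Generates datasets with the statistical structure the analysis pipeline
assumes, so every stage can be exercised and validated without external
sequence downloads:

* per-locus alignments with a configurable number of *diagnostic* sites
  (fixed and disjoint between the two species) plus *intraspecific* sites
  segregating within one species at a minor-allele frequency drawn uniform
  on (0.1, 0.5) — the structure of a published polymorphic-site matrix;
* optional mitochondrial introgression: a configurable fraction of
  specimens carry the other species' states at all diagnostic sites of
  maternally inherited loci (mito capture), the signature the mito-nuclear
  concordance test detects;
* genital measurements drawn from per-species normal distributions
  truncated at zero, binary characters as Bernoulli scores, and
  endosymbiont infection states as Bernoulli draws.

Defaults reproduce the study conditions of the packaged reference dataset:
16 + 13 *juvernica*-like vs 12 + 5 *sinapis*-like specimens
(males + females), a maternal 631-bp COI-like locus with 15 diagnostic
sites, biparental ITS2- and CAD-like loci, measurement means/SDs and
binary-trait frequencies matching the reference summary table, and 91.8 %
infection prevalence.

A single root seed drives everything through independently spawned
substreams, so repeated runs are byte-identical and components can be
regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import (
    InfectionRecord,
    MultilocusGenotype,
    assemble_multilocus,
    call_by_diagnostic_states,
)
from .morphometrics import BINARY_TRAITS, MorphoRecord, records_to_frame
from .seqmodel import LocusAlignment, Specimen, write_locus_alignment

__all__ = [
    "LocusConfig",
    "SimulationConfig",
    "StudyBundle",
    "simulate_locus",
    "simulate_morphometrics",
    "simulate_infections",
    "simulate_study",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LocusConfig:
    """One simulated locus: length, site counts, and inheritance mode
    (``maternal`` loci are the ones swapped in introgressed specimens)."""

    name: str
    length: int
    n_diagnostic_sites: int
    n_intraspecific_sites: int = 0
    inheritance: str = "biparental"

    def __post_init__(self) -> None:
        if self.inheritance not in ("biparental", "maternal"):
            raise ValueError(f"invalid inheritance {self.inheritance!r}")
        if self.n_diagnostic_sites < 0 or self.n_intraspecific_sites < 0:
            raise ValueError("site counts must be >= 0")
        # two species draw intraspecific sites each
        if self.length < self.n_diagnostic_sites + 2 * self.n_intraspecific_sites:
            raise ValueError(
                f"{self.name}: length {self.length} too short for "
                f"{self.n_diagnostic_sites} diagnostic + "
                f"2x{self.n_intraspecific_sites} intraspecific sites"
            )


def _default_loci() -> tuple[LocusConfig, ...]:
    return (
        LocusConfig("COI", 631, 15, 3, "maternal"),
        LocusConfig("ITS2", 684, 1, 1, "biparental"),
        LocusConfig("CAD", 571, 2, 1, "biparental"),
    )


def _default_morpho() -> dict[str, dict[str, tuple[float, float]]]:
    # (mean, sd) in mm per species; S/V is derived per specimen, not drawn.
    return {
        "S": {"j": (0.81, 0.10), "s": (0.63, 0.07)},
        "V": {"j": (0.76, 0.07), "s": (0.84, 0.07)},
        "D": {"j": (0.96, 0.16), "s": (0.58, 0.03)},
    }


def _default_binary() -> dict[str, dict[str, float]]:
    # Bernoulli P(score = 1) per species, the observed male frequencies.
    return {
        "saccus_curvature": {"j": 15 / 16, "s": 6 / 12},
        "general_size": {"j": 13 / 16, "s": 4 / 12},
        "hindwing_suffusion": {"j": 16 / 16, "s": 3 / 12},
        "forewing_apex": {"j": 10 / 16, "s": 4 / 12},
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    species: tuple[str, str] = ("j", "s")
    n_males: Mapping[str, int] = field(
        default_factory=lambda: {"j": 16, "s": 12}
    )
    n_females: Mapping[str, int] = field(
        default_factory=lambda: {"j": 13, "s": 5}
    )
    loci: Sequence[LocusConfig] = field(default_factory=_default_loci)
    introgression_rate: float = 0.0
    morpho_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=_default_morpho
    )
    binary_params: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_binary
    )
    infection_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"j": 0.918, "s": 0.918}
    )

    def __post_init__(self) -> None:
        if len(self.species) != 2:
            raise ValueError("exactly two species labels required")
        if not 0 <= self.introgression_rate <= 1:
            raise ValueError("introgression_rate must lie in [0, 1]")
        for sp, p in self.infection_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"infection prevalence for {sp!r} outside [0, 1]")
        for trait, per_sp in self.morpho_params.items():
            for sp, (_, sd) in per_sp.items():
                if sd < 0:
                    raise ValueError(f"negative sd for {trait}/{sp}")
        for trait, per_sp in self.binary_params.items():
            for sp, p in per_sp.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability for {trait}/{sp} outside [0, 1]")

    def roster(self) -> list[Specimen]:
        """Deterministic specimen roster implied by the sample sizes."""
        out = []
        for sp in self.species:
            for i in range(int(self.n_males.get(sp, 0))):
                out.append(Specimen(f"{sp}M{i + 1:03d}", "male", sp))
            for i in range(int(self.n_females.get(sp, 0))):
                out.append(Specimen(f"{sp}F{i + 1:03d}", "female", sp))
        return out


def simulate_locus(
    cfg: SimulationConfig,
    locus: LocusConfig,
    labels: Mapping[str, str],
    rng: np.random.Generator,
    introgressed: set[str] | frozenset[str] = frozenset(),
) -> tuple[LocusAlignment, dict]:
    """Simulate one locus alignment plus its ground truth.

    ``labels`` maps specimen id -> true species.  Diagnostic sites are
    fixed-and-disjoint between the species; each species receives its own
    intraspecific segregating sites (minor-allele frequency uniform(0.1,
    0.5), carrier count clamped so the site is actually polymorphic in the
    sample); specimens in ``introgressed`` carry the other species' states
    at all diagnostic sites when the locus is maternally inherited.
    """
    sp_a, sp_b = cfg.species
    ids = list(labels)
    backbone = rng.choice(_BASES, size=locus.length)

    n_sites = locus.n_diagnostic_sites + 2 * locus.n_intraspecific_sites
    cols = rng.choice(locus.length, size=n_sites, replace=False)
    diag_cols = cols[: locus.n_diagnostic_sites]
    intra_cols = {
        sp_a: cols[
            locus.n_diagnostic_sites : locus.n_diagnostic_sites
            + locus.n_intraspecific_sites
        ],
        sp_b: cols[locus.n_diagnostic_sites + locus.n_intraspecific_sites :],
    }

    diagnostic_states: dict[int, dict[str, str]] = {}
    for col in diag_cols:
        base_a, base_b = rng.choice(_BASES, size=2, replace=False)
        diagnostic_states[int(col) + 1] = {sp_a: str(base_a), sp_b: str(base_b)}

    members = {sp: [i for i in ids if labels[i] == sp] for sp in cfg.species}
    intra_truth: dict[str, dict[int, dict]] = {sp: {} for sp in cfg.species}
    for sp in cfg.species:
        for col in intra_cols[sp]:
            ref = str(backbone[col])
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            freq = rng.uniform(0.1, 0.5)
            n_sp = len(members[sp])
            if n_sp < 2:
                continue  # cannot segregate in a sample of < 2
            count = int(np.clip(rng.binomial(n_sp, freq), 1, n_sp - 1))
            carriers = list(rng.choice(members[sp], size=count, replace=False))
            intra_truth[sp][int(col) + 1] = {
                "alt": alt,
                "frequency": freq,
                "carriers": carriers,
            }

    other = {sp_a: sp_b, sp_b: sp_a}
    sequences = {}
    for sid in ids:
        chars = backbone.copy()
        effective = labels[sid]
        if locus.inheritance == "maternal" and sid in introgressed:
            effective = other[effective]
        for pos, states in diagnostic_states.items():
            chars[pos - 1] = states[effective]
        # Intraspecific variation rides on the *true* species' background
        # only when the background itself was not swapped.
        for pos, info in intra_truth[effective].items():
            if sid in info["carriers"]:
                chars[pos - 1] = info["alt"]
        sequences[sid] = "".join(chars)

    aln = LocusAlignment(locus.name, sequences, ref_start=1)
    truth = {
        "diagnostic_states": diagnostic_states,
        "intraspecific": intra_truth,
        "inheritance": locus.inheritance,
    }
    return aln, truth


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws re-sampled until positive (lengths cannot be <= 0)."""
    if sd == 0:
        return np.full(size, mean)
    values = rng.normal(mean, sd, size)
    while np.any(values <= 0):
        bad = values <= 0
        values[bad] = rng.normal(mean, sd, int(bad.sum()))
    return values


def simulate_morphometrics(
    cfg: SimulationConfig,
    roster: Sequence[Specimen],
    rng: np.random.Generator,
) -> list[MorphoRecord]:
    """Draw S/V (males) and D (females) from the per-species normals and
    binary characters from the per-species Bernoulli frequencies."""
    records = []
    males = [s for s in roster if s.sex == "male"]
    females = [s for s in roster if s.sex == "female"]
    draws: dict[tuple[str, str], np.ndarray] = {}
    for trait in ("S", "V"):
        for sp in cfg.species:
            group = [s for s in males if s.species_label == sp]
            mean, sd = cfg.morpho_params[trait][sp]
            draws[(trait, sp)] = _truncated_normal(rng, mean, sd, len(group))
    for sp in cfg.species:
        group = [s for s in females if s.species_label == sp]
        mean, sd = cfg.morpho_params["D"][sp]
        draws[("D", sp)] = _truncated_normal(rng, mean, sd, len(group))

    index = {sp: 0 for sp in cfg.species}
    for spec in males:
        sp = spec.species_label
        i = index[sp]
        traits = {
            t: int(rng.random() < cfg.binary_params[t][sp]) for t in BINARY_TRAITS
        }
        records.append(
            MorphoRecord(
                specimen_id=spec.id,
                sex="male",
                molecular_label=sp,
                S=float(draws[("S", sp)][i]),
                V=float(draws[("V", sp)][i]),
                binary_traits=traits,
            )
        )
        index[sp] += 1
    index = {sp: 0 for sp in cfg.species}
    for spec in females:
        sp = spec.species_label
        records.append(
            MorphoRecord(
                specimen_id=spec.id,
                sex="female",
                molecular_label=sp,
                D=float(draws[("D", sp)][index[sp]]),
            )
        )
        index[sp] += 1
    return records


def simulate_infections(
    cfg: SimulationConfig,
    roster: Sequence[Specimen],
    rng: np.random.Generator,
) -> list[InfectionRecord]:
    return [
        InfectionRecord(
            specimen_id=s.id,
            group=s.species_label,
            sex=s.sex,
            infected=(
                "positive"
                if rng.random() < cfg.infection_prevalence[s.species_label]
                else "negative"
            ),
        )
        for s in roster
    ]


@dataclass
class StudyBundle:
    """Everything one simulated study produces, plus its ground truth."""

    config: SimulationConfig
    specimens: list[Specimen]
    labels: dict[str, str]
    introgressed: list[str]
    alignments: dict[str, LocusAlignment]
    locus_truth: dict[str, dict]
    caps_calls: pd.DataFrame
    genotypes: list[MultilocusGenotype]
    morpho: list[MorphoRecord]
    infections: list[InfectionRecord]

    def write(self, outdir: str | Path) -> None:
        """Write the bundle in the same formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, aln in self.alignments.items():
            write_locus_alignment(aln, outdir / f"{name}.fasta")
        pd.DataFrame(
            {
                "id": s.id,
                "sex": s.sex,
                "species_label": s.species_label,
            }
            for s in self.specimens
        ).to_csv(outdir / "specimens.tsv", sep="\t", index=False)
        self.caps_calls.to_csv(outdir / "caps_calls.tsv", sep="\t", index=False)
        records_to_frame(self.morpho).to_csv(
            outdir / "morphometrics.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {
                "id": r.specimen_id,
                "group": r.group,
                "sex": r.sex,
                "infected": r.infected,
            }
            for r in self.infections
        ).to_csv(outdir / "infection.tsv", sep="\t", index=False)
        truth = {
            "labels": self.labels,
            "introgressed": self.introgressed,
            "loci": {
                name: {
                    "inheritance": t["inheritance"],
                    "diagnostic_states": {
                        str(p): s for p, s in t["diagnostic_states"].items()
                    },
                }
                for name, t in self.locus_truth.items()
            },
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def simulate_study(cfg: SimulationConfig) -> StudyBundle:
    """Generate a full synthetic study driven by one root seed.

    Truth labels drive every component: sequences carry the species'
    diagnostic states (swapped at maternal loci for introgressed
    specimens), CAPS-style calls are derived from the simulated sequences
    via the diagnostic sites, morphometrics and infection states are drawn
    from the per-species models.
    """
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(3 + len(cfg.loci))
    rng_intro = np.random.default_rng(streams[0])
    rng_morpho = np.random.default_rng(streams[1])
    rng_infect = np.random.default_rng(streams[2])

    roster = cfg.roster()
    labels = {s.id: s.species_label for s in roster}
    introgressed = sorted(
        s.id for s in roster if rng_intro.random() < cfg.introgression_rate
    )

    alignments: dict[str, LocusAlignment] = {}
    locus_truth: dict[str, dict] = {}
    call_rows = []
    for locus, stream in zip(cfg.loci, streams[3:]):
        rng = np.random.default_rng(stream)
        aln, truth = simulate_locus(
            cfg, locus, labels, rng, introgressed=set(introgressed)
        )
        alignments[locus.name] = aln
        locus_truth[locus.name] = truth
        calls = call_by_diagnostic_states(aln, truth["diagnostic_states"])
        call_rows.extend(
            {"specimen": sid, "locus": locus.name, "call": call}
            for sid, call in calls.items()
        )
    caps_calls = pd.DataFrame(call_rows)
    genotypes = assemble_multilocus(caps_calls)
    morpho = simulate_morphometrics(cfg, roster, rng_morpho)
    infections = simulate_infections(cfg, roster, rng_infect)
    return StudyBundle(
        config=cfg,
        specimens=roster,
        labels=labels,
        introgressed=introgressed,
        alignments=alignments,
        locus_truth=locus_truth,
        caps_calls=caps_calls,
        genotypes=genotypes,
        morpho=morpho,
        infections=infections,
    )
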