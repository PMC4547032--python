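"""End-to-end orchestration: reproduce the full analysis as one run.

``run_pipeline`` executes the stages — polymorphic-site table and
diagnostic classification, group consensus comparison, p-distance
summaries, multilocus concordance, morphometric discrimination, infection
prevalence, and (when amplicon inputs are available) CAPS marker design —
writing one machine-readable report per stage plus a run log.  With no
inputs configured it analyses the packaged reference dataset.

Stage failures are collected and re-raised together with their stage
names; the command-line wrapper turns that into a non-zero exit status.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import fixtures
from .caps import GelModel, design_caps_markers, markers_to_frame
from .concordance import (
    assemble_multilocus,
    concordance_report,
    infection_prevalence,
    prevalence_from_counts,
    sex_ratio_test,
)
from .distances import group_distance_summary, pairwise_distances
from .morphometrics import (
    BINARY_TRAITS,
    MEASUREMENTS,
    gap_analysis,
    load_morpho_table,
    phi_coefficient,
    round_half_up,
    trait_group_summary,
    two_sample_t,
)
from .polymorphism import (
    build_site_table,
    classify_sites,
    consensus_difference_count,
    expand_to_specimens,
    reconstruct_alleles,
)
from .seqmodel import (
    load_enzyme_library,
    load_locus_alignment,
    load_specimen_table,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Aggregated stage failures, labelled by stage name."""

    def __init__(self, failures: dict[str, Exception]):
        self.failures = failures
        details = "; ".join(f"{stage}: {err}" for stage, err in failures.items())
        super().__init__(f"pipeline stage(s) failed: {details}")


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run.

    Any path left ``None`` falls back to the packaged reference dataset.
    ``group_labels`` are the two taxon labels compared throughout.
    """

    outdir: str | Path = "woodwhite_out"
    seed: int = 0
    group_labels: tuple[str, str] = ("j", "s")
    alignment_fasta: str | Path | None = None
    alignment_locus: str = "COI"
    alignment_ref_start: int = 1
    specimen_table: str | Path | None = None
    caps_calls: str | Path | None = None
    morpho_table: str | Path | None = None
    enzyme_library: str | Path | None = None
    amplicon_fasta_a: str | Path | None = None
    amplicon_fasta_b: str | Path | None = None
    gel_min_fragment: int = 50
    gel_min_diff: int = 20
    t_method: str = "welch_on_rounded_summaries"
    round_digits: int = 2
    bootstrap_replicates: int = 500

    def __post_init__(self) -> None:
        if len(self.group_labels) != 2 or not all(self.group_labels):
            raise ValueError("group_labels must be two non-empty labels")
        for name in (
            "alignment_fasta",
            "specimen_table",
            "caps_calls",
            "morpho_table",
            "enzyme_library",
            "amplicon_fasta_a",
            "amplicon_fasta_b",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured {name} does not exist: {path}")

    @property
    def gel(self) -> GelModel:
        return GelModel(self.gel_min_fragment, self.gel_min_diff)


def _load_alignment_stage(config: RunConfig):
    """Alignment + grouping, from configured files or the reference data."""
    if config.alignment_fasta is not None:
        aln = load_locus_alignment(
            config.alignment_fasta,
            config.alignment_locus,
            ref_start=config.alignment_ref_start,
        )
        grouping = {}
        if config.specimen_table is not None:
            grouping = {
                s.id: s.species_label
                for s in load_specimen_table(config.specimen_table)
            }
        table = build_site_table(aln, grouping)
        return aln, table
    table = fixtures.coi_site_table()
    aln = reconstruct_alleles(table, fixtures.COI_LENGTH)
    return aln, table


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; write reports under ``config.outdir``.

    Returns the in-memory report bundle (one entry per stage).  Raises
    :class:`PipelineError` after all stages ran if any failed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ga, gb = config.group_labels
    reports: dict = {}
    failures: dict[str, Exception] = {}

    aln = table = None
    try:
        logger.info("stage sites: building polymorphic-site table")
        aln, table = _load_alignment_stage(config)
        classification, n_diag = classify_sites(table, ga, gb)
        n_consensus, consensus_positions, _ = consensus_difference_count(
            table, ga, gb
        )
        table.write_tsv(outdir / "site_table.tsv")
        reports["sites"] = {
            "locus": table.locus,
            "n_polymorphic": len(table.positions),
            "n_haplotypes": len(table.haplotypes),
            "n_diagnostic": n_diag,
            "diagnostic_positions": [
                p for p, c in sorted(classification.items()) if c == "diagnostic"
            ],
            "n_consensus_differences": n_consensus,
            "consensus_positions": consensus_positions,
        }
    except Exception as err:  # noqa: BLE001 - stage isolation
        failures["sites"] = err
        logger.exception("stage sites failed")

    try:
        if table is None or aln is None:
            raise RuntimeError("site stage unavailable")
        logger.info("stage distances: p-distance summaries")
        specimen_aln = expand_to_specimens(aln, table)
        grouping = {}
        for hap in table.haplotypes:
            for sid in hap.carrier_specimens:
                grouping[sid] = table.group_assignment[hap.allele_id]
        matrix = pairwise_distances(specimen_aln)
        summary = group_distance_summary(
            matrix,
            grouping,
            alignment=specimen_aln,
            n_bootstrap=config.bootstrap_replicates,
            seed=config.seed,
        )
        matrix.to_long_frame().to_csv(
            outdir / "distances_long.tsv", sep="\t", index=False
        )
        summary.write_tsv(outdir / "distance_summary.tsv")
        pair = summary.get(ga, gb)
        reports["distances"] = {
            "mean": pair.mean,
            "minimum": pair.minimum,
            "se": pair.se,
            "se_bootstrap": pair.se_bootstrap,
            "n_pairs": pair.n_pairs,
        }
    except Exception as err:  # noqa: BLE001
        failures["distances"] = err
        logger.exception("stage distances failed")

    try:
        if config.amplicon_fasta_a and config.amplicon_fasta_b:
            logger.info("stage caps: marker design")
            enzymes = (
                load_enzyme_library(config.enzyme_library)
                if config.enzyme_library
                else fixtures.default_enzyme_library()
            )
            aln_a = load_locus_alignment(config.amplicon_fasta_a, "ampliconA")
            aln_b = load_locus_alignment(config.amplicon_fasta_b, "ampliconB")
            markers = design_caps_markers(
                list(aln_a.sequences.values()),
                list(aln_b.sequences.values()),
                enzymes,
                gel=config.gel,
                labels=(ga, gb),
            )
            markers_to_frame(markers).to_csv(
                outdir / "caps_markers.tsv", sep="\t", index=False
            )
            reports["caps"] = {"n_markers": len(markers)}
    except Exception as err:  # noqa: BLE001
        failures["caps"] = err
        logger.exception("stage caps failed")

    try:
        logger.info("stage concordance: multilocus genotypes")
        calls = (
            pd.read_csv(config.caps_calls, sep="\t", comment="#")
            if config.caps_calls is not None
            else fixtures.caps_call_frame()
        )
        genotypes = assemble_multilocus(calls)
        report = concordance_report(genotypes)
        (outdir / "concordance.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        reports["concordance"] = report.to_dict()
    except Exception as err:  # noqa: BLE001
        failures["concordance"] = err
        logger.exception("stage concordance failed")

    try:
        logger.info("stage morpho: morphometric discrimination")
        records = (
            load_morpho_table(config.morpho_table)
            if config.morpho_table is not None
            else fixtures.morpho_records()
        )
        morpho_report = _morphometrics_stage(records, config)
        pd.DataFrame(morpho_report["summaries"]).to_csv(
            outdir / "morpho_summary.tsv", sep="\t", index=False
        )
        (outdir / "morpho_tests.json").write_text(
            json.dumps(
                {k: v for k, v in morpho_report.items() if k != "summaries"},
                indent=2,
            )
        )
        # Scatter data for the classic S-vs-V and S/V-vs-S plots.
        males = [r for r in records if r.sex == "male" and r.S and r.V]
        pd.DataFrame(
            {
                "id": r.specimen_id,
                "molecular_label": r.molecular_label,
                "S": r.S,
                "V": r.V,
                "S_over_V": r.S_over_V,
            }
            for r in males
        ).to_csv(outdir / "morpho_scatter.tsv", sep="\t", index=False)
        reports["morpho"] = morpho_report
    except Exception as err:  # noqa: BLE001
        failures["morpho"] = err
        logger.exception("stage morpho failed")

    try:
        logger.info("stage prevalence: infection screening")
        rows = []
        for (group, sex), (pos, tested) in fixtures.wsp_screen_counts().items():
            rows.append(
                {"group": group, "sex": sex, **prevalence_from_counts(pos, tested)}
            )
        # Pooled united-sample row over both sexes.
        sj = [
            v
            for (g, _), v in fixtures.wsp_screen_counts().items()
            if g == "sinapis+juvernica"
        ]
        pos, tested = sum(v[0] for v in sj), sum(v[1] for v in sj)
        rows.append(
            {
                "group": "sinapis+juvernica",
                "sex": "both",
                **prevalence_from_counts(pos, tested),
            }
        )
        prev = pd.DataFrame(rows)
        prev.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)
        reports["prevalence"] = rows
        reports["sex_ratio"] = sex_ratio_test(fixtures.infection_records())
    except Exception as err:  # noqa: BLE001
        failures["prevalence"] = err
        logger.exception("stage prevalence failed")

    run_log = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            k: str(v) for k, v in dataclasses.asdict(config).items()
        },
        "stages_completed": sorted(reports),
        "stages_failed": sorted(failures),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    (outdir / "report.json").write_text(json.dumps(reports, indent=2, default=str))

    if failures:
        raise PipelineError(failures)
    return reports


def _morphometrics_stage(records, config: RunConfig) -> dict:
    ga, gb = config.group_labels
    nd = config.round_digits
    summaries = []
    tests = {}
    gaps = {}
    for trait in MEASUREMENTS:
        try:
            per_group = trait_group_summary(records, trait)
        except ValueError:
            continue
        for s in per_group:
            r = s.rounded(nd)
            summaries.append(
                {
                    "trait": trait,
                    "group": s.group,
                    "n": s.n,
                    "mean": r.mean,
                    "sd": r.sd,
                }
            )
        by_group = {s.group: s for s in per_group}
        if ga in by_group and gb in by_group:
            res = two_sample_t(
                by_group[ga], by_group[gb], method=config.t_method, trait=trait
            )
            tests[trait] = {
                "method": res.method,
                "t": round_half_up(res.t, nd),
                "df": res.df,
                "p": res.p,
            }
            gap = gap_analysis(records, trait, groups=(ga, gb))
            gaps[trait] = {
                "gap": gap.gap,
                "interval": [round_half_up(x, nd) for x in gap.interval],
                "lower_group": gap.lower_group,
                "upper_group": gap.upper_group,
            }
    phis = {}
    for trait in BINARY_TRAITS:
        try:
            res = phi_coefficient(records, trait, groups=(ga, gb))
        except ValueError:
            continue
        phis[trait] = {
            "phi": round_half_up(res.phi, nd),
            "chi_square": res.chi_square,
            "p": res.p,
            "counts": list(res.counts),
        }
    return {"summaries": summaries, "t_tests": tests, "gaps": gaps, "phi": phis}
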