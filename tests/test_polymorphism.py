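"""Site tables, diagnostic classification, consensus comparison, codon
annotation, and allele reconstruction."""

import pytest
from hypothesis import given, strategies as st

from woodwhite import (
    LocusAlignment,
    annotate_coding_substitution,
    build_site_table,
    classify_sites,
    consensus_difference_count,
    reconstruct_alleles,
)
from woodwhite import fixtures

DIAGNOSTIC_POSITIONS = [
    1530, 1599, 1624, 1659, 1720, 1854, 1860, 1914,
    1926, 1947, 1959, 2103, 2121, 2133, 2148,
]


def _toy_alignment(seqs, grouping=None, ref_start=1):
    return build_site_table(
        LocusAlignment("toy", seqs, ref_start=ref_start), grouping or {}
    )


class TestBuildSiteTable:
    def test_reference_matrix_recovered_from_alignment(self, coi_table, coi_alleles):
        """Reconstructing the six alleles and re-tabulating recovers the
        21 polymorphic positions and the carrier partition."""
        grouping = {
            sid: coi_table.group_assignment[h.allele_id]
            for h in coi_table.haplotypes
            for sid in h.carrier_specimens
        }
        from woodwhite import expand_to_specimens

        specimen_aln = expand_to_specimens(coi_alleles, coi_table)
        rebuilt = build_site_table(specimen_aln, grouping)
        assert rebuilt.positions == coi_table.positions
        assert len(rebuilt.haplotypes) == 6
        carrier_sets = {frozenset(h.carrier_specimens) for h in rebuilt.haplotypes}
        assert carrier_sets == {
            frozenset({"L10", "L11", "L14"}),
            frozenset({"L12", "L13"}),
            frozenset({"L19"}),
            frozenset({"L15"}),
            frozenset({"L16", "L17"}),
            frozenset({"L18"}),
        }

    def test_identical_sequences_no_polymorphism(self):
        table = _toy_alignment({"a": "ACGT", "b": "ACGT"})
        assert table.positions == []
        assert len(table.haplotypes) == 1

    def test_amurensis_single_site(self):
        """The 13-specimen sample: one T/A site at 1969, carriers 12 vs 1."""
        table = fixtures.amurensis_coi_site_table()
        aln = reconstruct_alleles(table, fixtures.COI_LENGTH)
        from woodwhite import expand_to_specimens

        rebuilt = build_site_table(expand_to_specimens(aln, table), {})
        assert rebuilt.positions == [1969]
        counts = sorted(h.n_carriers for h in rebuilt.haplotypes)
        assert counts == [1, 12]

    def test_ambiguity_columns_flagged(self):
        table = _toy_alignment({"a": "ACGT", "b": "ARGT"})
        assert table.positions == [2]
        assert table.flagged_positions == [2]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            LocusAlignment("x", {})


class TestClassifySites:
    def test_reference_diagnostic_set(self, coi_table):
        classification, n = classify_sites(coi_table, "j", "s")
        assert n == 15
        diag = [p for p, c in sorted(classification.items()) if c == "diagnostic"]
        assert diag == DIAGNOSTIC_POSITIONS

    def test_identical_fixed_groups(self):
        table = _toy_alignment(
            {"a": "ACG", "b": "ACT"}, {"a": "A", "b": "B"}
        )
        # one polymorphic position, diagnostic (both fixed, disjoint)
        _, n = classify_sites(table, "A", "B")
        assert n == 1

    def test_unfixed_group_not_diagnostic(self):
        """A-group {ACG, ACG}, B-group {TCG, ACG}: site 1 not fixed in B."""
        table = _toy_alignment(
            {"a1": "ACG", "a2": "ACG", "b1": "TCG", "b2": "ACG"},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        _, n = classify_sites(table, "A", "B")
        assert n == 0

    def test_unknown_group_rejected(self, coi_table):
        with pytest.raises(ValueError, match="no alleles"):
            classify_sites(coi_table, "j", "nosuch")

    def test_invariant_under_relabeling(self, coi_table):
        _, forward = classify_sites(coi_table, "j", "s")
        _, backward = classify_sites(coi_table, "s", "j")
        assert forward == backward


class TestConsensusDifferences:
    def test_reference_matrix_count(self, coi_table):
        """Carrier-weighted majority consensuses of the j and s groups
        differ at the 15 diagnostic positions plus 1587, 1674 and 1917,
        where the minority allele carries the other group's state."""
        n, positions, states = consensus_difference_count(coi_table, "j", "s")
        assert n == 18
        assert set(positions) == set(DIAGNOSTIC_POSITIONS) | {1587, 1674, 1917}
        assert states[1587] == ("A", "G")
        assert states[1917] == ("C", "T")

    def test_weighting_modes_agree_on_reference(self, coi_table):
        n_w, pos_w, _ = consensus_difference_count(coi_table, "j", "s", weighted=True)
        n_u, pos_u, _ = consensus_difference_count(coi_table, "j", "s", weighted=False)
        assert (n_w, pos_w) == (n_u, pos_u)

    def test_diagnostic_subset_of_consensus_differences(self, coi_table):
        classification, _ = classify_sites(coi_table, "j", "s")
        _, positions, _ = consensus_difference_count(coi_table, "j", "s")
        diagnostic = {p for p, c in classification.items() if c == "diagnostic"}
        assert diagnostic <= set(positions)

    def test_hand_majority(self):
        """A {A,A,T} (carriers 2,1) vs B {T}: weighted majority A vs T."""
        table = _toy_alignment(
            {"a1": "A", "a2": "A", "a3": "T", "b1": "T"},
            {"a1": "A", "a2": "A", "a3": "A", "b1": "B"},
        )
        n, positions, _ = consensus_difference_count(table, "A", "B")
        assert (n, positions) == (1, [1])

    def test_identical_groups(self):
        table = _toy_alignment(
            {"a": "ACGT", "b": "ACGT"}, {"a": "A", "b": "B"}
        )
        n, _, _ = consensus_difference_count(table, "A", "B")
        assert n == 0

    def test_tie_broken_toward_shared_state(self):
        """Equal carrier weights within A at a site where one allele matches
        B's consensus: the conservative tie-break yields no difference."""
        table = _toy_alignment(
            {"a1": "A", "a2": "G", "b1": "G"},
            {"a1": "A", "a2": "A", "b1": "B"},
        )
        n, _, _ = consensus_difference_count(table, "A", "B")
        assert n == 0


class TestCodingAnnotation:
    def test_first_codon_position_change(self):
        ann = annotate_coding_substitution(747, 346, "G", "A")
        assert (ann.codon_number, ann.codon_position) == (116, 1)
        assert ann.synonymous is None

    @pytest.mark.parametrize(
        "pos, codon_position", [(570, 3), (654, 3), (27, 3), (456, 3), (36, 3)]
    )
    def test_third_position_sites(self, pos, codon_position):
        ann = annotate_coding_substitution(747, pos, "G", "A")
        assert ann.codon_position == codon_position

    def test_boundary(self):
        ann = annotate_coding_substitution(747, 3, "G", "A")
        assert (ann.codon_number, ann.codon_position) == (1, 3)

    def test_synonymy_from_context(self):
        # ATG GCA: pos 4 G->A makes GCA->ACA (Ala->Thr, non-synonymous);
        # pos 6 A->G makes GCA->GCG (still Ala, synonymous).
        ann = annotate_coding_substitution(6, 4, "G", "A", cds_sequence="ATGGCA")
        assert ann.synonymous is False and ann.aa_change == "A2T"
        ann = annotate_coding_substitution(6, 6, "A", "G", cds_sequence="ATGGCA")
        assert ann.synonymous is True and ann.aa_change is None

    def test_genetic_code_matters(self):
        # AGA codes Arg (standard) but Ser (invertebrate mitochondrial):
        # AGA->AGG is synonymous in both, AGA->GGA is not; a cleaner probe
        # is ATA (Ile standard / Met invert-mito) vs ATG.
        ann_std = annotate_coding_substitution(
            3, 3, "A", "G", genetic_code="standard", cds_sequence="ATA"
        )
        ann_mito = annotate_coding_substitution(
            3, 3, "A", "G", genetic_code="invertebrate_mitochondrial",
            cds_sequence="ATA",
        )
        assert ann_std.synonymous is False  # Ile -> Met
        assert ann_mito.synonymous is True  # Met -> Met

    def test_errors(self):
        with pytest.raises(ValueError):
            annotate_coding_substitution(747, 748, "G", "A")
        with pytest.raises(ValueError):
            annotate_coding_substitution(746, 10, "G", "A")


class TestReconstructAlleles:
    def test_reference_pair_differences(self, coi_table, coi_alleles):
        seqs = coi_alleles.sequences
        diff = lambda a, b: sum(x != y for x, y in zip(seqs[a], seqs[b]))
        assert diff("s2", "s3") == 1  # only position 2076
        assert diff("s1", "j3") == 15  # exactly the diagnostic set

    def test_empty_table_identical(self):
        from woodwhite import SiteTable, Haplotype

        table = SiteTable(
            locus="x",
            positions=[],
            haplotypes=[Haplotype("a", {}, ["c1"]), Haplotype("b", {}, ["c2"])],
            group_assignment={"a": "A", "b": "B"},
        )
        aln = reconstruct_alleles(table, 10)
        assert len(set(aln.sequences.values())) == 1

    def test_position_out_of_range(self, coi_table):
        with pytest.raises(ValueError, match="outside"):
            reconstruct_alleles(coi_table, 100)

    def test_roundtrip_recovers_table(self, coi_table):
        """reconstruct_alleles then build_site_table is the identity on the
        (positions, per-position state pattern, carrier multiset) content."""
        aln = reconstruct_alleles(coi_table, fixtures.COI_LENGTH)
        from woodwhite import expand_to_specimens

        rebuilt = build_site_table(expand_to_specimens(aln, coi_table), {})
        assert rebuilt.positions == coi_table.positions
        original = {
            p: sorted(
                (tuple(sorted(h.carrier_specimens)), h.states[p])
                for h in coi_table.haplotypes
            )
            for p in coi_table.positions
        }
        recovered = {
            p: sorted(
                (tuple(sorted(h.carrier_specimens)), h.states[p])
                for h in rebuilt.haplotypes
            )
            for p in rebuilt.positions
        }
        assert original == recovered

    @given(data=st.data())
    def test_roundtrip_random_tables(self, data):
        from woodwhite import Haplotype, SiteTable

        length = data.draw(st.integers(5, 30))
        n_alleles = data.draw(st.integers(2, 4))
        positions = data.draw(
            st.lists(st.integers(1, length), min_size=1, max_size=5, unique=True)
        )
        states = {}
        for pos in positions:
            # guarantee >= 2 states across alleles at each listed position
            column = data.draw(
                st.lists(
                    st.sampled_from("ACGT"),
                    min_size=n_alleles,
                    max_size=n_alleles,
                ).filter(lambda c: len(set(c)) >= 2)
            )
            states[pos] = column
        haplotypes = [
            Haplotype(
                f"h{i}", {p: states[p][i] for p in positions}, [f"c{i}"]
            )
            for i in range(n_alleles)
        ]
        table = SiteTable(
            locus="r",
            positions=list(positions),
            haplotypes=haplotypes,
            group_assignment={f"h{i}": "A" for i in range(n_alleles)},
        )
        aln = reconstruct_alleles(table, length, backbone="C")
        rebuilt = build_site_table(aln, {})
        # Some drawn columns may coincide in pattern with the backbone for a
        # subset of alleles; positions where alleles truly differ must match.
        assert rebuilt.positions == sorted(
            p for p in positions
            if len({h.states[p] for h in haplotypes}) >= 2
        )
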