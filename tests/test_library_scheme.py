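"""Library scheme model: fixture structure, validation, frequencies, diversity."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.Seq import Seq

from degenlib import (
    STOP,
    DegenerateCodon,
    LibraryScheme,
    RandomizedPosition,
    diversity,
    expand_codon,
    expected_distinct_variants,
    nanobody_cdr3_14_scheme,
    restriction_site_risk,
    theoretical_frequencies,
    validate_scheme,
)
from conftest import make_scheme


class TestBuiltinScheme:
    def test_has_25_randomized_positions(self, builtin_scheme):
        assert len(builtin_scheme.positions) == 25
        by_region = {}
        for p in builtin_scheme.positions:
            by_region.setdefault(p.region, []).append(p)
        assert len(by_region["CDR1"]) == 7
        assert len(by_region["CDR2"]) == 4
        assert len(by_region["CDR3"]) == 14

    def test_cdr1_cdr2_codon_assignments(self, builtin_scheme):
        expected = {
            "27": "DMY", "28": "VRN", "30": "HWY", "31": "VRN",
            "33": "DMY", "34": "VNN", "36": "KMY",
            "55": "KMY", "56": "WBG", "57": "VRN", "60": "ADM",
        }
        for label, codon in expected.items():
            assert builtin_scheme.position(label).codon.bases == codon

    def test_cdr3_codon_string(self, builtin_scheme):
        cdr3 = sorted(
            (p for p in builtin_scheme.positions if p.region == "CDR3"),
            key=lambda p: p.codon_index,
        )
        assert [p.codon.bases for p in cdr3] == [
            "VNN", "VRN", "WMY", "VRN", "WMY", "VNN", "WMY",
            "VRN", "WMY", "VNN", "WMY", "TWY", "VRN", "TMY",
        ]
        assert cdr3[-3].label == "115" and cdr3[-3].codon.bases == "TWY"
        assert cdr3[-2].label == "116" and cdr3[-2].codon.bases == "VRN"
        assert cdr3[-1].label == "117" and cdr3[-1].codon.bases == "TMY"

    def test_validates_clean(self, builtin_scheme):
        assert validate_scheme(builtin_scheme) == []

    def test_template_is_in_frame_and_consistent(self, builtin_scheme):
        assert len(builtin_scheme.template_nt) % 3 == 0
        for p in builtin_scheme.positions:
            assert builtin_scheme.template_codon(p.codon_index) == p.codon.bases

    def test_json_round_trip(self, builtin_scheme, tmp_path):
        path = tmp_path / "scheme.json"
        builtin_scheme.to_json(path)
        back = LibraryScheme.from_json(path)
        assert back == builtin_scheme

    def test_fasta_and_tsv_exports(self, builtin_scheme):
        fasta = builtin_scheme.template_fasta()
        assert fasta.startswith(">nanobody-cdr3-14\n")
        assert "".join(fasta.splitlines()[1:]) == builtin_scheme.template_nt
        tsv = builtin_scheme.positions_tsv()
        assert len(tsv.strip().splitlines()) == 26  # header + 25 positions


class TestValidation:
    def test_stop_reachable_flagged(self):
        s = make_scheme(["NNN"])
        assert any("stop reachable" in v for v in validate_scheme(s))

    def test_cys_reachable_flagged(self):
        s = make_scheme(["TGY"])
        assert any("residue C reachable" in v for v in validate_scheme(s))

    def test_mutating_builtin_codon_to_cys_fails(self, builtin_scheme):
        bad_positions = []
        for p in builtin_scheme.positions:
            if p.label == "117":
                p = RandomizedPosition(p.codon_index, p.label,
                                       DegenerateCodon("TGY"), p.region)
                idx = p.codon_index
            bad_positions.append(p)
        t = builtin_scheme.template_nt
        bad_template = t[: 3 * idx] + "TGY" + t[3 * idx + 3 :]
        bad = LibraryScheme(
            name="bad", template_nt=bad_template, positions=tuple(bad_positions),
            forbidden=builtin_scheme.forbidden,
        )
        assert any("reachable" in v for v in validate_scheme(bad))

    def test_template_codon_mismatch_flagged(self):
        s = make_scheme(["TWY"])
        # declare WMY but leave TWY in the template
        bad = LibraryScheme(
            name=s.name, template_nt=s.template_nt,
            positions=(RandomizedPosition(5, "p1", DegenerateCodon("WMY"), "R1"),),
            forbidden=s.forbidden,
        )
        assert any("differs from declared" in v for v in validate_scheme(bad))

    def test_out_of_frame_template_flagged(self):
        s = make_scheme(["TWY"])
        bad = LibraryScheme(
            name="bad", template_nt=s.template_nt + "AC",
            positions=s.positions, forbidden=s.forbidden,
        )
        assert any("divisible by 3" in v for v in validate_scheme(bad))


class TestTheoreticalFrequencies:
    def test_terminal_cdr3_positions(self, builtin_scheme):
        table = theoretical_frequencies(builtin_scheme)
        assert table.frequencies("117") == {"S": 0.5, "Y": 0.5}
        assert table.frequencies("115") == {"F": 0.5, "Y": 0.5}
        assert table.frequencies("28")["R"] == pytest.approx(6 / 24)

    def test_rows_sum_to_one(self, builtin_scheme):
        table = theoretical_frequencies(builtin_scheme)
        for label in table.labels:
            assert sum(table.frequencies(label).values()) == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.text(alphabet="ACGTRYSWKMBDHVN", min_size=3, max_size=3),
            min_size=1,
            max_size=4,
        )
    )
    def test_rows_sum_to_one_on_random_schemes(self, codons):
        s = make_scheme(codons, forbidden=())
        table = theoretical_frequencies(s)
        for label in table.labels:
            assert sum(table.frequencies(label).values()) == pytest.approx(1.0, abs=1e-9)


def brute_force_protein_diversity(scheme):
    """Enumerate every concrete realization, translate, count distinct proteins."""
    expansions = [expand_codon(p.codon) for p in scheme.positions]
    proteins = set()
    for combo in itertools.product(*expansions):
        proteins.add(tuple(str(Seq(c).translate()) for c in combo))
    return len(proteins)


class TestDiversity:
    def test_cdr2_only_protein_diversity(self, cdr2_scheme):
        rep = diversity(cdr2_scheme)
        assert rep.protein_diversity == 4 * 6 * 9 * 5 == 1080
        assert rep.dna_diversity == 8 * 6 * 24 * 6

    @pytest.mark.parametrize(
        "codons",
        [["TWY"], ["TMY", "WMY"], ["KMY", "WBG", "HWY"], ["ADM", "DMY", "TWY", "KMY"]],
    )
    def test_protein_diversity_matches_brute_force(self, codons):
        s = make_scheme(codons)
        assert diversity(s).protein_diversity == brute_force_protein_diversity(s)

    def test_dna_at_least_protein_at_least_one(self, builtin_scheme):
        rep = diversity(builtin_scheme)
        assert rep.dna_diversity >= rep.protein_diversity >= 1
        # far beyond 64-bit range: exact integers required
        assert rep.dna_diversity > 2**64

    def test_equiprobable_entropy_is_log2_k(self, builtin_scheme):
        rep = diversity(builtin_scheme)
        assert rep.per_position_entropy["117"] == pytest.approx(1.0)  # TMY: 2 residues
        wmy_labels = [
            p.label for p in builtin_scheme.positions if p.codon.bases == "WMY"
        ]
        assert rep.per_position_entropy[wmy_labels[0]] == pytest.approx(2.0)

    def test_empty_scheme_has_unit_diversity(self):
        s = LibraryScheme(name="fixed", template_nt="ATGGCTGCAGCTTAA", positions=())
        rep = diversity(s)
        assert rep.dna_diversity == rep.protein_diversity == 1

    def test_order_invariance(self, cdr2_scheme):
        reordered = LibraryScheme(
            name=cdr2_scheme.name,
            template_nt=cdr2_scheme.template_nt,
            positions=tuple(reversed(cdr2_scheme.positions)),
            forbidden=cdr2_scheme.forbidden,
        )
        a, b = diversity(cdr2_scheme), diversity(reordered)
        assert a.dna_diversity == b.dna_diversity
        assert a.protein_diversity == b.protein_diversity

    def test_sampling_ratio(self, cdr2_scheme):
        rep = diversity(cdr2_scheme, transformants=540)
        assert rep.sampling_ratio == pytest.approx(0.5)
        assert rep.log10_sampling_ratio == pytest.approx(math.log10(0.5))


class TestOccupancy:
    def test_expected_distinct_matches_direct_enumeration(self):
        s = make_scheme(["TWY", "WMY"])
        n = 10
        # independent route: enumerate every variant probability directly
        freqs = []
        for p in s.positions:
            prof = p.codon.profile()
            freqs.append([c / prof.total_codons for c in prof.counts.values()])
        expected = sum(
            1 - (1 - math.prod(combo)) ** n
            for combo in itertools.product(*freqs)
        )
        assert expected_distinct_variants(s, n) == pytest.approx(expected, rel=1e-12)

    def test_refuses_oversized_spaces(self, builtin_scheme):
        with pytest.raises(ValueError, match="exceeds"):
            expected_distinct_variants(builtin_scheme, 100)


class TestRestrictionRisk:
    def test_exact_match_is_guaranteed(self):
        s = LibraryScheme(name="t", template_nt="CCATGG", positions=())
        hits = restriction_site_risk(s, ["CCATGG"])
        assert len(hits) == 1 and hits[0].guaranteed and hits[0].offset == 0

    def test_degenerate_overlap_is_possible_not_guaranteed(self):
        s = LibraryScheme(
            name="t", template_nt="CCATGS",
            positions=(RandomizedPosition(1, "p1", DegenerateCodon("TGS"), "R1"),),
            forbidden=frozenset(),
        )
        hits = restriction_site_risk(s, ["CCATGG"])
        assert len(hits) == 1 and not hits[0].guaranteed

    def test_no_hit(self):
        s = LibraryScheme(name="t", template_nt="AAAAAA", positions=())
        assert restriction_site_risk(s, ["CCATGG"]) == []

    def test_empty_pattern_rejected(self):
        s = LibraryScheme(name="t", template_nt="AAAAAA", positions=())
        with pytest.raises(ValueError):
            restriction_site_risk(s, [""])

    def test_builtin_scheme_free_of_cloning_sites(self, builtin_scheme):
        # NcoI and NotI must stay unique to the vector: no guaranteed internal site
        hits = restriction_site_risk(builtin_scheme, ["CCATGG", "GCGGCCGC"])
        assert all(not h.guaranteed for h in hits)
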