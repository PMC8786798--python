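import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tlpfam.identification import (
    THAUMATIN_SIGNATURE,
    MotifDefinition,
    check_reddd,
    classify_size,
    compute_mw,
    compute_pi,
    physicochemical_profile,
    scan_signature,
    screen_candidates,
)
from tlpfam.sequence_io import SequenceRecord

from .oracles import mw_oracle_kda, prosite_scan_oracle

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _protein(seq, pid="p"):
    return SequenceRecord(pid, seq)


class TestSignatureScan:
    def test_planted_instance_spans_full_match(self):
        hits = scan_signature(_protein("GAGACATGDCAGAAC"))
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 15)
        assert hits[0].matched_substring == "GAGACATGDCAGAAC"

    def test_no_hits_on_low_complexity(self):
        assert scan_signature(_protein("AAAAAAAA")) == []

    def test_matched_substring_equals_protein_slice(self):
        seq = "MK" + "GAGACATGDCAGAAC" + "WY"
        (hit,) = scan_signature(_protein(seq))
        assert hit.matched_substring == seq[hit.start - 1 : hit.end]

    def test_shortest_run_expansion_reported(self):
        # X(1,2) then G then X(2,3) then C: both short and long expansions
        # exist here; the non-greedy scanner must report the short one
        seq = "GAGACATGDCAGAACGAAC"
        (first, *_) = scan_signature(_protein(seq))
        assert first.end == 15

    def test_matches_exhaustive_oracle_on_random_proteins(self, rng):
        for _ in range(40):
            seq = "".join(rng.choice(list("GFCATD" + AA20), size=300))
            got = [(h.start, h.end) for h in scan_signature(_protein(seq))]
            want = prosite_scan_oracle(seq, THAUMATIN_SIGNATURE.positions)
            assert got == want

    def test_pattern_requires_a_fixed_position(self):
        with pytest.raises(ValueError, match="fixed"):
            MotifDefinition.from_prosite("X-X(1,2)", name="bad")


class TestScreen:
    def test_only_motif_bearing_candidates_accepted(self):
        with_motif = _protein("MK" + "GAGACATGDCAGAAC" + "LL", "yes")
        plain = [_protein("M" + "K" * 30, "no1"), _protein("M" + "L" * 40, "no2")]
        accepted, rejected = screen_candidates([with_motif, *plain])
        assert [p.id for p in accepted] == ["yes"]
        assert sorted(p.id for p, _ in rejected) == ["no1", "no2"]
        assert all("thaumatin_signature" in reason for _, reason in rejected)

    def test_empty_input(self):
        assert screen_candidates([]) == ([], [])


class TestSizeClassification:
    @pytest.mark.parametrize(
        "domain_len, mw, expected",
        [(210, 30.0, "long"), (150, 18.0, "small"), (150, 25.0, "ambiguous")],
    )
    def test_threshold_rules(self, domain_len, mw, expected):
        profile = physicochemical_profile(_protein("A" * 100))
        profile = type(profile)(100, mw, profile.pi, profile.cysteine_count)
        assert classify_size(profile, domain_len).size_class == expected

    def test_nonpositive_domain_length_rejected(self):
        profile = physicochemical_profile(_protein("A" * 10))
        with pytest.raises(ValueError):
            classify_size(profile, 0)

    def test_partition_is_total(self, rng):
        classes = []
        for _ in range(30):
            n = int(rng.integers(50, 400))
            seq = "".join(rng.choice(list(AA20), size=n))
            profile = physicochemical_profile(_protein(seq))
            classes.append(classify_size(profile, n).size_class)
        assert all(c in ("long", "small", "ambiguous") for c in classes)


class TestMolecularWeight:
    def test_single_glycine(self):
        assert compute_mw(_protein("G")) == pytest.approx(0.0750672, abs=1e-7)

    def test_two_glycines(self):
        assert compute_mw(_protein("GG")) == pytest.approx(0.1321191, abs=1e-7)

    def test_matches_independent_mass_table(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list(AA20), size=int(rng.integers(1, 200))))
            assert compute_mw(_protein(seq)) == pytest.approx(
                mw_oracle_kda(seq), abs=1e-6
            )

    @given(
        a=st.text(AA20, min_size=1, max_size=30),
        b=st.text(AA20, min_size=1, max_size=30),
    )
    def test_additive_up_to_one_water(self, a, b):
        whole = compute_mw(_protein(a + b))
        parts = compute_mw(_protein(a)) + compute_mw(_protein(b)) - 18.0153 / 1000
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_unknown_residue_warns(self):
        with pytest.warns(UserWarning, match="unknown residue"):
            compute_mw(_protein("GXG"))


class TestIsoelectricPoint:
    def test_basic_residue_dominates(self):
        assert compute_pi(_protein("K")) > 7

    def test_acidic_residue_dominates(self):
        assert compute_pi(_protein("D")) < 7

    def test_composition_only(self):
        assert compute_pi(_protein("DK")) == compute_pi(_protein("KD"))

    def test_monotone_in_charged_residues(self):
        base = "GAVLG"
        pi0 = compute_pi(_protein(base))
        assert compute_pi(_protein(base + "D")) <= pi0
        assert compute_pi(_protein(base + "K")) >= pi0

    def test_charge_balance_at_reported_pi(self):
        from tlpfam.identification import net_charge

        seq = "MKDEHRCYSTW"
        pi = compute_pi(_protein(seq))
        assert abs(net_charge(_protein(seq), pi)) < 1e-4


class TestReddd:
    COLUMNS = (10, 20, 30, 40, 50)

    def _alignment(self, residues):
        aligned = list("A" * 60)
        for col, ch in zip(self.COLUMNS, residues):
            aligned[col - 1] = ch
        return {"query": "".join(aligned)}

    def test_intact_motif_present(self):
        result = check_reddd("query", self._alignment("REDDD"), self.COLUMNS)
        assert result.present and result.substitutions == ()

    def test_r_to_k_substitution(self):
        result = check_reddd("query", self._alignment("KEDDD"), self.COLUMNS)
        assert not result.present
        assert result.substitutions == (("R", "K"),)

    def test_gap_counts_as_substitution(self):
        result = check_reddd("query", self._alignment("-EDDD"), self.COLUMNS)
        assert not result.present
        assert result.residues_found[0] == (10, "-")

    def test_missing_query_errors(self):
        with pytest.raises(KeyError):
            check_reddd("absent", self._alignment("REDDD"), self.COLUMNS)


class TestPlantedFamilies:
    def test_cysteine_census_matches_plant(self, default_bundle):
        truth = default_bundle["family"].ground_truth
        by_id = {p.id: p for p in default_bundle["family"].proteins}
        for gid, gt in truth.genes.items():
            if gt.group_id is None:
                continue  # homeolog members carry the exact planted census
            expected = 16 if gt.size_class == "long" else 10
            assert by_id[gid].residues.count("C") == expected == gt.cysteines

    def test_screen_recovers_exactly_the_planted_motifs(self, default_bundle):
        family = default_bundle["family"]
        accepted, rejected = screen_candidates(family.proteins)
        truth = family.ground_truth.genes
        assert {p.id for p in accepted} == {
            g for g, t in truth.items() if t.has_motif
        }
        assert {p.id for p, _ in rejected} == {
            g for g, t in truth.items() if not t.has_motif
        }
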