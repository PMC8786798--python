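import math

import numpy as np
import pytest

from tlpfam.evolution import (
    CodonAlignment,
    backtranslate,
    chi2_sf,
    classify_selection,
    divergence_time,
    ng86_kaks,
    tajima_relative_rate,
    translate_cds,
)
from tlpfam.synthetic import evolve_pair, reverse_translate

from .oracles import ng86_oracle

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _codons(cds):
    return tuple(cds[i : i + 3] for i in range(0, len(cds), 3))


def _random_cds(rng, n_codons):
    protein = "M" + "".join(rng.choice(list(AA20), n_codons - 1))
    return reverse_translate(protein, rng, stop=False)


class TestBacktranslate:
    def test_gap_codon_inserted(self):
        aln = backtranslate(
            [("a", "MKV"), ("b", "M-V")],
            {"a": "ATGAAAGTT", "b": "ATGGTT"},
        )
        assert aln.row("b") == ("ATG", "---", "GTT")
        assert aln.row("a") == ("ATG", "AAA", "GTT")

    def test_trailing_stop_stripped(self):
        aln = backtranslate([("a", "MK")], {"a": "ATGAAATAA"})
        assert aln.degapped("a") == "ATGAAA"

    def test_internal_stop_errors(self):
        with pytest.raises(ValueError, match="stop"):
            backtranslate([("a", "M*K")], {"a": "ATGTAAAAA"})

    def test_translation_mismatch_names_position(self):
        with pytest.raises(ValueError, match="codon 2"):
            backtranslate([("a", "MW")], {"a": "ATGAAA"})

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            backtranslate([("a", "MK")], {"a": "ATGAAAG"})

    def test_roundtrip_on_simulated_pairs(self, rng):
        from tlpfam.family import global_align

        for _ in range(30):
            cds = _random_cds(rng, 60)
            a, b = evolve_pair(cds, 0.5, 0.4, rng)
            pa, pb = translate_cds(a), translate_cds(b)
            aln_a, aln_b, _ = global_align(pa, pb)
            codon_aln = backtranslate([("a", aln_a), ("b", aln_b)], {"a": a, "b": b})
            assert codon_aln.degapped("a") == a
            assert codon_aln.degapped("b") == b


class TestNg86:
    def test_identical_sequences(self):
        codons = _codons("ATGAAAGTTCCG")
        r = ng86_kaks(CodonAlignment(("a", "b"), (codons, codons)))
        assert r.ka == 0.0 and r.ks == 0.0 and r.omega is None

    def test_single_synonymous_change(self):
        a = _codons("ATGAAACCTGGTGCTACT" * 3)
        b = list(a)
        b[1] = "AAG"  # K -> K, third-position synonymous change
        r = ng86_kaks(CodonAlignment(("a", "b"), (a, tuple(b))))
        assert r.ka == 0.0 and r.ks > 0.0

    def test_symmetry(self, rng):
        for _ in range(10):
            cds = _random_cds(rng, 80)
            a, b = evolve_pair(cds, 0.3, 0.6, rng)
            r1 = ng86_kaks(CodonAlignment(("a", "b"), (_codons(a), _codons(b))))
            r2 = ng86_kaks(CodonAlignment(("b", "a"), (_codons(b), _codons(a))))
            assert r1.ka == r2.ka and r1.ks == r2.ks

    def test_gap_and_ambiguous_columns_skipped(self):
        a = ("ATG", "---", "AAN", "GTT")
        b = ("ATG", "AAA", "AAA", "GTT")
        r = ng86_kaks(CodonAlignment(("a", "b"), (a, b)))
        assert r.usable_codons == 2

    def test_monotone_in_appended_differences(self):
        base_a = ["ATG", "GCT", "ACT", "CCT", "GGT", "TCT"] * 10
        base_b = list(base_a)
        prev_ks = prev_ka = 0.0
        # each appended differing column raises the matching distance
        for extra, kind in (
            (("AAA", "AAG"), "syn"),
            (("CAT", "CGT"), "nonsyn"),
            (("TTA", "TTG"), "syn"),
        ):
            base_a.append(extra[0])
            base_b.append(extra[1])
            r = ng86_kaks(CodonAlignment(("a", "b"), (tuple(base_a), tuple(base_b))))
            if kind == "syn":
                assert r.ks > prev_ks
            else:
                assert r.ka > prev_ka
            prev_ks, prev_ka = r.ks, r.ka

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(15):
            cds = _random_cds(rng, 100)
            omega = float(rng.uniform(0.05, 1.2))
            ks = float(rng.uniform(0.1, 0.9))
            a, b = evolve_pair(cds, omega, ks, rng)
            got = ng86_kaks(CodonAlignment(("a", "b"), (_codons(a), _codons(b))))
            want_ka, want_ks = ng86_oracle(_codons(a), _codons(b))
            for mine, ref in ((got.ka, want_ka), (got.ks, want_ks)):
                if mine is None or ref is None:
                    assert mine == ref  # saturation must agree
                else:
                    assert mine == pytest.approx(ref, abs=1e-9)

    def test_zero_usable_codons_errors(self):
        with pytest.raises(ValueError, match="usable"):
            ng86_kaks(CodonAlignment(("a", "b"), (("---",), ("AAA",))))


class TestDivergenceTime:
    @pytest.mark.parametrize(
        "ks, expected", [(1.0810, 83.2), (0.0, 0.0), (1.7816, 137.0)]
    )
    def test_published_and_degenerate_values(self, ks, expected):
        assert divergence_time(ks).t_mya == expected

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)


class TestSelection:
    @pytest.mark.parametrize(
        "omega, expected",
        [(0.1020, "purifying"), (1.0, "neutral"), (1.7, "positive")],
    )
    def test_calls(self, omega, expected):
        assert classify_selection(omega) == expected


def _triple_from_counts(nt, na, nb):
    """Aligned sequences realizing given relative-rate counts: na columns
    where A differs while B equals the outgroup, nb columns the reverse."""
    a = "A" * nt + "C" * na + "G" * nb
    b = "A" * nt + "G" * na + "C" * nb
    o = "A" * nt + "G" * na + "G" * nb
    return a, b, o


class TestTajima:
    def test_published_counts_chi2_and_p(self):
        a, b, o = _triple_from_counts(403, 47, 42)
        r = tajima_relative_rate(a, b, o)
        assert (r.nt, r.na, r.nb) == (403, 47, 42)
        assert round(r.chi2, 2) == 0.28
        assert round(r.p, 5) == 0.59611

    def test_equal_counts_give_chi2_zero_p_one(self):
        a, b, o = _triple_from_counts(411, 34, 34)
        r = tajima_relative_rate(a, b, o)
        assert r.chi2 == 0.0 and r.p == 1.0

    def test_all_identical_p_one(self):
        r = tajima_relative_rate("ACGT", "ACGT", "ACGT")
        assert (r.nt, r.na, r.nb, r.chi2, r.p) == (4, 0, 0, 0.0, 1.0)

    def test_antisymmetric_in_a_b(self, rng):
        for _ in range(10):
            n = 200
            seqs = ["".join(rng.choice(list("ACGT"), n)) for _ in range(3)]
            r1 = tajima_relative_rate(seqs[0], seqs[1], seqs[2])
            r2 = tajima_relative_rate(seqs[1], seqs[0], seqs[2])
            assert (r1.na, r1.nb) == (r2.nb, r2.na)
            assert r1.chi2 == r2.chi2 and r1.p == r2.p

    def test_uninformative_columns_ignored(self):
        # all three distinct, and A=B jointly differing, count nowhere
        r = tajima_relative_rate("ACT", "GCT", "TCA")
        assert (r.nt, r.na, r.nb) == (1, 0, 0)

    def test_gap_and_ambiguity_columns_skipped(self):
        r = tajima_relative_rate("A-CN", "AACA", "AACA")
        assert r.nt == 2  # only the gap-free, unambiguous columns count

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            tajima_relative_rate("ACGT", "ACG", "ACGT")


class TestChi2Sf:
    def test_zero_gives_one(self):
        assert chi2_sf(0.0) == 1.0

    def test_published_statistic(self):
        assert round(chi2_sf(2.4694), 5) == 0.11608

    def test_textbook_critical_value(self):
        assert chi2_sf(3.841459) == pytest.approx(0.05, abs=5e-5)

    def test_matches_erfc_form(self, rng):
        for x in rng.uniform(0, 20, 25):
            assert chi2_sf(float(x)) == pytest.approx(
                math.erfc(math.sqrt(x / 2)), abs=1e-12
            )
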