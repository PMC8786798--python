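import numpy as np
import pytest

from tlpfam.family import (
    BLOSUM62,
    GAP_EXTEND,
    GAP_OPEN,
    _AA_INDEX,
    DuplicatePair,
    SimilarityEdge,
    build_similarity_edges,
    chromosome_distribution,
    classify_duplication,
    find_duplicates,
    global_align,
    group_homeologs,
    identity_from_alignment,
    intron_phases,
    pairwise_identity,
)
from tlpfam.sequence_io import GeneModel, SequenceRecord

from .oracles import gotoh_oracle

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _blosum(x, y):
    return float(BLOSUM62[_AA_INDEX[x], _AA_INDEX[y]])


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        a = SequenceRecord("a", "MKVLITGGAGFIG")
        b = SequenceRecord("b", "MKVLITGGAGFIG")
        assert pairwise_identity(a, b) == 100.0

    def test_three_of_four_columns(self):
        assert pairwise_identity(
            SequenceRecord("a", "AAAA"), SequenceRecord("b", "AATA")
        ) == 75.0

    def test_symmetric(self, rng):
        for _ in range(10):
            a = SequenceRecord("a", "".join(rng.choice(list(AA20), 40)))
            b = SequenceRecord("b", "".join(rng.choice(list(AA20), 35)))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_matches_independent_dp_oracle(self, rng):
        for _ in range(25):
            n, m = int(rng.integers(5, 50)), int(rng.integers(5, 50))
            a = "".join(rng.choice(list(AA20), n))
            b = "".join(rng.choice(list(AA20), m))
            if a > b:
                a, b = b, a
            got_a, got_b, got_score = global_align(a, b)
            want_a, want_b, want_score = gotoh_oracle(a, b, _blosum, GAP_OPEN, GAP_EXTEND)
            assert got_score == pytest.approx(want_score)
            assert (got_a, got_b) == (want_a, want_b)
            assert identity_from_alignment(got_a, got_b) == identity_from_alignment(
                want_a, want_b
            )

    def test_terminal_overhangs_excluded(self):
        # overhanging prefix should not dilute identity
        assert identity_from_alignment("---AAAA", "KKKAAAA") == 100.0


def _edge(a, b, pct, mutual=True):
    a, b = sorted((a, b))
    return SimilarityEdge(a, b, pct, best_hit_a_to_b=mutual, best_hit_b_to_a=mutual)


class TestFindDuplicates:
    def test_greedy_one_pair_per_gene(self):
        edges = [_edge("a", "b", 95), _edge("a", "c", 85), _edge("b", "c", 70, mutual=False)]
        pairs = find_duplicates(edges)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b")]

    def test_below_threshold_empty(self):
        assert find_duplicates([_edge("a", "b", 79.9)]) == []

    def test_requires_mutual_best_hit(self):
        assert find_duplicates([_edge("a", "b", 95, mutual=False)]) == []

    def test_order_invariant(self, rng):
        edges = [
            _edge("g1", "g2", 92),
            _edge("g3", "g4", 88),
            _edge("g5", "g6", 85),
            _edge("g1", "g5", 81, mutual=False),
        ]
        reference = find_duplicates(edges)
        for _ in range(5):
            shuffled = list(edges)
            rng.shuffle(shuffled)
            assert find_duplicates(shuffled) == reference


def _model(gid, chrom, start, end, sub=None):
    return GeneModel(gid, chrom, "+", start, end, exons=[(start, end)], subgenome=sub)


class TestClassifyDuplication:
    def test_nearby_same_chromosome_is_tandem(self):
        models = {
            "a": _model("a", "3B", 1_000, 2_000),
            "b": _model("b", "3B", 52_000, 53_000),
        }
        pair = classify_duplication(DuplicatePair("a", "b", 90.0), models)
        assert pair.kind == "tandem" and pair.chrom_a == pair.chrom_b == "3B"

    def test_different_chromosomes_are_segmental(self):
        models = {"a": _model("a", "1A", 1, 100), "b": _model("b", "5D", 1, 100)}
        assert classify_duplication(DuplicatePair("a", "b", 85.0), models).kind == "segmental"

    def test_distant_with_many_intervening_is_segmental(self):
        models = {
            "a": _model("a", "2A", 1_000, 2_000),
            "b": _model("b", "2A", 2_100_000, 2_101_000),
        }
        for k in range(10):
            models[f"x{k}"] = _model(f"x{k}", "2A", 10_000 + 5_000 * k, 11_000 + 5_000 * k)
        pair = classify_duplication(DuplicatePair("a", "b", 85.0), models)
        assert pair.kind == "segmental" and pair.intervening_genes == 10

    def test_unplaced_scaffold_flagged(self):
        models = {
            "a": _model("a", "scaffold_17", 1, 100),
            "b": _model("b", "1A", 1, 100),
        }
        pair = classify_duplication(DuplicatePair("a", "b", 85.0), models)
        assert pair.kind is None and pair.unplaced

    def test_tandem_pairs_share_chromosome(self, default_bundle):
        import pandas as pd

        dp = pd.read_csv(default_bundle["results"] / "duplicate_pairs.tsv", sep="\t")
        truth = {
            (p.gene_a, p.gene_b)
            for p in default_bundle["family"].ground_truth.duplicate_pairs
        }
        got = {(r.gene_a, r.gene_b) for r in dp.itertuples()} | {
            (r.gene_b, r.gene_a) for r in dp.itertuples()
        }
        assert truth <= got


class TestHomeologGroups:
    def _models(self):
        return {
            "g1-A": _model("g1-A", "5A", 1, 10, "A"),
            "g1-B": _model("g1-B", "5B", 1, 10, "B"),
            "g1-D": _model("g1-D", "5D", 1, 10, "D"),
            "g2-D": _model("g2-D", "2D", 1, 10, "D"),
            "g2-A": _model("g2-A", "2A", 1, 10, "A"),
            "g2-B": _model("g2-B", "2B", 1, 10, "B"),
        }

    def test_triplet_forms_one_group(self):
        edges = [
            _edge("g1-A", "g1-B", 97),
            _edge("g1-A", "g1-D", 97),
            _edge("g1-B", "g1-D", 97),
        ]
        groups = group_homeologs(edges, self._models())
        assert len(groups) == 1 and groups[0].members == ("g1-A", "g1-B", "g1-D")

    def test_threshold_excludes_weak_member(self):
        edges = [
            _edge("g2-A", "g2-B", 92),
            _edge("g2-A", "g2-D", 88),
            _edge("g2-B", "g2-D", 88),
        ]
        groups = group_homeologs(edges, self._models())
        assert len(groups) == 1 and groups[0].members == ("g2-A", "g2-B")

    def test_same_subgenome_never_grouped(self):
        models = {
            "x1": _model("x1", "3A", 1, 10, "A"),
            "x2": _model("x2", "3A", 500, 510, "A"),
        }
        assert group_homeologs([_edge("x1", "x2", 99)], models) == []

    def test_different_chromosome_number_never_grouped(self):
        models = {
            "x1": _model("x1", "3A", 1, 10, "A"),
            "x2": _model("x2", "4B", 1, 10, "B"),
        }
        assert group_homeologs([_edge("x1", "x2", 99)], models) == []

    def test_planted_groups_recovered_exactly(self, default_bundle):
        import pandas as pd

        got = {
            tuple(sorted(m.split(",")))
            for m in pd.read_csv(
                default_bundle["results"] / "homeolog_groups.tsv", sep="\t"
            ).members
        }
        want = {
            tuple(sorted(g))
            for g in default_bundle["family"].ground_truth.homeolog_groups
        }
        assert got == want


class TestIntronPhases:
    def _gene(self, exon_lengths, strand="+"):
        exons = []
        pos = 1
        for ln in exon_lengths:
            exons.append((pos, pos + ln - 1))
            pos += ln + 100
        if strand == "-":
            exons = list(reversed(exons))
        cds = [(s, e, None) for s, e in exons]
        start = min(s for s, _ in exons)
        end = max(e for _, e in exons)
        return GeneModel("g", "1A", strand, start, end, exons=exons, cds_segments=cds)

    def test_two_exons_phase_one(self):
        arch = intron_phases(self._gene([100, 200]))
        assert arch.intron_phases == (1,) and not arch.intronless

    def test_single_exon_intronless(self):
        arch = intron_phases(self._gene([300]))
        assert arch.intronless and arch.intron_phases == ()

    def test_three_codon_multiple_exons(self):
        assert intron_phases(self._gene([99, 99, 99])).intron_phases == (0, 0)

    def test_non_codon_total_warns(self):
        with pytest.warns(UserWarning, match="multiple of 3"):
            intron_phases(self._gene([100]))

    def test_strand_invariance(self, default_bundle):
        # phases computed in transcription order must agree with the phase
        # implied by cumulative CDS length regardless of strand
        for m in default_bundle["family"].gene_models:
            if not m.cds_segments:
                continue
            arch = intron_phases(m)
            lengths = [e - s + 1 for s, e, _ in m.cds_segments]
            expected = tuple(
                sum(lengths[: i + 1]) % 3 for i in range(len(lengths) - 1)
            )
            assert arch.intron_phases == expected
            assert sum(lengths) % 3 == 0


class TestChromosomeDistribution:
    def test_counts(self):
        models = [
            _model("a", "chr4", 1, 10),
            _model("b", "chr4", 100, 110),
            _model("c", "chr4", 200, 210),
            _model("d", "chr1", 1, 10),
        ]
        counts, unplaced = chromosome_distribution(models)
        assert dict(counts) == {"chr4": 3, "chr1": 1} and unplaced == []

    def test_empty(self):
        counts, unplaced = chromosome_distribution([])
        assert dict(counts) == {} and unplaced == []

    def test_unplaced_reported_separately(self):
        models = [_model("a", "scaffold_1", 1, 10), _model("b", "1A", 1, 10)]
        counts, unplaced = chromosome_distribution(models)
        assert dict(counts) == {"1A": 1} and unplaced == ["a"]

    def test_planted_distribution_recovered(self, default_bundle):
        family = default_bundle["family"]
        truth = family.ground_truth.genes
        expected = {}
        for gid, t in truth.items():
            if t.has_motif:
                expected[t.chromosome] = expected.get(t.chromosome, 0) + 1
        accepted = [
            m for m in family.gene_models if truth[m.gene_id].has_motif
        ]
        counts, _ = chromosome_distribution(accepted)
        assert dict(counts) == expected
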