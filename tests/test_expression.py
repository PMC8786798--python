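import numpy as np
import pandas as pd
import pytest

from tlpfam.expression import (
    ExpressionMatrix,
    QpcrRow,
    QpcrTable,
    cluster_genes,
    ddct_fold,
    differential_filter,
    duplicate_fate,
    fpkm,
    significance_stars,
)

from .oracles import two_sample_t_oracle


def _matrix(values, genes=None, conds=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    conds = conds or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=conds))


class TestFpkm:
    def _inputs(self, counts):
        counts = pd.DataFrame(counts, index=["g1"], columns=["s1"])
        lengths = pd.Series({"g1": 1000.0})
        totals = pd.Series({"s1": 1e6})
        return counts, lengths, totals

    def test_unit_construction(self):
        m = fpkm(*self._inputs([[10]]))
        assert m.values.iloc[0, 0] == 10.0

    def test_zero_counts(self):
        assert fpkm(*self._inputs([[0]])).values.iloc[0, 0] == 0.0

    def test_doubling_total_halves_fpkm(self):
        counts, lengths, totals = self._inputs([[10]])
        half = fpkm(counts, lengths, totals * 2)
        assert half.values.iloc[0, 0] == 5.0

    def test_linear_in_counts_inverse_in_totals(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, (6, 4)), index=list("abcdef"), columns=list("wxyz")
        )
        lengths = pd.Series(rng.integers(200, 3000, 6).astype(float), index=list("abcdef"))
        totals = pd.Series(rng.integers(int(1e5), int(1e7), 4).astype(float), index=list("wxyz"))
        base = fpkm(counts, lengths, totals).values
        assert np.allclose(fpkm(counts * 3, lengths, totals).values, base * 3)
        assert np.allclose(fpkm(counts, lengths, totals * 4).values, base / 4)

    def test_zero_length_rejected(self):
        counts, lengths, totals = self._inputs([[10]])
        with pytest.raises(ValueError, match="length"):
            fpkm(counts, lengths * 0, totals)


class TestDifferentialFilter:
    def test_two_fold_boundary(self):
        m = _matrix([[5, 11], [5, 9]], conds=["control", "treated"])
        calls = {c.gene_id: c for c in differential_filter(m, "control", ["treated"])}
        assert calls["g0"].flagged  # (11.01/5.01) = 2.20 >= 2
        assert not calls["g1"].flagged  # 1.80 < 2

    def test_downregulation_flagged(self):
        m = _matrix([[20, 4]], conds=["control", "treated"])
        (call,) = differential_filter(m, "control", ["treated"])
        assert call.flagged

    def test_swap_inverts_folds_keeps_flags(self):
        m = _matrix([[5, 11], [8, 8], [20, 4]], conds=["a", "b"])
        fwd = differential_filter(m, "a", ["b"])
        rev = differential_filter(m, "b", ["a"])
        for f, r in zip(fwd, rev):
            assert f.folds["b"] == pytest.approx(1.0 / r.folds["a"])
            assert f.flagged == r.flagged

    def test_planted_differential_genes_recovered(self, default_bundle):
        diff = pd.read_csv(default_bundle["results"] / "differential.tsv", sep="\t")
        flagged = set(diff[diff.flagged].gene_id)
        assert flagged == default_bundle["expression_truth"].differential


class TestClustering:
    def test_identical_rows_cocluster(self):
        m = _matrix([[1, 2, 3], [1, 2, 3], [50, 1, 90]])
        labels = cluster_genes(m, k=2).labels
        assert labels["g0"] == labels["g1"] != labels["g2"]

    def test_permutation_invariance(self, rng):
        values = rng.uniform(0, 100, (12, 5))
        m = _matrix(values)
        ref = cluster_genes(m, k=3).labels
        order = rng.permutation(12)
        m2 = ExpressionMatrix(m.values.iloc[order])
        permuted = cluster_genes(m2, k=3).labels
        # same partition regardless of row order
        by_pair = lambda lab: {
            (a, b)
            for i, a in enumerate(sorted(lab))
            for b in sorted(lab)[i + 1 :]
            if lab[a] == lab[b]
        }
        assert by_pair(ref) == by_pair(permuted)

    def test_constant_matrix_single_cluster_warns(self):
        m = _matrix([[1, 1], [1, 1], [1, 1]])
        with pytest.warns(UserWarning, match="constant"):
            result = cluster_genes(m, k=2)
        assert set(result.labels.values()) == {1}

    def test_planted_archetypes_recovered_under_noise(self):
        from sklearn.metrics import adjusted_rand_score

        from tlpfam.synthetic import generate_expression
        from tlpfam.expression import fpkm as _fpkm

        genes = [f"g{i}" for i in range(80)]
        scores = []
        for seed in range(20):
            counts, lengths, totals, truth = generate_expression(
                genes, noise_sd=0.3, seed=seed
            )
            m = _fpkm(counts, lengths, totals)
            labels = cluster_genes(m, k=4).labels
            planted = [truth.archetype_of[g] for g in genes]
            got = [labels[g] for g in genes]
            scores.append(adjusted_rand_score(planted, got))
        assert np.mean(scores) >= 0.9


class TestDdctFold:
    def _table(self, treated, control):
        rows = []
        for i, d in enumerate(control):
            rows.append(QpcrRow("g1", "control", i, 20.0 + d, 20.0))
        for i, d in enumerate(treated):
            rows.append(QpcrRow("g1", "stress", i, 20.0 + d, 20.0))
        return QpcrTable(rows, "control")

    def test_zero_ddct_fold_one(self):
        (r,) = ddct_fold(self._table([2.0, 2.0], [2.0, 2.0]))
        assert r.fold == 1.0

    def test_minus_one_ddct_fold_two(self):
        (r,) = ddct_fold(self._table([1.0, 1.0], [2.0, 2.0]))
        assert r.fold == 2.0

    def test_replicate_statistics_match_t_oracle(self):
        treated, control = [2.0, 2.1, 1.9], [3.0, 3.1, 2.9]
        (r,) = ddct_fold(self._table(treated, control))
        assert r.fold == pytest.approx(2.0)
        _, p = two_sample_t_oracle(treated, control)
        assert r.p_value == pytest.approx(p, abs=1e-9)
        assert r.significance == significance_stars(p)

    def test_reciprocal_folds(self):
        table = self._table([1.3, 1.5, 1.4], [2.2, 2.4, 2.3])
        (fwd,) = ddct_fold(table, "control")
        (rev,) = ddct_fold(table, "stress")
        assert fwd.fold * rev.fold == pytest.approx(1.0)

    def test_single_replicate_flagged_without_stats(self):
        rows = [
            QpcrRow("g1", "control", 0, 22.0, 20.0),
            QpcrRow("g1", "stress", 0, 21.0, 20.0),
        ]
        (r,) = ddct_fold(QpcrTable(rows, "control"))
        assert r.insufficient_replicates and r.p_value is None and r.fold == 2.0

    def test_ct_range_validated(self):
        with pytest.raises(ValueError):
            QpcrRow("g", "c", 0, 50.0, 20.0)


class TestDuplicateFate:
    def test_identical_profiles_retention(self):
        m = _matrix([[5, 10, 20], [5, 10, 20]])
        f = duplicate_fate(m, ("g0", "g1"))
        assert f.fate == "retention" and f.correlation == pytest.approx(1.0)

    def test_silent_copy_pseudo_functionalization(self):
        m = _matrix([[5, 10, 20], [0, 0, 0]])
        f = duplicate_fate(m, ("g0", "g1"))
        assert f.fate == "pseudo_functionalization"
        assert f.expressed_a and not f.expressed_b

    def test_anticorrelated_profiles_neo_functionalization(self):
        m = _matrix([[2, 10, 30], [30, 10, 2]])
        assert duplicate_fate(m, ("g0", "g1")).fate == "neo_functionalization"

    def test_zero_variance_flagged(self):
        m = _matrix([[5, 5, 5], [5, 10, 20]])
        f = duplicate_fate(m, ("g0", "g1"))
        assert f.correlation_undefined and f.correlation is None

    def test_missing_gene_errors(self):
        m = _matrix([[1, 2]])
        with pytest.raises(KeyError):
            duplicate_fate(m, ("g0", "absent"))


class TestMatrixInvariants:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[-1.0, 2.0]])

    def test_duplicate_conditions_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["c", "c"])
        with pytest.raises(ValueError):
            ExpressionMatrix(df)
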