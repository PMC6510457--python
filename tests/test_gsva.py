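import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from imds.data import ExpressionMatrix
from imds.gsva import (
    gene_ranking,
    gsva_scores,
    kcdf_transform,
    rank_statistic,
    walk_es,
)
from imds.signatures import GeneSignature, SignatureLibrary

from naive_es import naive_es_matrix, naive_kcdf, naive_walk


def _expr_from_array(values, prefix="S"):
    genes = [f"G{i:03d}" for i in range(values.shape[0])]
    samples = [f"{prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.DataFrame(index=samples),
    )


class TestKcdf:
    def test_fewer_than_three_samples_errors(self):
        with pytest.raises(ValueError, match=">= 3 samples"):
            kcdf_transform(np.zeros((5, 2)))

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 6))
        shifted = x.copy()
        shifted[3] += 17.0
        np.testing.assert_allclose(kcdf_transform(x)[3], kcdf_transform(shifted)[3])

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 6))
        scaled = x.copy()
        scaled[2] *= 5.0
        np.testing.assert_allclose(
            kcdf_transform(x)[2], kcdf_transform(scaled)[2], rtol=1e-12
        )

    def test_two_sample_hand_evaluation(self):
        # n=3 rule relaxed: direct evaluation of the two-term kernel sum
        x = np.array([[0.0, 1.0]])
        z = kcdf_transform(x, min_samples=2)
        h = np.std([0.0, 1.0], ddof=1) / 4.0
        expected = np.array([
            [(ndtr(0.0) + ndtr(-1.0 / h)) / 2.0, (ndtr(1.0 / h) + ndtr(0.0)) / 2.0]
        ])
        np.testing.assert_allclose(z, expected)
        np.testing.assert_allclose(z, [[0.25, 0.75]], atol=1e-7)

    def test_zero_variance_row_maps_to_half(self):
        x = np.vstack([np.full(5, 3.0), np.arange(5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = kcdf_transform(x)
        np.testing.assert_array_equal(z[0], 0.5)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 4))
        np.testing.assert_allclose(
            kcdf_transform(x), np.array(naive_kcdf(x.tolist())), atol=1e-12
        )


class TestRankStatistic:
    def test_direct_formula_p4(self):
        # one sample whose z already orders genes 1..4 -> r = (1, 0, 1, 2)
        z = np.array([[4.0], [3.0], [2.0], [1.0]])
        np.testing.assert_array_equal(rank_statistic(z)[:, 0], [1.0, 0.0, 1.0, 2.0])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(9, 3))
        perm = rng.permutation(9)
        np.testing.assert_array_equal(rank_statistic(z)[perm], rank_statistic(z[perm]))

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(10, 3))
        r = rank_statistic(z)
        p = z.shape[0]
        for j in range(3):
            order = sorted(range(p), key=lambda g: -z[g, j])
            for k, g in enumerate(order):
                assert r[g, j] == abs(p / 2.0 - (k + 1))

    def test_nonfinite_rejected(self):
        z = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="finite"):
            rank_statistic(z)


class TestWalk:
    @staticmethod
    def _setup(p=6, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(p, 1))
        r = rank_statistic(z)
        order = gene_ranking(z)
        return z, r[:, 0], order[:, 0]

    def test_top_genes_positive(self):
        z, r, order = self._setup()
        assert walk_es(r, order, set(order[:2])) > 0

    def test_bottom_genes_negative(self):
        z, r, order = self._setup()
        assert walk_es(r, order, set(order[-2:])) < 0

    def test_matches_stepwise_oracle(self):
        z, r, order = self._setup(p=6, seed=4)
        for geneset in [{0, 3}, {1, 2, 5}, {4}]:
            expected = naive_walk(z.tolist(), 0, geneset)
            assert walk_es(r, order, geneset) == pytest.approx(expected, abs=1e-12)

    def test_bounds(self):
        z, r, order = self._setup(p=30, seed=9)
        for size in (1, 5, 15, 29):
            es = walk_es(r, order, set(range(size)))
            assert -1.0 <= es <= 1.0

    def test_empty_or_full_set_rejected(self):
        z, r, order = self._setup()
        with pytest.raises(ValueError):
            walk_es(r, order, set())
        with pytest.raises(ValueError):
            walk_es(r, order, set(range(6)))


class TestGsvaScores:
    @staticmethod
    def _random_fixture(seed, p=10, n=6):
        rng = np.random.default_rng(seed)
        expr = _expr_from_array(rng.normal(7, 1, size=(p, n)))
        lib = SignatureLibrary([
            GeneSignature(id="setA", genes=tuple(f"G{i:03d}" for i in (0, 2, 4, 6, 8))),
            GeneSignature(id="setB", genes=tuple(f"G{i:03d}" for i in (1, 3, 5, 7, 9))),
        ])
        return expr, lib

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_oracle_equivalence(self, seed):
        expr, lib = self._random_fixture(seed)
        es = gsva_scores(expr, lib)
        genesets = {
            sig.id: [expr.gene_ids.index(g) for g in sig.genes] for sig in lib
        }
        expected = naive_es_matrix(expr.values.to_numpy().tolist(), genesets)
        for sig_id, values in expected.items():
            np.testing.assert_allclose(
                es.scores.loc[sig_id].to_numpy(), values, atol=1e-10
            )

    def test_scores_bounded(self, default_es):
        assert (default_es.scores.to_numpy() >= -1.0).all()
        assert (default_es.scores.to_numpy() <= 1.0).all()

    def test_per_gene_affine_invariance(self):
        expr, lib = self._random_fixture(11)
        es1 = gsva_scores(expr, lib)
        rng = np.random.default_rng(99)
        scale = rng.uniform(0.5, 3.0, size=expr.n_genes)
        shift = rng.normal(0, 10, size=expr.n_genes)
        transformed = _expr_from_array(
            expr.values.to_numpy() * scale[:, None] + shift[:, None]
        )
        es2 = gsva_scores(transformed, lib)
        np.testing.assert_allclose(es1.scores.to_numpy(), es2.scores.to_numpy(),
                                   atol=1e-12)

    def test_gene_relabeling_invariance(self):
        expr, lib = self._random_fixture(12)
        es1 = gsva_scores(expr, lib)
        # permute gene rows (ids travel with their rows)
        perm = np.random.default_rng(5).permutation(expr.n_genes)
        permuted = ExpressionMatrix(expr.values.iloc[perm], expr.annotations)
        es2 = gsva_scores(permuted, lib)
        np.testing.assert_allclose(es1.scores.to_numpy(), es2.scores.to_numpy(),
                                   atol=1e-12)

    def test_signature_order_invariance(self):
        expr, lib = self._random_fixture(13)
        es1 = gsva_scores(expr, lib)
        reversed_lib = SignatureLibrary(list(lib)[::-1])
        es2 = gsva_scores(expr, reversed_lib)
        np.testing.assert_allclose(
            es1.scores.loc[["setA", "setB"]].to_numpy(),
            es2.scores.loc[["setA", "setB"]].to_numpy(),
        )

    def test_duplicated_sample_column_scores_identically(self):
        expr, lib = self._random_fixture(14)
        values = expr.values.copy()
        values["S_dup"] = values["S0"]
        dup = ExpressionMatrix(values, pd.DataFrame(index=values.columns))
        es = gsva_scores(dup, lib)
        np.testing.assert_allclose(
            es.scores["S0"].to_numpy(), es.scores["S_dup"].to_numpy()
        )

    def test_planted_signature_scores_higher(self):
        rng = np.random.default_rng(21)
        values = rng.normal(7, 0.5, size=(20, 8))
        values[:5, :4] += 3.0  # planted high expression in first 4 samples
        expr = _expr_from_array(values)
        lib = SignatureLibrary([
            GeneSignature(id="planted", genes=tuple(f"G{i:03d}" for i in range(5))),
            GeneSignature(id="null", genes=tuple(f"G{i:03d}" for i in range(10, 15))),
        ])
        es = gsva_scores(expr, lib)
        planted = es.scores.loc["planted"]
        assert planted.iloc[:4].min() > planted.iloc[4:].max()

    def test_monotone_in_planted_shift(self):
        rng = np.random.default_rng(31)
        base = rng.normal(7, 0.5, size=(30, 6))
        lib = SignatureLibrary([
            GeneSignature(id="sig", genes=tuple(f"G{i:03d}" for i in range(6))),
        ])
        previous = -np.inf
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            values = base.copy()
            values[:6, 0] += shift
            es = gsva_scores(_expr_from_array(values), lib)
            current = es.scores.loc["sig"].iloc[0]
            assert current >= previous - 1e-12
            previous = current

    def test_size_filters_drop_with_warning(self):
        expr, _ = self._random_fixture(15)
        lib = SignatureLibrary([
            GeneSignature(id="tiny", genes=("G000", "G001")),
            GeneSignature(id="ok", genes=tuple(f"G{i:03d}" for i in range(5))),
        ])
        with pytest.warns(UserWarning, match="'tiny' dropped"):
            es = gsva_scores(expr, lib)
        assert es.signature_ids == ["ok"]

    def test_no_surviving_signature_errors(self):
        expr, _ = self._random_fixture(16)
        lib = SignatureLibrary([
            GeneSignature(id="alien", genes=("NOTAGENE1", "NOTAGENE2", "NOTAGENE3",
                                             "NOTAGENE4", "NOTAGENE5")),
        ])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no signature survives"):
                gsva_scores(expr, lib)

    def test_deterministic(self):
        expr, lib = self._random_fixture(17)
        es1 = gsva_scores(expr, lib)
        es2 = gsva_scores(expr, lib)
        pd.testing.assert_frame_equal(es1.scores, es2.scores)

    def test_round_trip_io(self, tmp_path):
        expr, lib = self._random_fixture(18)
        es = gsva_scores(expr, lib)
        path = tmp_path / "es.tsv"
        es.write(path)
        again = type(es).read(path)
        np.testing.assert_allclose(es.scores.to_numpy(), again.scores.to_numpy())
        assert again.params["kernel"] == "gaussian"
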