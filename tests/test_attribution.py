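"""Variance partitioning, Procrustes/protest, and LUI arithmetic."""

import numpy as np
import pandas as pd
import pytest

from exudomics import attribution, ordination


class TestAdjustedR2:
    def test_null_predictor_near_zero(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(200, 4))
        X = rng.normal(size=(200, 2))
        assert abs(attribution.adjusted_r2(Y, X)) < 0.05

    def test_perfect_fit_equals_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        Y = X @ rng.normal(size=(3, 5))
        assert attribution.adjusted_r2(Y, X) == pytest.approx(1.0)

    def test_saturated_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            attribution.adjusted_r2(rng.normal(size=(5, 2)),
                                    rng.normal(size=(5, 4)))

    def test_unbiased_under_null(self):
        # adjusted R2 centers on 0 for uninformative predictors
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(300):
            Y = rng.normal(size=(40, 2))
            X = rng.normal(size=(40, 20))
            vals.append(attribution.adjusted_r2(Y, X))
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(mean) <= 3 * se + 0.01

    def test_equals_rda_constrained_proportion_adjusted(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(30, 5))
        X = ordination.one_hot(rng.choice(list("abc"), 30))
        r2 = ordination.rda(Y, X).constrained_proportion
        n, p = 30, 2
        want = 1 - (1 - r2) * (n - 1) / (n - p - 1)
        assert attribution.adjusted_r2(Y, X) == pytest.approx(
            want, abs=1e-10
        )


class TestVariancePartition:
    def test_single_set_degenerate_partition(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(50, 3))
        X = rng.normal(size=(50, 2))
        part = attribution.variance_partition(Y, {"A": X})
        a = attribution.adjusted_r2(Y, X)
        assert part.fractions[frozenset(["A"])] == pytest.approx(a)
        assert part.fractions["residual"] == pytest.approx(1 - a)

    def test_fractions_sum_to_one_and_match_subset_oracle(self):
        rng = np.random.default_rng(6)
        groups = np.repeat(list("abcd"), 15)
        Y = (
            ordination.one_hot(groups).to_numpy()
            @ rng.normal(size=(4, 6))
            + rng.normal(size=(60, 6))
        )
        sets = {
            "Species": ordination.one_hot(groups),
            "Plot": rng.normal(size=(60, 3)),
            "SV": rng.normal(size=(60, 1)),
        }
        part = attribution.variance_partition(Y, sets)
        total = sum(part.fractions.values())
        assert total == pytest.approx(1.0, abs=1e-10)
        # oracle: evaluate all 7 subset models independently and invert
        # the inclusion-exclusion by hand for the three-set case
        import itertools

        def r2(names):
            X = np.hstack([
                np.asarray(sets[n], dtype=float) for n in names
            ])
            return attribution.adjusted_r2(Y, X)

        rA, rB, rC = r2(["Species"]), r2(["Plot"]), r2(["SV"])
        rAB = r2(["Species", "Plot"])
        rAC = r2(["Species", "SV"])
        rBC = r2(["Plot", "SV"])
        rABC = r2(["Species", "Plot", "SV"])
        unique_A = rABC - rBC
        unique_B = rABC - rAC
        unique_C = rABC - rAB
        ab = rAC + rBC - rC - rABC  # shared by A and B only
        ac = rAB + rBC - rB - rABC
        bc = rAB + rAC - rA - rABC
        abc = rABC - unique_A - unique_B - unique_C - ab - ac - bc
        f = part.fractions
        assert f[frozenset(["Species"])] == pytest.approx(unique_A,
                                                          abs=1e-10)
        assert f[frozenset(["Plot"])] == pytest.approx(unique_B, abs=1e-10)
        assert f[frozenset(["SV"])] == pytest.approx(unique_C, abs=1e-10)
        assert f[frozenset(["Species", "Plot"])] == pytest.approx(
            ab, abs=1e-10
        )
        assert f[frozenset(["Species", "SV"])] == pytest.approx(
            ac, abs=1e-10
        )
        assert f[frozenset(["Plot", "SV"])] == pytest.approx(bc, abs=1e-10)
        assert f[frozenset(["Species", "Plot", "SV"])] == pytest.approx(
            abc, abs=1e-10
        )
        assert f["residual"] == pytest.approx(1 - rABC, abs=1e-10)

    def test_orthogonal_predictors_share_nothing(self):
        rng = np.random.default_rng(7)
        n = 400
        base = rng.normal(size=(n, 8))
        Q, _ = np.linalg.qr(base - base.mean(0))
        A, B = Q[:, :3], Q[:, 3:6]
        Y = A @ rng.normal(size=(3, 5)) + B @ rng.normal(size=(3, 5)) \
            + 0.5 * rng.normal(size=(n, 5))
        part = attribution.variance_partition(Y, {"A": A, "B": B})
        assert abs(part.fractions[frozenset(["A", "B"])]) < 0.02

    def test_more_than_four_sets_rejected(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(30, 2))
        sets = {f"S{i}": rng.normal(size=(30, 1)) for i in range(5)}
        with pytest.raises(ValueError):
            attribution.variance_partition(Y, sets)

    def test_table_layout_order(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(40, 3))
        part = attribution.variance_partition(
            Y,
            {"Species": rng.normal(size=(40, 2)),
             "Plot": rng.normal(size=(40, 2)),
             "SV": rng.normal(size=(40, 1))},
        )
        t = part.table()
        assert list(t.index) == [
            "Species", "Plot", "SV", "Plot + Species", "SV + Species",
            "Plot + SV", "Plot + SV + Species", "residual",
        ]
        assert t.sum() == pytest.approx(1.0, abs=1e-10)


def _random_rotation(k, rng):
    Q, _ = np.linalg.qr(rng.normal(size=(k, k)))
    return Q


class TestProcrustes:
    def test_identity_configuration(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 3))
        res = attribution.procrustes_fit(X, X)
        assert res.correlation == pytest.approx(1.0, abs=1e-12)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)

    def test_similarity_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 4))
        R = _random_rotation(4, rng)
        Y = 5.0 * (X @ R) + rng.normal(size=4)
        res = attribution.procrustes_fit(X, Y)
        assert res.correlation == pytest.approx(1.0, abs=1e-12)

    def test_matches_algebraic_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(100, 3))
        Y = rng.normal(size=(100, 3))
        res = attribution.procrustes_fit(X, Y)
        # independent route: nuclear norm via eigh of the Gram matrix
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        Xn = Xc / np.sqrt((Xc**2).sum())
        Yn = Yc / np.sqrt((Yc**2).sum())
        C = Xn.T @ Yn
        w = np.linalg.eigvalsh(C.T @ C)
        trace = np.sqrt(np.clip(w, 0, None)).sum()
        assert res.correlation == pytest.approx(trace, abs=1e-10)
        assert res.m2 == pytest.approx(1 - trace**2, abs=1e-10)

    def test_different_column_counts_supported(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 6))
        Y = rng.normal(size=(30, 2))
        res = attribution.procrustes_fit(X, Y)
        assert 0.0 <= res.correlation <= 1.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            attribution.procrustes_fit(np.ones((2, 2)),
                                       np.ones((2, 2)))


class TestProtest:
    def test_identical_configurations_minimum_p(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(40, 3))
        res = attribution.protest(X, X, n_permutations=99, seed=5)
        assert res.permutation_p == pytest.approx(1 / 100)

    def test_same_seed_same_p(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 3))
        a = attribution.protest(X, Y, n_permutations=199, seed=9)
        b = attribution.protest(X, Y, n_permutations=199, seed=9)
        assert a.permutation_p == b.permutation_p

    def test_p_within_valid_range(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(25, 2))
        Y = rng.normal(size=(25, 2))
        res = attribution.protest(X, Y, n_permutations=49, seed=1)
        assert 1 / 50 <= res.permutation_p <= 1.0

    def test_detects_planted_association(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 3))
        Y = X @ _random_rotation(3, rng) + 0.3 * rng.normal(size=(60, 3))
        res = attribution.protest(X, Y, n_permutations=199, seed=2)
        assert res.permutation_p <= 0.05


class TestLUI:
    def _components(self, rows):
        return pd.DataFrame(
            rows, columns=["plot", "year", "fertilization", "mowing",
                           "grazing"]
        )

    def test_reference_plot_scores_three(self):
        comp = self._components(
            [["p1", 2006, 30.0, 2.0, 100.0], ["p2", 2006, 30.0, 2.0, 100.0]]
        )
        lui = attribution.lui_index(comp)
        assert np.allclose(lui["lui_2006"], 3.0)

    def test_double_fert_no_mowing_reference_grazing(self):
        comp = self._components(
            [
                ["p1", 2006, 20.0, 0.0, 50.0],
                ["p2", 2006, 0.0, 4.0, 50.0],
            ]
        )
        # means: F=10, M=2, G=50 -> p1: 2 + 0 + 1 = 3
        lui = attribution.lui_index(comp)
        assert lui.loc["p1", "lui_2006"] == pytest.approx(3.0)

    def test_nine_year_mean_matches_hand_average(self):
        rng = np.random.default_rng(18)
        rows = []
        for year in range(2006, 2015):
            for plot in ("p1", "p2", "p3"):
                rows.append([plot, year, rng.uniform(5, 50),
                             rng.uniform(0, 3), rng.uniform(10, 200)])
        comp = self._components(rows)
        lui = attribution.lui_index(comp)
        # hand recomputation for p2
        by_hand = []
        for year in range(2006, 2015):
            sub = comp[comp["year"] == year]
            row = sub[sub["plot"] == "p2"].iloc[0]
            by_hand.append(
                row["fertilization"] / sub["fertilization"].mean()
                + row["mowing"] / sub["mowing"].mean()
                + row["grazing"] / sub["grazing"].mean()
            )
        assert lui.loc["p2", "lui_mean_2006_2014"] == pytest.approx(
            np.mean(by_hand)
        )

    def test_fixed_reference_means(self):
        comp = self._components([["p1", 2006, 20.0, 1.0, 50.0]])
        lui = attribution.lui_index(
            comp,
            reference_means={"fertilization": 10.0, "mowing": 2.0,
                             "grazing": 100.0},
        )
        assert lui.loc["p1", "lui_2006"] == pytest.approx(2 + 0.5 + 0.5)

    def test_zero_reference_rejected(self):
        comp = self._components([["p1", 2006, 0.0, 0.0, 5.0]])
        with pytest.raises(ValueError):
            attribution.lui_index(comp)
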