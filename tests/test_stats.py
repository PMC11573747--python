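"""Paired tests, many-to-one comparisons, Sidak, and PCA of profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats as sps

from scenith import (
    StatsError,
    build_profile_matrix,
    compare_to_control,
    paired_difference_test,
    pairwise_condition_tests,
    pca_profiles,
    sidak_adjust,
    top_loadings,
)


class TestPairedTest:
    def test_identical_pairs_give_p_one(self):
        res = paired_difference_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_known_differences(self):
        # diffs {1,2,3}: t = 2 / (1/sqrt(3)) = 3.464, df = 2
        res = paired_difference_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(3.464, abs=1e-3)
        assert res.df == 2
        assert res.pvalue == pytest.approx(2 * sps.t.sf(res.statistic, 2), rel=1e-12)
        assert res.pvalue == pytest.approx(0.0742, abs=2e-4)

    def test_too_few_pairs(self):
        with pytest.raises(StatsError):
            paired_difference_test([1.0, 2.0], [0.0, 1.0])

    def test_nan_pairs_dropped(self):
        res = paired_difference_test([1, 2, 3, np.nan], [0, 0, 0, 5])
        assert res.n == 3

    def test_type_one_error_calibrated(self, rng):
        # 2000 null simulations, n = 6 donors: rejection rate ~ 5%
        n_sims, n = 2000, 6
        x = rng.standard_normal((n_sims, n))
        y = rng.standard_normal((n_sims, n))
        rejections = 0
        for i in range(n_sims):
            if paired_difference_test(x[i], y[i]).pvalue <= 0.05:
                rejections += 1
        rate = rejections / n_sims
        # binomial 99% envelope around 0.05 with 2000 sims: +- ~1.3%
        assert 0.035 <= rate <= 0.065


def _long(wide: np.ndarray, groups: list[str]) -> pd.DataFrame:
    rows = []
    for d in range(wide.shape[0]):
        for j, g in enumerate(groups):
            rows.append({"donor": f"d{d}", "group": g, "value": wide[d, j]})
    return pd.DataFrame(rows)


class TestCompareToControl:
    GROUPS = ["Medium", "LPS", "CpG", "TransAct"]

    def test_identical_groups_give_p_one(self):
        wide = np.tile(np.arange(6, dtype=float)[:, None], (1, 4))
        out = compare_to_control(_long(wide, self.GROUPS), seed=1)
        assert np.all(out["adjusted_p"] == 1.0)

    def test_single_comparison_reduces_to_paired_t(self, rng):
        wide = rng.normal(size=(6, 2))
        out = compare_to_control(_long(wide, ["Medium", "LPS"]), seed=1)
        expected = paired_difference_test(wide[:, 1], wide[:, 0])
        assert out.loc[0, "raw_p"] == pytest.approx(expected.pvalue, rel=1e-9)
        assert out.loc[0, "adjusted_p"] == out.loc[0, "raw_p"]

    def test_adjusted_monotone_above_raw(self, rng):
        wide = rng.normal(size=(6, 4)) + np.array([0, 1.0, 0, 0.3])
        out = compare_to_control(_long(wide, self.GROUPS), n_mc=5000, seed=2)
        assert np.all(out["adjusted_p"] >= out["raw_p"] - 1e-12)
        assert np.all((out["adjusted_p"] >= 0) & (out["adjusted_p"] <= 1))

    def test_missing_cell_is_error(self, rng):
        frame = _long(rng.normal(size=(6, 4)), self.GROUPS).iloc[:-1]
        with pytest.raises(StatsError, match="missing"):
            compare_to_control(frame)

    def test_family_wise_error_controlled(self, rng):
        # 2000 null simulations, 4 groups (3 comparisons), 6 donors
        n_sims, n_donors = 2000, 6
        rejections = 0
        for i in range(n_sims):
            wide = rng.normal(size=(n_donors, 4))
            out = compare_to_control(
                _long(wide, self.GROUPS), n_mc=4000, seed=1000 + i
            )
            if (out["adjusted_p"] <= 0.05).any():
                rejections += 1
        assert rejections / n_sims <= 0.065


class TestSidak:
    def test_family_of_one_is_identity(self):
        assert sidak_adjust(0.2, 1) == pytest.approx(0.2)

    def test_closed_form(self):
        assert sidak_adjust(0.05, 3) == pytest.approx(1 - 0.95**3, rel=1e-12)
        assert sidak_adjust(0.05, 3) == pytest.approx(0.142625, rel=1e-9)

    def test_pairwise_contrasts_adjusted(self, rng):
        rows = []
        for d in range(6):
            for stim in ("Medium", "LPS"):
                for method in ("HPG", "Puro"):
                    rows.append(
                        {
                            "donor": f"d{d}",
                            "stim": stim,
                            "method": method,
                            "value": rng.normal(50 + (stim == "LPS") * 10, 5),
                        }
                    )
        frame = pd.DataFrame(rows)
        contrasts = [
            (("Medium", "HPG"), ("LPS", "HPG")),
            (("Medium", "Puro"), ("LPS", "Puro")),
        ]
        out = pairwise_condition_tests(frame, contrasts, "stim", "method")
        assert np.allclose(out["adjusted_p"], sidak_adjust(out["raw_p"].to_numpy(), 2))
        assert np.all(out["adjusted_p"] >= out["raw_p"])

    def test_missing_cells_rejected(self):
        frame = pd.DataFrame(
            {"donor": ["d1"] * 2, "stim": ["Medium", "LPS"],
             "method": ["HPG", "HPG"], "value": [1.0, 2.0]}
        )
        with pytest.raises(StatsError, match="missing"):
            pairwise_condition_tests(
                frame, [(("Medium", "Puro"), ("LPS", "Puro"))], "stim", "method"
            )


def _random_matrix(rng, n=6, p=4):
    return pd.DataFrame(
        rng.normal(size=(n, p)) @ rng.normal(size=(p, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"pop{j}:glucose_dependence" for j in range(p)],
    )


class TestPCA:
    def test_duplicated_feature_gives_full_first_component(self, rng):
        base = rng.normal(size=8)
        matrix = pd.DataFrame(
            {"a:glucose_dependence": base, "b:glucose_dependence": 2 * base + 1},
            index=[f"s{i}" for i in range(8)],
        )
        res = pca_profiles(matrix)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_reconstruct_scaled_matrix(self, rng):
        matrix = _random_matrix(rng)
        res = pca_profiles(matrix)
        x = matrix.to_numpy()
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, x, atol=1e-9)

    def test_matches_eigendecomposition_of_correlation_matrix(self, rng):
        matrix = _random_matrix(rng, n=6, p=4)
        res = pca_profiles(matrix)
        # independent oracle: eigen-decomposition of the correlation matrix
        corr = np.corrcoef(matrix.to_numpy(), rowvar=False)
        eigval, eigvec = linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        # explained fractions: note SVD uses n-1 scaling consistently
        expected_frac = eigval / eigval.sum()
        k = len(res.explained_variance_fraction)
        assert np.allclose(res.explained_variance_fraction, expected_frac[:k],
                           atol=1e-9)
        for j in range(k):
            got = res.loadings.iloc[:, j].to_numpy()
            ref = eigvec[:, j]
            assert np.allclose(np.abs(got), np.abs(ref), atol=1e-8)

    def test_loadings_orthonormal_and_variance_monotone(self, rng):
        res = pca_profiles(_random_matrix(rng, n=10, p=5))
        v = res.loadings.to_numpy()
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-9)
        frac = res.explained_variance_fraction
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1 + 1e-9

    def test_invariant_to_feature_and_sample_order(self, rng):
        matrix = _random_matrix(rng)
        res = pca_profiles(matrix)
        shuffled = matrix.iloc[::-1, ::-1]
        res2 = pca_profiles(shuffled)
        assert np.allclose(
            res2.explained_variance_fraction, res.explained_variance_fraction
        )
        assert np.allclose(
            res2.loadings.loc[res.loadings.index].to_numpy(),
            res.loadings.to_numpy(),
            atol=1e-9,
        )

    def test_zero_variance_feature_dropped(self, rng):
        matrix = _random_matrix(rng)
        matrix["const:glucose_dependence"] = 5.0
        res = pca_profiles(matrix)
        assert res.dropped_features == ["const:glucose_dependence"]

    def test_all_constant_is_error(self):
        matrix = pd.DataFrame(
            np.ones((4, 3)), columns=["a:x", "b:x", "c:x"]
        )
        with pytest.raises(StatsError):
            pca_profiles(matrix)


class TestTopLoadings:
    def test_duplicated_pair_ranked_first(self, rng):
        base = rng.normal(size=8)
        matrix = pd.DataFrame(
            {
                "a:glucose_dependence": base,
                "b:glucose_dependence": base * 3,
                "c:glucose_dependence": rng.normal(size=8) * 0.01 + base,
            },
            index=[f"s{i}" for i in range(8)],
        )
        res = pca_profiles(matrix)
        top = top_loadings(res, "PC1", k=1)
        assert top.loc[0, "feature"].endswith("glucose_dependence")

    def test_tie_broken_by_name(self):
        base = np.array([1.0, -1.0, 2.0, -2.0])
        matrix = pd.DataFrame(
            {"b:x": base, "a:x": base}, index=[f"s{i}" for i in range(4)]
        )
        res = pca_profiles(matrix)
        top = top_loadings(res, "PC1", k=2)
        assert list(top["feature"]) == ["a:x", "b:x"]

    def test_k_truncated_to_feature_count(self, rng):
        res = pca_profiles(_random_matrix(rng))
        assert len(top_loadings(res, "PC1", k=99)) == 4

    def test_metric_class_parsed(self, rng):
        profiles = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"] * 2,
                "population": ["mac"] * 3 + ["tc"] * 3,
                "glucose_dependence": rng.uniform(0, 100, 6),
                "mitochondrial_dependence": rng.uniform(0, 100, 6),
            }
        )
        matrix = build_profile_matrix(profiles)
        assert matrix.shape == (3, 4)
        res = pca_profiles(matrix)
        top = top_loadings(res, "PC1", k=4)
        assert set(top["metric_class"]) <= {
            "glucose_dependence", "mitochondrial_dependence"
        }
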