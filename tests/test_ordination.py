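"""MCA / rank-PCA / MFA: closed-form oracles and structural invariants."""

import numpy as np
import pandas as pd
import pytest

from medipdmr import (MCA, MFA, dim_correlations, group_ellipses,
                      load_lesion_fixture, mca, merge_rare_categories, mfa,
                      rank_pca)


# ---------------------------------------------------------------------------
# category merging


class TestMergeRareCategories:
    def test_fixture_merges_match_reported_labels(self):
        scores, _ = load_lesion_fixture()
        merged = merge_rare_categories(scores.dropna())
        assert set(merged["S"]) == {"S0", "S1S2"}
        assert int((merged["S"] == "S1S2").sum()) == 5
        assert set(merged["A"]) == {"A0", "A1", "A2A3"}
        assert set(merged["C"]) == {"C0", "C1C2"}
        assert set(merged["I"]) == {"I0", "I1I2"}
        # R, F, G have no rare observed categories and stay untouched
        assert set(merged["R"]) == {"R0", "R1", "R2"}
        assert set(merged["F"]) == {"F0", "F2", "F3"}
        assert set(merged["G"]) == {"G0", "G2"}

    def test_no_rare_categories_is_identity(self):
        table = pd.DataFrame({"X": ["X0"] * 5 + ["X1"] * 5})
        out = merge_rare_categories(table)
        pd.testing.assert_frame_equal(out, table)

    def test_variable_collapsing_to_one_category_dropped(self):
        table = pd.DataFrame({"X": ["X0"] * 2 + ["X1"] * 1,
                              "Y": ["Y0"] * 2 + ["Y1"] * 1})
        with pytest.warns(UserWarning, match="dropped"):
            out = merge_rare_categories(table, min_count=4)
        assert out.shape[1] == 0


# ---------------------------------------------------------------------------
# MCA


def _crossed_binary(n_per_cell, associated):
    """Two binary variables, perfectly associated or fully crossed."""
    if associated:
        a = ["u"] * n_per_cell + ["v"] * n_per_cell
        b = ["x"] * n_per_cell + ["y"] * n_per_cell
    else:
        a = ["u", "u", "v", "v"] * n_per_cell
        b = ["x", "y", "x", "y"] * n_per_cell
    return pd.DataFrame({"A": a, "B": b})


class TestMCA:
    def test_perfect_association_closed_form(self):
        res = mca(_crossed_binary(4, associated=True))
        assert res.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-8)
        assert res.total_inertia == pytest.approx(1.0)

    def test_independent_crossed_closed_form(self):
        res = mca(_crossed_binary(2, associated=False))
        assert np.allclose(res.eigenvalues, [0.5, 0.5], atol=1e-10)
        assert res.pct_variance[0] == pytest.approx(50.0, abs=1e-8)

    def test_lesion_fixture_first_dimension_share(self):
        scores, _ = load_lesion_fixture()
        res = mca(merge_rare_categories(scores.dropna()))
        assert res.pct_variance[0] == pytest.approx(35.0, abs=1.0)

    def test_total_inertia_and_eigenvalue_range(self):
        scores, _ = load_lesion_fixture()
        merged = merge_rare_categories(scores.dropna())
        res = mca(merged)
        J = sum(merged[c].nunique() for c in merged)
        Q = merged.shape[1]
        assert res.total_inertia == pytest.approx(J / Q - 1, abs=1e-10)
        assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, abs=1e-10)
        assert ((res.eigenvalues >= -1e-12) & (res.eigenvalues <= 1 + 1e-12)).all()
        assert res.pct_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_row_scores_orthogonal(self):
        scores, _ = load_lesion_fixture()
        res = mca(merge_rare_categories(scores.dropna()))
        F = res.row_coords.to_numpy()
        gram = F.T @ F
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_missing_cells_rejected(self):
        scores, _ = load_lesion_fixture()
        with pytest.raises(ValueError, match="missing"):
            mca(scores)

    def test_agrees_with_burt_matrix_eigen_oracle(self):
        """Indicator-SVD eigenvalues^2 equal Burt-matrix eigenvalues."""
        table = _crossed_binary(2, associated=False).iloc[:6]
        res = mca(table)
        Z = pd.get_dummies(table).to_numpy(float)
        n, Q = len(table), table.shape[1]
        P = Z / (n * Q)
        c = P.sum(axis=0)
        burt = (Z.T @ Z) / (n * Q * Q)   # Burt correspondence table
        Dc = np.diag(1 / np.sqrt(c))
        M = Dc @ (burt - np.outer(c, c)) @ Dc
        oracle = np.sort(np.linalg.eigvalsh(M))[::-1]
        k = len(res.eigenvalues)
        assert np.allclose(res.eigenvalues, oracle[:k], atol=1e-10)


# ---------------------------------------------------------------------------
# rank-PCA


class TestRankPCA:
    def test_comonotone_pair_is_one_dimensional(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        table = pd.DataFrame({"a": x, "b": np.exp(x)})
        res = rank_pca(table)
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_antimonotone_pair_is_one_dimensional(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        res = rank_pca(pd.DataFrame({"a": x, "b": -(x ** 3)}))
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        res1 = rank_pca(table)
        warped = table.copy()
        warped["a"] = np.exp(warped["a"])
        warped["c"] = warped["c"] ** 3
        res2 = rank_pca(warped)
        assert np.allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)
        pd.testing.assert_frame_equal(res1.row_coords, res2.row_coords)

    def test_zero_variance_column_excluded(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1],
                              "c": [7.0, 7, 7, 7]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = rank_pca(table)
        assert list(res.col_coords.index) == ["a", "b"]

    def test_agrees_with_correlation_eigen_oracle(self):
        from scipy.stats import rankdata
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(10, 5)),
                             columns=list("abcde"))
        res = rank_pca(table)
        R = np.corrcoef(np.column_stack(
            [rankdata(table[c]) for c in table]), rowvar=False)
        oracle = np.sort(np.linalg.eigvalsh(R))[::-1]
        assert np.allclose(res.eigenvalues, oracle, atol=1e-10)


# ---------------------------------------------------------------------------
# MFA


def _uncorrelated_pair(n=12, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a = a - a.mean()
    b = b - b.mean()
    b = b - a * (a @ b) / (a @ a)  # uncorrelated after centring
    return a, b


class TestMFA:
    def test_identical_single_variable_sets(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=10)
        res = mfa({"s1": pd.DataFrame({"a": v}), "s2": pd.DataFrame({"b": v})})
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(res.group_coords["dim1"], [1.0, 1.0], atol=1e-10)

    def test_orthogonal_sets_block_coordinates(self):
        a, b = _uncorrelated_pair()
        res = mfa({"s1": pd.DataFrame({"a": a}), "s2": pd.DataFrame({"b": b})})
        got = res.group_coords[["dim1", "dim2"]].to_numpy()
        assert np.allclose(got, np.eye(2), atol=1e-8)

    def test_group_coordinate_sum_equals_eigenvalue(self):
        rng = np.random.default_rng(7)
        sets = {"x": pd.DataFrame(rng.normal(size=(14, 3)), columns=list("abc")),
                "y": pd.DataFrame(rng.normal(size=(14, 2)), columns=list("de"))}
        res = mfa(sets)
        sums = res.group_coords.sum(axis=0).to_numpy()
        assert np.allclose(sums, res.eigenvalues, atol=1e-8)
        assert (res.group_coords.to_numpy() <= 1 + 1e-8).all()

    def test_weighted_sets_have_unit_first_eigenvalue(self):
        rng = np.random.default_rng(8)
        sets = {"x": pd.DataFrame(rng.normal(size=(20, 4))),
                "y": pd.DataFrame(rng.normal(size=(20, 3)))}
        sets = {k: v.set_axis([f"{k}{i}" for i in range(v.shape[1])], axis=1)
                for k, v in sets.items()}
        res = mfa(sets)
        n = 20
        for name, table in sets.items():
            Z = (table - table.mean()) / table.std(ddof=0)
            Zw = Z / np.sqrt(res.set_first_eigenvalues[name])
            top = np.linalg.svd(Zw.to_numpy() / np.sqrt(n),
                                compute_uv=False)[0] ** 2
            assert top == pytest.approx(1.0, abs=1e-10)

    def test_illustrative_eta2_separated_groups(self):
        rng = np.random.default_rng(9)
        n = 20
        shift = np.r_[np.zeros(10), np.full(10, 50.0)]
        sets = {
            "x": pd.DataFrame({"a": shift + rng.normal(size=n),
                               "b": shift + rng.normal(size=n)}),
            "y": pd.DataFrame({"c": shift + rng.normal(size=n)}),
        }
        groups = pd.Series(["g1"] * 10 + ["g2"] * 10, name="Group")
        res = mfa(sets, illustrative=groups)
        assert res.illustrative_coords.loc["Group", "dim1"] >= 0.99
        assert 0 <= res.illustrative_coords.loc["Group", "dim2"] <= 1

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mfa({"s1": pd.DataFrame({"a": [1.0, 1, 1, 1]}),
                 "s2": pd.DataFrame({"b": [1.0, 2, 3, 4]})})

    def test_mismatched_rows_rejected(self):
        a = pd.DataFrame({"a": [1.0, 2, 3]}, index=[0, 1, 2])
        b = pd.DataFrame({"b": [1.0, 2, 3]}, index=[5, 6, 7])
        with pytest.raises(ValueError, match="mismatched"):
            mfa({"s1": a, "s2": b})

    def test_agrees_with_explicit_eigen_oracle(self):
        """Global axes equal the eigen-decomposition of the weighted
        correlation-like matrix built by hand."""
        rng = np.random.default_rng(11)
        sets = {"x": pd.DataFrame(rng.normal(size=(9, 3)), columns=list("abc")),
                "y": pd.DataFrame(rng.normal(size=(9, 2)), columns=list("de"))}
        res = mfa(sets)
        n = 9
        blocks = []
        for name, table in sets.items():
            Z = (table - table.mean()) / table.std(ddof=0)
            lam1 = np.linalg.svd(Z.to_numpy() / np.sqrt(n),
                                 compute_uv=False)[0] ** 2
            blocks.append(Z.to_numpy() / np.sqrt(lam1))
        Xw = np.hstack(blocks)
        oracle = np.sort(np.linalg.eigvalsh(Xw.T @ Xw / n))[::-1]
        k = len(res.eigenvalues)
        assert np.allclose(res.eigenvalues, oracle[:k], atol=1e-9)


# ---------------------------------------------------------------------------
# axis correlations and ellipses


class TestDimCorrelations:
    def test_variable_equal_to_axis(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        res = rank_pca(table)
        vars_ = pd.DataFrame({"axis_copy": res.row_coords["dim1"]})
        out = dim_correlations(res, vars_, dim=1)
        assert out.r.iloc[0] == pytest.approx(1.0)
        assert bool(out.significant.iloc[0])

    def test_null_variable_type_i_rate(self):
        """Pure-noise variables flag at roughly the nominal alpha."""
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(17, 3)), columns=list("abc"))
        res = rank_pca(table)
        noise = pd.DataFrame(rng.normal(size=(17, 400)),
                             index=table.index,
                             columns=[f"n{i}" for i in range(400)])
        out = dim_correlations(res, noise, dim=1, alpha=0.05)
        rate = out.significant.mean()
        assert 0.01 < rate < 0.11  # 3 binomial SE around 0.05 for 400 trials

    def test_short_variable_skipped(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.normal(size=(10, 2)), columns=list("ab"))
        res = rank_pca(table)
        sparse = pd.DataFrame({"v": [1.0, 2.0] + [np.nan] * 8},
                              index=table.index)
        with pytest.warns(UserWarning, match="skipped"):
            out = dim_correlations(res, sparse)
        assert len(out) == 0


class TestGroupEllipses:
    def test_isotropic_gaussian_is_circular(self):
        rng = np.random.default_rng(10)
        n = 4000
        coords = pd.DataFrame(rng.normal(0, 2.0, size=(n, 2)),
                              columns=["dim1", "dim2"])
        groups = pd.Series(["g"] * n, index=coords.index)
        (ell,) = group_ellipses(coords, groups)
        expected = np.eye(2) * 4.0 / n
        assert np.allclose(ell.dispersion, expected, rtol=0.2, atol=1e-4)
        from scipy.stats import chi2
        assert ell.scale == pytest.approx(chi2.ppf(0.95, 2))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(30, 2))
        coords = pd.DataFrame(np.vstack([base, base + [10, -5]]),
                              columns=["dim1", "dim2"])
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=coords.index)
        ea, eb = group_ellipses(coords, groups)
        assert np.allclose(ea.dispersion, eb.dispersion)
        assert np.allclose(eb.center - ea.center, [10, -5], atol=1e-12)

    def test_degenerate_and_small_groups(self):
        coords = pd.DataFrame([[0.0, 0], [0, 0], [0, 0], [5, 5]],
                              columns=["dim1", "dim2"])
        groups = pd.Series(["same", "same", "same", "tiny"],
                           index=coords.index)
        with pytest.warns(UserWarning, match="< 3 members"):
            ellipses = group_ellipses(coords, groups)
        assert len(ellipses) == 1 and ellipses[0].degenerate
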