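"""Factorial design coding, per-gene OLS inference, BH adjustment, dual selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitofactor as mf

from conftest import make_matrix


def balanced_design(n_per_cell=1):
    rows = []
    for geno in ("ko", "wt"):
        for treat in ("treated", "untreated"):
            for r in range(n_per_cell):
                rows.append([f"{geno}_{treat}_{r}", geno, treat, True])
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment", "include"])


class TestEncodeDesign:
    def test_balanced_columns_orthogonal(self):
        X = mf.encode_design(balanced_design(1))
        M = X.to_numpy()
        gram = M.T @ M
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-12)

    def test_unbalanced_full_rank_not_orthogonal(self):
        d = balanced_design(2).iloc[:-1]  # one cell loses a sample
        X = mf.encode_design(d).to_numpy()
        assert np.linalg.matrix_rank(X) == 4
        gram = X.T @ X
        assert np.abs(gram - np.diag(np.diag(gram))).max() > 0

    def test_excluded_samples_dropped(self):
        d = balanced_design(2)
        d.loc[0, "include"] = False
        X = mf.encode_design(d)
        assert d.loc[0, "sample_id"] not in X.index
        assert len(X) == 7

    def test_single_level_factor_rejected(self):
        d = balanced_design(2)
        d["treatment"] = "treated"
        with pytest.raises(ValueError, match="treatment"):
            mf.encode_design(d)

    def test_coding_signs(self):
        X = mf.encode_design(balanced_design(1))
        assert X.loc["ko_treated_0"].tolist() == [1.0, 1.0, 1.0, 1.0]
        assert X.loc["wt_untreated_0"].tolist() == [1.0, -1.0, -1.0, 1.0]


def _fit(y_by_sample, design):
    X = mf.encode_design(design)
    m = make_matrix(
        np.array([[y_by_sample[s] for s in X.index]]),
        gene_ids=["g"], sample_ids=list(X.index), scale="normlog",
    )
    return mf.fit_factorial(m, X)


class TestFitFactorial:
    def test_pure_interaction_contrast(self):
        d = balanced_design(1)
        y = {"ko_treated_0": 1.0, "ko_untreated_0": -1.0,
             "wt_treated_0": -1.0, "wt_untreated_0": 1.0}
        res = _fit(y, d)
        assert res["beta_gt"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        for c in ("beta0", "beta_g", "beta_t"):
            assert res[c].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_beta_g_is_half_group_difference(self):
        rng = np.random.default_rng(21)
        d = balanced_design(3)
        X = mf.encode_design(d)
        Y = rng.normal(2.0, 0.4, (20, len(X)))
        m = make_matrix(Y, sample_ids=list(X.index), scale="normlog")
        res = mf.fit_factorial(m, X)
        ko = [s for s in X.index if s.startswith("ko")]
        wt = [s for s in X.index if s.startswith("wt")]
        expected = (m.values[ko].mean(axis=1) - m.values[wt].mean(axis=1)) / 2.0
        np.testing.assert_allclose(res["beta_g"], expected.to_numpy(), atol=1e-10)

    def test_normal_equations_oracle(self):
        # brute-force (X'X)^-1 X'y on a seeded 8-sample toy
        rng = np.random.default_rng(8)
        d = balanced_design(2)
        X = mf.encode_design(d)
        Y = rng.normal(0.0, 1.0, (15, 8))
        m = make_matrix(Y, sample_ids=list(X.index), scale="normlog")
        res = mf.fit_factorial(m, X)
        Xa = X.to_numpy()
        beta_oracle = np.linalg.solve(Xa.T @ Xa, Xa.T @ Y.T).T
        ours = res[["beta0", "beta_g", "beta_t", "beta_gt"]].to_numpy()
        assert np.abs(ours - beta_oracle).max() <= 1e-10

    def test_matches_classical_two_way_anova(self):
        # in a balanced design the per-coefficient t test equals the 1-df F test
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(4)
        d = balanced_design(3)
        X = mf.encode_design(d)
        y = rng.normal(1.0, 0.5, len(X))
        m = make_matrix(y[None, :], gene_ids=["g"], sample_ids=list(X.index), scale="normlog")
        res = mf.fit_factorial(m, X)

        df = pd.DataFrame({
            "y": y,
            "G": ["ko" if s.startswith("ko") else "wt" for s in X.index],
            "T": ["treated" if "_treated" in s else "untreated" for s in X.index],
        })
        lm = smf.ols("y ~ C(G) * C(T)", data=df).fit()
        aov = anova_lm(lm, typ=2)
        assert res["p_genotype"].iloc[0] == pytest.approx(aov.loc["C(G)", "PR(>F)"], rel=1e-9)
        assert res["p_treatment"].iloc[0] == pytest.approx(aov.loc["C(T)", "PR(>F)"], rel=1e-9)
        assert res["p_interaction"].iloc[0] == pytest.approx(
            aov.loc["C(G):C(T)", "PR(>F)"], rel=1e-9)
        assert res["t_genotype"].iloc[0] ** 2 == pytest.approx(aov.loc["C(G)", "F"], rel=1e-9)

    def test_rank_deficient_rejected(self):
        d = balanced_design(2)
        X = mf.encode_design(d)
        X["interaction"] = X["genotype"]
        m = make_matrix(np.ones((2, 8)), sample_ids=list(X.index), scale="normlog")
        with pytest.raises(ValueError, match="rank"):
            mf.fit_factorial(m, X)

    def test_zero_residual_df_gives_nan_inference(self):
        d = balanced_design(1)
        X = mf.encode_design(d)
        m = make_matrix(np.arange(4.0)[None, :], sample_ids=list(X.index), scale="normlog")
        res = mf.fit_factorial(m, X)
        assert res["df"].iloc[0] == 0
        assert np.isnan(res["p_genotype"].iloc[0])


def _bh_oracle(p):
    # textbook step-up: p_(i) * n / i, cumulative min from the top, clip at 1
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


class TestBHAdjust:
    def test_hand_step_up_oracle(self):
        res = mf.bh_adjust([0.005, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(res, [0.02, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(mf.bh_adjust([0.3]), [0.3])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(mf.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            mf.bh_adjust([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_independent_step_up(self, p):
        np.testing.assert_allclose(mf.bh_adjust(p), _bh_oracle(p), atol=1e-12)


class TestSelectDualSignificant:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "adj_p_genotype", "adj_p_treatment", "adj_p_interaction"]
        )

    def test_both_main_effects_selected(self):
        t = self._table([["g", 0.005, 0.005, 0.9]])
        assert mf.select_dual_significant(t) == {"g"}

    def test_single_effect_not_selected(self):
        t = self._table([["g", 0.005, 0.5, 0.005]])
        assert mf.select_dual_significant(t) == set()

    def test_alpha_zero_empty(self):
        t = self._table([["g", 0.0, 0.0, 0.0]])
        assert mf.select_dual_significant(t, alpha=0.0) == set()

    def test_interaction_flag(self):
        t = self._table([["g", 0.005, 0.005, 0.9], ["h", 0.005, 0.005, 0.001]])
        assert mf.select_dual_significant(t, include_interaction=True) == {"h"}
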