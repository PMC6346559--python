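"""Delta coefficient, additivity test, design-system OLS, coessentiality
edges and the self-expression screen."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from screenaudit.interactions import (
    additivity_test,
    coessentiality_edges,
    delta_coefficient,
    expected_min_lfc,
    self_expression_screen,
    solve_design_ols,
)


class TestDeltaCoefficient:
    def test_zero_when_guide_equals_clean_mean(self, rng):
        clean = rng.normal(size=(10, 3))
        y = np.column_stack([clean.mean(axis=1), clean])
        fit = delta_coefficient(y)
        assert fit.delta == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_closed_form_equivalence(self, seed):
        """delta-hat equals mean_i(y_i1 - clean-guide mean_i) exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        n_g = int(rng.integers(2, 8))
        y = rng.normal(size=(n, n_g))
        fit = delta_coefficient(y)
        closed = float(np.mean(y[:, 0] - y[:, 1:].mean(axis=1)))
        assert fit.delta == pytest.approx(closed, abs=1e-10)

    def test_matches_generic_ols_oracle(self, rng):
        n, n_g = 8, 4
        y = rng.normal(size=(n, n_g))
        fit = delta_coefficient(y)
        # dummy-coded design with statsmodels as the independent route
        obs = y.ravel()
        cells = np.repeat(np.arange(n), n_g)
        interest = np.tile(np.arange(n_g) == 0, n).astype(float)
        X = pd.get_dummies(pd.Series(cells), drop_first=True, dtype=float)
        X["interest"] = interest
        model = sm.OLS(obs, sm.add_constant(X)).fit()
        assert fit.delta == pytest.approx(model.params["interest"], abs=1e-10)
        assert fit.se_delta == pytest.approx(model.bse["interest"], abs=1e-10)
        assert fit.p_value == pytest.approx(model.pvalues["interest"], abs=1e-10)

    def test_requires_clean_guides(self, rng):
        with pytest.raises(ValueError, match="clean"):
            delta_coefficient(rng.normal(size=(5, 1)))

    def test_alpha_is_clean_guide_mean_under_sum_to_zero(self, rng):
        y = rng.normal(size=(6, 5))
        fit = delta_coefficient(y)
        assert fit.alpha == pytest.approx(float(y[:, 1:].mean()), abs=1e-10)
        assert fit.cell_effects.sum() == pytest.approx(0.0, abs=1e-10)


class TestAdditivity:
    def test_exact_additivity_gives_zero_contrast(self):
        a, b = -0.4, 0.1
        fit = additivity_test([a] * 6, [b] * 6, [a + b] * 6)
        assert fit.contrast == pytest.approx(0.0, abs=1e-12)
        assert fit.beta_a + fit.beta_b - fit.beta_ab == pytest.approx(fit.contrast)

    def test_matches_statsmodels_oracle(self, rng):
        ya, yb, yab = rng.normal(size=20), rng.normal(size=25), rng.normal(size=15)
        fit = additivity_test(ya, yb, yab)
        y = np.concatenate([ya, yb, yab])
        X = np.zeros((60, 3))
        X[:20, 0] = 1
        X[20:45, 1] = 1
        X[45:, 2] = 1
        model = sm.OLS(y, X).fit()
        assert (fit.beta_a, fit.beta_b, fit.beta_ab) == pytest.approx(tuple(model.params))
        tt = model.t_test([1, 1, -1])
        assert fit.t_contrast == pytest.approx(float(np.squeeze(tt.tvalue)))
        assert fit.p_contrast == pytest.approx(float(np.squeeze(tt.pvalue)))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            additivity_test([1.0], [], [1.0])

    def test_null_p_uniform(self, rng):
        """Under additive truth the contrast p value is uniform."""
        from scipy import stats as sps

        ps = []
        for _ in range(400):
            ba, bb = rng.normal(0, 0.3, 2)
            ya = ba + rng.normal(0, 0.1, 40)
            yb = bb + rng.normal(0, 0.1, 40)
            yab = (ba + bb) + rng.normal(0, 0.1, 40)
            ps.append(additivity_test(ya, yb, yab).p_contrast)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_planted_synthetic_lethality(self, rng):
        gate = rng.random(100) < 0.4
        ya = 0.05 + rng.normal(0, 0.1, 100)
        yb = 0.05 + rng.normal(0, 0.1, 100)
        yab = 0.1 + (-1.0) * gate + rng.normal(0, 0.1, 100)
        fit = additivity_test(ya, yb, yab)
        assert fit.contrast > 0 and fit.p_contrast < 1e-6

    def test_cluster_robust_se_larger_with_shared_cells(self, rng):
        cells = np.repeat(np.arange(10), 4)
        shock = rng.normal(0, 0.5, 10)[cells % 10]
        ya = shock + rng.normal(0, 0.05, 40)
        yb = rng.normal(0, 0.05, 40)
        yab = rng.normal(0, 0.05, 40)
        classical = additivity_test(ya, yb, yab)
        robust = additivity_test(ya, yb, yab, cell_ids=(cells, cells, cells))
        assert robust.se[0] > classical.se[0]


def test_expected_min_lfc_branches():
    assert expected_min_lfc(0.0, 0.0) == 0.0
    assert expected_min_lfc(-1.0, 0.5) == -1.0
    assert expected_min_lfc(-0.4, -0.3) == pytest.approx(-0.7)
    with pytest.raises(ValueError):
        expected_min_lfc(float("nan"), 0.0)


def readthrough_incidence():
    """The 4/3/1 guide x gene incidence of a readthrough design."""
    inc = pd.DataFrame(
        0, index=[f"y{i}" for i in range(1, 9)], columns=["TMED7", "TICAM2", "Fusion"]
    )
    inc.loc["y1":"y4", ["TMED7", "Fusion"]] = 1
    inc.loc["y5":"y7", ["TICAM2", "Fusion"]] = 1
    inc.loc["y8", "TICAM2"] = 1
    return inc


class TestSolveDesignOLS:
    def test_readthrough_closed_forms(self):
        """beta_TICAM2 = y8; beta_Fusion = mean(y5..y7) - beta_TICAM2;
        beta_TMED7 = mean(y1..y4) - beta_Fusion."""
        inc = readthrough_incidence()
        y = pd.Series([-0.8, -0.8, -0.8, -0.8, -0.6, -0.6, -0.6, -0.3], index=inc.index)
        fit = solve_design_ols(inc, y)
        assert fit.scores["TICAM2"] == pytest.approx(-0.3, abs=1e-12)
        assert fit.scores["Fusion"] == pytest.approx(-0.3, abs=1e-12)
        assert fit.scores["TMED7"] == pytest.approx(-0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_readthrough_closed_forms_arbitrary_y(self, seed):
        rng = np.random.default_rng(seed)
        inc = readthrough_incidence()
        y = pd.Series(rng.normal(size=8), index=inc.index)
        fit = solve_design_ols(inc, y)
        b_ticam2 = y["y8"]
        b_fusion = y["y5":"y7"].mean() - b_ticam2
        b_tmed7 = y["y1":"y4"].mean() - b_fusion
        assert fit.scores["TICAM2"] == pytest.approx(b_ticam2, abs=1e-10)
        assert fit.scores["Fusion"] == pytest.approx(b_fusion, abs=1e-10)
        assert fit.scores["TMED7"] == pytest.approx(b_tmed7, abs=1e-10)

    def test_identity_incidence(self, rng):
        y = pd.Series(rng.normal(size=4), index=list("abcd"))
        inc = pd.DataFrame(np.eye(4), index=y.index, columns=["g1", "g2", "g3", "g4"])
        fit = solve_design_ols(inc, y)
        assert np.allclose(fit.scores, y)

    def test_matches_normal_equations(self, rng):
        inc = pd.DataFrame(rng.integers(0, 2, size=(12, 4)), columns=list("wxyz"),
                           index=[f"g{i}" for i in range(12)])
        while np.linalg.matrix_rank(inc) < 4:
            inc = pd.DataFrame(rng.integers(0, 2, size=(12, 4)), columns=list("wxyz"),
                               index=[f"g{i}" for i in range(12)])
        y = pd.Series(rng.normal(size=12), index=inc.index)
        fit = solve_design_ols(inc, y)
        X = inc.to_numpy(float)
        ref = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        assert np.allclose(fit.scores, ref)

    def test_rank_deficient_reported(self, rng):
        inc = pd.DataFrame({"a": [1, 1, 0], "b": [1, 1, 0], "c": [0, 0, 1]},
                           index=["g1", "g2", "g3"])
        y = pd.Series([1.0, 1.2, 0.5], index=inc.index)
        fit = solve_design_ols(inc, y)
        assert set(fit.unidentifiable) == {"a", "b"}
        assert np.isnan(fit.scores["a"]) and np.isnan(fit.scores["b"])
        assert fit.scores["c"] == pytest.approx(0.5)

    def test_design_induced_negative_covariance(self, rng):
        """TMED7 and Fusion scores are negatively coupled by construction."""
        inc = readthrough_incidence()
        fit = solve_design_ols(inc, pd.Series(rng.normal(size=8), index=inc.index))
        assert fit.cov.loc["TMED7", "Fusion"] < 0
        # empirical check under independent noise
        tmed, fus = [], []
        for _ in range(300):
            f = solve_design_ols(inc, pd.Series(rng.normal(size=8), index=inc.index))
            tmed.append(f.scores["TMED7"])
            fus.append(f.scores["Fusion"])
        assert np.corrcoef(tmed, fus)[0, 1] < 0


class TestCoessentiality:
    def test_duplicated_rows_edge(self, rng):
        x = rng.normal(size=20)
        scores = pd.DataFrame([x, x, rng.normal(size=20)], index=["a", "b", "c"])
        edges = coessentiality_edges(scores, 0.35)
        pairs = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        assert ("a", "b") in pairs

    def test_independent_noise_no_edges(self, rng):
        scores = pd.DataFrame(rng.normal(size=(8, 500)), index=[f"g{i}" for i in range(8)])
        edges = coessentiality_edges(scores, 0.35)
        assert edges.empty

    def test_matches_bruteforce_pairwise(self, rng):
        scores = pd.DataFrame(rng.normal(size=(6, 30)), index=[f"g{i}" for i in range(6)])
        scores.iloc[1] = scores.iloc[0] + rng.normal(0, 0.3, 30)
        edges = coessentiality_edges(scores, 0.35)
        expected = set()
        for i in range(6):
            for j in range(i + 1, 6):
                r = np.corrcoef(scores.iloc[i], scores.iloc[j])[0, 1]
                if r >= 0.35:
                    expected.add((f"g{i}", f"g{j}"))
        assert set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy())) == expected

    def test_constant_rows_excluded(self, rng):
        scores = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
        scores.loc["c"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            edges = coessentiality_edges(scores, 0.35)
        assert not edges["gene_a"].eq("c").any() and not edges["gene_b"].eq("c").any()


class TestSelfExpressionScreen:
    def _summaries(self, flagged_gene_guides):
        from test_toxicity import make_summary

        summaries = {}
        for gid, hit in flagged_gene_guides.items():
            s = make_summary(gid, n_perfect=1, n_1mm=1 if hit else 0)
            summaries[gid] = s.__class__(**{**s.__dict__, "genes_hit_1mm": frozenset(hit)})
        return summaries

    def test_unflagged_without_offtarget(self, rng):
        scores = pd.DataFrame(rng.normal(size=(3, 30)), index=["A", "B", "C"],
                              columns=[f"c{i}" for i in range(30)])
        expression = pd.DataFrame(rng.normal(5, 1, size=(3, 30)), index=["A", "B", "C"],
                                  columns=scores.columns)
        summaries = self._summaries({"gA": (), "gB": (), "gC": ()})
        table = self_expression_screen(scores, expression, summaries,
                                       {"gA": "A", "gB": "B", "gC": "C"})
        assert not table["has_exonic_1mm_offtarget"].any()
        assert (table["r_self_expression"].abs() < 0.6).all()

    def test_flag_set_by_exonic_1mm_offtarget(self, rng):
        cells = [f"c{i}" for i in range(40)]
        expr_a = rng.normal(5, 2, 40)
        scores = pd.DataFrame({"A": -0.2 * expr_a + rng.normal(0, 0.1, 40)}, index=cells).T
        expression = pd.DataFrame({"A": expr_a}, index=cells).T
        summaries = self._summaries({"gA": ("B",)})
        table = self_expression_screen(scores, expression, summaries, {"gA": "A"})
        row = table.iloc[0]
        assert row["has_exonic_1mm_offtarget"] and row["offtarget_genes"] == "B"
        assert row["r_self_expression"] < -0.5

    def test_missing_expression_dropped(self, rng):
        cells = [f"c{i}" for i in range(10)]
        scores = pd.DataFrame(rng.normal(size=(2, 10)), index=["A", "B"], columns=cells)
        expression = pd.DataFrame(rng.normal(size=(1, 10)), index=["A"], columns=cells)
        table = self_expression_screen(scores, expression, self._summaries({}), {})
        assert list(table["gene_id"]) == ["A"]
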