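"""Toxicity curve fitting, LFC adjustment and mismatch stratification tests."""

import numpy as np
import pandas as pd
import pytest

from screenaudit.alignment import GuideAlignmentSummary
from screenaudit.toxicity import (
    adjust_for_toxicity,
    fit_toxicity_curve,
    single_mismatch_position_table,
    stratified_mismatch_table,
    toxicity_metric,
    trend_over_alignment_count,
)


def make_summary(gid, n_perfect=1, n_1mm=0, n_2mm=0, pos_1mm=()):
    return GuideAlignmentSummary(
        guide_id=gid,
        n_perfect=n_perfect,
        n_1mm=n_1mm,
        n_2mm=n_2mm,
        n_exonic_1mm=0,
        genes_hit_perfect=frozenset(),
        genes_hit_1mm=frozenset(),
        label="",
        mismatch_positions_1mm=tuple((p,) for p in pos_1mm),
    )


def toxicity_data(rng, n_guides=300, sigma=0.0, t1=-0.05, t2=-0.01, n_values=range(1, 9)):
    summaries, y = {}, {}
    for i in range(n_guides):
        n = int(rng.choice(list(n_values)))
        gid = f"g{i}"
        summaries[gid] = make_summary(gid, n_perfect=n)
        y[gid] = t1 * (n - 1) + t2 * (n - 1) ** 2 + rng.normal(0, sigma)
    return pd.Series(y), summaries


class TestFitToxicityCurve:
    def test_noiseless_quadratic_recovered(self, rng):
        lfc, summaries = toxicity_data(rng, sigma=0.0)
        curve = fit_toxicity_curve(lfc, summaries, "on_target")
        # y = -0.05(n-1) - 0.01(n-1)^2 = -0.04 - 0.03 n - 0.01 n^2 ... expand:
        # t1*(n-1)+t2*(n-1)^2 = (t2 - t1) + (t1 - 2 t2) n + t2 n^2
        assert curve.coef[0] == pytest.approx(0.04, abs=1e-9)
        assert curve.coef[1] == pytest.approx(-0.03, abs=1e-9)
        assert curve.coef[2] == pytest.approx(-0.01, abs=1e-9)

    def test_noisy_recovery_within_3se(self, rng):
        lfc, summaries = toxicity_data(rng, n_guides=2000, sigma=0.1)
        curve = fit_toxicity_curve(lfc, summaries, "on_target")
        truth = (0.04, -0.03, -0.01)
        for est, se, tr in zip(curve.coef, curve.coef_se, truth):
            assert abs(est - tr) < 3 * se

    def test_equals_normal_equations_oracle(self, rng):
        lfc, summaries = toxicity_data(rng, n_guides=150, sigma=0.2)
        curve = fit_toxicity_curve(lfc, summaries, "on_target")
        x = np.array([summaries[g].n_perfect for g in lfc.index], float)
        X = np.column_stack([np.ones_like(x), x, x * x])
        beta = np.linalg.solve(X.T @ X, X.T @ lfc.to_numpy())
        assert np.allclose(curve.coef, beta)

    def test_single_mismatch_guides_excluded_from_on_target_fit(self, rng):
        lfc, summaries = toxicity_data(rng, n_guides=100)
        # poison: guides with 1-mm off-targets and absurd LFCs must be ignored
        for i in range(20):
            gid = f"bad{i}"
            summaries[gid] = make_summary(gid, n_perfect=2, n_1mm=3)
            lfc[gid] = -50.0
        clean_only = fit_toxicity_curve(lfc, summaries, "on_target")
        assert clean_only.n_guides == 100

    def test_off_target_kind_restricted_to_single_perfect(self, rng):
        summaries, y = {}, {}
        for i in range(200):
            gid = f"g{i}"
            k = int(rng.integers(0, 5))
            summaries[gid] = make_summary(gid, n_perfect=1, n_1mm=k)
            y[gid] = -0.1 * k + rng.normal(0, 0.05)
        summaries["multi"] = make_summary("multi", n_perfect=4, n_1mm=2)
        y["multi"] = -99.0
        curve = fit_toxicity_curve(pd.Series(y), summaries, "off_target_1mm")
        assert curve.n_guides == 200

    def test_insufficient_support_raises(self):
        summaries = {f"g{i}": make_summary(f"g{i}", n_perfect=1) for i in range(10)}
        lfc = pd.Series(0.0, index=list(summaries))
        with pytest.raises(ValueError):
            fit_toxicity_curve(lfc, summaries, "on_target")


class TestAdjustForToxicity:
    def _curves(self, rng, cells):
        lfc, summaries = toxicity_data(rng, n_guides=500, sigma=0.0)
        mat = pd.DataFrame({c: lfc for c in cells})
        curves = {c: fit_toxicity_curve(mat[c], summaries, "on_target", cell_line=c) for c in cells}
        return mat, summaries, curves

    def test_single_target_guides_unchanged(self, rng):
        mat, summaries, curves = self._curves(rng, ["c1", "c2"])
        adjusted = adjust_for_toxicity(mat, summaries, curves)
        singles = [g for g, s in summaries.items() if s.n_perfect == 1]
        assert np.allclose(adjusted.loc[singles], mat.loc[singles])

    def test_removes_n_bin_trend(self, rng):
        mat, summaries, curves = self._curves(rng, ["c1"])
        adjusted = adjust_for_toxicity(mat, summaries, curves)
        for n in range(1, 9):
            gids = [g for g, s in summaries.items() if s.n_perfect == n]
            assert adjusted.loc[gids, "c1"].mean() == pytest.approx(0.0, abs=1e-8)

    def test_linear_in_input(self, rng):
        mat, summaries, curves = self._curves(rng, ["c1"])
        other = mat + rng.normal(size=mat.shape)
        lhs = adjust_for_toxicity(mat + other, summaries, curves)
        rhs = adjust_for_toxicity(mat, summaries, curves) + adjust_for_toxicity(other, summaries, curves)
        # adjustment shift is applied twice on the sum; linearity holds for differences
        diff = adjust_for_toxicity(mat, summaries, curves) - adjust_for_toxicity(other, summaries, curves)
        assert np.allclose(diff, mat - other)

    def test_out_of_domain_clamped(self, rng):
        mat, summaries, curves = self._curves(rng, ["c1"])
        summaries["huge"] = make_summary("huge", n_perfect=50)
        mat.loc["huge"] = -1.0
        with pytest.warns(UserWarning, match="clamped"):
            adjusted = adjust_for_toxicity(mat, summaries, curves)
        curve = curves["c1"]
        shift = curve.predict(np.array([curve.n_max]), clamp=False) - curve.predict(np.array([1.0]), clamp=False)
        assert adjusted.loc["huge", "c1"] == pytest.approx(-1.0 - shift[0])


class TestStratifiedTables:
    def test_identical_lfc_gives_equal_medians(self):
        summaries = {}
        for i in range(40):
            pos = 5 if i % 2 else 15
            summaries[f"g{i}"] = make_summary(f"g{i}", n_perfect=1, n_1mm=1, pos_1mm=(pos,))
        lfc = pd.Series(-0.3, index=list(summaries))
        table = stratified_mismatch_table(lfc, summaries)
        medians = table["median_lfc"].dropna()
        assert np.allclose(medians, -0.3)

    def test_distal_more_toxic_than_proximal(self, rng):
        summaries, y = {}, {}
        for i in range(200):
            distal = i % 2 == 0
            gid = f"g{i}"
            summaries[gid] = make_summary(gid, n_perfect=1, n_1mm=1, pos_1mm=(15 if distal else 5,))
            y[gid] = (-0.6 if distal else -0.05) + rng.normal(0, 0.05)
        table = stratified_mismatch_table(pd.Series(y), summaries)
        row = table.set_index("position_class")
        assert row.loc["pam_distal", "median_lfc"] < row.loc["pam_proximal", "median_lfc"]
        assert row.loc["pam_distal", "p_vs_proximal"] < 0.001

    def test_medians_match_groupwise_oracle(self, rng):
        summaries, y = {}, {}
        for i in range(100):
            k = int(rng.integers(1, 3))
            pos = tuple(int(rng.choice([3, 16])) for _ in range(k))
            gid = f"g{i}"
            summaries[gid] = make_summary(gid, n_perfect=1, n_1mm=k, pos_1mm=pos)
            y[gid] = float(rng.normal())
        lfc = pd.Series(y)
        table = stratified_mismatch_table(lfc, summaries)
        for _, row in table.iterrows():
            if row["position_class"] == "none":
                continue
            vals = [
                lfc[g]
                for g, s in summaries.items()
                if s.n_1mm == row["n_1mm"]
                and (
                    ("pam_proximal" if all(p[0] <= 10 for p in s.mismatch_positions_1mm) else
                     "pam_distal" if all(p[0] >= 11 for p in s.mismatch_positions_1mm) else "mixed")
                    == row["position_class"]
                )
            ]
            assert row["median_lfc"] == pytest.approx(np.median(vals))

    def test_position_table_groups_by_position(self, rng):
        summaries = {f"g{i}": make_summary(f"g{i}", 1, 1, pos_1mm=(1 + i % 20,)) for i in range(60)}
        lfc = pd.Series({g: -s.mismatch_positions_1mm[0][0] / 20 for g, s in summaries.items()})
        table = single_mismatch_position_table(lfc, summaries)
        assert list(table["position"]) == list(range(1, 21))
        assert table["median_lfc"].is_monotonic_decreasing


class TestTrend:
    def test_decreasing_trend_detected(self, rng):
        lfc, summaries = toxicity_data(rng, n_guides=400, sigma=0.05)
        res = trend_over_alignment_count(lfc, summaries, "on_target", alternative="decreasing")
        assert res.p_value < 1e-10

    def test_too_few_groups_raise(self):
        summaries = {f"g{i}": make_summary(f"g{i}", n_perfect=1) for i in range(10)}
        lfc = pd.Series(0.0, index=list(summaries))
        with pytest.raises(ValueError):
            trend_over_alignment_count(lfc, summaries)


def test_toxicity_metric_minimum_bin_size(rng):
    summaries = {f"g{i}": make_summary(f"g{i}", n_perfect=4, n_1mm=0) for i in range(3)}
    lfc = pd.Series(-0.5, index=list(summaries))
    m = toxicity_metric(lfc, summaries, min_guides=5)
    assert np.isnan(m.on_target_at_4) and m.n_on == 3
    m2 = toxicity_metric(lfc, summaries, min_guides=3)
    assert m2.on_target_at_4 == pytest.approx(-0.5)
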