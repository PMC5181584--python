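"""Variance dissection, heritability, plasticity and trait transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gxemap import phenostats as ps


def make_table(values_by_cell, location="Avi"):
    """Build a long table from {(group, accession, regime): [replicates]}."""
    rows = []
    for (group, acc, regime), vals in values_by_cell.items():
        for r, v in enumerate(vals, start=1):
            rows.append((acc, group, location, regime, r, "trait", float(v)))
    return pd.DataFrame(
        rows, columns=["accession", "group", "location", "regime", "replicate", "trait", "value"]
    )


def balanced_table(rng, n_groups=2, n_acc=4, n_rep=2, g_effect=0.0, acc_sd=1.0,
                   w_effect=0.0, gxw=0.0, noise=1.0):
    cells = {}
    for g in range(n_groups):
        for a in range(n_acc):
            acc_val = rng.normal(0, acc_sd)
            for k, regime in enumerate(("C", "D")):
                mu = g * g_effect + acc_val + k * w_effect + g * k * gxw
                cells[(f"g{g}", f"g{g}a{a}", regime)] = mu + rng.normal(0, noise, n_rep)
    return make_table(cells)


class TestBoxCox:
    def test_symmetric_data_keeps_identity(self):
        x = np.concatenate([np.linspace(1, 9, 101), np.linspace(1, 9, 101)])
        _, lam, shift = ps.boxcox_transform(x)
        assert lam == 1.0
        assert shift == 0.0

    def test_lognormal_sample_chooses_log(self):
        hits = 0
        for seed in range(20):
            x = np.exp(np.random.default_rng(seed).standard_normal(500))
            _, lam, _ = ps.boxcox_transform(x)
            hits += abs(lam) < 0.25
        assert hits >= 15

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ps.boxcox_transform(np.ones(10))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ps.boxcox_transform(np.array([1.0, np.nan, 2.0]))

    def test_nonpositive_data_shifted(self):
        x = np.random.default_rng(0).standard_normal(100)  # has negatives
        t, lam, shift = ps.boxcox_transform(x)
        assert shift > 0
        assert np.isfinite(t).all()


class TestAnova:
    def test_fractions_sum_to_one_and_df_to_n_minus_1(self):
        table = balanced_table(np.random.default_rng(0), g_effect=1, w_effect=0.5, gxw=0.3)
        res = ps.anova_partition(table, "trait", "Avi")
        assert res["fraction"].sum() == pytest.approx(1.0, abs=1e-10)
        assert res["df"].sum() == len(table) - 1

    def test_balanced_sums_of_squares_match_closed_form(self):
        # balanced design -> sequential SS equal the classical cell-mean
        # formulas computed independently here
        table = balanced_table(np.random.default_rng(1), g_effect=2, w_effect=1, gxw=0.7)
        res = ps.anova_partition(table, "trait", "Avi")
        y = table.set_index(["group", "accession", "regime", "replicate"])["value"]
        grand = y.mean()
        n_per_group = y.groupby("group").size()
        ss_gr = float((n_per_group * (y.groupby("group").mean() - grand) ** 2).sum())
        acc_means = y.groupby(["group", "accession"]).mean()
        grp_of = acc_means.index.get_level_values(0)
        grp_means = y.groupby("group").mean()
        n_per_acc = y.groupby(["group", "accession"]).size()
        ss_acc = float((n_per_acc * (acc_means - grp_means[grp_of].to_numpy()) ** 2).sum())
        n_per_w = y.groupby("regime").size()
        ss_w = float((n_per_w * (y.groupby("regime").mean() - grand) ** 2).sum())
        assert res.loc["Gr", "ss"] == pytest.approx(ss_gr, rel=1e-9)
        assert res.loc["Gr(G)", "ss"] == pytest.approx(ss_acc, rel=1e-9)
        assert res.loc["W", "ss"] == pytest.approx(ss_w, rel=1e-9)

    def test_all_equal_values_give_zero_ss(self):
        cells = {(g, f"{g}a{a}", w): [5.0, 5.0] for g in ("g0", "g1")
                 for a in range(3) for w in ("C", "D")}
        res = ps.anova_partition(make_table(cells), "trait", "Avi")
        assert res["ss"].sum() == pytest.approx(0.0, abs=1e-18)

    def test_null_regime_effect_rarely_significant(self):
        hits = 0
        for seed in range(20):
            table = balanced_table(np.random.default_rng(seed), n_acc=10, w_effect=0.0)
            res = ps.anova_partition(table, "trait", "Avi")
            hits += res.loc["W", "pvalue"] > 0.05
        assert hits >= 16

    def test_missing_regime_errors(self):
        cells = {("g0", "a0", "C"): [1, 2], ("g0", "a1", "C"): [2, 3]}
        with pytest.raises(ValueError):
            ps.anova_partition(make_table(cells), "trait", "Avi")


class TestHeritability:
    def test_closed_form_formula(self):
        r = ps.HeritabilityResult(sigma_g2=3.0, sigma_e2=2.0, n_replicates=2)
        assert r.H2 == pytest.approx(0.75)

    def test_reml_matches_anova_estimator_on_balanced_data(self):
        rng = np.random.default_rng(3)
        table = balanced_table(rng, n_groups=1, n_acc=40, n_rep=2, acc_sd=2.0, noise=1.0)
        sub = table[table["regime"] == "C"]
        est = ps.heritability(table, "trait", "Avi", "C")
        # method-of-moments on the one-way balanced layout
        y = sub.set_index(["accession", "replicate"])["value"]
        ms_b = 2 * y.groupby("accession").mean().var(ddof=1)
        ms_w = float(y.groupby("accession").var(ddof=1).mean())
        sg2_mom = (ms_b - ms_w) / 2
        assert est.sigma_g2 == pytest.approx(sg2_mom, rel=1e-3)
        assert est.sigma_e2 == pytest.approx(ms_w, rel=1e-3)

    def test_pure_noise_gives_low_h2(self):
        hits = 0
        for seed in range(10):
            table = balanced_table(np.random.default_rng(100 + seed),
                                   n_groups=1, n_acc=141, acc_sd=0.0, noise=1.0)
            hits += ps.heritability(table, "trait", "Avi", "C").H2 < 0.15
        assert hits >= 9

    def test_single_replicate_errors(self):
        cells = {("g0", f"a{i}", "C"): [float(i)] for i in range(5)}
        with pytest.raises(ValueError, match="replicate"):
            ps.heritability(make_table(cells), "trait", "Avi", "C")


class TestPlasticity:
    @pytest.mark.parametrize("C,D,expected", [(10, 12, 0.2), (10, 10, 0.0), (10, 8, -0.2)])
    def test_delta_formula(self, C, D, expected):
        cells = {("g0", "a0", "C"): [C], ("g0", "a0", "D"): [D]}
        out = ps.plasticity(make_table(cells), "trait", "Avi")
        assert out.loc["a0", "delta"] == pytest.approx(expected)

    def test_zero_control_mean_flagged_missing(self):
        cells = {("g0", "a0", "C"): [0.0], ("g0", "a0", "D"): [1.0]}
        with pytest.warns(UserWarning, match="zero control mean"):
            out = ps.plasticity(make_table(cells), "trait", "Avi")
        assert np.isnan(out.loc["a0", "delta"])

    @given(c=st.floats(0.1, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        base = {("g0", f"a{i}", w): rng.uniform(5, 10, 2)
                for i in range(5) for w in ("C", "D")}
        t1 = make_table(base)
        t2 = t1.copy()
        t2["value"] *= c
        d1 = ps.plasticity(t1, "trait", "Avi")["delta"]
        d2 = ps.plasticity(t2, "trait", "Avi")["delta"]
        np.testing.assert_allclose(d1, d2, rtol=1e-9)


class TestInteractionPartition:
    def _table_from_means(self, C, D):
        cells = {}
        for i, (c, d) in enumerate(zip(C, D)):
            cells[("g0", f"a{i:02d}", "C")] = [c]
            cells[("g0", f"a{i:02d}", "D")] = [d]
        return make_table(cells)

    def test_no_interaction_returns_zero_pair(self):
        C = np.arange(10, dtype=float)
        out = ps.interaction_partition(self._table_from_means(C, C + 3.0), "trait", "Avi")
        assert out == (0.0, 0.0)

    def test_pure_reranking_when_sds_equal(self):
        # construct exact correlation 0.5 with exactly equal sds
        rng = np.random.default_rng(0)
        z = rng.standard_normal((20, 2))
        q, _ = np.linalg.qr(z - z.mean(axis=0))
        z1, z2 = q[:, 0], q[:, 1]
        C = z1
        D = 0.5 * z1 + np.sqrt(0.75) * z2
        frac_rr, frac_sc = ps.interaction_partition(self._table_from_means(C, D), "trait", "Avi")
        assert frac_rr == pytest.approx(1.0, abs=1e-9)
        assert frac_sc == pytest.approx(0.0, abs=1e-9)

    def test_pure_scale_change_when_correlation_one(self):
        C = np.arange(12, dtype=float)
        D = 0.5 * C + 2.0
        frac_rr, frac_sc = ps.interaction_partition(self._table_from_means(C, D), "trait", "Avi")
        assert frac_sc == pytest.approx(1.0, abs=1e-9)
        assert frac_rr == pytest.approx(0.0, abs=1e-9)

    def test_fractions_sum_to_one_when_interaction_positive(self, phenotypes):
        table, _ = phenotypes
        frac_rr, frac_sc = ps.interaction_partition(table, "trait1", "Avi")
        assert frac_rr + frac_sc == pytest.approx(1.0, abs=1e-12)

    def test_too_few_accessions_errors(self):
        with pytest.raises(ValueError, match="3 accessions"):
            ps.interaction_partition(self._table_from_means([1, 2], [2, 1]), "trait", "Avi")


class TestDerivedTraitsAndCorrelations:
    def test_yield_is_product_of_means(self):
        rows = []
        for trait, vals in (("FW", [10, 10]), ("Nbfruits", [20, 20])):
            for r, v in enumerate(vals, 1):
                rows.append(("a0", "g0", "Avi", "C", r, trait, v))
        table = pd.DataFrame(rows, columns=["accession", "group", "location", "regime",
                                            "replicate", "trait", "value"])
        out = ps.derive_yield(table)
        y = out[out["trait"] == "Yield"]
        assert len(y) == 1
        assert y["value"].iloc[0] == pytest.approx(200.0)

    def test_zero_fruit_number_gives_zero_yield(self):
        rows = [("a0", "g0", "Avi", "C", 1, "FW", 10.0),
                ("a0", "g0", "Avi", "C", 1, "Nbfruits", 0.0)]
        table = pd.DataFrame(rows, columns=["accession", "group", "location", "regime",
                                            "replicate", "trait", "value"])
        out = ps.derive_yield(table)
        assert out[out["trait"] == "Yield"]["value"].iloc[0] == 0.0

    def test_missing_component_skipped_with_warning(self):
        rows = [("a0", "g0", "Avi", "C", 1, "FW", 10.0),
                ("a1", "g0", "Avi", "C", 1, "FW", 12.0),
                ("a1", "g0", "Avi", "C", 1, "Nbfruits", 3.0)]
        table = pd.DataFrame(rows, columns=["accession", "group", "location", "regime",
                                            "replicate", "trait", "value"])
        with pytest.warns(UserWarning):
            out = ps.derive_yield(table)
        y = out[out["trait"] == "Yield"]
        assert list(y["accession"]) == ["a1"]

    def test_rank_correlations_limits_and_toy(self):
        df = pd.DataFrame({"H2_C": [0.3, 0.5, 0.7, 0.9],
                           "H2_D": [0.3, 0.5, 0.7, 0.9],
                           "varG_C": [1, 2, 3, 4],
                           "varG_D": [4, 3, 2, 1]})
        r_h2, r_vg = ps.cross_regime_correlations(df)
        assert r_h2 == pytest.approx(1.0)
        assert r_vg == pytest.approx(-1.0)
        df5 = pd.DataFrame({"H2_C": [0.3, 0.9, 0.5, 0.6, 0.2],
                            "H2_D": [0.35, 0.7, 0.55, 0.65, 0.3],
                            "varG_C": [2, 9, 4, 6, 1],
                            "varG_D": [1, 8, 5, 6, 2]})
        r_h2, r_vg = ps.cross_regime_correlations(df5)
        assert r_h2 == pytest.approx(sps.spearmanr(df5["H2_C"], df5["H2_D"]).statistic)
        with pytest.raises(ValueError):
            ps.cross_regime_correlations(df5.iloc[:2])


class TestTukey:
    def test_equal_cell_means_not_significant(self):
        rng = np.random.default_rng(5)
        cells = {(g, f"{g}a{a}", w): 5 + rng.normal(0, 0.1, 3)
                 for g in ("g0", "g1") for a in range(4) for w in ("C", "D")}
        out = ps.tukey_posthoc(make_table(cells), "trait", "Avi")
        assert (out.loc[~out["untestable"], "p_adj"].astype(float) > 0.5).all()

    def test_shifted_cell_detected(self):
        rng = np.random.default_rng(6)
        cells = {}
        for g in ("g0", "g1"):
            for a in range(4):
                for w in ("C", "D"):
                    shift = 10.0 if (g, w) == ("g1", "D") else 0.0
                    cells[(g, f"{g}a{a}", w)] = shift + rng.normal(0, 1, 3)
        out = ps.tukey_posthoc(make_table(cells), "trait", "Avi")
        hot = out[(out["group1"] == "g1:D") | (out["group2"] == "g1:D")]
        assert hot["reject"].astype(bool).all()

    def test_two_groups_give_all_six_cell_pairs(self):
        rng = np.random.default_rng(7)
        cells = {(g, f"{g}a{a}", w): rng.normal(0, 1, 2)
                 for g in ("g0", "g1") for a in range(3) for w in ("C", "D")}
        out = ps.tukey_posthoc(make_table(cells), "trait", "Avi")
        assert len(out[~out["untestable"]]) == 6  # 4 cells -> C(4,2)
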