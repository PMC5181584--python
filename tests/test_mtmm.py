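"""Bivariate multi-trait mixed model: tests and LD merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gxemap import mlmm, mtmm
from gxemap.mixedmodel import KinshipSpectrum

from conftest import toy_panel


class TestDegenerateDuplicate:
    def test_identical_traits_factorize_to_univariate(self, panel, accession_means,
                                                      structure, spectrum):
        y_C, _ = accession_means
        res = mtmm.mtmm_tests(panel, y_C, y_C.copy(), structure.coords, spectrum)
        uni = mlmm.scan_markers(panel, y_C, structure.coords, spectrum)
        ok = res["p_global"].notna() & uni["pvalue"].notna()
        lg_m = -np.log10(res["p_global"][ok])
        lg_u = -np.log10(uni["pvalue"][ok])
        np.testing.assert_allclose(lg_m, lg_u, rtol=1e-3)
        assert np.all(res["p_gxw"][ok] == 1.0)

    def test_identical_traits_give_unit_genetic_correlation(self, accession_means,
                                                            structure, spectrum):
        y_C, _ = accession_means
        vc = mtmm.fit_mtmm_null(y_C, y_C.copy(), structure.coords, spectrum)
        assert vc.rho_g >= 0.99
        assert vc.sigma_g2_C == pytest.approx(vc.sigma_g2_D)


class TestVarianceComponents:
    def test_rho_recovery(self, kinship, spectrum):
        L = np.linalg.cholesky(kinship)
        n = kinship.shape[0]
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(7000 + seed)
            u1, u2 = rng.standard_normal(n), rng.standard_normal(n)
            gC = L @ u1
            gD = L @ (0.5 * u1 + np.sqrt(0.75) * u2)
            y_C = gC + rng.standard_normal(n)
            y_D = gD + rng.standard_normal(n)
            vc = mtmm.fit_mtmm_null(y_C, y_D, None, spectrum)
            errs.append(vc.rho_g - 0.5)
        assert abs(np.mean(errs)) < 0.2

    def test_independent_noise_gives_small_genetic_signal(self, spectrum):
        n = spectrum.S.size
        rng = np.random.default_rng(1)
        vc = mtmm.fit_mtmm_null(rng.standard_normal(n), rng.standard_normal(n),
                                None, spectrum)
        tot_C = vc.sigma_g2_C + vc.sigma_e2_C
        assert abs(vc.rho_g * vc.sigma_g2_C) < 0.5 * tot_C

    def test_misaligned_traits_rejected(self, spectrum):
        with pytest.raises(ValueError, match="aligned"):
            mtmm.fit_mtmm_null(np.zeros(10), np.zeros(11), None, spectrum)


class TestMarkerTests:
    def dense_oracle(self, panel, y_C, y_D, X, vc, K, j):
        """Brute-force stacked GLS with the full 2n x 2n covariance."""
        n = len(y_C)
        Vg = vc.genetic_covariance()
        Ve = vc.residual_covariance()
        # ordering: accession-major pairs (C_i, D_i) to match nothing — build
        # regime-major [y_C; y_D] explicitly instead
        V = np.block([
            [Vg[0, 0] * K + Ve[0, 0] * np.eye(n), Vg[0, 1] * K],
            [Vg[1, 0] * K, Vg[1, 1] * K + Ve[1, 1] * np.eye(n)],
        ])
        Li = np.linalg.inv(np.linalg.cholesky(V))
        y = Li @ np.concatenate([y_C, y_D])
        X0 = Li @ np.block([[X, np.zeros_like(X)], [np.zeros_like(X), X]])
        x = panel.dosages[:, j]
        xc = Li @ np.concatenate([x, x])
        xf = Li @ np.block([[x[:, None], np.zeros((n, 1))],
                            [np.zeros((n, 1)), x[:, None]]])

        def rss(A):
            b, *_ = np.linalg.lstsq(A, y, rcond=None)
            r = y - A @ b
            return float(r @ r)

        r0 = rss(X0)
        r1 = rss(np.hstack([X0, xc[:, None]]))
        r2 = rss(np.hstack([X0, xf]))
        N, p0 = X0.shape
        f_g = (r0 - r1) / (r1 / (N - p0 - 1))
        f_i = (r1 - r2) / (r2 / (N - p0 - 2))
        return (sps.f.sf(f_g, 1, N - p0 - 1), sps.f.sf(f_i, 1, N - p0 - 2))

    def test_blocked_gls_matches_dense_oracle(self, panel, accession_means,
                                              structure, kinship, spectrum):
        y_C, y_D = accession_means
        vc = mtmm.fit_mtmm_null(y_C, y_D, structure.coords, spectrum)
        res = mtmm.mtmm_tests(panel, y_C, y_D, structure.coords, spectrum, vc)
        X = np.hstack([np.ones((len(y_C), 1)), structure.coords])
        rng = np.random.default_rng(0)
        K_eff = spectrum.U @ np.diag(spectrum.S) @ spectrum.U.T
        for j in rng.choice(panel.n_markers, size=12, replace=False):
            if np.isnan(res.loc[j, "p_global"]):
                continue
            pg, pi = self.dense_oracle(panel, y_C, y_D, X, vc, K_eff, j)
            assert res.loc[j, "p_global"] == pytest.approx(pg, rel=1e-6)
            assert res.loc[j, "p_gxw"] == pytest.approx(pi, rel=1e-6)

    def test_invariant_under_regime_label_swap(self, panel, accession_means,
                                               structure, spectrum):
        y_C, y_D = accession_means
        vc = mtmm.fit_mtmm_null(y_C, y_D, structure.coords, spectrum)
        vc_sw = mtmm.MTMMVarianceComponents(
            sigma_g2_C=vc.sigma_g2_D, sigma_g2_D=vc.sigma_g2_C, rho_g=vc.rho_g,
            sigma_e2_C=vc.sigma_e2_D, sigma_e2_D=vc.sigma_e2_C,
        )
        a = mtmm.mtmm_tests(panel, y_C, y_D, structure.coords, spectrum, vc)
        b = mtmm.mtmm_tests(panel, y_D, y_C, structure.coords, spectrum, vc_sw)
        ok = a["p_global"].notna()
        np.testing.assert_allclose(a["p_global"][ok], b["p_global"][ok], rtol=1e-8)
        np.testing.assert_allclose(a["p_gxw"][ok], b["p_gxw"][ok], rtol=1e-8)
        np.testing.assert_allclose(a["beta_C"][ok], b["beta_D"][ok], rtol=1e-8)

    def test_monomorphic_marker_flagged(self, accession_means, structure, spectrum):
        y_C, y_D = accession_means
        n = len(y_C)
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(n, 3)).astype(float)
        d[:, 1] = 2.0
        p = toy_panel(d)
        res = mtmm.mtmm_tests(p, y_C, y_D, structure.coords, spectrum)
        assert np.isnan(res.loc[1, "p_global"]) and np.isnan(res.loc[1, "p_gxw"])

    def test_constitutive_effect_keeps_gxw_null(self, panel, spectrum, structure, kinship):
        rng = np.random.default_rng(3)
        n = panel.n_accessions
        L = np.linalg.cholesky(kinship)
        j = int(np.argmax(panel.dosages.var(axis=0)))
        x = panel.dosages[:, j]
        global_hits, gxw_calm = 0, 0
        for seed in range(5):
            rng = np.random.default_rng(400 + seed)
            u = L @ rng.standard_normal(n)
            beta = np.sqrt(0.25 * (np.var(u) + 1) / np.var(x) / 0.75)
            y_C = beta * x + u + rng.standard_normal(n)
            y_D = beta * x + 0.9 * u + L @ rng.standard_normal(n) * np.sqrt(0.19) \
                + rng.standard_normal(n)
            res = mtmm.mtmm_tests(panel, y_C, y_D, structure.coords, spectrum)
            global_hits += res.loc[j, "p_global"] < 1e-4
            gxw_calm += res.loc[j, "p_gxw"] > 0.01
        assert global_hits >= 4
        assert gxw_calm >= 4


class TestLDMerging:
    def make_sig(self, panel, markers, pvals):
        mm = panel.marker_map
        sig = mm[mm["marker_id"].isin(markers)].copy()
        sig["pvalue"] = [pvals[m] for m in sig["marker_id"]]
        return sig

    def test_high_ld_pair_merges_low_ld_pair_does_not(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 3, 60).astype(float)
        y = x.copy()
        y[:4] = 2 - y[:4]  # r2 still high
        z = rng.integers(0, 3, 60).astype(float)  # unlinked
        p = toy_panel(np.column_stack([x, y, z]), chrom=np.array([1, 1, 1]),
                      pos=np.array([100, 200, 300]))
        sig = self.make_sig(p, list(p.marker_ids), dict(zip(p.marker_ids, [1e-6, 1e-5, 1e-7])))
        groups = mtmm.merge_ld_significant(sig, p, threshold=0.28)
        sizes = sorted(len(g["members"]) for g in groups)
        assert sizes == [1, 2]
        two = next(g for g in groups if len(g["members"]) == 2)
        assert two["representative"] == p.marker_ids[0]  # min p of the pair

    def test_single_linkage_chain_is_one_qtl(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 3, 80).astype(float)
        b = a.copy()
        b[:20] = rng.integers(0, 3, 20)  # a-b moderate LD
        c = b.copy()
        c[40:60] = rng.integers(0, 3, 20)  # b-c moderate, a-c lower
        p = toy_panel(np.column_stack([a, b, c]), chrom=np.array([1, 1, 1]),
                      pos=np.array([100, 200, 300]))
        from gxemap.qc import ld_r2

        r_ab = ld_r2(a, b)
        r_bc = ld_r2(b, c)
        r_ac = ld_r2(a, c)
        thr = (min(r_ab, r_bc) + r_ac) / 2  # between the chain links and a-c
        assert r_ac < thr < min(r_ab, r_bc)
        sig = self.make_sig(p, list(p.marker_ids), dict(zip(p.marker_ids, [1e-5] * 3)))
        groups = mtmm.merge_ld_significant(sig, p, threshold=thr)
        assert len(groups) == 1
        assert len(groups[0]["members"]) == 3

    def test_different_chromosomes_never_merge(self):
        x = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        p = toy_panel(np.column_stack([x, x]), chrom=np.array([1, 2]),
                      pos=np.array([100, 100]))
        sig = self.make_sig(p, list(p.marker_ids), dict(zip(p.marker_ids, [1e-5, 1e-6])))
        groups = mtmm.merge_ld_significant(sig, p, threshold=0.28)
        assert len(groups) == 2
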