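"""PEVMean recovery from the fixed-effect block, and the pairwise statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import gconnect as g
from gconnect import connectedness as cn

from conftest import fit_scenario


def _disconnected_singletons():
    """Two unrelated animals, one per CG: the fully disconnected closed form."""
    vc = g.VarianceComponents(1.81, 7.43)
    ped = g.order_pedigree([("1", "0", "0"), ("2", "0", "0")])
    rec = pd.DataFrame({"animal": ["1", "2"], "cg": ["a", "b"], "y": [3.0, 4.0]})
    dm = g.build_design(rec, g.ModelSpec(cg="cg"), ped)
    fit = g.fit_mme(dm, sp.eye(2, format="csr"), vc, rec["y"].to_numpy(),
                    extract_pev_block=True)
    return vc, ped, dm, fit


class TestPEVMeanSources:
    def test_direct_is_explicit_block_averaging(self, small_multi_effect):
        sc, ped, rec, dm, fit = small_multi_effect
        pm = g.pevmean_direct(fit.pev, dm)
        # brute-force oracle: average PEV sub-blocks by CG membership
        idx_by_cg = {c: [] for c in dm.cg_labels}
        animal_idx = ped.indices_of(rec["animal"].tolist())
        for r, c in enumerate(rec["cg"]):
            idx_by_cg[c].append(animal_idx[r])
        expected = np.empty_like(pm.values)
        for i, ci in enumerate(dm.cg_labels):
            for j, cj in enumerate(dm.cg_labels):
                expected[i, j] = fit.pev[np.ix_(idx_by_cg[ci], idx_by_cg[cj])].mean()
        np.testing.assert_allclose(pm.values, expected, atol=1e-10)

    def test_single_cg_mean_of_all_pev_entries(self):
        vc = g.VarianceComponents(1.81, 7.43)
        ped = g.order_pedigree([("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2")])
        rec = pd.DataFrame({"animal": ["1", "2", "3"], "cg": ["a"] * 3,
                            "y": [1.0, 2.0, 3.0]})
        dm = g.build_design(rec, g.ModelSpec(cg="cg"), ped)
        fit = g.fit_mme(dm, g.build_A_inverse(ped), vc, rec["y"].to_numpy(),
                        extract_pev_block=True)
        pm = g.pevmean_direct(fit.pev, dm)
        assert pm.values[0, 0] == pytest.approx(fit.pev.mean())

    def test_function2_exact_in_cg_only_model(self, small_cg_only):
        sc, ped, rec, dm, fit = small_cg_only
        pm2 = g.function2(fit.var_beta, dm, sc.vc.sigma_e2)
        pmd = g.pevmean_direct(fit.pev, dm)
        assert np.abs(pm2.values - pmd.values).max() < 1e-8

    def test_function1_offdiagonals_exact_in_cg_only_model(self, small_cg_only):
        sc, ped, rec, dm, fit = small_cg_only
        pm1 = g.function1(fit.var_beta, dm)
        pmd = g.pevmean_direct(fit.pev, dm)
        off = ~np.eye(dm.p1, dtype=bool)
        assert np.abs(pm1.values[off] - pmd.values[off]).max() < 1e-10
        # diagonals exceed the direct ones by exactly sigma_e^2 / n_i
        np.testing.assert_allclose(np.diag(pm1.values) - np.diag(pmd.values),
                                   sc.vc.sigma_e2 / dm.n_per_cg, atol=1e-8)

    def test_function2_complete_shrinkage_closed_form(self):
        # 1 CG, 1 record, unrelated animal: Var(beta) = 9.24, function2 = 1.81
        vc = g.VarianceComponents(1.81, 7.43)
        ped = g.order_pedigree([("1", "0", "0")])
        rec = pd.DataFrame({"animal": ["1"], "cg": ["a"], "y": [5.0]})
        dm = g.build_design(rec, g.ModelSpec(cg="cg"), ped)
        fit = g.fit_mme(dm, sp.eye(1, format="csr"), vc, rec["y"].to_numpy())
        assert fit.var_beta.full[0, 0] == pytest.approx(9.24)
        pm2 = g.function2(fit.var_beta, dm, vc.sigma_e2)
        assert pm2.values[0, 0] == pytest.approx(1.81)

    def test_function3_exact_with_other_fixed_effects(self, small_multi_effect):
        sc, ped, rec, dm, fit = small_multi_effect
        pm3 = g.function3(fit.var_beta, dm, sc.vc.sigma_e2)
        pmd = g.pevmean_direct(fit.pev, dm)
        scale = 1e-8 * (1 + np.abs(pmd.values).max())
        assert np.abs(pm3.values - pmd.values).max() < scale
        flat = np.corrcoef(pm3.values.ravel(), pmd.values.ravel())[0, 1]
        assert flat == pytest.approx(1.0, abs=1e-12)

    def test_function3_defers_to_function2_without_x2(self, small_cg_only):
        sc, ped, rec, dm, fit = small_cg_only
        pm3 = g.function3(fit.var_beta, dm, sc.vc.sigma_e2)
        pm2 = g.function2(fit.var_beta, dm, sc.vc.sigma_e2)
        np.testing.assert_array_equal(pm3.values, pm2.values)
        assert pm3.source == "function3"

    def test_correction_factor_is_function3_minus_function2(self, small_multi_effect):
        sc, ped, rec, dm, fit = small_multi_effect
        corr = g.correction_factor(fit.var_beta, dm)
        pm2 = g.function2(fit.var_beta, dm, sc.vc.sigma_e2)
        pm3 = g.function3(fit.var_beta, dm, sc.vc.sigma_e2)
        np.testing.assert_allclose(pm2.values + corr, pm3.values, atol=1e-12)


class TestOrthogonalAndBalanced:
    def _fit_with_covariate(self, values_by_record, seed=0):
        """CG-only herd re-fitted with a supplied covariate column."""
        sc = g.SimScenario(n_cgs=3, offspring_per_cg=12, n_generations=1,
                           link_sire_fraction=0.5, seed=seed)
        ped, rec = g.simulate_pedigree_and_records(sc)
        rec = rec.copy()
        rec["cov1"] = values_by_record(rec)
        spec = g.ModelSpec(cg="cg", covariates=(g.Covariate("cov1"),))
        dm = g.build_design(rec, spec, ped)
        fit = g.fit_mme(dm, g.build_A_inverse(ped), sc.vc, rec["y"].to_numpy(),
                        extract_pev_block=True)
        return sc, dm, fit

    def test_orthogonal_design_zero_correction(self):
        rng = np.random.default_rng(1)

        def per_cg_centred(rec):
            v = rng.normal(0, 1, len(rec))
            for cg in rec["cg"].unique():
                m = (rec["cg"] == cg).to_numpy()
                v[m] -= v[m].mean()
            return v

        sc, dm, fit = self._fit_with_covariate(per_cg_centred)
        ok, _ = g.check_orthogonality(dm.X1, dm.X2)
        assert ok
        corr = g.correction_factor(fit.var_beta, dm)
        assert np.abs(corr).max() < 1e-8
        pm3 = g.function3(fit.var_beta, dm, sc.vc.sigma_e2)
        pm2 = g.function2(fit.var_beta, dm, sc.vc.sigma_e2)
        np.testing.assert_allclose(pm3.values, pm2.values, atol=1e-10)

    def test_balanced_covariate_correction_structure(self):
        rng = np.random.default_rng(2)
        base = rng.normal(20, 4, 12)

        def balanced(rec):
            v = np.empty(len(rec))
            for cg in rec["cg"].unique():
                idx = np.where((rec["cg"] == cg).to_numpy())[0]
                v[idx] = base[: idx.size]
            return v

        sc, dm, fit = self._fit_with_covariate(balanced)
        corr = g.correction_factor(fit.var_beta, dm)
        # c*11' + 1v' + v1' structure: double-centring annihilates it
        n = corr.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        assert np.abs(J @ corr @ J).max() < 1e-8
        # hence PEVD is identical from function2 and function3
        pm2 = g.function2(fit.var_beta, dm, sc.vc.sigma_e2)
        pm3 = g.function3(fit.var_beta, dm, sc.vc.sigma_e2)
        for i in range(n):
            for j in range(i + 1, n):
                assert g.pevd(pm3, i, j) == pytest.approx(g.pevd(pm2, i, j),
                                                          abs=1e-8)
        # and corrected VED equals PEVD from the direct path
        pmd = g.pevmean_direct(fit.pev, dm)
        for i in range(n):
            for j in range(i + 1, n):
                cv = g.corrected_ved(fit.var_beta, dm.n_per_cg, sc.vc.sigma_e2, i, j)
                assert cv == pytest.approx(g.pevd(pmd, i, j), abs=1e-8)

    def test_rescaling_invariance_of_function3(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 4, 200)

        def raw(rec):
            return vals[: len(rec)]

        def scaled(rec):
            return 10.0 * vals[: len(rec)] + 100.0

        sc, dm_a, fit_a = self._fit_with_covariate(raw, seed=4)
        _, dm_b, fit_b = self._fit_with_covariate(scaled, seed=4)
        # Var(beta1) changes ...
        assert np.abs(fit_a.var_beta.v11 - fit_b.var_beta.v11).max() > 1e-4
        # ... but the recovered PEVMean does not
        pm_a = g.function3(fit_a.var_beta, dm_a, sc.vc.sigma_e2)
        pm_b = g.function3(fit_b.var_beta, dm_b, sc.vc.sigma_e2)
        assert np.abs(pm_a.values - pm_b.values).max() < 1e-8


class TestPairwiseStatistics:
    def test_disconnected_closed_forms(self):
        vc, ped, dm, fit = _disconnected_singletons()
        pmd = g.pevmean_direct(fit.pev, dm)
        np.testing.assert_allclose(pmd.values, vc.sigma_g2 * np.eye(2), atol=1e-10)
        assert g.pevd(pmd, 0, 1) == pytest.approx(3.62)  # 2 sigma_g^2
        assert g.flock_correlation(pmd, 0, 1) == pytest.approx(0.0, abs=1e-10)
        assert g.ved(fit.var_beta, 0, 1) == pytest.approx(18.48)  # 2(sg2+se2)
        assert g.corrected_ved(fit.var_beta, dm.n_per_cg, vc.sigma_e2, 0, 1) \
            == pytest.approx(3.62)
        assert g.cr(fit.var_beta, 0, 1) == pytest.approx(0.0, abs=1e-10)
        kbar = g.prior_cg_variance(np.eye(2), dm, vc.sigma_g2)
        assert g.cd_contrast(pmd, kbar, 0, 1) == pytest.approx(0.0, abs=1e-8)

    def test_pevd_contrast_vector_oracle(self, small_multi_effect):
        sc, ped, rec, dm, fit = small_multi_effect
        pmd = g.pevmean_direct(fit.pev, dm)
        Z = dm.Z.toarray()
        T = (dm.X1.T @ Z) / dm.n_per_cg[:, None]
        for i in range(dm.p1):
            for j in range(i + 1, dm.p1):
                x = T[i] - T[j]  # mean-difference contrast over animals
                oracle = float(x @ fit.pev @ x)
                assert g.pevd(pmd, i, j) == pytest.approx(oracle, abs=1e-8)

    def test_pevd_equal_diag_offdiag_gives_zero(self):
        pm = cn.PEVMeanMatrix(np.full((2, 2), 1.3), ("a", "b"), "direct")
        assert g.pevd(pm, 0, 1) == pytest.approx(0.0)
        assert g.flock_correlation(pm, 0, 1) == pytest.approx(1.0)

    def test_same_group_rejected(self):
        pm = cn.PEVMeanMatrix(np.eye(2), ("a", "b"), "direct")
        with pytest.raises(ValueError):
            g.pevd(pm, 1, 1)

    def test_pevd_from_function3_equals_direct_all_pairs(self, small_multi_effect):
        sc, ped, rec, dm, fit = small_multi_effect
        pm3 = g.function3(fit.var_beta, dm, sc.vc.sigma_e2)
        pmd = g.pevmean_direct(fit.pev, dm)
        for i in range(dm.p1):
            for j in range(i + 1, dm.p1):
                assert g.pevd(pm3, i, j) == pytest.approx(g.pevd(pmd, i, j),
                                                          abs=1e-8)

    def test_corrected_ved_equals_pevd_cg_only(self, small_cg_only):
        sc, ped, rec, dm, fit = small_cg_only
        pmd = g.pevmean_direct(fit.pev, dm)
        for i in range(dm.p1):
            for j in range(i + 1, dm.p1):
                cv = g.corrected_ved(fit.var_beta, dm.n_per_cg, sc.vc.sigma_e2, i, j)
                assert cv == pytest.approx(g.pevd(pmd, i, j), abs=1e-8)

    def test_equal_counts_correction_is_two_sigma_over_n(self):
        vc, ped, dm, fit = _disconnected_singletons()
        got = g.ved(fit.var_beta, 0, 1) - g.corrected_ved(
            fit.var_beta, dm.n_per_cg, vc.sigma_e2, 0, 1)
        assert got == pytest.approx(2 * vc.sigma_e2 / 1)

    def test_cr_below_flock_r_in_cg_only_models(self, small_cg_only):
        sc, ped, rec, dm, fit = small_cg_only
        pmd = g.pevmean_direct(fit.pev, dm)
        for i in range(dm.p1):
            for j in range(i + 1, dm.p1):
                assert g.cr(fit.var_beta, i, j) <= \
                    g.flock_correlation(pmd, i, j) + 1e-10

    def test_flock_r_matches_raw_averaging_oracle(self, small_multi_effect):
        sc, ped, rec, dm, fit = small_multi_effect
        pmd = g.pevmean_direct(fit.pev, dm)
        v = pmd.values
        for i in range(dm.p1):
            for j in range(i + 1, dm.p1):
                oracle = v[i, j] / np.sqrt(v[i, i] * v[j, j])
                assert g.flock_correlation(pmd, i, j) == pytest.approx(oracle)

    def test_cd_direct_formula_oracle(self, small_multi_effect):
        sc, ped, rec, dm, fit = small_multi_effect
        A = g.build_A(ped)
        kbar = g.prior_cg_variance(A, dm, sc.vc.sigma_g2)
        pmd = g.pevmean_direct(fit.pev, dm)
        Z = dm.Z.toarray()
        T = (dm.X1.T @ Z) / dm.n_per_cg[:, None]
        for i in range(dm.p1):
            for j in range(i + 1, dm.p1):
                x = T[i] - T[j]
                num = float(x @ (sc.vc.sigma_g2 * A - fit.pev) @ x)
                den = float(x @ (sc.vc.sigma_g2 * A) @ x)
                assert g.cd_contrast(pmd, kbar, i, j) == pytest.approx(
                    num / den, abs=1e-8)
                assert -1e-8 <= g.cd_contrast(pmd, kbar, i, j) <= 1 + 1e-8

    def test_cd_perfect_information_limit(self):
        kbar = np.array([[2.0, 0.0], [0.0, 2.0]])
        pm0 = cn.PEVMeanMatrix(np.zeros((2, 2)), ("a", "b"), "direct")
        assert g.cd_contrast(pm0, kbar, 0, 1) == pytest.approx(1.0)


class TestMonotoneInformation:
    def test_adding_records_never_inflates_pevmean_diagonal(self):
        """More records in a CG cannot increase its mean prediction error."""
        vc = g.VarianceComponents(1.81, 7.43)
        triples = [(f"f{i}", "0", "0") for i in range(1, 9)]
        ped = g.order_pedigree(triples + [(f"k{i}", "f1", f"f{i}")
                                          for i in range(2, 8)])
        base = pd.DataFrame({
            "animal": ["k2", "k3", "k4"], "cg": ["a", "a", "b"],
            "y": [1.0, 2.0, 3.0]})
        extra = pd.DataFrame({
            "animal": ["k5", "k6"], "cg": ["a", "b"], "y": [2.5, 2.0]})

        def diag_of(rec):
            dm = g.build_design(rec, g.ModelSpec(cg="cg"), ped)
            fit = g.fit_mme(dm, g.build_A_inverse(ped), vc,
                            rec["y"].to_numpy(), extract_pev_block=True)
            return np.diag(g.pevmean_direct(fit.pev, dm).values)

        d_small = diag_of(base)
        d_big = diag_of(pd.concat([base, extra], ignore_index=True))
        assert (d_big <= d_small + 1e-10).all()


class TestReport:
    def test_report_covers_all_pairs_with_expected_columns(self, small_multi_effect):
        sc, ped, rec, dm, fit = small_multi_effect
        pm3 = g.function3(fit.var_beta, dm, sc.vc.sigma_e2)
        pmd = g.pevmean_direct(fit.pev, dm)
        A = g.build_A(ped)
        kbar = g.prior_cg_variance(A, dm, sc.vc.sigma_g2)
        rep = g.build_report(pm3, fit.var_beta, dm, sc.vc.sigma_e2,
                             kbar=kbar, pm_direct=pmd)
        assert len(rep) == dm.p1 * (dm.p1 - 1) // 2
        for col in ("cg_i", "cg_j", "n_i", "n_j", "pevd", "flock_r", "ved",
                    "corrected_ved", "cr", "cd", "flagged", "max_dev_direct"):
            assert col in rep.columns
        assert (rep["max_dev_direct"] < 1e-8).all()
        assert rep["pevd"].min() >= -1e-10
        assert rep["flock_r"].abs().max() <= 1 + 1e-10
        assert rep["cr"].abs().max() <= 1 + 1e-10

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="asymmetry"):
            cn.PEVMeanMatrix(bad, ("a", "b"), "function3")
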