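"""APIM engine: bookkeeping, ML contracts, oracles, and fit indices."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dyadstat.apim import (APIMSpec, build_model, compute_fit_indices,
                           equality_constraint_test, fit_apim, run_apim_suite)
from dyadstat.errors import EstimationError, ValidationError
from dyadstat.synthetic import DyadScenario, OutcomeSpec, generate_dyads

SPEC = APIMSpec(outcome="qol")
SPEC_NOCOV = APIMSpec(outcome="qol", covariate_scope="none")


def _table(n, a1=-0.15, p1=-0.02, a2=-0.17, p2=-0.05, seed=5, rho_e=0.15):
    scn = DyadScenario(
        n_dyads=n,
        outcomes={"qol": OutcomeSpec(a1, p1, a2, p2, (11.8, 14.5),
                                     (3.0, 2.2), rho_e=rho_e)},
    )
    return generate_dyads(scn, seed=seed)


def sur_ifgls(y, x_sets, tol=1e-12, max_iter=500):
    """Iterated feasible GLS for a two-equation SUR system.

    Independent closed-form oracle for the ML path estimator: stack the two
    equations, weight by the inverse residual covariance, iterate to the
    fixed point.  ``y`` is (n, 2); ``x_sets`` gives each equation's design
    matrix (with intercept column prepended here).
    """
    n = y.shape[0]
    X = [np.column_stack([np.ones(n), xs]) for xs in x_sets]
    beta = [np.linalg.lstsq(X[i], y[:, i], rcond=None)[0] for i in range(2)]
    for _ in range(max_iter):
        resid = np.column_stack([y[:, i] - X[i] @ beta[i] for i in range(2)])
        omega = resid.T @ resid / n
        w = np.linalg.inv(omega)
        k = [X[i].shape[1] for i in range(2)]
        A = np.zeros((sum(k), sum(k)))
        b = np.zeros(sum(k))
        off = [0, k[0]]
        for i in range(2):
            for j in range(2):
                A[off[i]:off[i] + k[i], off[j]:off[j] + k[j]] = (
                    w[i, j] * X[i].T @ X[j]
                )
            b[off[i]:off[i] + k[i]] = sum(
                w[i, j] * X[i].T @ y[:, j] for j in range(2)
            )
        new = np.linalg.solve(A, b)
        change = np.max(np.abs(new - np.concatenate(beta)))
        beta = [new[:k[0]], new[k[0]:]]
        if change < tol:
            break
    return beta


class TestBookkeeping:
    def test_saturated_df_zero(self, big_table):
        model = build_model(SPEC_NOCOV, big_table)
        # 4 paths + 2 residual variances + 1 residual covariance + 3
        # exogenous moments = 10 free parameters = all moments of 4 variables
        assert model.n_free == 10
        assert model.df == 0

    def test_own_covariates_df_eight(self, big_table):
        model = build_model(SPEC, big_table)
        # 8 cross-member covariate paths fixed at zero
        assert model.df == 8

    def test_one_constraint_adds_one_df(self, big_table):
        model = build_model(
            replace(SPEC_NOCOV, constraints=frozenset({"actor_equal"})),
            big_table,
        )
        assert model.df == 1

    def test_both_members_scope_saturated(self, big_table):
        model = build_model(
            replace(SPEC, covariate_scope="both_members"), big_table
        )
        assert model.df == 0

    def test_missing_column_diagnostic(self, big_table):
        with pytest.raises(ValidationError, match="absent"):
            build_model(APIMSpec(outcome="nonexistent"), big_table)

    def test_infeasible_sample_size(self, big_table):
        with pytest.raises(EstimationError, match="infeasible"):
            build_model(SPEC, big_table.head(10))


class TestSaturatedContract:
    def test_chi2_zero_and_ols_equivalence(self):
        """A saturated model reproduces S perfectly and its ML paths equal
        per-equation least squares."""
        tab = _table(500)
        res = fit_apim(tab, SPEC_NOCOV)
        assert res.fit.chi2 <= 1e-8
        assert res.fit.cfi == 1.0
        assert res.fit.srmr <= 1e-8
        assert np.isnan(res.fit.chi2_df_ratio)

        X = tab[["p_stigma", "c_stigma"]].to_numpy()
        Xd = np.column_stack([np.ones(len(tab)), X])
        for eq, (ycol, actor, partner) in enumerate(
            [("p_qol", "a1", "p1"), ("c_qol", "a2", "p2")]
        ):
            beta = np.linalg.lstsq(Xd, tab[ycol].to_numpy(), rcond=None)[0]
            own, other = (1, 2) if eq == 0 else (2, 1)
            assert res.estimate.params[actor] == pytest.approx(
                beta[own], abs=1e-6
            )
            assert res.estimate.params[partner] == pytest.approx(
                beta[other], abs=1e-6
            )

    def test_residual_covariance_bounds(self):
        res = fit_apim(_table(300), SPEC)
        est = res.estimate
        assert est.psi11 > 0 and est.psi22 > 0
        assert abs(est.psi12) <= np.sqrt(est.psi11 * est.psi22) + 1e-12


class TestSurOracle:
    def test_overidentified_matches_iterated_fgls(self):
        """Own-covariates-only APIM == ML SUR; the iterated FGLS fixed
        point is an independent route to the same estimator."""
        tab = _table(200, seed=11)
        res = fit_apim(tab, SPEC)

        y = tab[["p_qol", "c_qol"]].to_numpy()
        covs = ["age", "female", "married", "edu"]
        x1 = tab[["p_stigma", "c_stigma"] + ["p_" + c for c in covs]].to_numpy()
        x2 = tab[["c_stigma", "p_stigma"] + ["c_" + c for c in covs]].to_numpy()
        beta1, beta2 = sur_ifgls(y, [x1, x2])

        assert res.estimate.params["a1"] == pytest.approx(beta1[1], abs=1e-4)
        assert res.estimate.params["p1"] == pytest.approx(beta1[2], abs=1e-4)
        assert res.estimate.params["a2"] == pytest.approx(beta2[1], abs=1e-4)
        assert res.estimate.params["p2"] == pytest.approx(beta2[2], abs=1e-4)
        for j, c in enumerate(covs):
            assert res.estimate.params[f"p_qol~p_{c}"] == pytest.approx(
                beta1[3 + j], abs=1e-4
            )
            assert res.estimate.params[f"c_qol~c_{c}"] == pytest.approx(
                beta2[3 + j], abs=1e-4
            )


class TestInvariances:
    def test_role_swap_symmetry(self):
        """Relabeling member1 <-> member2 swaps (a1,p1) with (a2,p2) and
        psi11 with psi22 exactly."""
        tab = _table(250, seed=13)
        swapped = tab.rename(
            columns=lambda c: ("c_" + c[2:] if c.startswith("p_")
                               else "p_" + c[2:] if c.startswith("c_") else c)
        )
        a = fit_apim(tab, SPEC).estimate
        b = fit_apim(swapped, SPEC).estimate
        assert a.params["a1"] == pytest.approx(b.params["a2"], abs=1e-7)
        assert a.params["p1"] == pytest.approx(b.params["p2"], abs=1e-7)
        assert a.psi11 == pytest.approx(b.psi22, abs=1e-7)
        assert a.psi12 == pytest.approx(b.psi12, abs=1e-7)

    def test_monotone_nesting(self, study_table):
        base = fit_apim(study_table, APIMSpec(outcome="phys"),
                        compute_se=False)
        for constraint in ("actor_equal", "partner_equal"):
            con = fit_apim(
                study_table,
                APIMSpec(outcome="phys", constraints=frozenset({constraint})),
                compute_se=False,
            )
            assert con.fit.chi2 >= base.fit.chi2 - 1e-8

    @given(k=st.floats(0.5, 3.0))
    def test_scale_equivariance(self, k):
        """Multiplying the outcome by k multiplies paths and SEs by k and
        leaves chi-square, CFI and SRMR unchanged."""
        tab = _table(200, seed=17)
        scaled = tab.assign(p_qol=k * tab["p_qol"], c_qol=k * tab["c_qol"])
        a = fit_apim(tab, SPEC)
        b = fit_apim(scaled, SPEC)
        assert b.estimate.params["a1"] == pytest.approx(
            k * a.estimate.params["a1"], rel=1e-6)
        assert b.estimate.se["a1"] == pytest.approx(
            k * a.estimate.se["a1"], rel=1e-4)
        assert b.fit.chi2 == pytest.approx(a.fit.chi2, abs=1e-6)
        assert b.fit.cfi == pytest.approx(a.fit.cfi, abs=1e-8)
        assert b.fit.srmr == pytest.approx(a.fit.srmr, abs=1e-8)

    def test_bias_shrinks_with_n(self):
        truth = {"a1": -0.15, "p1": -0.02, "a2": -0.17, "p2": -0.05}
        err = {}
        for n in (200, 2000, 10_000):
            errs = []
            for seed in range(5):
                res = fit_apim(_table(n, seed=100 + seed), SPEC,
                               compute_se=False)
                errs.append(max(abs(res.estimate.params[k] - v)
                                for k, v in truth.items()))
            err[n] = np.mean(errs)
        assert err[10_000] < err[200]


class TestFitIndices:
    def test_perfect_fit(self):
        S = np.array([[4.0, 1.0], [1.0, 2.0]])
        fi = compute_fit_indices(0.0, 0, S, S.copy(), 35.0, 1, 100)
        assert fi.srmr == 0.0 and fi.cfi == 1.0

    def test_t_equal_df_gives_cfi_one(self):
        S = np.eye(3)
        fi = compute_fit_indices(5.0, 5, S, S.copy(), 50.0, 3, 100)
        assert fi.cfi == 1.0

    def test_hand_computed_srmr(self):
        # one fixed-zero covariance: s_13 = 1.2 vs sigma_13 = 0 with
        # s_11 = 4, s_33 = 2.25 -> standardized residual 1.2/3 = 0.4;
        # 6 unique moments -> srmr = 0.4/sqrt(6)
        S = np.array([[4.0, 0.5, 1.2], [0.5, 9.0, 0.3], [1.2, 0.3, 2.25]])
        Sigma = S.copy()
        Sigma[0, 2] = Sigma[2, 0] = 0.0
        fi = compute_fit_indices(3.0, 1, S, Sigma, 40.0, 3, 100)
        assert fi.srmr == pytest.approx(0.4 / np.sqrt(6), abs=1e-12)

    def test_baseline_worse_than_model(self):
        res = fit_apim(_table(300, seed=23), SPEC)
        assert res.fit.baseline_chi2 > res.fit.chi2
        assert res.fit.baseline_df > res.fit.df


class TestEqualityConstraints:
    def test_identical_fits_give_zero(self, study_table):
        spec = APIMSpec(outcome="phys")
        res = fit_apim(study_table, spec, compute_se=False)
        test = equality_constraint_test(res, res, constraint_name="self")
        assert test.chi2_diff == 0.0 and test.p_value == 1.0

    def test_one_constraint_one_df(self, study_table):
        spec = APIMSpec(outcome="phys")
        base = fit_apim(study_table, spec, compute_se=False)
        con = fit_apim(
            study_table,
            replace(spec, constraints=frozenset({"actor_equal"})),
            compute_se=False,
        )
        test = equality_constraint_test(base, con)
        assert test.df_diff == 1
        assert test.chi2_diff >= 0.0
        assert 0.0 <= test.p_value <= 1.0

    def test_non_nested_rejected(self, study_table):
        phys = fit_apim(study_table, APIMSpec(outcome="phys"),
                        compute_se=False)
        env_con = fit_apim(
            study_table,
            APIMSpec(outcome="env", constraints=frozenset({"actor_equal"})),
            compute_se=False,
        )
        with pytest.raises(ValidationError):
            equality_constraint_test(phys, env_con)


class TestSuite:
    def test_report_shape_and_determinism(self, study_table):
        report = run_apim_suite(study_table)
        assert set(report["outcomes"]) == {"phys", "psych", "soc", "env"}
        total_tests = sum(
            len(block["constraint_tests"])
            for block in report["outcomes"].values()
        )
        assert total_tests == 8
        for block in report["outcomes"].values():
            assert set(block["paths"]) == {"a1", "p1", "a2", "p2"}
            for entry in block["paths"].values():
                lo, hi = entry["ci"]
                assert lo <= entry["estimate"] <= hi
            assert block["constraint_tests"]["actor_equal"]["df_diff"] == 1
        # byte-identical on rerun
        import json

        again = run_apim_suite(study_table)
        assert json.dumps(report, sort_keys=True) == json.dumps(
            again, sort_keys=True
        )
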