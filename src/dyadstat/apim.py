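"""Actor-Partner Interdependence Model (APIM) for distinguishable dyads.

The APIM is a two-equation path model estimated at the dyad level.  With
member 1 (PLWHA) and member 2 (caregiver), outcome scores (Y1, Y2) and
predictor scores (X1, X2):

    Y1 = A1*X1 + P1*X2 + (covariates) + E1
    Y2 = A2*X2 + P2*X1 + (covariates) + E2

A1, A2 are actor effects (own predictor on own outcome), P1, P2 partner
effects (partner's predictor on own outcome).  The predictors are allowed
to covary, and the residuals E1, E2 carry the residual non-independence of
the dyad through their covariance psi12.

Estimation is maximum-likelihood covariance-structure fitting: with the
variables ordered (Y1, Y2, X1, X2, covariates), the implied covariance is

    Sigma_yy = Gamma Phi Gamma' + Psi,   Sigma_yx = Gamma Phi,
    Sigma_xx = Phi,

where Gamma holds the path coefficients (with structural zeros for omitted
paths), Phi is the freely-estimated exogenous covariance matrix and Psi the
2x2 residual covariance.  The discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^{-1}) - ln|S| - p

is minimised over the free parameters; T = (N-1) * F_ML is the model
chi-square (the scaling constant N is available as an option).  Because
Phi enters the likelihood only through the marginal distribution of the
exogenous block, its ML estimate is the sample S_xx exactly, and the free
paths can be found by minimising ln|Psi(Gamma)| where Psi(Gamma) is the
moment matrix of the residuals — the estimator therefore coincides with
ML seemingly-unrelated-regression.  Standard errors come from the inverse
Hessian of F_ML scaled by 2/(N-1); the Hessian is exactly block-diagonal
between (Gamma, Psi) and Phi, so only the (Gamma, Psi) block is needed.

Nested models (actor effects constrained equal, partner effects constrained
equal) are compared by the likelihood-ratio chi-square difference test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EstimationError, ValidationError

__all__ = [
    "APIMSpec",
    "ModelStructure",
    "APIMEstimate",
    "FitIndices",
    "ConstraintTestResult",
    "APIMResult",
    "build_model",
    "fit_ml",
    "fit_apim",
    "compute_fit_indices",
    "equality_constraint_test",
    "run_apim_suite",
]

PATH_NAMES = ("a1", "p1", "a2", "p2")
DEFAULT_COVARIATES = ("age", "female", "married", "edu")
_GRAD_TOL = 1e-8
_NEG_CHI2_TOL = 1e-6


@dataclass(frozen=True)
class APIMSpec:
    """Configuration of one APIM: which outcome, which covariates, and
    which equality constraints are imposed.

    covariate_scope:
      * ``own_member_only`` (default) — each member's outcome is regressed
        on that member's own covariates; cross-member covariate paths are
        fixed to zero (these structural zeros are what give the model its
        testable degrees of freedom).
      * ``both_members`` — every covariate enters both equations
        (saturated regression block, df = 0 without constraints).
      * ``none`` — no covariates.

    constraints: subset of {"actor_equal", "partner_equal"}.
    """

    outcome: str
    predictor: str = "stigma"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    covariate_scope: str = "own_member_only"
    constraints: frozenset[str] = frozenset()
    chi2_scale: str = "nm1"  # "nm1" -> T=(N-1)F, "n" -> T=N*F
    role_prefixes: tuple[str, str] = ("p_", "c_")

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "constraints", frozenset(self.constraints))
        if self.covariate_scope not in ("own_member_only", "both_members", "none"):
            raise ValidationError(
                f"unknown covariate_scope {self.covariate_scope!r}"
            )
        bad = self.constraints - {"actor_equal", "partner_equal"}
        if bad:
            raise ValidationError(f"unknown constraints {sorted(bad)}")
        if self.chi2_scale not in ("nm1", "n"):
            raise ValidationError(f"chi2_scale must be 'nm1' or 'n'")


@dataclass
class ModelStructure:
    """Free-parameter bookkeeping for one APIM.

    ``gamma_params`` lists (name, cells) for each free path coefficient;
    every cell is an (equation, exog-index) position in the 2 x q path
    matrix.  A parameter with two cells is an equality-constrained pair.
    """

    spec: APIMSpec
    endog: tuple[str, str]
    exog: tuple[str, ...]
    gamma_params: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]

    @property
    def n_vars(self) -> int:
        return 2 + len(self.exog)

    @property
    def n_moments(self) -> int:
        p = self.n_vars
        return p * (p + 1) // 2

    @property
    def n_free(self) -> int:
        q = len(self.exog)
        return len(self.gamma_params) + 3 + q * (q + 1) // 2

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    @property
    def var_names(self) -> tuple[str, ...]:
        return self.endog + self.exog

    def gamma_from_vec(self, vec: np.ndarray) -> np.ndarray:
        G = np.zeros((2, len(self.exog)))
        for val, (_, cells) in zip(vec, self.gamma_params):
            for r, c in cells:
                G[r, c] = val
        return G


@dataclass
class FitIndices:
    chi2: float
    df: int
    chi2_df_ratio: float  # NaN when df = 0
    cfi: float
    srmr: float
    baseline_chi2: float
    baseline_df: int
    n_dyads: int


@dataclass
class APIMEstimate:
    """Point estimates, standard errors and symmetric 95% CIs.

    ``params`` maps each free path name (a1, p1, a2, p2 — or the shared
    ``actor``/``partner`` under an equality constraint — plus covariate
    paths named ``y~x``) to its estimate; ``psi11``/``psi22``/``psi12`` are
    the residual (co)variances and ``phi`` the exogenous covariance matrix.
    """

    params: dict[str, float]
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    psi11: float
    psi22: float
    psi12: float
    phi: pd.DataFrame
    n_dyads: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": k,
                "estimate": v,
                "se": self.se.get(k, np.nan),
                "ci_low": self.ci.get(k, (np.nan, np.nan))[0],
                "ci_high": self.ci.get(k, (np.nan, np.nan))[1],
            }
            for k, v in self.params.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class ConstraintTestResult:
    chi2_diff: float
    df_diff: int
    p_value: float
    constraint_name: str


@dataclass
class APIMResult:
    """Bundle returned by :func:`fit_apim`."""

    spec: APIMSpec
    model: ModelStructure
    estimate: APIMEstimate
    fit: FitIndices


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_model(spec: APIMSpec, data: pd.DataFrame) -> ModelStructure:
    """Resolve the variable ordering and free-parameter map for one APIM."""
    pre1, pre2 = spec.role_prefixes
    y1, y2 = pre1 + spec.outcome, pre2 + spec.outcome
    x1, x2 = pre1 + spec.predictor, pre2 + spec.predictor
    if spec.covariate_scope == "none":
        covs1: tuple[str, ...] = ()
        covs2: tuple[str, ...] = ()
    else:
        covs1 = tuple(pre1 + c for c in spec.covariates)
        covs2 = tuple(pre2 + c for c in spec.covariates)
    exog = (x1, x2) + covs1 + covs2
    needed = (y1, y2) + exog
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValidationError(f"columns absent from dyad table: {missing}")

    # exog indices: x1=0, x2=1, member-1 covariates, member-2 covariates
    params: list[tuple[str, tuple[tuple[int, int], ...]]] = []
    if "actor_equal" in spec.constraints:
        params.append(("actor", (((0, 0), (1, 1)))))
    else:
        params.append(("a1", ((0, 0),)))
        params.append(("a2", ((1, 1),)))
    if "partner_equal" in spec.constraints:
        params.append(("partner", (((0, 1), (1, 0)))))
    else:
        params.append(("p1", ((0, 1),)))
        params.append(("p2", ((1, 0),)))
    n_cov = len(spec.covariates) if spec.covariate_scope != "none" else 0
    for j, name in enumerate(covs1):
        idx = 2 + j
        params.append((f"{y1}~{name}", ((0, idx),)))
        if spec.covariate_scope == "both_members":
            params.append((f"{y2}~{name}", ((1, idx),)))
    for j, name in enumerate(covs2):
        idx = 2 + n_cov + j
        params.append((f"{y2}~{name}", ((1, idx),)))
        if spec.covariate_scope == "both_members":
            params.append((f"{y1}~{name}", ((0, idx),)))

    model = ModelStructure(
        spec=spec, endog=(y1, y2), exog=exog, gamma_params=tuple(params)
    )
    n_complete = int(data[list(needed)].dropna().shape[0])
    if n_complete < model.n_free:
        raise EstimationError(
            f"{n_complete} complete dyads but {model.n_free} free parameters: "
            "estimation infeasible"
        )
    return model


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

def _moment_blocks(model: ModelStructure, data: pd.DataFrame):
    cols = list(model.var_names)
    complete = data[cols].dropna()
    N = len(complete)
    Z = complete.to_numpy(dtype=float)
    S = np.cov(Z, rowvar=False, ddof=1)
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0 or np.linalg.eigvalsh(S).min() <= 0:
        raise EstimationError(
            "sample covariance matrix is not positive definite; audit the "
            "listwise-complete analysis variables for collinearity"
        )
    return S, N


def _resid_moment(G, Syy, Syx, Sxx):
    GS = G @ Syx.T  # Gamma S_xy
    return Syy - GS - GS.T + G @ Sxx @ G.T


def _profile_obj_grad(vec, model, Syy, Syx, Sxx):
    """ln|Psi(Gamma)| and its gradient in the free path coefficients."""
    G = model.gamma_from_vec(vec)
    M = _resid_moment(G, Syy, Syx, Sxx)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return np.inf, np.zeros_like(vec)
    Minv = np.linalg.inv(M)
    GSxx = G @ Sxx
    grad = np.empty(len(vec))
    for k, (_, cells) in enumerate(model.gamma_params):
        g = 0.0
        for r, c in cells:
            # d M / d gamma_k for a unit basis matrix at (r, c):
            # -(B Sxy + Sxy' B') + B Sxx G' + G Sxx B'
            row = -Syx[:, c] + GSxx[:, c]  # contribution to row r (and col r)
            g += 2.0 * (Minv[r, :] @ row)
        grad[k] = g
    return logdet, grad


def _start_values(model: ModelStructure, S: np.ndarray) -> np.ndarray:
    """Per-equation least squares on each equation's included regressors;
    equality-constrained parameters start at the mean of their pair."""
    q = len(model.exog)
    Syx = S[:2, 2:]
    Sxx = S[2:, 2:]
    included = [sorted({c for _, cells in model.gamma_params for r, c in cells if r == eq})
                for eq in (0, 1)]
    ols = np.zeros((2, q))
    for eq in (0, 1):
        J = included[eq]
        if J:
            ols[eq, J] = np.linalg.solve(Sxx[np.ix_(J, J)], Syx[eq, J])
    start = np.empty(len(model.gamma_params))
    for k, (_, cells) in enumerate(model.gamma_params):
        start[k] = float(np.mean([ols[r, c] for r, c in cells]))
    return start


def _assemble_sigma(G, Phi, Psi):
    p = 2 + Phi.shape[0]
    Sigma = np.empty((p, p))
    GPhi = G @ Phi
    Sigma[:2, :2] = GPhi @ G.T + Psi
    Sigma[:2, 2:] = GPhi
    Sigma[2:, :2] = GPhi.T
    Sigma[2:, 2:] = Phi
    return Sigma


def _f_ml(Sigma, S, logdet_S):
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    return logdet + float(np.trace(np.linalg.solve(Sigma, S))) - logdet_S - S.shape[0]


def _numeric_hessian(fun, theta, rel_step=1e-4):
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (fun(theta + ei) - 2.0 * f0 + fun(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej)
                - fun(theta + ei - ej)
                - fun(theta - ei + ej)
                + fun(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_ml(
    model: ModelStructure,
    data: pd.DataFrame,
    compute_se: bool = True,
) -> tuple[APIMEstimate, FitIndices]:
    """Fit one APIM by ML covariance-structure estimation.

    Listwise-deletes dyads with any missing analysis variable, minimises
    F_ML over the free paths (profiling out Psi and Phi, which have
    closed-form conditional solutions), and returns estimates with fit
    indices.  Convergence requires the profile gradient norm to fall below
    1e-8.
    """
    S, N = _moment_blocks(model, data)
    Syy, Syx, Sxx = S[:2, :2], S[:2, 2:], S[2:, 2:]
    start = _start_values(model, S)

    res = optimize.minimize(
        _profile_obj_grad,
        start,
        args=(model, Syy, Syx, Sxx),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 1000},
    )
    gnorm = float(np.linalg.norm(res.jac))
    if gnorm > _GRAD_TOL:
        # one polish from the current point before giving up
        res = optimize.minimize(
            _profile_obj_grad,
            res.x,
            args=(model, Syy, Syx, Sxx),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-12, "maxiter": 2000},
        )
        gnorm = float(np.linalg.norm(res.jac))
        if gnorm > 1e-6:
            raise EstimationError(
                f"APIM optimizer did not converge: |grad| = {gnorm:.3g}"
            )

    gamma_hat = res.x
    G = model.gamma_from_vec(gamma_hat)
    Psi = _resid_moment(G, Syy, Syx, Sxx)
    Phi = Sxx
    Sigma_hat = _assemble_sigma(G, Phi, Psi)
    logdet_S = float(np.linalg.slogdet(S)[1])
    F = _f_ml(Sigma_hat, S, logdet_S)
    scale_const = (N - 1) if model.spec.chi2_scale == "nm1" else N
    T = max(scale_const * F, 0.0)

    param_names = [name for name, _ in model.gamma_params]
    se: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    if compute_se:
        n_gamma = len(gamma_hat)

        def f_full(theta):
            Gt = model.gamma_from_vec(theta[:n_gamma])
            Psit = np.array(
                [[theta[n_gamma], theta[n_gamma + 2]],
                 [theta[n_gamma + 2], theta[n_gamma + 1]]]
            )
            return _f_ml(_assemble_sigma(Gt, Phi, Psit), S, logdet_S)

        theta_hat = np.concatenate([gamma_hat, [Psi[0, 0], Psi[1, 1], Psi[0, 1]]])
        H = _numeric_hessian(f_full, theta_hat)
        try:
            acov = (2.0 / scale_const) * np.linalg.inv(H)
            d = np.diag(acov).copy()
            if (d < 0).any():
                warnings.warn(
                    "negative variance estimate in inverse Hessian; "
                    "affected standard errors reported as NaN",
                    stacklevel=2,
                )
                d[d < 0] = np.nan
            ses = np.sqrt(d)
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian; standard errors unavailable",
                          stacklevel=2)
            ses = np.full(len(theta_hat), np.nan)
        full_names = param_names + ["psi11", "psi22", "psi12"]
        full_est = np.concatenate([gamma_hat, [Psi[0, 0], Psi[1, 1], Psi[0, 1]]])
        for name, est, s in zip(full_names, full_est, ses):
            se[name] = float(s)
            ci[name] = (float(est - 1.96 * s), float(est + 1.96 * s))

    estimate = APIMEstimate(
        params={n: float(v) for n, v in zip(param_names, gamma_hat)},
        se=se,
        ci=ci,
        psi11=float(Psi[0, 0]),
        psi22=float(Psi[1, 1]),
        psi12=float(Psi[0, 1]),
        phi=pd.DataFrame(Phi, index=list(model.exog), columns=list(model.exog)),
        n_dyads=N,
    )
    baseline_chi2, baseline_df = _baseline_fit(S, scale_const)
    fit = compute_fit_indices(
        T, model.df, S, Sigma_hat, baseline_chi2, baseline_df, N
    )
    return estimate, fit


def _baseline_fit(S: np.ndarray, scale_const: float) -> tuple[float, int]:
    """Independence model: all covariances fixed at zero, variances free.

    Its ML solution is sigma_ii = s_ii exactly, so T_b reduces to
    -scale * ln|R| with R the sample correlation matrix.
    """
    p = S.shape[0]
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    T_b = -scale_const * float(np.linalg.slogdet(R)[1])
    df_b = p * (p - 1) // 2
    return max(T_b, 0.0), df_b


def compute_fit_indices(
    chi2: float,
    df: int,
    S: np.ndarray,
    sigma_hat: np.ndarray,
    baseline_chi2: float,
    baseline_df: int,
    n_dyads: int,
) -> FitIndices:
    """Model chi-square ratio, CFI and SRMR.

    CFI = 1 - max(T - df, 0) / max(T_b - df_b, T - df, 0); SRMR is the
    root-mean-square of the standardized covariance residuals
    (s_ij - sigma_ij)/sqrt(s_ii s_jj) over the unique moments.  chi2/df is
    reported as NaN for a saturated model (df = 0).
    """
    excess = max(chi2 - df, 0.0)
    denom = max(baseline_chi2 - baseline_df, excess, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess / denom
    d = np.sqrt(np.diag(S))
    std_resid = (S - sigma_hat) / np.outer(d, d)
    iu = np.triu_indices_from(S)
    srmr = float(np.sqrt(np.mean(std_resid[iu] ** 2)))
    ratio = chi2 / df if df > 0 else float("nan")
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        chi2_df_ratio=float(ratio),
        cfi=float(cfi),
        srmr=srmr,
        baseline_chi2=float(baseline_chi2),
        baseline_df=int(baseline_df),
        n_dyads=int(n_dyads),
    )


def fit_apim(
    data: pd.DataFrame, spec: APIMSpec, compute_se: bool = True
) -> APIMResult:
    """Build and fit one APIM; convenience wrapper over build_model/fit_ml."""
    model = build_model(spec, data)
    estimate, fit = fit_ml(model, data, compute_se=compute_se)
    return APIMResult(spec=spec, model=model, estimate=estimate, fit=fit)


# ---------------------------------------------------------------------------
# Equality-constraint tests
# ---------------------------------------------------------------------------

def _is_nested(unconstrained: ModelStructure, constrained: ModelStructure) -> bool:
    """The constrained parameter map must merge (but never split or move)
    the unconstrained one over an identical path-cell set."""
    if (unconstrained.endog != constrained.endog
            or unconstrained.exog != constrained.exog):
        return False
    cells_u = {cells for _, cells in unconstrained.gamma_params}
    all_u = {c for cells in cells_u for c in cells}
    all_c = {c for _, cells in constrained.gamma_params for c in cells}
    if all_u != all_c:
        return False
    for _, cells in constrained.gamma_params:
        covered = set()
        for cu in cells_u:
            if set(cu) <= set(cells):
                covered |= set(cu)
        if covered != set(cells):
            return False
    return True


def equality_constraint_test(
    unconstrained: APIMResult,
    constrained: APIMResult,
    constraint_name: str | None = None,
) -> ConstraintTestResult:
    """Likelihood-ratio chi-square difference test for a nested constraint.

    chi2_diff = T(constrained) - T(unconstrained) on df_diff degrees of
    freedom.  Small negative differences (within 1e-6, optimizer noise) are
    clamped to zero with a warning; larger negatives are an error.
    """
    if not _is_nested(unconstrained.model, constrained.model):
        raise ValidationError(
            "constrained model is not nested in the unconstrained model"
        )
    if unconstrained.estimate.n_dyads != constrained.estimate.n_dyads:
        raise ValidationError("models were fitted to different analysis samples")
    df_diff = constrained.model.df - unconstrained.model.df
    if df_diff < 0:
        raise ValidationError("constrained model has fewer df than unconstrained")
    chi2_diff = constrained.fit.chi2 - unconstrained.fit.chi2
    if chi2_diff < 0:
        if chi2_diff < -_NEG_CHI2_TOL:
            raise EstimationError(
                f"chi-square difference {chi2_diff:.3g} is negative beyond "
                "optimizer tolerance; one of the fits failed"
            )
        warnings.warn(
            f"negative chi-square difference {chi2_diff:.3g} clamped to 0",
            stacklevel=2,
        )
        chi2_diff = 0.0
    if df_diff == 0:
        p = 1.0 if chi2_diff == 0.0 else 0.0
    else:
        p = float(stats.chi2.sf(chi2_diff, df_diff))
    name = constraint_name or "+".join(
        sorted(constrained.spec.constraints - unconstrained.spec.constraints)
    )
    return ConstraintTestResult(
        chi2_diff=float(chi2_diff), df_diff=int(df_diff), p_value=p,
        constraint_name=name,
    )


# ---------------------------------------------------------------------------
# Study-level suite
# ---------------------------------------------------------------------------

def run_apim_suite(
    data: pd.DataFrame,
    outcomes: tuple[str, ...] = ("phys", "psych", "soc", "env"),
    predictor: str = "stigma",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    covariate_scope: str = "own_member_only",
    chi2_scale: str = "nm1",
) -> dict:
    """Fit the full study analog: one APIM per outcome plus actor-equal and
    partner-equal constrained refits with chi-square difference tests.

    Returns a JSON-serialisable report (coefficients with 95% CIs, residual
    covariances, fit indices, and both constraint tests per outcome).
    """
    report: dict = {"schema_version": 1, "outcomes": {}}
    for outcome in outcomes:
        spec = APIMSpec(
            outcome=outcome,
            predictor=predictor,
            covariates=covariates,
            covariate_scope=covariate_scope,
            chi2_scale=chi2_scale,
        )
        base = fit_apim(data, spec)
        block: dict = {
            "n_dyads": base.estimate.n_dyads,
            "paths": {},
            "covariates": {},
            "residuals": {
                "psi11": base.estimate.psi11,
                "psi22": base.estimate.psi22,
                "psi12": base.estimate.psi12,
            },
            "fit": {
                "chi2": base.fit.chi2,
                "df": base.fit.df,
                "chi2_df_ratio": base.fit.chi2_df_ratio,
                "cfi": base.fit.cfi,
                "srmr": base.fit.srmr,
            },
            "constraint_tests": {},
        }
        for name, val in base.estimate.params.items():
            entry = {
                "estimate": val,
                "se": base.estimate.se.get(name),
                "ci": list(base.estimate.ci.get(name, (None, None))),
            }
            if name in PATH_NAMES:
                block["paths"][name] = entry
            else:
                block["covariates"][name] = entry
        for constraint in ("actor_equal", "partner_equal"):
            cspec = replace(spec, constraints=frozenset({constraint}))
            cfit = fit_apim(data, cspec, compute_se=False)
            test = equality_constraint_test(base, cfit, constraint_name=constraint)
            block["constraint_tests"][constraint] = {
                "chi2_diff": test.chi2_diff,
                "df_diff": test.df_diff,
                "p_value": test.p_value,
            }
        report["outcomes"][outcome] = block
    return report
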