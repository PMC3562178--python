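"""Dyad-level descriptive statistics.

The analytic layer that precedes the path model: paired comparisons between
the two members of each dyad (paired t for continuous variables, McNemar
for binary ones), Pearson correlation matrices across both members'
variables, Welch t-tests against externally published summary statistics,
and the dyad-exclusion ledger.

Data convention: one row per dyad, columns prefixed ``p_`` for member 1
(the person living with HIV/AIDS) and ``c_`` for member 2 (the caregiver),
e.g. ``p_stigma``/``c_stigma``, ``p_phys`` ... ``c_env``, plus covariates
``*_age``, ``*_female``, ``*_married``, ``*_edu``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import UndefinedResultError, ValidationError

__all__ = [
    "PairedTestResult",
    "CorrelationMatrix",
    "ExclusionLedger",
    "filter_dyads",
    "paired_t_test",
    "mcnemar_test",
    "pearson_matrix",
    "welch_t_from_summary",
    "validate_dyad_table",
    "significance_stars",
]

ROLE_PREFIXES = ("p_", "c_")


@dataclass
class PairedTestResult:
    statistic: float
    df: float
    p_value: float
    n_pairs: int
    test_name: str


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    ``r``, ``p`` and ``n`` are DataFrames over the same variable ordering;
    ``r`` is symmetric with a unit diagonal.  Variables that are constant in
    the pairwise-complete sample yield NaN entries and a diagnostic.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    diagnostics: list[str] = field(default_factory=list)


@dataclass
class ExclusionLedger:
    invited: int
    refused: int
    missing_required: int

    @property
    def retained(self) -> int:
        return self.invited - self.refused - self.missing_required

    def as_dict(self) -> dict[str, int]:
        return {
            "invited": self.invited,
            "refused": self.refused,
            "missing_required": self.missing_required,
            "retained": self.retained,
        }


def validate_dyad_table(df: pd.DataFrame, id_column: str = "dyad_id") -> None:
    """Reject duplicate dyad ids; warn on out-of-instrument-range scores.

    Range violations are a warning rather than an error because the default
    synthetic generator produces continuous scores that can stray slightly
    outside the integer instrument range; for real instrument data the
    warning flags a coding problem worth auditing.
    """
    if id_column in df.columns:
        dup = df[id_column][df[id_column].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate dyad ids: {sorted(set(dup))[:5]}")
    for col in df.columns:
        if col.endswith("_stigma"):
            vals = df[col].dropna()
            if len(vals) and ((vals < 0).any() or (vals > 27).any()):
                warnings.warn(
                    f"{col}: values outside the 0-27 instrument range",
                    stacklevel=2,
                )


def filter_dyads(
    raw: pd.DataFrame,
    required_fields: tuple[str, ...] = ("p_stigma", "c_stigma"),
    status_column: str = "status",
    id_column: str = "dyad_id",
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the study exclusion rules and return the retained table + ledger.

    Rows whose ``status`` is ``"refused"`` are dropped first; of the
    remainder, rows missing any required field are dropped.  The ledger
    satisfies retained = invited - refused - missing_required.
    """
    if id_column in raw.columns:
        dup = raw[id_column][raw[id_column].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate dyad ids: {sorted(set(dup))[:5]}")
    invited = len(raw)
    if status_column in raw.columns:
        refused_mask = raw[status_column].astype(str).str.lower() == "refused"
    else:
        refused_mask = pd.Series(False, index=raw.index)
    consented = raw.loc[~refused_mask]
    present = [f for f in required_fields if f in consented.columns]
    missing_mask = consented[present].isna().any(axis=1) if present else pd.Series(
        False, index=consented.index
    )
    retained = consented.loc[~missing_mask].drop(
        columns=[status_column], errors="ignore"
    )
    ledger = ExclusionLedger(
        invited=invited,
        refused=int(refused_mask.sum()),
        missing_required=int(missing_mask.sum()),
    )
    if ledger.retained == 0:
        warnings.warn("all dyads excluded; returning empty table", stacklevel=2)
    return retained.reset_index(drop=True), ledger


def paired_t_test(x, y) -> PairedTestResult:
    """Paired-sample t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.

    Incomplete pairs are dropped.  If the differences have zero variance the
    result degenerates: t = 0, p = 1 when the members are identical, and an
    infinite t with p = 0 when they differ by a nonzero constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        raise ValidationError(f"need at least 2 complete pairs, got {n}")
    d = x - y
    if np.ptp(d) == 0:  # constant differences
        if d[0] == 0:
            return PairedTestResult(0.0, float(n - 1), 1.0, n, "paired_t")
        return PairedTestResult(
            float(np.sign(d[0]) * np.inf), float(n - 1), 0.0, n, "paired_t"
        )
    res = stats.ttest_rel(x, y)
    return PairedTestResult(
        float(res.statistic), float(n - 1), float(res.pvalue), n, "paired_t"
    )


def mcnemar_test(x, y, correction: bool = False) -> PairedTestResult:
    """McNemar chi-square test for paired binary outcomes.

    With discordant counts b (x=1, y=0) and c (x=0, y=1), the statistic is
    (|b - c| - 1)^2/(b + c) under the Edwards continuity correction, or
    (b - c)^2/(b + c) without (the default); df = 1.  Concordant pairs do
    not enter the statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValidationError("mcnemar_test requires binary 0/1 values")
    n = len(x)
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    if b + c == 0:
        raise UndefinedResultError(
            "no discordant pairs: the McNemar statistic is undefined"
        )
    a = int(np.sum((x == 1) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    res = _sm_mcnemar([[a, b], [c, d]], exact=False, correction=correction)
    return PairedTestResult(
        float(res.statistic), 1.0, float(res.pvalue), n, "mcnemar"
    )


def pearson_matrix(data: pd.DataFrame, variables: list[str]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation matrix with two-sided p-values.

    p-values come from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    Pairs with fewer than 3 complete observations, or a constant variable,
    yield NaN with a diagnostic message.
    """
    missing = set(variables) - set(data.columns)
    if missing:
        raise ValidationError(f"variables absent from table: {sorted(missing)}")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    diagnostics: list[str] = []
    cols = {v: data[v].to_numpy(dtype=float) for v in variables}
    for i in range(k):
        n[i, i] = int(np.sum(~np.isnan(cols[variables[i]])))
        for j in range(i + 1, k):
            xi, xj = cols[variables[i]], cols[variables[j]]
            keep = ~(np.isnan(xi) | np.isnan(xj))
            nij = int(keep.sum())
            n[i, j] = n[j, i] = nij
            if nij < 3:
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
                diagnostics.append(
                    f"{variables[i]}~{variables[j]}: only {nij} complete pairs"
                )
                continue
            a, b = xi[keep], xj[keep]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
                const = variables[i] if np.ptp(a) == 0 else variables[j]
                diagnostics.append(f"{const}: constant in pairwise-complete sample")
                continue
            res = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(variables)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        diagnostics=diagnostics,
    )


def welch_t_from_summary(
    m1: float,
    sd1: float,
    n1: int,
    m2: float,
    sd2: float,
    n2: int,
    equal_var: bool = False,
) -> PairedTestResult:
    """Two-sample t-test from summary statistics (Welch by default).

    Used to compare a domain mean against a mean published elsewhere when
    only (mean, sd, n) are available.  Set ``equal_var=True`` for the
    pooled-variance variant.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("both sample sizes must be at least 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        m1, sd1, n1, m2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return PairedTestResult(
        float(res.statistic),
        float(df),
        float(res.pvalue),
        min(n1, n2),
        "pooled_t" if equal_var else "welch_t",
    )


def significance_stars(p: float) -> str:
    """Report-layer stars: ** for p <= 0.01, * for p <= 0.05."""
    if np.isnan(p):
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""
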