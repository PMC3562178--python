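"""End-to-end study orchestration: score, describe, model, report.

One :class:`StudyConfig` drives the whole analysis analog.  A run either
*simulates* a dyad table from a named scenario preset or *loads* a scored
wide-format dyad CSV (optionally scoring item-level CSVs first), then
emits:

* a member-comparison table (means/SDs, paired t-tests for continuous
  variables, McNemar tests for binary ones),
* a correlation matrix across both members' stigma and QOL domain scores,
* the APIM suite: per-outcome actor/partner effects with 95% CIs, fit
  indices, and actor-equal / partner-equal constraint tests,
* an exclusion ledger and a run log (seed, package version, config).

All outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .apim import run_apim_suite
from .descriptives import (
    filter_dyads,
    mcnemar_test,
    paired_t_test,
    pearson_matrix,
    significance_stars,
)
from .errors import ConfigurationError
from .io import read_dyad_csv, write_dyad_csv, write_json_report
from .scales import SCALE_PRESETS, LikertItemMatrix, cronbach_alpha, score_composite
from .synthetic import SCENARIO_PRESETS, study_replicate

CONTINUOUS_VARS = ("stigma", "phys", "psych", "soc", "env", "age")
BINARY_VARS = ("female", "married", "edu")
OUTCOMES = ("phys", "psych", "soc", "env")


@dataclass
class StudyConfig:
    """Configuration for one pipeline run.

    Exactly one of ``scenario_preset`` (simulate mode) or ``dyad_csv``
    (real-input mode) must be set.
    """

    seed: int = 0
    out_dir: str = "results"
    scenario_preset: str | None = None
    n_dyads: int | None = None
    dyad_csv: str | None = None
    item_csvs: dict[str, str] = field(default_factory=dict)  # role -> path
    predictor: str = "stigma"
    outcomes: tuple[str, ...] = OUTCOMES
    covariates: tuple[str, ...] = ("age", "female", "married", "edu")
    covariate_scope: str = "own_member_only"
    chi2_scale: str = "nm1"
    required_fields: tuple[str, ...] = ("p_stigma", "c_stigma")

    def __post_init__(self):
        modes = (self.scenario_preset is not None, self.dyad_csv is not None)
        if sum(modes) != 1:
            raise ConfigurationError(
                "exactly one of scenario_preset (simulate mode) or dyad_csv "
                "(input mode) must be set"
            )
        if self.scenario_preset is not None and (
            self.scenario_preset not in SCENARIO_PRESETS
        ):
            raise ConfigurationError(
                f"unknown scenario preset {self.scenario_preset!r}; "
                f"available: {sorted(SCENARIO_PRESETS)}"
            )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("outcomes", "covariates", "required_fields"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def score_stigma_items(item_csv: str, role_prefix: str) -> pd.DataFrame:
    """Score a stigma item CSV into a one-column composite frame."""
    mat = LikertItemMatrix.from_csv(item_csv, "stigma", 0, 3)
    definition = SCALE_PRESETS["stigma"]
    # accept any column naming as long as there are 9 items in order
    renamed = mat.responses.copy()
    renamed.columns = list(definition.item_ids)[: len(renamed.columns)]
    mat = LikertItemMatrix("stigma", renamed, 0, 3)
    scores = score_composite(mat, definition)
    scores.columns = [role_prefix + "stigma"]
    return scores


def member_comparison_table(df: pd.DataFrame) -> pd.DataFrame:
    """Demographics / stigma / QOL comparison between the two members."""
    rows = []
    for var in CONTINUOUS_VARS:
        p, c = "p_" + var, "c_" + var
        if p not in df.columns or c not in df.columns:
            continue
        res = paired_t_test(df[p], df[c])
        rows.append({
            "variable": var, "type": "continuous",
            "member1_mean": float(df[p].mean()), "member1_sd": float(df[p].std(ddof=1)),
            "member2_mean": float(df[c].mean()), "member2_sd": float(df[c].std(ddof=1)),
            "statistic": res.statistic, "test": res.test_name,
            "p_value": res.p_value, "n": res.n_pairs,
        })
    for var in BINARY_VARS:
        p, c = "p_" + var, "c_" + var
        if p not in df.columns or c not in df.columns:
            continue
        try:
            res = mcnemar_test(df[p], df[c])
            stat, pval = res.statistic, res.p_value
        except Exception:
            stat, pval = float("nan"), float("nan")
        rows.append({
            "variable": var, "type": "binary",
            "member1_mean": float(df[p].mean()), "member1_sd": float("nan"),
            "member2_mean": float(df[c].mean()), "member2_sd": float("nan"),
            "statistic": stat, "test": "mcnemar",
            "p_value": pval, "n": int(df[[p, c]].dropna().shape[0]),
        })
    return pd.DataFrame(rows)


def correlation_report(df: pd.DataFrame) -> dict:
    """Correlations among both members' stigma and QOL domain scores."""
    variables = [
        pre + v for pre in ("p_", "c_") for v in ("stigma",) + OUTCOMES
        if pre + v in df.columns
    ]
    corr = pearson_matrix(df, variables)
    return {
        "variables": variables,
        "r": corr.r.round(6).values.tolist(),
        "p": corr.p.round(6).values.tolist(),
        "n": corr.n.values.tolist(),
        "stars": [
            [significance_stars(corr.p.iloc[i, j]) if i != j else ""
             for j in range(len(variables))]
            for i in range(len(variables))
        ],
        "diagnostics": corr.diagnostics,
    }


def run_study(config: StudyConfig) -> dict:
    """Execute the full pipeline and write the report bundle to
    ``config.out_dir``.  Returns the in-memory report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reliability = {}
    if config.scenario_preset is not None:
        table, items = study_replicate(
            config.scenario_preset, config.seed, n_dyads=config.n_dyads
        )
        for role, mat in items.items():
            rel = cronbach_alpha(mat, name=f"stigma_{role}")
            reliability[rel.scale_or_domain] = {
                "alpha": rel.alpha, "n_items": rel.n_items,
                "n_respondents": rel.n_respondents,
            }
        ledger = {"invited": len(table), "refused": 0,
                  "missing_required": 0, "retained": len(table)}
    else:
        raw = read_dyad_csv(config.dyad_csv)
        for role, path in config.item_csvs.items():
            prefix = {"plwha": "p_", "caregiver": "c_"}[role]
            scores = score_stigma_items(path, prefix)
            raw = raw.drop(columns=scores.columns, errors="ignore").merge(
                scores, left_on="dyad_id", right_index=True, how="left"
            )
        table, led = filter_dyads(raw, required_fields=config.required_fields)
        ledger = led.as_dict()

    write_dyad_csv(table, out / "dyad_table.csv")

    comparison = member_comparison_table(table)
    comparison.to_csv(out / "member_comparison.csv", index=False)
    correlations = correlation_report(table)

    apim_report = run_apim_suite(
        table,
        outcomes=config.outcomes,
        predictor=config.predictor,
        covariates=config.covariates,
        covariate_scope=config.covariate_scope,
        chi2_scale=config.chi2_scale,
    )

    report = {
        "run": {
            "seed": config.seed,
            "version": __version__,
            "mode": "simulate" if config.scenario_preset else "input",
            "preset": config.scenario_preset,
            "n_dyads": int(len(table)),
        },
        "exclusion_ledger": ledger,
        "reliability": reliability,
        "member_comparison": comparison.to_dict(orient="records"),
        "correlations": correlations,
        "apim": apim_report,
    }
    write_json_report(report, out / "report.json")
    return report
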