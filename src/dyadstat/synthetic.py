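"""Synthetic dyad and Likert-item generators.

The study population being emulated: dyads of one person living with
HIV/AIDS (member 1, prefix ``p_``) and one primary caregiver (member 2,
prefix ``c_``), each contributing a perceived-stigma composite (0-27
scale), four quality-of-life domain scores (4-20 scale) and demographic
covariates.  Outcomes are generated forward through the actor-partner
equations

    Y1 = b01 + a1*X1 + p1*X2 + beta1'C1 + E1
    Y2 = b02 + a2*X2 + p2*X1 + beta2'C2 + E2

with (X1, X2) correlated bivariate normal, covariates independent, and
(E1, E2) correlated bivariate normal — exactly the structure the APIM
estimator assumes.  Residual variances are solved internally so that each
outcome hits its target marginal SD; the implied residual variance must be
positive or the scenario is rejected.

Scores are continuous by default (the estimator's assumption); ``clip=True``
additionally rounds stigma composites to integers clipped to [0, 27] and
outcomes to [4, 20] for realism at the cost of slight moment distortion.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` child streams, so every fixture is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .scales import LikertItemMatrix

__all__ = [
    "OutcomeSpec",
    "DyadScenario",
    "ItemScenario",
    "generate_dyads",
    "generate_items",
    "study_replicate",
    "loading_for_alpha",
    "SCENARIO_PRESETS",
    "STIGMA_ITEM_SCENARIO",
]


@dataclass(frozen=True)
class OutcomeSpec:
    """True paths and target moments for one outcome (QOL domain) pair."""

    a1: float  # actor effect, member 1
    p1: float  # partner effect of member 2's predictor on member 1's outcome
    a2: float  # actor effect, member 2
    p2: float  # partner effect of member 1's predictor on member 2's outcome
    mean: tuple[float, float]  # target outcome means (member1, member2)
    sd: tuple[float, float]    # target outcome SDs
    rho_e: float = 0.15        # residual correlation (dyadic non-independence)


@dataclass(frozen=True)
class DyadScenario:
    """Full generating recipe for a wide-format dyad table.

    Default moments follow the emulated survey: stigma mean (SD) 6.3 (5.8)
    for PLWHAs and 3.8 (5.3) for caregivers with a weak positive
    between-member correlation; covariate distributions match the reported
    demographics (PLWHAs on average 3.2 years older, caregivers more often
    female and married).
    """

    n_dyads: int = 148
    x_mean: tuple[float, float] = (6.3, 3.8)
    x_sd: tuple[float, float] = (5.8, 5.3)
    rho_x: float = 0.15
    outcomes: dict[str, OutcomeSpec] = field(default_factory=dict)
    # own-member covariate effects per outcome unit, shared across outcomes
    cov_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": -0.02, "female": 0.3, "married": 0.5, "edu": 0.4,
        }
    )
    age_mean: tuple[float, float] = (40.7, 37.5)
    age_sd: tuple[float, float] = (11.4, 11.2)
    p_female: tuple[float, float] = (0.304, 0.608)
    p_married: tuple[float, float] = (0.703, 0.797)
    p_edu: tuple[float, float] = (0.743, 0.770)
    clip: bool = False

    def __post_init__(self):
        for name, r in (("rho_x", self.rho_x),):
            if not -1.0 < r < 1.0:
                raise ValidationError(f"{name} must lie in (-1, 1), got {r}")
        for o, spec in self.outcomes.items():
            if not -1.0 < spec.rho_e < 1.0:
                raise ValidationError(
                    f"outcome {o!r}: rho_e must lie in (-1, 1), got {spec.rho_e}"
                )
        if min(self.x_sd) <= 0 or min(self.age_sd) <= 0:
            raise ValidationError("scale parameters must be positive")


def _residual_sds(scenario: DyadScenario, spec: OutcomeSpec) -> tuple[float, float]:
    """Solve the residual SDs that make each outcome hit its target SD."""
    s1, s2 = scenario.x_sd
    rho = scenario.rho_x
    cov_x = rho * s1 * s2
    cov_var = sum(
        b**2 * v
        for b, v in zip(
            scenario.cov_effects.values(),
            _covariate_variances(scenario),
        )
    ) if scenario.cov_effects else 0.0

    out = []
    for role, (a, p) in enumerate(((spec.a1, spec.p1), (spec.a2, spec.p2))):
        own_var = s1**2 if role == 0 else s2**2
        other_var = s2**2 if role == 0 else s1**2
        explained = a**2 * own_var + p**2 * other_var + 2 * a * p * cov_x + cov_var
        resid_var = spec.sd[role] ** 2 - explained
        if resid_var <= 0:
            raise ValidationError(
                f"implied residual variance non-positive ({resid_var:.3g}) "
                f"for target SD {spec.sd[role]}"
            )
        out.append(float(np.sqrt(resid_var)))
    return out[0], out[1]


def _covariate_variances(scenario: DyadScenario):
    # variance of each own-member covariate, averaged over the two roles
    # (effects are shared across roles, so only a rough average matters
    # for hitting the target outcome SD)
    def bvar(p):
        return p * (1 - p)

    return (
        float(np.mean(np.square(scenario.age_sd))),
        float(np.mean([bvar(p) for p in scenario.p_female])),
        float(np.mean([bvar(p) for p in scenario.p_married])),
        float(np.mean([bvar(p) for p in scenario.p_edu])),
    )


def generate_dyads(scenario: DyadScenario, seed: int) -> pd.DataFrame:
    """Draw a wide-format dyad table under the scenario's generating model.

    Deterministic under a fixed seed.  Columns: ``dyad_id``, ``p_stigma``,
    ``c_stigma``, one ``p_``/``c_`` pair per outcome, and the covariates
    ``*_age``, ``*_female``, ``*_married``, ``*_edu``.
    """
    n = scenario.n_dyads
    streams = np.random.SeedSequence(seed).spawn(3)
    rng_x = np.random.default_rng(streams[0])
    rng_cov = np.random.default_rng(streams[1])
    rng_e = np.random.default_rng(streams[2])

    s1, s2 = scenario.x_sd
    cov_x = np.array(
        [[s1**2, scenario.rho_x * s1 * s2],
         [scenario.rho_x * s1 * s2, s2**2]]
    )
    X = rng_x.multivariate_normal(scenario.x_mean, cov_x, size=n)

    data = {"dyad_id": np.arange(1, n + 1)}
    if scenario.clip:
        data["p_stigma"] = np.clip(np.round(X[:, 0]), 0, 27)
        data["c_stigma"] = np.clip(np.round(X[:, 1]), 0, 27)
    else:
        data["p_stigma"] = X[:, 0]
        data["c_stigma"] = X[:, 1]

    covs = {}
    for role, pre in enumerate(("p_", "c_")):
        covs[pre + "age"] = rng_cov.normal(
            scenario.age_mean[role], scenario.age_sd[role], n
        )
        covs[pre + "female"] = rng_cov.binomial(1, scenario.p_female[role], n).astype(float)
        covs[pre + "married"] = rng_cov.binomial(1, scenario.p_married[role], n).astype(float)
        covs[pre + "edu"] = rng_cov.binomial(1, scenario.p_edu[role], n).astype(float)
    data.update(covs)

    beta = scenario.cov_effects
    for name, ospec in scenario.outcomes.items():
        sd_e1, sd_e2 = _residual_sds(scenario, ospec)
        cov_e = np.array(
            [[sd_e1**2, ospec.rho_e * sd_e1 * sd_e2],
             [ospec.rho_e * sd_e1 * sd_e2, sd_e2**2]]
        )
        E = rng_e.multivariate_normal((0.0, 0.0), cov_e, size=n)
        for role, pre in enumerate(("p_", "c_")):
            a = ospec.a1 if role == 0 else ospec.a2
            p = ospec.p1 if role == 0 else ospec.p2
            own_x = X[:, role]
            other_x = X[:, 1 - role]
            cov_part = np.zeros(n)
            cov_mean = 0.0
            for cname, b in beta.items():
                cov_part += b * covs[pre + cname]
                if cname == "age":
                    cov_mean += b * scenario.age_mean[role]
                else:
                    prob = getattr(scenario, "p_" + cname)[role]
                    cov_mean += b * prob
            intercept = (
                ospec.mean[role]
                - a * scenario.x_mean[role]
                - p * scenario.x_mean[1 - role]
                - cov_mean
            )
            y = intercept + a * own_x + p * other_x + cov_part + E[:, role]
            if scenario.clip:
                y = np.clip(y, 4.0, 20.0)
            data[pre + name] = y

    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Item-level generator
# ---------------------------------------------------------------------------

def loading_for_alpha(target_alpha: float, n_items: int) -> float:
    """Continuous-scale loading that yields the target alpha for parallel
    items (Spearman-Brown): inter-item correlation
    rho = alpha / (k - alpha*(k-1)), loading = sqrt(rho).

    Discretizing onto a coarse Likert grid attenuates correlations, so a
    discretized scenario needs a loading above this value (see
    ItemScenario.loading defaults, which are calibrated for their threshold
    sets).
    """
    if not 0 < target_alpha < 1:
        raise ValidationError("target alpha must lie in (0, 1)")
    rho = target_alpha / (n_items - target_alpha * (n_items - 1))
    if rho >= 1:
        raise ValidationError(
            f"alpha {target_alpha} unattainable with {n_items} items"
        )
    return float(np.sqrt(rho))


@dataclass(frozen=True)
class ItemScenario:
    """Recipe for respondent x item Likert responses with a target
    reliability.

    Items are generated as loading*latent + sqrt(1-loading^2)*noise, then
    cut at ``thresholds`` (strictly increasing, on the standard-normal
    scale) into the integer range [response_min, response_min + len(thresholds)].
    """

    scale_id: str
    n_items: int
    loading: float
    thresholds: tuple[float, ...]
    response_min: int = 0
    target_alpha: float | None = None

    def __post_init__(self):
        if not 0 <= self.loading <= 1:
            raise ValidationError("loading must lie in [0, 1]")
        t = np.asarray(self.thresholds, dtype=float)
        if len(t) < 1 or (np.diff(t) <= 0).any():
            raise ValidationError("thresholds must be strictly increasing")
        if self.n_items < 2:
            raise ValidationError("need at least 2 items")

    @property
    def response_max(self) -> int:
        return self.response_min + len(self.thresholds)


def generate_items(
    scenario: ItemScenario, latent: np.ndarray, seed: int
) -> LikertItemMatrix:
    """Discretized parallel items driven by a standardized latent vector."""
    latent = np.asarray(latent, dtype=float)
    n = len(latent)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    lam = scenario.loading
    noise_sd = float(np.sqrt(max(1.0 - lam**2, 0.0)))
    cont = lam * latent[:, None] + noise_sd * rng.standard_normal(
        (n, scenario.n_items)
    )
    coded = scenario.response_min + np.searchsorted(
        np.asarray(scenario.thresholds), cont
    ).astype(float)
    df = pd.DataFrame(
        coded,
        index=pd.RangeIndex(1, n + 1, name="respondent_id"),
        columns=[f"{scenario.scale_id}{i}" for i in range(1, scenario.n_items + 1)],
    )
    return LikertItemMatrix(
        scenario.scale_id, df, scenario.response_min, scenario.response_max
    )


#: Stigma item generator: 9 items on 0-3 with right-skewed category
#: probabilities (most respondents near the scale floor, matching a mean
#: composite well below the midpoint).  The loading is calibrated so that
#: the empirical alpha of the discretized items is ~0.89 at large n; it
#: exceeds the continuous-scale Spearman-Brown value (0.688) because the
#: 4-category cut attenuates inter-item correlations.
STIGMA_ITEM_SCENARIO = ItemScenario(
    scale_id="stig",
    n_items=9,
    loading=0.754,
    thresholds=(0.126, 0.842, 1.405),  # P(0)=.55, P(1)=.25, P(2)=.12, P(3)=.08
    response_min=0,
    target_alpha=0.89,
)


# ---------------------------------------------------------------------------
# Study-replicate presets
# ---------------------------------------------------------------------------

def _study_outcomes(path_scale: float = 1.0, partner_boost: float = 0.0):
    """Four QOL domains at the emulated study's effect magnitudes."""
    base = {
        "phys": OutcomeSpec(-0.13, -0.02, -0.15, -0.05, (11.8, 14.5), (3.0, 2.2)),
        "psych": OutcomeSpec(-0.15, 0.02, -0.21, -0.002, (11.1, 13.1), (2.8, 2.6)),
        "soc": OutcomeSpec(-0.11, -0.006, -0.13, -0.06, (12.8, 14.2), (2.6, 2.5)),
        "env": OutcomeSpec(-0.17, 0.005, -0.17, -0.02, (10.8, 11.9), (2.5, 2.5)),
    }
    out = {}
    for k, v in base.items():
        out[k] = replace(
            v,
            a1=v.a1 * path_scale,
            a2=v.a2 * path_scale,
            p1=v.p1 * path_scale - partner_boost,
            p2=v.p2 * path_scale - partner_boost,
        )
    return out


SCENARIO_PRESETS: dict[str, DyadScenario] = {
    # no stigma-QOL association at all; for null calibration and coverage
    "null": DyadScenario(outcomes=_study_outcomes(path_scale=0.0)),
    # actor/partner effects at the emulated study's magnitudes
    "paper_magnitude": DyadScenario(outcomes=_study_outcomes()),
    # counterfactual: substantial partner effects
    "strong_partner": DyadScenario(outcomes=_study_outcomes(partner_boost=0.12)),
}


def study_replicate(
    preset: str, seed: int, n_dyads: int | None = None
) -> tuple[pd.DataFrame, dict[str, LikertItemMatrix]]:
    """One full study-sized replicate: a dyad table plus item-level stigma
    responses for each role whose latent scores are the (standardized)
    stigma composites in the table.
    """
    if preset not in SCENARIO_PRESETS:
        raise ValidationError(
            f"unknown preset {preset!r}; available: {sorted(SCENARIO_PRESETS)}"
        )
    scenario = SCENARIO_PRESETS[preset]
    if n_dyads is not None:
        scenario = replace(scenario, n_dyads=n_dyads)
    # derive three independent integer sub-seeds from the master seed
    sub = np.random.SeedSequence(seed).generate_state(3) >> 1  # keep below 2**31

    table = generate_dyads(scenario, seed=int(sub[0]))
    items = {}
    for role, pre in (("plwha", "p_"), ("caregiver", "c_")):
        x = table[pre + "stigma"].to_numpy()
        latent = (x - x.mean()) / x.std(ddof=1)
        item_scn = replace(STIGMA_ITEM_SCENARIO, scale_id=f"stig_{role}_")
        items[role] = generate_items(item_scn, latent, seed=int(sub[1 if role == "plwha" else 2]))
    return table, items
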