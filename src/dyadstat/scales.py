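"""Likert scale scoring and internal-consistency reliability.

Two scoring rules are supported:

* ``composite_sum`` — the total of the (possibly reverse-coded) item
  responses, used for the 9-item perceived HIV stigma scale (items coded
  0-3, composite range 0-27).
* ``domain_mean_times_4`` — the WHOQOL-BREF convention: the mean of the
  items in each named domain, multiplied by 4 so that every domain score
  lies on a common 4-20 scale (for 1-5 item coding).

Missing item responses propagate: a respondent with any missing item in a
composite (or in a domain) receives a missing score for that composite (or
domain).  No imputation or partial-domain proration is applied; downstream
analyses delete incomplete rows listwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, UndefinedResultError, ValidationError

__all__ = [
    "LikertItemMatrix",
    "ScaleDefinition",
    "ReliabilityResult",
    "score_composite",
    "score_domains",
    "cronbach_alpha",
    "reverse_code",
    "STIGMA_SCALE",
    "WHOQOL_BREF",
]


@dataclass
class LikertItemMatrix:
    """Respondent x item integer responses for one named scale.

    ``responses`` is a DataFrame indexed by respondent id with one column
    per item id; missing responses are NaN.  Every non-missing entry must
    lie in ``[response_min, response_max]``.
    """

    scale_id: str
    responses: pd.DataFrame
    response_min: int
    response_max: int

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise ConfigurationError(
                f"response_min ({self.response_min}) must be below "
                f"response_max ({self.response_max})"
            )
        vals = self.responses.to_numpy(dtype=float)
        bad = np.where(
            ~np.isnan(vals) & ((vals < self.response_min) | (vals > self.response_max))
        )
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"scale {self.scale_id!r}: response {vals[i, j]:g} at "
                f"respondent {self.responses.index[i]!r}, item "
                f"{self.responses.columns[j]!r} outside "
                f"[{self.response_min}, {self.response_max}]"
            )

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @classmethod
    def from_csv(
        cls,
        path,
        scale_id: str,
        response_min: int,
        response_max: int,
        id_column: str = "respondent_id",
    ) -> "LikertItemMatrix":
        df = pd.read_csv(path).set_index(id_column)
        return cls(scale_id, df, response_min, response_max)


@dataclass
class ScaleDefinition:
    """Scoring recipe for a Likert scale.

    ``domain_partition`` maps domain name -> list of item ids and is
    required only for the ``domain_mean_times_4`` rule; the domains must
    not overlap.  ``reverse_items`` are recoded as
    ``response_min + response_max - r`` before scoring.
    """

    scale_id: str
    item_ids: tuple[str, ...]
    response_min: int
    response_max: int
    scoring_rule: str  # "composite_sum" | "domain_mean_times_4"
    reverse_items: tuple[str, ...] = ()
    domain_partition: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.item_ids = tuple(self.item_ids)
        self.reverse_items = tuple(self.reverse_items)
        if self.scoring_rule not in ("composite_sum", "domain_mean_times_4"):
            raise ConfigurationError(f"unknown scoring_rule {self.scoring_rule!r}")
        unknown = set(self.reverse_items) - set(self.item_ids)
        if unknown:
            raise ConfigurationError(f"reverse_items not in item_ids: {sorted(unknown)}")
        if self.domain_partition:
            self.domain_partition = {
                d: tuple(items) for d, items in self.domain_partition.items()
            }
            seen: set[str] = set()
            for domain, items in self.domain_partition.items():
                if not items:
                    raise ConfigurationError(f"domain {domain!r} is empty")
                overlap = seen & set(items)
                if overlap:
                    raise ConfigurationError(
                        f"items {sorted(overlap)} appear in more than one domain"
                    )
                unknown = set(items) - set(self.item_ids)
                if unknown:
                    raise ConfigurationError(
                        f"domain {domain!r} references unknown items {sorted(unknown)}"
                    )
                seen |= set(items)

    @classmethod
    def from_yaml(cls, path) -> "ScaleDefinition":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            scale_id=raw["scale_id"],
            item_ids=tuple(raw["item_ids"]),
            response_min=int(raw["response_min"]),
            response_max=int(raw["response_max"]),
            scoring_rule=raw["scoring_rule"],
            reverse_items=tuple(raw.get("reverse_items", ())),
            domain_partition={
                d: tuple(v) for d, v in raw.get("domain_partition", {}).items()
            },
        )

    def to_yaml(self, path) -> None:
        doc = {
            "scale_id": self.scale_id,
            "item_ids": list(self.item_ids),
            "response_min": self.response_min,
            "response_max": self.response_max,
            "scoring_rule": self.scoring_rule,
            "reverse_items": list(self.reverse_items),
            "domain_partition": {d: list(v) for d, v in self.domain_partition.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class ReliabilityResult:
    scale_or_domain: str
    alpha: float
    n_items: int
    n_respondents: int


def reverse_code(items: LikertItemMatrix, definition: ScaleDefinition) -> pd.DataFrame:
    """Return the response matrix with the flagged items reverse-coded.

    Reverse coding maps r -> response_min + response_max - r; applying it
    twice restores the original matrix.
    """
    out = items.responses.copy()
    flip = definition.response_min + definition.response_max
    for item in definition.reverse_items:
        if item in out.columns:
            out[item] = flip - out[item]
    return out


def _check_items(items: LikertItemMatrix, definition: ScaleDefinition) -> pd.DataFrame:
    if items.response_min != definition.response_min or (
        items.response_max != definition.response_max
    ):
        raise ValidationError(
            f"scale {definition.scale_id!r} expects responses coded "
            f"{definition.response_min}-{definition.response_max}; matrix is coded "
            f"{items.response_min}-{items.response_max} (recode explicitly, no "
            "silent shifting)"
        )
    missing = set(definition.item_ids) - set(items.responses.columns)
    if missing:
        raise ConfigurationError(
            f"scale {definition.scale_id!r}: items absent from matrix: {sorted(missing)}"
        )
    return reverse_code(items, definition)


def score_composite(
    items: LikertItemMatrix, definition: ScaleDefinition
) -> pd.DataFrame:
    """Sum of (reverse-coded where flagged) item responses per respondent.

    Respondents with any missing item receive NaN.  Returns a one-column
    DataFrame named after the scale.
    """
    if definition.scoring_rule != "composite_sum":
        raise ConfigurationError(
            f"score_composite requires scoring_rule='composite_sum', got "
            f"{definition.scoring_rule!r}"
        )
    coded = _check_items(items, definition)[list(definition.item_ids)]
    total = coded.sum(axis=1, skipna=False)
    return total.to_frame(definition.scale_id)


def score_domains(items: LikertItemMatrix, definition: ScaleDefinition) -> pd.DataFrame:
    """Per-domain score = (mean of the domain's items) x 4.

    On 1-5 coding each domain score lies in [4, 20].  Domains with any
    missing item yield NaN for that respondent.  Returns a DataFrame with
    one column per domain.
    """
    if definition.scoring_rule != "domain_mean_times_4":
        raise ConfigurationError(
            f"score_domains requires scoring_rule='domain_mean_times_4', got "
            f"{definition.scoring_rule!r}"
        )
    if not definition.domain_partition:
        raise ConfigurationError(
            f"scale {definition.scale_id!r} has no domain_partition"
        )
    coded = _check_items(items, definition)
    out = {}
    for domain, domain_items in definition.domain_partition.items():
        out[domain] = coded[list(domain_items)].mean(axis=1, skipna=False) * 4.0
    return pd.DataFrame(out, index=items.responses.index)


def cronbach_alpha(
    items: LikertItemMatrix, name: str | None = None
) -> ReliabilityResult:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/variance(total)).

    Sample variances use denominator n-1; respondents with any missing item
    are dropped listwise for this computation.  Alpha is at most 1 but may
    be negative for pathological data; it is reported as computed.
    """
    k = items.n_items
    if k < 2:
        raise ValidationError(f"need at least 2 items for alpha, got {k}")
    complete = items.responses.dropna(axis=0, how="any")
    n = len(complete)
    if n < 2:
        raise ValidationError(
            f"need at least 2 complete respondents for alpha, got {n}"
        )
    vals = complete.to_numpy(dtype=float)
    item_vars = vals.var(axis=0, ddof=1)
    total_var = vals.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedResultError(
            "total-score variance is zero; alpha is undefined"
        )
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityResult(name or items.scale_id, float(alpha), k, n)


# ---------------------------------------------------------------------------
# Shipped presets
# ---------------------------------------------------------------------------

#: 9-item perceived HIV stigma scale, items coded 0 (strongly disagree) to
#: 3 (strongly agree), summed to a 0-27 composite.  The published item
#: wordings are not fully reproduced anywhere public, so the item ids are
#: positional placeholders.
STIGMA_SCALE = ScaleDefinition(
    scale_id="stigma",
    item_ids=tuple(f"stig{i}" for i in range(1, 10)),
    response_min=0,
    response_max=3,
    scoring_rule="composite_sum",
)

#: WHOQOL-BREF, 26 items coded 1-5.  The two overall items (q1 general QOL,
#: q2 general health) are excluded from the four domains.  Reverse-scored
#: items follow the standard instrument (pain q3, medication dependence q4,
#: negative feelings q26).
WHOQOL_BREF = ScaleDefinition(
    scale_id="whoqol_bref",
    item_ids=tuple(f"q{i}" for i in range(1, 27)),
    response_min=1,
    response_max=5,
    scoring_rule="domain_mean_times_4",
    reverse_items=("q3", "q4", "q26"),
    domain_partition={
        "phys": ("q3", "q4", "q10", "q15", "q16", "q17", "q18"),
        "psych": ("q5", "q6", "q7", "q11", "q19", "q26"),
        "soc": ("q20", "q21", "q22"),
        "env": ("q8", "q9", "q12", "q13", "q14", "q23", "q24", "q25"),
    },
)

SCALE_PRESETS: dict[str, ScaleDefinition] = {
    "stigma": STIGMA_SCALE,
    "whoqol_bref": WHOQOL_BREF,
}
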