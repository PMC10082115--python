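"""Shared column schema, result containers and small utilities.

The cohort table is a plain :class:`pandas.DataFrame` with one row per
unrelated participant and a fixed column schema: a continuous polygenic
score (``pgs``), its cohort-specific quintile (``exposure_quintile``,
1 = lowest liability), the mediator (``mediator``, average minutes/day of
moderate-to-vigorous physical activity), the outcome (``outcome``, BMI in
kg/m^2) and three confounders (child ``sex``, ordinal
``maternal_education``, continuous ``maternal_bmi``).  Missing cells are
``NaN``; on disk they are empty CSV fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# -- column schema ----------------------------------------------------------

PGS = "pgs"
EXPOSURE = "exposure_quintile"
MEDIATOR = "mediator"
OUTCOME = "outcome"
SEX = "sex"
EDUCATION = "maternal_education"
MATERNAL_BMI = "maternal_bmi"

CONFOUNDERS = (SEX, EDUCATION, MATERNAL_BMI)
COHORT_COLUMNS = (PGS, EXPOSURE, MEDIATOR, OUTCOME) + CONFOUNDERS

#: variables that may enter analysis / imputation models
ANALYSIS_VARIABLES = (PGS, MEDIATOR, OUTCOME) + CONFOUNDERS


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer sub-seeds (< 2**31) from ``seed``."""
    ss = np.random.SeedSequence(int(seed))
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


# -- estimand container -----------------------------------------------------


@dataclass
class DisparityEstimate:
    """Per-contrast Adjusted Total Association and IDM direct effect.

    ``difference`` is a derived property, so the identity
    ``difference_j == adj_ta_j - idm_de_j`` holds exactly by construction.
    All values are in outcome units (kg/m^2).
    """

    reference: int
    adj_ta: dict[int, float]
    idm_de: dict[int, float]
    k: int | None = None
    n: int | None = None
    adj_ta_se: dict[int, float] | None = None
    idm_de_mc_se: dict[int, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.adj_ta) != set(self.idm_de):
            raise ValidationError(
                "adj_ta and idm_de must cover the same contrasts; got "
                f"{sorted(self.adj_ta)} vs {sorted(self.idm_de)}"
            )

    @property
    def contrasts(self) -> tuple[int, ...]:
        return tuple(sorted(self.adj_ta))

    @property
    def difference(self) -> dict[int, float]:
        return {j: self.adj_ta[j] - self.idm_de[j] for j in self.contrasts}

    def to_frame(self) -> pd.DataFrame:
        """One row per contrast: (contrast, adj_ta, idm_de, difference)."""
        rows = [
            {
                "contrast": j,
                "adj_ta": self.adj_ta[j],
                "idm_de": self.idm_de[j],
                "difference": self.difference[j],
            }
            for j in self.contrasts
        ]
        return pd.DataFrame(rows)


def validate_cohort(df: pd.DataFrame, require: tuple[str, ...] = COHORT_COLUMNS) -> None:
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table is missing columns: {missing}")
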