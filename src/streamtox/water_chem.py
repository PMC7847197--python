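"""Hardness-adjusted water-quality criteria and cumulative criterion units.

Dissolved metal concentrations in soft water are scored against the U.S. EPA
freshwater chronic ambient water-quality criteria (CCC), which for Cu, Zn, Cd
and Pb are hardness equations of the form

    criterion = exp(mA * ln(hardness) + bA) * CF      [µg/L dissolved]

where CF converts a total-recoverable criterion to a dissolved one and is
itself hardness-dependent for Cd and Pb.  The cumulative criterion unit (CCU)
is the sum over metals of measured dissolved concentration divided by its
criterion; CCU > 1 flags potential risk from the metal mixture.

Concentrations below the limit of quantification (LOQ) are censored and must
be substituted before summation; the substitution policy is explicit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Metal",
    "MetalConcentration",
    "CriterionSet",
    "CCUResult",
    "CensoringPolicy",
    "CHRONIC_CRITERION_CONSTANTS",
    "DEFAULT_LOQ",
    "compute_hardness",
    "hardness_adjusted_criterion",
    "compute_ccu",
    "ccu_table",
]


class Metal(str, Enum):
    """The four metals scored against chronic criteria."""

    CU = "Cu"
    ZN = "Zn"
    CD = "Cd"
    PB = "Pb"


class CensoringPolicy(str, Enum):
    """Substitution rule for concentrations below the LOQ."""

    ZERO = "zero"
    HALF_LOQ = "half_loq"
    LOQ = "loq"


# Freshwater chronic (CCC) hardness-equation constants from the U.S. EPA
# 2006 national recommended water-quality criteria tables.
# Each entry: (mA, bA, conversion factor).  For Cd and Pb the dissolved
# conversion factor is hardness-dependent: CF = cf_a - ln(H) * cf_b.
CHRONIC_CRITERION_CONSTANTS: dict[Metal, dict[str, float]] = {
    Metal.CU: {"mA": 0.8545, "bA": -1.702, "cf_a": 0.960, "cf_b": 0.0},
    Metal.ZN: {"mA": 0.8473, "bA": 0.884, "cf_a": 0.986, "cf_b": 0.0},
    Metal.CD: {"mA": 0.7409, "bA": -4.719, "cf_a": 1.101672, "cf_b": 0.041838},
    Metal.PB: {"mA": 1.273, "bA": -4.705, "cf_a": 1.46203, "cf_b": 0.145712},
}

# Analytical limits of quantification (µg/L) for dissolved metals by ICP-MS.
DEFAULT_LOQ: dict[Metal, float] = {
    Metal.CU: 0.001,
    Metal.ZN: 0.06,
    Metal.CD: 0.005,
    Metal.PB: 0.005,
}

# Lower end of the hardness range of the toxicity data behind the criteria;
# criteria extrapolated below this carry an interpretation caveat.
HARDNESS_CALIBRATION_FLOOR = 20.0


def compute_hardness(ca: float, mg: float) -> float:
    """Water hardness (mg/L as CaCO3) from dissolved Ca and Mg (mg/L).

    hardness = 2.497 * [Ca2+] + 4.118 * [Mg2+]
    """
    if ca < 0 or mg < 0:
        raise ValueError(f"Ca and Mg must be non-negative, got ca={ca}, mg={mg}")
    return 2.497 * ca + 4.118 * mg


def _conversion_factor(metal: Metal, hardness: float) -> float:
    c = CHRONIC_CRITERION_CONSTANTS[metal]
    return c["cf_a"] - math.log(hardness) * c["cf_b"]


def hardness_adjusted_criterion(metal: Metal | str, hardness: float) -> float:
    """Chronic dissolved criterion (µg/L) for one metal at a given hardness.

    Evaluates exp(mA*ln(H) + bA) * CF with the embedded chronic constants.
    Hardness below 20 mg/L is outside the calibration range of the criteria;
    the value is still computed but a warning is logged.
    """
    metal = Metal(metal)
    if hardness <= 0:
        raise ValueError(f"hardness must be positive, got {hardness}")
    if hardness < HARDNESS_CALIBRATION_FLOOR:
        logger.warning(
            "hardness %.3g mg/L is below the %.0f mg/L calibration floor of the "
            "criteria; interpret the resulting criterion with caution",
            hardness,
            HARDNESS_CALIBRATION_FLOOR,
        )
    c = CHRONIC_CRITERION_CONSTANTS[metal]
    return math.exp(c["mA"] * math.log(hardness) + c["bA"]) * _conversion_factor(
        metal, hardness
    )


@dataclass(frozen=True)
class MetalConcentration:
    """One dissolved-metal measurement, possibly censored below the LOQ."""

    metal: Metal
    value: float
    censored: bool = False
    loq: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "metal", Metal(self.metal))
        if self.loq is None:
            object.__setattr__(self, "loq", DEFAULT_LOQ[self.metal])
        if self.loq <= 0:
            raise ValueError(f"loq must be positive, got {self.loq}")
        if not self.censored and self.value < 0:
            raise ValueError(f"concentration must be non-negative, got {self.value}")

    def resolved(self, policy: CensoringPolicy) -> float:
        """Concentration after applying the censoring policy."""
        if not self.censored:
            return self.value
        policy = CensoringPolicy(policy)
        if policy is CensoringPolicy.ZERO:
            return 0.0
        if policy is CensoringPolicy.HALF_LOQ:
            return self.loq / 2.0
        return self.loq


@dataclass(frozen=True)
class CriterionSet:
    """Per-metal chronic criteria (µg/L) at a single water hardness."""

    hardness: float
    criteria: Mapping[Metal, float]

    @classmethod
    def from_hardness(cls, hardness: float) -> "CriterionSet":
        """Evaluate the four hardness equations at the given hardness."""
        return cls(
            hardness=hardness,
            criteria={m: hardness_adjusted_criterion(m, hardness) for m in Metal},
        )

    def rounded(self) -> "CriterionSet":
        """Criteria rounded to reporting precision (1 decimal for Cu/Zn,
        2 decimals for Cd/Pb), as printed in site-survey tables."""
        decimals = {Metal.CU: 1, Metal.ZN: 1, Metal.CD: 2, Metal.PB: 2}
        return CriterionSet(
            hardness=self.hardness,
            criteria={m: round(v, decimals[m]) for m, v in self.criteria.items()},
        )

    def __getitem__(self, metal: Metal | str) -> float:
        return self.criteria[Metal(metal)]


@dataclass
class CCUResult:
    """Cumulative criterion unit for one water sample or site mean."""

    site: str
    ratios: dict[Metal, float]
    ccu: float
    policy: CensoringPolicy
    warnings: list[str] = field(default_factory=list)


def compute_ccu(
    sample: Iterable[MetalConcentration],
    criteria: CriterionSet,
    policy: CensoringPolicy | str = CensoringPolicy.ZERO,
    site: str = "",
) -> CCUResult:
    """CCU = Σ m_i / c_i over the metals in the sample.

    Censored values are substituted per ``policy`` before the ratios are
    summed.  Per-metal ratios are retained for reporting.  A sample whose
    metals lack a criterion raises; an all-censored sample is valid (its CCU
    is whatever the policy implies, zero under zero-substitution).
    """
    policy = CensoringPolicy(policy)
    ratios: dict[Metal, float] = {}
    warnings: list[str] = []
    for conc in sample:
        if conc.metal in ratios:
            raise ValueError(f"duplicate measurement for {conc.metal.value}")
        try:
            criterion = criteria[conc.metal]
        except KeyError:
            raise KeyError(
                f"no criterion available for metal {conc.metal.value}"
            ) from None
        ratios[conc.metal] = conc.resolved(policy) / criterion
        if conc.censored:
            warnings.append(
                f"{conc.metal.value} below LOQ ({conc.loq} µg/L); "
                f"substituted per policy '{policy.value}'"
            )
    return CCUResult(
        site=site, ratios=ratios, ccu=sum(ratios.values()), policy=policy,
        warnings=warnings,
    )


def ccu_table(
    water: pd.DataFrame,
    criteria: CriterionSet,
    policy: CensoringPolicy | str = CensoringPolicy.ZERO,
) -> pd.DataFrame:
    """Site-level CCU report from a long-form water table.

    ``water`` needs columns site, metal, value, censored (bool) and
    optionally loq and replicate.  Replicates are averaged per site and
    metal *after* censoring substitution (a censored replicate contributes
    its substituted value to the mean).  Returns one row per site with
    per-metal ratio columns, the CCU and the policy used.
    """
    policy = CensoringPolicy(policy)
    required = {"site", "metal", "value", "censored"}
    missing = required - set(water.columns)
    if missing:
        raise ValueError(f"water table missing columns: {sorted(missing)}")

    df = water.copy()
    df["metal"] = df["metal"].map(Metal)
    if "loq" not in df.columns:
        df["loq"] = df["metal"].map(DEFAULT_LOQ)
    df["resolved"] = [
        MetalConcentration(m, v, bool(c), q).resolved(policy)
        for m, v, c, q in zip(df["metal"], df["value"], df["censored"], df["loq"])
    ]
    site_means = df.groupby(["site", "metal"], observed=True, sort=False)[
        "resolved"
    ].mean()

    rows = []
    for site_id, per_metal in site_means.groupby(level="site", sort=False):
        ratios = {
            metal: conc / criteria[metal]
            for (_, metal), conc in per_metal.items()
        }
        row: dict[str, object] = {"site": site_id}
        row.update({f"ratio_{m.value}": r for m, r in ratios.items()})
        row["ccu"] = sum(ratios.values())
        row["policy"] = policy.value
        rows.append(row)
    return pd.DataFrame(rows)
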