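"""Fish population metrics: abundance, condition factor, hatchery proportion.

Fish are collected by single-pass electrofishing (plus cast-netting) in five
~50 m² sampling areas per site.  Abundance is the number of individuals per
sampling area, log10(x+1)-transformed before site means/SEs; the Fulton-type
condition factor CF = 1000·W/L³ (weight in g, fork length in cm) is computed
per individual and pooled within sites.  Where hatchery-reared conspecifics
were stocked, a per-site otolith-mark subsample estimates the hatchery
proportion, and wild abundance is obtained by scaling the area counts by
(1 − proportion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_metrics import summarize_by_site

__all__ = [
    "condition_factor",
    "abundance_by_area",
    "abundance_summary",
    "HatcheryProportion",
    "hatchery_proportion",
    "wild_abundance",
    "species_to_analyze",
]

NOMINAL_AREA_M2 = 50.0
# Site-wide capture total at or below which a species is dropped from the
# analysis (too few individuals for meaningful site comparisons).
DEFAULT_RARE_SPECIES_FLOOR = 5


def condition_factor(weight_g, fork_length_cm):
    """Fulton-type condition factor, CF = body weight (g) / fork length (cm)³ × 1000.

    Accepts scalars or arrays; all inputs must be strictly positive.
    """
    w = np.asarray(weight_g, dtype=float)
    length = np.asarray(fork_length_cm, dtype=float)
    if (w <= 0).any() or (length <= 0).any():
        raise ValueError("weight and fork length must be strictly positive")
    cf = 1000.0 * w / length**3
    return float(cf) if cf.ndim == 0 else cf


def abundance_by_area(
    captures: pd.DataFrame, species: str, areas: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Counts of one species per (site, area), including zero-catch areas.

    ``captures`` has one row per fish with columns site, area, species.
    ``areas`` optionally enumerates every sampled (site, area) so areas with
    no catch contribute zeros; if omitted the areas present in ``captures``
    (any species) are used.
    """
    if areas is not None:
        index = pd.MultiIndex.from_frame(areas[["site", "area"]])
    else:
        index = pd.MultiIndex.from_frame(
            captures[["site", "area"]].drop_duplicates()
        )
    sub = captures[captures["species"] == species]
    counts = sub.groupby(["site", "area"]).size()
    return counts.reindex(index, fill_value=0).rename("count").to_frame()


def abundance_summary(
    area_counts: pd.DataFrame, metric_name: str = "abundance"
) -> pd.DataFrame:
    """Site mean and SE of log10(count+1) over the replicate sampling areas.

    ``area_counts`` is the output of :func:`abundance_by_area` (or any frame
    with a (site, area) index and a single count column, counts per nominal
    50 m² area).  Returns a tidy frame site, metric, mean, se, n.
    """
    values = area_counts.iloc[:, [0]].rename(
        columns={area_counts.columns[0]: metric_name}
    )
    return summarize_by_site(values, transform="log10p1")


@dataclass(frozen=True)
class HatcheryProportion:
    """Hatchery-origin proportion from an otolith-mark subsample."""

    site: str
    n_hatchery: int
    n_checked: int

    @property
    def proportion(self) -> float:
        return self.n_hatchery / self.n_checked

    @property
    def percent(self) -> int:
        """Proportion as a rounded whole percentage (reporting convention)."""
        return round(100 * self.proportion)


def hatchery_proportion(marks, site: str = "") -> HatcheryProportion:
    """Estimate the hatchery proportion from a list of origin marks.

    ``marks`` is an iterable over {'wild', 'hatchery'} read from otoliths.
    The estimator is the simple binomial fraction; raw counts are retained.
    """
    marks = list(marks)
    if not marks:
        raise ValueError("empty otolith subsample: proportion undefined")
    bad = {m for m in marks if m not in ("wild", "hatchery")}
    if bad:
        raise ValueError(f"unknown origin marks: {sorted(bad)}")
    return HatcheryProportion(
        site=site,
        n_hatchery=sum(m == "hatchery" for m in marks),
        n_checked=len(marks),
    )


def wild_abundance(area_counts: pd.DataFrame, proportion: float) -> pd.DataFrame:
    """Scale per-area counts by (1 − hatchery proportion).

    The adjusted counts are generally non-integer; downstream transforms
    operate on reals, so no rounding is applied.
    """
    if not 0 <= proportion <= 1:
        raise ValueError(f"proportion must lie in [0, 1], got {proportion}")
    return area_counts * (1.0 - proportion)


def species_to_analyze(
    captures: pd.DataFrame, floor: int = DEFAULT_RARE_SPECIES_FLOOR
) -> list[str]:
    """Species with more than ``floor`` captures in total, in catch order.

    Species at or below the floor (e.g. a couple of stray cyprinids) are
    excluded from abundance and condition-factor comparisons.
    """
    totals = captures.groupby("species", sort=False).size()
    return [s for s, n in totals.items() if n > floor]
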