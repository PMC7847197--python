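"""Benthic macroinvertebrate community metrics from stone-level counts.

The replicate unit is a single riffle stone sampled with a Surber-type net.
From a stones × taxa count table and a taxonomy (taxon → family, order) the
module computes, per stone, eight community metrics — total abundance, total
taxon richness, and order-level abundance and richness for the three major
aquatic insect orders (Ephemeroptera, Trichoptera, Diptera) — plus the
abundances of "dominant" families selected by a share-of-abundance and an
occupancy rule.  Abundances are log10(x+1)-transformed per stone before site
means and standard errors are taken; richness metrics stay on the count
scale.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "MAJOR_ORDERS",
    "ABUNDANCE_METRICS",
    "RICHNESS_METRICS",
    "stone_metrics",
    "dominant_families",
    "family_abundances",
    "summarize_by_site",
]

MAJOR_ORDERS = ("Ephemeroptera", "Trichoptera", "Diptera")

ABUNDANCE_METRICS = (
    "total_abundance",
    "ephemeroptera_abundance",
    "trichoptera_abundance",
    "diptera_abundance",
)
RICHNESS_METRICS = (
    "total_richness",
    "ephemeroptera_richness",
    "trichoptera_richness",
    "diptera_richness",
)


def _check_taxonomy(counts: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Validate and index the taxonomy against the count table's taxa."""
    required = {"taxon", "family", "order"}
    missing = required - set(taxonomy.columns)
    if missing:
        raise ValueError(f"taxonomy missing columns: {sorted(missing)}")
    tax = taxonomy.set_index("taxon")
    unknown = [t for t in counts.columns if t not in tax.index]
    if unknown:
        raise ValueError(f"taxa without taxonomy entries: {unknown}")
    bad = tax.loc[list(counts.columns)]["order"].isna()
    if bad.any():
        raise ValueError(
            f"taxa with unresolved order: {list(bad.index[bad])}"
        )
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return tax


def stone_metrics(counts: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Per-stone values of the eight community metrics.

    Parameters
    ----------
    counts
        Stones × taxa count table; index identifies the stone (conventionally
        a (site, stone) MultiIndex), columns are taxon names.
    taxonomy
        Columns taxon, family, order.  Every taxon in ``counts`` must resolve
        to an order; counts identified above family level (family = NA) still
        contribute to order-level metrics.

    Returns
    -------
    DataFrame with one row per stone and the eight metric columns.  Richness
    is the number of distinct taxa with count > 0.
    """
    tax = _check_taxonomy(counts, taxonomy)
    arr = counts.to_numpy(dtype=float)
    present = arr > 0
    out = pd.DataFrame(index=counts.index)
    out["total_abundance"] = arr.sum(axis=1)
    out["total_richness"] = present.sum(axis=1)
    orders = tax.loc[list(counts.columns)]["order"].to_numpy()
    for order in MAJOR_ORDERS:
        mask = orders == order
        key = order.lower()
        out[f"{key}_abundance"] = arr[:, mask].sum(axis=1)
        out[f"{key}_richness"] = present[:, mask].sum(axis=1)
    return out


def dominant_families(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    share_threshold: float = 0.05,
    occupancy_threshold: float = 0.30,
    share_scope: Literal["any_stone", "all_stones"] = "any_stone",
) -> set[str]:
    """Families dominating the assemblage, by a share rule and an occupancy rule.

    A family qualifies iff

    * its share of a stone's total abundance exceeds ``share_threshold``
      on at least one stone (``share_scope='any_stone'``, the default) or on
      every stone where anything was collected (``'all_stones'``), and
    * it occurs (count > 0) on strictly more than
      ``ceil(occupancy_threshold * n_stones)`` of all stones pooled across
      sites — with the 30% default and the 45-stone reference design this is
      "more than 14 stones", i.e. at least 15.

    Counts not resolved to family (family = NA in the taxonomy) are ignored
    by both rules.
    """
    if not 0 < share_threshold < 1 or not 0 < occupancy_threshold < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    tax = _check_taxonomy(counts, taxonomy)
    families = tax.loc[list(counts.columns)]["family"]
    by_family = counts.T.groupby(families.values).sum().T  # stones × families
    stone_totals = counts.sum(axis=1)

    n_stones = len(counts)
    min_stones = math.ceil(occupancy_threshold * n_stones)
    occupancy = (by_family > 0).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        shares = by_family.div(stone_totals, axis=0)
    nonempty = stone_totals > 0
    if share_scope == "any_stone":
        share_ok = (shares[nonempty] > share_threshold).any(axis=0)
    elif share_scope == "all_stones":
        share_ok = (shares[nonempty] > share_threshold).all(axis=0)
    else:
        raise ValueError(f"unknown share_scope {share_scope!r}")

    qualified = share_ok & (occupancy > min_stones)
    return set(qualified.index[qualified])


def family_abundances(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, families: Iterable[str]
) -> pd.DataFrame:
    """Per-stone summed counts for the given families (columns in that order)."""
    tax = _check_taxonomy(counts, taxonomy)
    fam = tax.loc[list(counts.columns)]["family"]
    out = pd.DataFrame(index=counts.index)
    for family in families:
        cols = [t for t, f in fam.items() if f == family]
        out[family] = counts[cols].sum(axis=1) if cols else 0.0
    return out


def summarize_by_site(
    values: pd.DataFrame,
    transform: Literal["log10p1", "none"] = "none",
    site_level: str | int = 0,
) -> pd.DataFrame:
    """Site means and standard errors of per-stone metric values.

    Abundance metrics are log10(x+1)-transformed per stone *before*
    averaging (``transform='log10p1'``); richness metrics are left on the
    count scale (``'none'``).  The standard error is sd/sqrt(n) over the
    stones of a site; a single-stone site yields its mean with the SE flagged
    undefined (NaN).

    Returns a tidy frame: site, metric, mean, se, n.
    """
    if transform == "log10p1":
        values = np.log10(values + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    grouped = values.groupby(level=site_level, sort=False)
    mean = grouped.mean()
    n = grouped.size()
    se = grouped.std(ddof=1).div(np.sqrt(n), axis=0)
    tidy = (
        pd.concat({"mean": mean, "se": se}, axis=1)
        .stack(future_stack=True)
        .reset_index()
    )
    tidy.columns = ["site", "metric", "mean", "se"]
    tidy["n"] = tidy["site"].map(n)
    return tidy[["site", "metric", "mean", "se", "n"]]
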