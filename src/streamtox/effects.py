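"""Reference ranges, multiplicity-adjusted paired contrasts, effect labels.

The assessment asks two independent questions about each biological metric at
each contaminated site:

1. **Range gate** — is the contaminated-site mean outside the "reference
   range", the 90% prediction interval for a new site mean obtained from an
   intercept-only regression on the reference-site means?  With n reference
   means of sample SD s the closed form is

       mean ± t_{1-α/2, n-1} · s · sqrt(1 + 1/n)

2. **Test gate** — is the contaminated site significantly different from its
   elevation-matched reference site?  A one-way fixed-effects ANOVA is fitted
   over all sites on the analysis-scale replicate values, the paired
   contrasts are formed, and p-values are adjusted by the single-step max-|t|
   method: p_i = 1 − P(max_j |T_j| ≤ |t_i|) under the central multivariate t
   with the contrasts' correlation matrix and the residual degrees of
   freedom.

The two gates combine into a three-way label: both triggered → ``adverse``;
exactly one → ``some_concern``; neither → ``no_concern``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SiteDesign",
    "ReferenceRange",
    "ContrastResult",
    "EffectClassification",
    "reference_range",
    "paired_contrasts",
    "singlestep_adjusted_p",
    "classify",
    "percent_difference",
    "assess_metric",
]

# Seed of the quasi-random multivariate-t integration; fixed so adjusted
# p-values are reproducible run to run.  Integration tolerance ~1e-4.
DEFAULT_MVT_SEED = 20180626
_MAXPTS_PER_DIM = 25_000


@dataclass(frozen=True)
class SiteDesign:
    """Contaminated/reference status and contaminated → reference pairing.

    ``pairs`` maps each contaminated site to its elevation-matched reference
    site; many-to-one is allowed (two adjacent contaminated sites may share
    one reference).
    """

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("design needs at least one contaminated/reference pair")
        overlap = set(self.pairs) & set(self.pairs.values())
        if overlap:
            raise ValueError(f"sites cannot be both contaminated and reference: {overlap}")

    @property
    def contaminated(self) -> list[str]:
        return list(self.pairs)

    @property
    def reference(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.pairs.values():
            seen.setdefault(r)
        return list(seen)

    @property
    def sites(self) -> list[str]:
        return self.contaminated + self.reference


@dataclass(frozen=True)
class ReferenceRange:
    """90% (by default) prediction interval for a new reference-site mean."""

    metric: str
    mean: float
    lower: float
    upper: float
    n_ref: int
    alpha: float
    defined: bool = True

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass(frozen=True)
class ContrastResult:
    """One contaminated-vs-reference contrast from the pooled ANOVA."""

    metric: str
    contaminated: str
    reference: str
    estimate: float  # contaminated − reference, analysis scale
    t: float
    df: float
    p_raw: float
    p_adjusted: float

    @property
    def direction(self) -> Literal["lower", "higher", "none"]:
        if self.estimate < 0:
            return "lower"
        if self.estimate > 0:
            return "higher"
        return "none"


@dataclass(frozen=True)
class EffectClassification:
    """Three-way label from the range gate and the test gate."""

    metric: str
    contaminated: str
    outside_range: bool
    range_direction: Literal["lower", "higher", "none"]
    significant: bool
    test_direction: Literal["lower", "higher", "none"]
    p_adjusted: float
    label: Literal["adverse", "some_concern", "no_concern"]
    notes: tuple[str, ...] = field(default_factory=tuple)


def reference_range(
    ref_means: Sequence[float], alpha: float = 0.10, metric: str = ""
) -> ReferenceRange:
    """Prediction interval for a new site mean from the reference-site means.

    Equivalent to the prediction interval of an intercept-only least-squares
    fit to the n reference means.  With fewer than two reference means the
    interval is undefined and flagged (e.g. a species captured at a single
    reference site).
    """
    x = np.asarray(ref_means, dtype=float)
    if x.size < 2 or not np.isfinite(x).all():
        mean = float(x.mean()) if x.size else math.nan
        return ReferenceRange(
            metric=metric, mean=mean, lower=math.nan, upper=math.nan,
            n_ref=int(x.size), alpha=alpha, defined=False,
        )
    n = x.size
    mean = float(x.mean())
    s = float(x.std(ddof=1))
    half = stats.t.ppf(1 - alpha / 2, n - 1) * s * math.sqrt(1 + 1 / n)
    return ReferenceRange(
        metric=metric, mean=mean, lower=mean - half, upper=mean + half,
        n_ref=n, alpha=alpha,
    )


def singlestep_adjusted_p(
    t_stats: Sequence[float],
    corr: np.ndarray,
    df: float,
    seed: int = DEFAULT_MVT_SEED,
    maxpts_per_dim: int = _MAXPTS_PER_DIM,
) -> np.ndarray:
    """Single-step max-|t| adjusted p-values.

    p_i = 1 − P(∩_j |T_j| ≤ |t_i|) where T follows the central multivariate
    t with correlation ``corr`` and ``df`` degrees of freedom.  A single
    contrast reduces to the ordinary two-sided t p-value, computed exactly;
    the joint probability for k ≥ 2 is evaluated by quasi-random integration
    with a fixed seed.
    """
    t_abs = np.abs(np.asarray(t_stats, dtype=float))
    k = t_abs.size
    if k == 1:
        return np.atleast_1d(2 * stats.t.sf(t_abs, df))
    mvt = stats.multivariate_t(shape=np.asarray(corr), df=df, allow_singular=True)
    out = np.empty(k)
    for i, ti in enumerate(t_abs):
        if not np.isfinite(ti):
            out[i] = 0.0
            continue
        joint = mvt.cdf(
            np.full(k, ti),
            lower_limit=np.full(k, -ti),
            random_state=np.random.default_rng(seed),
            maxpts=maxpts_per_dim * k,
        )
        out[i] = min(max(1.0 - float(joint), 2 * float(stats.t.sf(ti, df))), 1.0)
    return out


def _group_stats(values: pd.DataFrame) -> pd.DataFrame:
    g = values.groupby("site", sort=False)["value"]
    return pd.DataFrame({"mean": g.mean(), "n": g.size(), "sse": g.apply(
        lambda x: float(((x - x.mean()) ** 2).sum())
    )})


def paired_contrasts(
    values: pd.DataFrame,
    design: SiteDesign,
    metric: str = "",
    variance: Literal["pooled", "welch"] = "pooled",
    seed: int = DEFAULT_MVT_SEED,
    maxpts_per_dim: int = _MAXPTS_PER_DIM,
) -> list[ContrastResult]:
    """ANOVA followed by single-step adjusted contaminated-vs-reference contrasts.

    ``values`` is a tidy frame with columns site, value holding the
    replicate-level observations on the analysis scale (log10(x+1) replicate
    values for abundances, raw counts for richness, individual fish for the
    condition factor).

    ``variance='pooled'`` (default) fits one homogeneous-variance one-way
    model over every site in the design, giving pooled-variance t statistics
    with the residual degrees of freedom and the exact contrast correlation
    (contrasts sharing a reference site are positively correlated).
    ``'welch'`` is a sensitivity option using per-pair Welch statistics; the
    joint adjustment then uses the smallest Welch df (conservative).
    """
    if not {"site", "value"} <= set(values.columns):
        raise ValueError("values needs columns 'site' and 'value'")
    values = values[values["site"].isin(design.sites)]
    missing = set(design.sites) - set(values["site"])
    if missing:
        raise ValueError(f"no observations for sites: {sorted(missing)}")
    g = _group_stats(values)
    if (g["n"] < 2).any():
        raise ValueError("every site needs at least two replicates")

    pairs = list(design.pairs.items())
    k = len(pairs)
    if variance == "pooled":
        df_resid = float(g["n"].sum() - len(g))
        mse = g["sse"].sum() / df_resid
        if mse == 0:
            logger.warning("zero residual variance: degenerate model for %s", metric)
        var_c = np.array([mse * (1 / g.loc[c, "n"] + 1 / g.loc[r, "n"]) for c, r in pairs])
        dfs = np.full(k, df_resid)
        # cov between contrasts: shared contaminated or reference site means
        cov = np.zeros((k, k))
        for i, (ci, ri) in enumerate(pairs):
            for j, (cj, rj) in enumerate(pairs):
                cov[i, j] = mse * (
                    (ci == cj) / g.loc[ci, "n"] + (ri == rj) / g.loc[ri, "n"]
                )
    elif variance == "welch":
        var_site = {
            s: g.loc[s, "sse"] / (g.loc[s, "n"] - 1) / g.loc[s, "n"] for s in g.index
        }
        var_c = np.array([var_site[c] + var_site[r] for c, r in pairs])
        dfs = np.array([
            (var_site[c] + var_site[r]) ** 2
            / (
                var_site[c] ** 2 / (g.loc[c, "n"] - 1)
                + var_site[r] ** 2 / (g.loc[r, "n"] - 1)
            )
            if var_site[c] + var_site[r] > 0 else np.nan
            for c, r in pairs
        ])
        cov = np.zeros((k, k))
        for i, (ci, ri) in enumerate(pairs):
            for j, (cj, rj) in enumerate(pairs):
                cov[i, j] = (ci == cj) * var_site[ci] + (ri == rj) * var_site[ri]
    else:
        raise ValueError(f"unknown variance option {variance!r}")

    est = np.array([g.loc[c, "mean"] - g.loc[r, "mean"] for c, r in pairs])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(var_c > 0, est / np.sqrt(var_c), np.where(est == 0, 0.0, np.inf))
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)

    df_joint = float(np.nanmin(dfs))
    p_adj = singlestep_adjusted_p(t_stats, corr, df_joint, seed=seed, maxpts_per_dim=maxpts_per_dim)
    results = []
    for i, (c, r) in enumerate(pairs):
        p_raw = float(2 * stats.t.sf(abs(t_stats[i]), dfs[i])) if np.isfinite(dfs[i]) else math.nan
        results.append(
            ContrastResult(
                metric=metric, contaminated=c, reference=r,
                estimate=float(est[i]), t=float(t_stats[i]), df=float(dfs[i]),
                p_raw=p_raw, p_adjusted=float(p_adj[i]),
            )
        )
    return results


def classify(
    range_: ReferenceRange,
    contrast: ContrastResult,
    site_mean: float,
    alpha_test: float = 0.05,
) -> EffectClassification:
    """Combine the range gate and the test gate into the three-way label.

    ``adverse`` requires both a mean outside the reference range and a
    significant adjusted contrast; either one alone is ``some_concern``;
    neither is ``no_concern``.  An undefined reference range leaves the
    range gate untriggered, with a note.
    """
    notes: list[str] = []
    if range_.defined:
        if site_mean < range_.lower:
            outside, range_dir = True, "lower"
        elif site_mean > range_.upper:
            outside, range_dir = True, "higher"
        else:
            outside, range_dir = False, "none"
    else:
        outside, range_dir = False, "none"
        notes.append("reference range undefined (fewer than 2 reference means); range gate skipped")

    significant = contrast.p_adjusted < alpha_test
    label = (
        "adverse" if outside and significant
        else "some_concern" if outside or significant
        else "no_concern"
    )
    return EffectClassification(
        metric=contrast.metric,
        contaminated=contrast.contaminated,
        outside_range=outside,
        range_direction=range_dir,  # type: ignore[arg-type]
        significant=significant,
        test_direction=contrast.direction,
        p_adjusted=contrast.p_adjusted,
        label=label,  # type: ignore[arg-type]
        notes=tuple(notes),
    )


def percent_difference(
    contaminated_mean: float,
    reference_mean: float,
    scale: Literal["backtransformed", "raw_mean"] = "backtransformed",
) -> float:
    """Percent reduction at the contaminated site relative to its reference.

    Positive = lower at the contaminated site.  For log10(x+1)-scale
    abundance means the comparison is made on the back-transformed count
    scale (10^mean − 1) by default; ``raw_mean`` compares the means as given.
    """
    if scale == "backtransformed":
        c = 10 ** contaminated_mean - 1
        r = 10 ** reference_mean - 1
    elif scale == "raw_mean":
        c, r = contaminated_mean, reference_mean
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if r <= 0:
        raise ValueError("reference mean must be positive for a percent difference")
    return 100.0 * (r - c) / r


def assess_metric(
    values: pd.DataFrame,
    design: SiteDesign,
    metric: str = "",
    alpha_range: float = 0.10,
    alpha_test: float = 0.05,
    variance: Literal["pooled", "welch"] = "pooled",
    seed: int = DEFAULT_MVT_SEED,
    maxpts_per_dim: int = _MAXPTS_PER_DIM,
) -> list[EffectClassification]:
    """Run the full two-gate assessment of one metric.

    Site means are taken over the replicate values in ``values`` (already on
    the analysis scale); the reference range comes from the reference-site
    means, the contrasts from the pooled ANOVA.
    """
    site_means = values.groupby("site", sort=False)["value"].mean()
    ref_means = [site_means[r] for r in design.reference if r in site_means]
    range_ = reference_range(ref_means, alpha=alpha_range, metric=metric)
    contrasts = paired_contrasts(values, design, metric=metric, variance=variance, seed=seed, maxpts_per_dim=maxpts_per_dim)
    return [
        classify(range_, con, float(site_means[con.contaminated]), alpha_test=alpha_test)
        for con in contrasts
    ]
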