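"""End-to-end orchestration: simulate/read → CCU → metrics → assessment.

`run_pipeline` ties the modules together the way the field study is
analysed: water chemistry is scored into CCUs, stone counts become the eight
community metrics plus dominant-family abundances, fish captures become
per-area abundances and pooled condition factors, and every metric is pushed
through the two-gate classification against the paired reference sites.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_metrics as cm
from . import fish_metrics as fm
from .effects import DEFAULT_MVT_SEED, SiteDesign, assess_metric
from .io_tables import (
    read_counts,
    read_design,
    read_fish_areas,
    read_fish_captures,
    read_otoliths,
    read_taxonomy,
    read_water,
    write_table,
)
from .simulate import ScenarioConfig, generate_all
from .water_chem import CensoringPolicy, CriterionSet, ccu_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "community_value_frames", "fish_value_frames"]


@dataclass
class RunConfig:
    """Serializable description of one analysis run.

    Either set ``simulate=True`` (synthetic survey from ``scenario_seed``)
    or point the ``*_path`` fields at CSVs with the documented schemas —
    the latter is the re-analysis path for real survey data.
    """

    simulate: bool = True
    scenario_seed: int = 0
    water_path: str | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    fish_captures_path: str | None = None
    fish_areas_path: str | None = None
    otoliths_path: str | None = None
    design_path: str | None = None
    hardness: float = 10.0
    use_rounded_criteria: bool = True
    censoring_policy: str = "zero"
    alpha_range: float = 0.10
    alpha_test: float = 0.05
    share_scope: str = "any_stone"
    variance: str = "pooled"
    mvt_seed: int = DEFAULT_MVT_SEED
    out_dir: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))


def community_value_frames(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, share_scope: str = "any_stone"
) -> dict[str, pd.DataFrame]:
    """Replicate-level analysis-scale values per community metric.

    Abundance metrics (and dominant-family abundances) are log10(x+1) per
    stone; richness metrics stay on the count scale.  Each value is one
    stone.
    """
    stones = cm.stone_metrics(counts, taxonomy)
    frames: dict[str, pd.DataFrame] = {}
    for metric in cm.ABUNDANCE_METRICS:
        frames[metric] = _tidy(np.log10(stones[metric] + 1))
    for metric in cm.RICHNESS_METRICS:
        frames[metric] = _tidy(stones[metric])
    dominants = sorted(
        cm.dominant_families(counts, taxonomy, share_scope=share_scope)  # type: ignore[arg-type]
    )
    fam = cm.family_abundances(counts, taxonomy, dominants)
    for family in dominants:
        frames[f"{family}_abundance"] = _tidy(np.log10(fam[family] + 1))
    return frames


def fish_value_frames(
    captures: pd.DataFrame,
    areas: pd.DataFrame,
    otoliths: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Replicate-level values per fish metric.

    Abundance: one log10(count+1) value per sampling area, per analysed
    species.  Condition factor: one value per individual fish, pooled within
    sites.  With otolith data, wild-only abundance frames are added for the
    stocked salmonid.
    """
    frames: dict[str, pd.DataFrame] = {}
    for species in fm.species_to_analyze(captures):
        key = species.replace(" ", "_")
        area_counts = fm.abundance_by_area(captures, species, areas)
        frames[f"{key}_abundance"] = _tidy(
            np.log10(area_counts["count"] + 1), level="site"
        )
        sub = captures[captures["species"] == species]
        cf = fm.condition_factor(
            sub["weight_g"].to_numpy(), sub["fork_length_cm"].to_numpy()
        )
        frames[f"{key}_condition_factor"] = pd.DataFrame(
            {"site": sub["site"].to_numpy(), "value": cf}
        )
        if otoliths is not None and species == "masu salmon" and len(otoliths):
            props = {
                row["site"]: row["n_hatchery"] / row["n_checked"]
                for _, row in otoliths.iterrows()
            }
            wild = area_counts.copy()
            wild["count"] = [
                c * (1 - props.get(site, 0.0))
                for (site, _), c in area_counts["count"].items()
            ]
            frames[f"{key}_wild_abundance"] = _tidy(
                np.log10(wild["count"] + 1), level="site"
            )
    return frames


def _tidy(series: pd.Series, level: str | int = "site") -> pd.DataFrame:
    df = series.rename("value").reset_index()
    site_col = level if isinstance(level, str) else df.columns[level]
    return df[[site_col, "value"]].rename(columns={site_col: "site"})


def _load_tables(config: RunConfig) -> tuple[dict[str, pd.DataFrame], SiteDesign]:
    if config.simulate:
        scenario = ScenarioConfig(seed=config.scenario_seed)
        tables = generate_all(scenario)
        return tables, scenario.design
    paths = {
        "water": config.water_path,
        "counts": config.counts_path,
        "taxonomy": config.taxonomy_path,
        "fish_captures": config.fish_captures_path,
        "fish_areas": config.fish_areas_path,
        "design": config.design_path,
    }
    missing = [k for k, v in paths.items() if v is None]
    if missing:
        raise ValueError(f"non-simulated run needs paths for: {missing}")
    design, design_df = read_design(config.design_path)
    tables = {
        "water": read_water(config.water_path),
        "benthos": read_counts(config.counts_path),
        "taxonomy": read_taxonomy(config.taxonomy_path),
        "fish_captures": read_fish_captures(config.fish_captures_path),
        "fish_areas": read_fish_areas(config.fish_areas_path),
        "otoliths": read_otoliths(config.otoliths_path)
        if config.otoliths_path
        else pd.DataFrame(columns=["site", "n_checked", "n_hatchery"]),
        "design": design_df,
    }
    return tables, design


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full assessment; return (and optionally write) the reports.

    Returns a dict with keys ``ccu`` (site CCU report), ``community_metrics``
    and ``fish_metrics`` (tidy site summaries), and ``classification`` (the
    metric × contaminated-site effect labels).  With ``config.out_dir`` set,
    each table is written as CSV alongside the echoed YAML config.
    """
    tables, design = _load_tables(config)

    criteria = CriterionSet.from_hardness(config.hardness)
    if config.use_rounded_criteria:
        criteria = criteria.rounded()
    ccu = ccu_table(
        tables["water"], criteria, CensoringPolicy(config.censoring_policy)
    )

    stones = cm.stone_metrics(tables["benthos"], tables["taxonomy"])
    community_summary = pd.concat(
        [
            cm.summarize_by_site(stones[list(cm.ABUNDANCE_METRICS)], "log10p1"),
            cm.summarize_by_site(stones[list(cm.RICHNESS_METRICS)], "none"),
        ],
        ignore_index=True,
    )

    frames = community_value_frames(
        tables["benthos"], tables["taxonomy"], config.share_scope
    )
    fish_frames = fish_value_frames(
        tables["fish_captures"], tables["fish_areas"], tables["otoliths"]
    )

    fish_summary_parts = []
    for name, frame in fish_frames.items():
        g = frame.groupby("site", sort=False)["value"]
        n = g.size()
        fish_summary_parts.append(
            pd.DataFrame(
                {
                    "site": n.index,
                    "metric": name,
                    "mean": g.mean().values,
                    "se": (g.std(ddof=1) / np.sqrt(n)).values,
                    "n": n.values,
                }
            )
        )
    fish_summary = (
        pd.concat(fish_summary_parts, ignore_index=True)
        if fish_summary_parts
        else pd.DataFrame(columns=["site", "metric", "mean", "se", "n"])
    )
    frames.update(fish_frames)

    rows = []
    for name, frame in frames.items():
        try:
            classifications = assess_metric(
                frame,
                design,
                metric=name,
                alpha_range=config.alpha_range,
                alpha_test=config.alpha_test,
                variance=config.variance,  # type: ignore[arg-type]
                seed=config.mvt_seed,
            )
        except ValueError as err:
            logger.warning("metric %s skipped: %s", name, err)
            continue
        site_means = frame.groupby("site")["value"].mean()
        for c in classifications:
            rows.append(
                {
                    "metric": c.metric,
                    "site": c.contaminated,
                    "site_mean": float(site_means[c.contaminated]),
                    "outside_range": c.outside_range,
                    "range_direction": c.range_direction,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.significant,
                    "test_direction": c.test_direction,
                    "label": c.label,
                    "notes": "; ".join(c.notes),
                }
            )
    classification = pd.DataFrame(rows)

    reports = {
        "ccu": ccu,
        "community_metrics": community_summary,
        "fish_metrics": fish_summary,
        "classification": classification,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in reports.items():
            write_table(df, out / f"{name}.csv")
        (out / "run_config.yaml").write_text(config.to_yaml())
        logger.info("reports written to %s", out)
    return reports
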