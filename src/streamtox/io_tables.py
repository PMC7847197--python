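"""Delimited-text readers and writers for the survey tables.

All tables are plain UTF-8 CSV (comma, dot-decimal).  Water chemistry can be
given in long form (site, metal, value, censored[, loq, replicate]) or wide
form with one column per metal where below-LOQ cells carry tokens like
``<0.005``, which are parsed into censored measurements.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .effects import SiteDesign
from .water_chem import DEFAULT_LOQ, Metal

__all__ = [
    "parse_censored_token",
    "read_water",
    "read_counts",
    "read_taxonomy",
    "read_fish_captures",
    "read_fish_areas",
    "read_otoliths",
    "read_design",
    "write_table",
]

_METAL_NAMES = [m.value for m in Metal]


def parse_censored_token(cell) -> tuple[float, bool, float | None]:
    """Parse one concentration cell → (value, censored, loq or None).

    ``"<0.005"`` means censored below a LOQ of 0.005; a plain number is an
    uncensored measurement.
    """
    if isinstance(cell, str) and cell.strip().startswith("<"):
        loq = float(cell.strip()[1:])
        return float("nan"), True, loq
    return float(cell), False, None


def _require(df: pd.DataFrame, cols: set[str], what: str, path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{what} table {path}: missing columns {sorted(missing)}")


def read_water(path) -> pd.DataFrame:
    """Read water chemistry, normalizing to long form.

    Returns columns site, replicate, metal, value, censored, loq.  Wide
    tables (one column per metal) are melted; ``<LOQ`` tokens become
    censored rows.  Extra columns (status, hardness, ...) are preserved.
    """
    df = pd.read_csv(path, dtype={"site": str})
    if "metal" in df.columns:  # long form
        _require(df, {"site", "metal", "value"}, "water", path)
        out = df.copy()
        if out["value"].dtype == object:
            parsed = out["value"].map(parse_censored_token)
            out["value"] = [p[0] for p in parsed]
            if "censored" not in out.columns:
                out["censored"] = [p[1] for p in parsed]
            if "loq" not in out.columns:
                out["loq"] = [p[2] for p in parsed]
        if "censored" not in out.columns:
            out["censored"] = False
    else:  # wide form
        metal_cols = [c for c in df.columns if c in _METAL_NAMES]
        if not metal_cols:
            raise ValueError(f"water table {path}: no metal columns found")
        keep = [c for c in df.columns if c not in metal_cols]
        out = df.melt(
            id_vars=keep, value_vars=metal_cols, var_name="metal", value_name="raw"
        )
        parsed = out["raw"].map(parse_censored_token)
        out["value"] = [p[0] for p in parsed]
        out["censored"] = [p[1] for p in parsed]
        out["loq"] = [p[2] for p in parsed]
        out = out.drop(columns="raw")
    if "replicate" not in out.columns:
        out["replicate"] = 1
    out["censored"] = out["censored"].astype(bool)
    if "loq" not in out.columns:
        out["loq"] = None
    out["loq"] = [
        q if pd.notna(q) else DEFAULT_LOQ[Metal(m)]
        for q, m in zip(out["loq"], out["metal"])
    ]
    bad = ~out["metal"].isin(_METAL_NAMES)
    if bad.any():
        raise ValueError(
            f"water table {path}: unknown metals {sorted(out['metal'][bad].unique())}"
        )
    if ((~out["censored"]) & (out["value"] < 0)).any():
        raise ValueError(f"water table {path}: negative concentrations")
    return out


def read_counts(path) -> pd.DataFrame:
    """Stone-level taxon counts: CSV with site, stone key columns, taxa after."""
    df = pd.read_csv(path, dtype={"site": str})
    _require(df, {"site", "stone"}, "counts", path)
    if df.duplicated(["site", "stone"]).any():
        dupes = df[df.duplicated(["site", "stone"], keep=False)]
        raise ValueError(
            f"counts table {path}: duplicate stone keys "
            f"{sorted(set(map(tuple, dupes[['site', 'stone']].values)))}"
        )
    out = df.set_index(["site", "stone"])
    non_numeric = out.columns[
        ~out.apply(pd.api.types.is_numeric_dtype)
    ]
    if len(non_numeric):
        raise ValueError(
            f"counts table {path}: non-numeric count columns {list(non_numeric)}"
        )
    return out


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, {"taxon", "family", "order"}, "taxonomy", path)
    if df["taxon"].duplicated().any():
        raise ValueError(f"taxonomy {path}: duplicate taxon entries")
    return df


def read_fish_captures(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site": str})
    _require(df, {"site", "area", "species"}, "fish captures", path)
    if "fork_length_mm" in df.columns and "fork_length_cm" not in df.columns:
        df["fork_length_cm"] = df["fork_length_mm"] / 10.0
    return df


def read_fish_areas(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site": str})
    _require(df, {"site", "area"}, "fish areas", path)
    return df


def read_otoliths(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site": str})
    _require(df, {"site", "n_checked", "n_hatchery"}, "otolith", path)
    if (df["n_hatchery"] > df["n_checked"]).any():
        raise ValueError(f"otolith table {path}: n_hatchery exceeds n_checked")
    return df


def read_design(path) -> tuple[SiteDesign, pd.DataFrame]:
    """Site-design table → (SiteDesign, full frame).

    Columns: site, status ∈ {contaminated, reference}, paired_reference
    (blank for reference sites), optional elevation.
    """
    df = pd.read_csv(path, dtype={"site": str, "paired_reference": str})
    _require(df, {"site", "status", "paired_reference"}, "design", path)
    bad_status = set(df["status"]) - {"contaminated", "reference"}
    if bad_status:
        raise ValueError(f"design {path}: unknown status values {sorted(bad_status)}")
    refs = set(df.loc[df["status"] == "reference", "site"])
    pairs = {}
    for _, row in df[df["status"] == "contaminated"].iterrows():
        ref = row["paired_reference"]
        if pd.isna(ref) or ref == "":
            raise ValueError(f"design {path}: {row['site']} has no paired reference")
        if ref not in refs:
            raise ValueError(
                f"design {path}: {row['site']} paired to unknown reference {ref!r}"
            )
        pairs[row["site"]] = ref
    return SiteDesign(pairs=pairs), df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=isinstance(df.index, pd.MultiIndex))
    return path
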