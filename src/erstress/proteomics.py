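"""Proteome compartment composition and differential statistics.

Works from an already-quantified label-free intensity table (one row per
protein group, one intensity column per day) annotated with subcellular
compartments.  Provides the composition accounting — union of the top-N
most abundant proteins per day, per-compartment mass fractions, shares
within the ER(+µs) proteome — plus fold changes, the intensity-binned
robust outlier statistic on log-ratios ("Significance B"), and a
per-protein ANOVA over days.

Intensities are treated as mass-proportional, so a compartment's mass
fraction is its share of summed intensity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SchemaError",
    "CompositionSummary",
    "read_protein_groups",
    "read_compartment_annotation",
    "intensity_columns",
    "select_abundant",
    "compartment_fractions",
    "er_internal_shares",
    "composition_summary",
    "fold_change",
    "significance_b",
    "anova_over_days",
]

_DAY_COL = re.compile(r"^intensity_day(\d+)$")

ER_KEY_PROTEINS: dict[str, tuple[str, ...]] = {
    "BiP": ("BiP",),
    "mu_s": ("mu_s",),
    "GRP94": ("GRP94",),
    "CRT": ("CRT",),
    "PDI_family": ("PDI", "ERp72", "P5", "ERp57"),
}


class SchemaError(ValueError):
    """An expected column is missing from an input table."""


@dataclass(frozen=True)
class CompositionSummary:
    """Per-day compartment fractions, ER-internal shares, and coverage."""

    compartment_fractions: pd.DataFrame  # index day, columns compartments
    er_shares: pd.DataFrame              # index day, columns ER species groups
    coverage: pd.Series                  # selected / total intensity per day


# ---------------------------------------------------------------------------
# input handling
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "protein_id": "Majority protein IDs",
    "name": "Protein names",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "intensity_prefix": "Intensity ",
}


def read_protein_groups(
    path,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a search-engine protein-groups table into the canonical layout.

    Rows flagged as reverse hits or known contaminants (a '+' in the flag
    columns, or ids prefixed REV__/CON__) are dropped.  Intensity columns
    are located by ``intensity_prefix`` and renamed to ``intensity_day<d>``.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("protein_id",):
        if cmap[key] not in raw.columns:
            raise SchemaError(f"missing mapped column {cmap[key]!r}")
    prefix = cmap["intensity_prefix"]
    day_cols = {c: f"intensity_day{c[len(prefix):].strip()}"
                for c in raw.columns if c.startswith(prefix)}
    if not day_cols:
        raise SchemaError(f"no intensity columns with prefix {prefix!r}")
    df = raw.rename(columns={cmap["protein_id"]: "protein_id", **day_cols})
    if cmap.get("name") in raw.columns:
        df = df.rename(columns={cmap["name"]: "name"})
    else:
        df["name"] = df["protein_id"]
    for flag in ("reverse", "contaminant"):
        col = cmap.get(flag)
        if col in df.columns:
            df = df[df[col].fillna("") != "+"]
    ids = df["protein_id"].astype(str)
    df = df[~ids.str.startswith(("REV__", "CON__"))]
    if df["protein_id"].duplicated().any():
        dupes = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise SchemaError(f"duplicate protein ids: {dupes[:5]}")
    keep = ["protein_id", "name"] + sorted(day_cols.values())
    if "compartment" in df.columns:
        keep.insert(2, "compartment")
    df = df[keep].reset_index(drop=True)
    for c in day_cols.values():
        df[c] = pd.to_numeric(df[c])
        if (df[c] < 0).any():
            raise SchemaError(f"negative intensities in {c}")
    return df


def read_compartment_annotation(path) -> pd.Series:
    """protein_id -> compartment mapping from a two-column TSV."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_id", "compartment"} <= set(ann.columns):
        raise SchemaError("annotation needs 'protein_id' and 'compartment'")
    return ann.set_index("protein_id")["compartment"]


def intensity_columns(table: pd.DataFrame) -> dict[int, str]:
    """Map day -> canonical intensity column present in ``table``."""
    out = {}
    for c in table.columns:
        m = _DAY_COL.match(c)
        if m:
            out[int(m.group(1))] = c
    if not out:
        raise SchemaError("no intensity_day<d> columns found")
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# composition accounting
# ---------------------------------------------------------------------------

def select_abundant(table: pd.DataFrame, top_n: int = 500) -> pd.Index:
    """Union over days of the top-N proteins by per-day intensity.

    Ties break by mean intensity across days, then lexicographic id, so the
    selection is deterministic.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    cols = intensity_columns(table)
    if len(table) < top_n:
        raise ValueError(f"table has {len(table)} rows < top_n={top_n}")
    mean_int = table[list(cols.values())].mean(axis=1)
    selected: set[str] = set()
    for col in cols.values():
        order = (
            table.assign(_k=table[col], _m=mean_int)
            .sort_values(["_k", "_m", "protein_id"],
                         ascending=[False, False, True],
                         kind="mergesort")
        )
        selected.update(order["protein_id"].head(top_n))
    return pd.Index(sorted(selected), name="protein_id")


def compartment_fractions(
    table: pd.DataFrame,
    selection: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-day fraction of selected intensity per compartment.

    µs ('client_mus') is carried as its own category, separate from ER
    residents.  Fractions sum to 1 per day.
    """
    if "compartment" not in table.columns:
        raise SchemaError("table lacks a 'compartment' column")
    sub = table if selection is None else table[
        table["protein_id"].isin(selection)
    ]
    if sub.empty:
        raise ValueError("selection is empty")
    cols = intensity_columns(sub)
    out = {}
    for day, col in cols.items():
        total = sub[col].sum()
        if total <= 0:
            raise ValueError(f"day {day} has zero total intensity")
        out[day] = sub.groupby("compartment")[col].sum() / total
    frac = pd.DataFrame(out).T.fillna(0.0)
    frac.index.name = "day"
    return frac


def er_internal_shares(
    table: pd.DataFrame,
    selection: pd.Index | None = None,
    key_proteins: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-day shares within the ER(+µs) proteome.

    Named species (BiP, µs, GRP94, CRT, the PDI family) are reported
    individually; the remaining residents pool into 'other_ER'.  Shares sum
    to 1 per day.
    """
    if key_proteins is None:
        key_proteins = ER_KEY_PROTEINS
    sub = table if selection is None else table[
        table["protein_id"].isin(selection)
    ]
    er = sub[sub["compartment"].isin(["ER_resident", "client_mus"])]
    if er.empty:
        raise ValueError("no ER proteins in selection")
    cols = intensity_columns(er)
    name_to_group = {n: g for g, names in key_proteins.items() for n in names}
    group = er["name"].map(name_to_group).fillna("other_ER")
    out = {}
    for day, col in cols.items():
        total = er[col].sum()
        if total <= 0:
            raise ValueError(f"day {day} has zero ER intensity")
        out[day] = er.groupby(group)[col].sum() / total
    shares = pd.DataFrame(out).T.fillna(0.0)
    shares.index.name = "day"
    return shares


def composition_summary(
    table: pd.DataFrame,
    top_n: int = 500,
) -> CompositionSummary:
    """Top-N selection, compartment fractions, ER shares, and coverage."""
    selection = select_abundant(table, top_n)
    sel = table[table["protein_id"].isin(selection)]
    cols = intensity_columns(table)
    coverage = pd.Series(
        {day: sel[col].sum() / table[col].sum() for day, col in cols.items()},
        name="coverage",
    )
    return CompositionSummary(
        compartment_fractions(table, selection),
        er_internal_shares(table, selection),
        coverage,
    )


# ---------------------------------------------------------------------------
# differential statistics
# ---------------------------------------------------------------------------

def fold_change(
    table: pd.DataFrame,
    day_a: int,
    day_b: int,
    pseudo: float = 0.0,
) -> pd.DataFrame:
    """Per-protein intensity ratios day_b / day_a.

    With the default pseudo-count of 0, a zero denominator gives +inf
    (flagged 'infinite'), and 0/0 gives NaN (flagged 'undefined') rather
    than being clipped.
    """
    cols = intensity_columns(table)
    for day in (day_a, day_b):
        if day not in cols:
            raise SchemaError(f"no intensity column for day {day}")
    a = table[cols[day_a]].to_numpy(float) + pseudo
    b = table[cols[day_b]].to_numpy(float) + pseudo
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = b / a
    return pd.DataFrame({
        "protein_id": table["protein_id"].to_numpy(),
        "ratio": ratio,
        "infinite": np.isinf(ratio),
        "undefined": np.isnan(ratio),
    })


def significance_b(
    log_ratios,
    intensities,
    bin_size: int = 300,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Intensity-binned robust outlier test on log-ratios.

    Proteins are ranked by intensity and grouped into bins of ``bin_size``
    (the last bin absorbs the remainder).  Within each bin, an asymmetric
    robust z is computed from the median and the 15.87/84.13 percentile
    half-widths of the log-ratios; the two-sided p is the standard-normal
    tail probability of |z|.  Significance is declared at p < ``alpha``.
    """
    r = np.asarray(log_ratios, float)
    x = np.asarray(intensities, float)
    if r.shape != x.shape or r.ndim != 1:
        raise ValueError("log_ratios and intensities must be equal-length 1-D")
    if bin_size < 3:
        raise ValueError("bin_size must be >= 3")
    n = r.size
    n_bins = n // bin_size
    if n_bins == 0:
        warnings.warn("fewer entries than one bin; using a single bin",
                      UserWarning, stacklevel=2)
        n_bins = 1
    order = np.argsort(-x, kind="mergesort")  # descending intensity
    bin_of = np.empty(n, int)
    for b in range(n_bins):
        hi = n if b == n_bins - 1 else (b + 1) * bin_size
        bin_of[order[b * bin_size:hi]] = b
    z = np.empty(n)
    for b in range(n_bins):
        idx = np.flatnonzero(bin_of == b)
        vals = r[idx]
        med = np.median(vals)
        lo, hi = np.percentile(vals, [15.87, 84.13])
        up_w, dn_w = hi - med, med - lo
        dev = vals - med
        with np.errstate(divide="ignore", invalid="ignore"):
            zz = np.where(dev >= 0,
                          np.divide(dev, up_w) if up_w > 0 else np.where(dev > 0, np.inf, 0.0),
                          np.divide(-dev, dn_w) if dn_w > 0 else np.inf)
        z[idx] = np.where(dev >= 0, zz, -np.abs(zz))
    p = special.erfc(np.abs(z) / np.sqrt(2.0))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "log_ratio": r,
        "intensity": x,
        "bin": bin_of,
        "z": z,
        "p_value": p,
        "significant": p < alpha,
    })


def anova_over_days(
    table: pd.DataFrame,
    day_columns: dict[int, list[str]],
    alpha: float = 0.01,
    *,
    bh_adjust: bool = True,
) -> pd.DataFrame:
    """Per-protein one-way ANOVA across days on replicate intensities.

    Each replicate column is first normalized by its summed intensity so
    that days are comparable; proteins with p < ``alpha`` form the changed
    set.  A Benjamini-Hochberg adjusted p is attached as an optional flag
    column.
    """
    if len(day_columns) < 2:
        raise ValueError("need >=2 days")
    groups = []
    for day, cols in sorted(day_columns.items()):
        if len(cols) < 2:
            raise ValueError(f"day {day} has <2 replicate columns")
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise SchemaError(f"missing replicate columns: {missing}")
        block = table[cols].to_numpy(float)
        groups.append(block / block.sum(axis=0, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.f_oneway(*groups, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance proteins: no change
    out = pd.DataFrame({
        "protein_id": table["protein_id"].to_numpy(),
        "p_value": p,
        "changed": p < alpha,
    })
    if bh_adjust:
        _, p_bh, _, _ = multipletests(p, method="fdr_bh")
        out["p_bh"] = p_bh
        out["changed_bh"] = p_bh < alpha
    return out
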