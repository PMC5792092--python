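"""Synthetic data emulating the HeLa-µs ER homeostatic readjustment study.

The generator produces every input the analysis pipeline consumes — blot
densitometry with purified-protein standards, EM area-fraction tables,
DAB-contrast-like micrographs, and a label-free proteome intensity table —
from a single :class:`GroundTruth` whose hidden parameters are the printed
study conditions:

* µs accumulates sigmoidally to ~1.7e8 copies/cell; BiP rises ~10-fold from
  ~2e7 copies with its half-time lagging the client (noticeable rise only
  from ~12 h onwards),
* ER area fractions of ~11% resting and ~18% once expanded (day >= 3),
  n = 10 cells per condition,
* an ER share of total protein mass moving 3% -> ~6% -> ~10% -> ~12% across
  days 0/1/3/7, with BiP rising from 15% to ~35% of the ER proteome and µs
  from ~1 ppm of total to ~2%.

Measurement noise is multiplicative lognormal (mean 1, given CV) for
densitometry and intensities, and additive truncated-normal for EM area
fractions.  Identical (seed, params) give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .quantitation import AVOGADRO, StandardSeries

__all__ = [
    "LogisticParams",
    "GroundTruth",
    "default_truth",
    "logistic_logtime",
    "lognormal_factors",
    "gen_expression_timecourse",
    "gen_blot_dataset",
    "gen_em_areas",
    "gen_synthetic_micrograph",
    "gen_proteome_table",
    "gen_replicated_proteome",
    "write_manifest",
]

# stream keys so that adding one generator never perturbs another's draws
_STREAMS = {"timecourse": 0, "blot": 1, "em": 2, "micrograph": 3,
            "proteome": 4, "replicates": 5}

ANALYTE_MW_KDA = {"BiP": 70.0, "mu_s": 67.0}
ANALYTE_PURITY = {"BiP": 1.0, "mu_s": 0.7}  # IgM standard is ~70% µs by mass
COMPARTMENTS = ("cytosol", "nucleus", "mitochondrion", "ER_resident",
                "other", "client_mus")


@dataclass(frozen=True)
class LogisticParams:
    """Four-parameter logistic on a log-time axis (copies/cell vs hours)."""

    baseline: float
    plateau: float
    half_time_hr: float
    hill: float

    def __post_init__(self) -> None:
        if not (self.plateau >= self.baseline >= 0):
            raise ValueError("need plateau >= baseline >= 0")
        if self.half_time_hr <= 0:
            raise ValueError("half-time must be positive")


def logistic_logtime(t, p: LogisticParams) -> np.ndarray:
    t = np.asarray(t, float)
    th = np.power(np.maximum(t, 0.0), p.hill)
    return p.baseline + (p.plateau - p.baseline) * th / (th + p.half_time_hr**p.hill)


@dataclass(frozen=True)
class GroundTruth:
    """Hidden true parameters behind every synthetic dataset."""

    analyte_params: Mapping[str, LogisticParams]
    em_params: Mapping[str, tuple[float, float]]  # condition -> (mean, sd)
    proteome_params: Mapping[int, Mapping[str, float]]  # day -> fractions of total
    er_internal_params: Mapping[int, float]  # day -> BiP share of ER(+µs)
    noise_cv: Mapping[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, (mean, sd) in self.em_params.items():
            if not (0.0 < mean < 1.0):
                raise ValueError(f"area-fraction mean for {cond!r} outside (0,1)")
            if sd < 0:
                raise ValueError("area-fraction sd must be >= 0")
        for day, fracs in self.proteome_params.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"day {day} compartment fractions sum to {total}, not 1"
                )
            if set(fracs) - set(COMPARTMENTS):
                raise ValueError(f"unknown compartments on day {day}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(_STREAMS[stream],))
        )


def default_truth(seed: int = 0) -> GroundTruth:
    """The study conditions as generator defaults.

    µs: 0 -> 1.7e8 copies/cell, half-time 10 h; BiP: 2e7 -> 2e8 (10-fold
    plateau/baseline) with half-time 24 h so its rise lags the client by
    over 12 h.  ER area fractions 0.11 resting / 0.18 induced.  Proteome
    mass-fraction targets per day follow the printed composition series.
    """
    er_total = {0: 0.03, 1: 0.06, 3: 0.10, 7: 0.12}
    mus_total = {0: 1e-6, 1: 0.01, 3: 0.02, 7: 0.02}
    # non-ER compartments keep fixed relative proportions
    base = {"cytosol": 0.50, "nucleus": 0.22, "mitochondrion": 0.13, "other": 0.15}
    proteome_params = {}
    for day in (0, 1, 3, 7):
        rest = 1.0 - er_total[day]
        fracs = {k: v * rest for k, v in base.items()}
        fracs["ER_resident"] = er_total[day] - mus_total[day]
        fracs["client_mus"] = mus_total[day]
        proteome_params[day] = fracs
    return GroundTruth(
        analyte_params={
            "mu_s": LogisticParams(0.0, 1.7e8, 10.0, 2.5),
            "BiP": LogisticParams(2e7, 2e8, 24.0, 3.0),
        },
        em_params={"resting": (0.11, 0.02), "induced": (0.18, 0.02)},
        proteome_params=proteome_params,
        er_internal_params={0: 0.15, 1: 0.25, 3: 0.30, 7: 0.35},
        noise_cv={"blot": 0.15, "intensity": 0.30, "em": 0.0},
        seed=seed,
    )


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv < 0:
        raise ValueError("CV must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# expression time courses and blots
# ---------------------------------------------------------------------------

def gen_expression_timecourse(
    truth: GroundTruth,
    times_hr: Sequence[float],
    replicates: int,
) -> pd.DataFrame:
    """True and lognormal-noised copies/cell per analyte, time, replicate."""
    times = np.asarray(times_hr, float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = truth.rng("timecourse")
    rows = []
    for analyte in sorted(truth.analyte_params):
        true = logistic_logtime(times, truth.analyte_params[analyte])
        noise = lognormal_factors(rng, truth.noise_cv["blot"],
                                  (times.size, replicates))
        for i, t in enumerate(times):
            for r in range(replicates):
                rows.append((analyte, float(t), r + 1, float(true[i]),
                             float(true[i] * noise[i, r])))
    return pd.DataFrame(
        rows, columns=["analyte", "time_hr", "replicate",
                       "true_copies", "noisy_signal"]
    )


def gen_blot_dataset(
    truth: GroundTruth,
    standard_masses_ng: Sequence[float] = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0),
    *,
    times_hr: Sequence[float] = (0.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0, 32.0,
                                 48.0, 64.0),
    replicates: int = 5,
    cells_per_lane: float = 7e4,
    sensitivity: float | None = None,
    background: float = 50.0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, StandardSeries], pd.DataFrame]:
    """Standards plus sample-lane densitometry for every analyte.

    Each blot draws its own detection sensitivity (signal per ng of
    analyte) and a background intercept; standard lanes carry the nominal
    standard protein mass (of which only ``purity`` is analyte), sample
    lanes carry the analyte mass implied by copies/cell and lane loading.
    """
    masses = np.asarray(standard_masses_ng, float)
    if np.unique(masses).size < 3:
        raise ValueError("need >=3 distinct standard masses")
    if rng is None:
        rng = truth.rng("blot")
    cv = truth.noise_cv["blot"]
    standards: dict[str, StandardSeries] = {}
    lane_rows = []
    times = np.asarray(times_hr, float)
    for analyte in sorted(truth.analyte_params):
        purity = ANALYTE_PURITY.get(analyte, 1.0)
        mw = ANALYTE_MW_KDA.get(analyte, 70.0)
        if sensitivity is None:  # per-blot detection slope, signal per ng
            blot_slope = 100.0 * float(rng.lognormal(0.0, 0.2))
        else:
            blot_slope = float(sensitivity)
        std_noise = lognormal_factors(rng, cv, masses.size)
        std_signals = (blot_slope * purity * masses + background) * std_noise
        standards[analyte] = StandardSeries(
            analyte, tuple(masses), tuple(std_signals), purity
        )
        true = logistic_logtime(times, truth.analyte_params[analyte])
        noise = lognormal_factors(rng, cv, (times.size, replicates))
        for i, t in enumerate(times):
            mass_ng = true[i] * cells_per_lane * mw * 1e3 / AVOGADRO * 1e9
            for r in range(replicates):
                signal = (blot_slope * mass_ng + background) * noise[i, r]
                lane_rows.append((analyte, float(t), r + 1, float(signal),
                                  float(cells_per_lane), float(true[i])))
    lanes = pd.DataFrame(
        lane_rows, columns=["analyte", "time_hr", "replicate", "signal",
                            "cells_per_lane", "true_copies"]
    )
    return standards, lanes


# ---------------------------------------------------------------------------
# electron microscopy
# ---------------------------------------------------------------------------

def gen_em_areas(
    truth: GroundTruth,
    condition: str,
    n_cells: int = 10,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cell ER area fractions ~ Normal(mean, sd) truncated to (0, 1)."""
    if condition not in truth.em_params:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"known: {sorted(truth.em_params)}")
    if n_cells < 2:
        raise ValueError("need >=2 cells")
    mean, sd = truth.em_params[condition]
    if rng is None:
        rng = truth.rng("em")
    if sd == 0:
        fractions = np.full(n_cells, mean)
    else:
        a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
        fractions = stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                        size=n_cells, random_state=rng)
    return pd.DataFrame({
        "cell_id": [f"{condition}_{i+1:02d}" for i in range(n_cells)],
        "condition": condition,
        "area_fraction": fractions,
    })


def gen_synthetic_micrograph(
    area_fraction: float,
    size: int = 256,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale micrograph with dark DAB-like blobs on a brighter cytoplasm.

    Returns (image uint16, cytoplasm mask bool).  Blobs are the sub-quantile
    set of a smoothed Gaussian random field, so the foreground fraction of
    the mask matches the target to within the quantile discreteness
    (well inside +/-0.5% absolute for the default size).
    """
    if not (0.0 < area_fraction < 1.0):
        raise ValueError("area_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= (0.47 * size) ** 2
    field_ = ndimage.gaussian_filter(rng.standard_normal((size, size)),
                                     sigma=size / 32.0)
    thresh = np.quantile(field_[mask], area_fraction)
    blobs = (field_ <= thresh) & mask
    image = np.full((size, size), 42000.0)
    image += rng.normal(0.0, 1500.0, (size, size))
    image[blobs] = 12000.0 + rng.normal(0.0, 1500.0, int(blobs.sum()))
    image = np.clip(image, 0, 65535).astype(np.uint16)
    return image, mask


# ---------------------------------------------------------------------------
# proteome table
# ---------------------------------------------------------------------------

_ER_NAMED = ("GRP94", "CRT", "PDI", "ERp72", "P5", "GRP170", "CNX", "ERp57")


def gen_proteome_table(
    truth: GroundTruth,
    days: Sequence[int] = (0, 1, 3, 7),
    *,
    n_proteins: int = 1000,
    total_intensity: float = 1e9,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic label-free proteome with programmed compartment fractions.

    ~``n_proteins`` proteins carry Zipf-like within-compartment abundance;
    per day, lognormal noise perturbs individual proteins and each
    compartment block is rescaled so its mass fraction of the summed
    intensity hits the ground-truth target exactly.  BiP is pinned to its
    programmed share of the ER(+µs) mass; µs is a single 'client_mus' row.
    """
    for day in days:
        if day not in truth.proteome_params:
            raise ValueError(f"no compartment fractions defined for day {day}")
    if rng is None:
        rng = truth.rng("proteome")
    counts = {"cytosol": 380, "nucleus": 230, "mitochondrion": 150,
              "other": 180}
    n_er = n_proteins - sum(counts.values()) - 1  # minus the µs row
    rows: list[tuple[str, str, str]] = []
    pid = 0
    for comp, n in counts.items():
        for i in range(n):
            pid += 1
            rows.append((f"P{pid:04d}", f"{comp}_{i+1}", comp))
    er_names = ["BiP"] + list(_ER_NAMED) + [
        f"ER_{i+1}" for i in range(n_er - 1 - len(_ER_NAMED))
    ]
    for name in er_names:
        pid += 1
        rows.append((f"P{pid:04d}", name, "ER_resident"))
    rows.append((f"P{pid+1:04d}", "mu_s", "client_mus"))
    df = pd.DataFrame(rows, columns=["protein_id", "name", "compartment"])

    # Zipf-like base weights within each compartment (exponent 1.1 keeps the
    # top-500 selection covering >90% of total intensity at this table size)
    base = np.empty(len(df))
    for comp in df["compartment"].unique():
        idx = np.flatnonzero(df["compartment"].to_numpy() == comp)
        if comp == "ER_resident":
            # named chaperones (GRP94, CRT, PDI family...) take the top ranks
            ranks = np.arange(1, idx.size + 1)
        else:
            ranks = rng.permutation(idx.size) + 1
        base[idx] = ranks ** -1.1
    cv = truth.noise_cv["intensity"]
    bip_row = df.index[df["name"] == "BiP"][0]
    for day in days:
        fracs = truth.proteome_params[day]
        bip_share = truth.er_internal_params[day]
        er_total_frac = fracs["ER_resident"] + fracs["client_mus"]
        weights = base * lognormal_factors(rng, cv, len(df))
        intens = np.zeros(len(df))
        for comp, frac in fracs.items():
            idx = np.flatnonzero(df["compartment"].to_numpy() == comp)
            target = frac * total_intensity
            if comp == "ER_resident":
                bip_target = bip_share * er_total_frac * total_intensity
                others = idx[idx != bip_row]
                w = weights[others]
                intens[others] = w / w.sum() * (target - bip_target)
                intens[bip_row] = bip_target
            else:
                w = weights[idx]
                intens[idx] = w / w.sum() * target
        df[f"intensity_day{day}"] = intens
    return df


def gen_replicated_proteome(
    truth: GroundTruth,
    days: Sequence[int] = (0, 1, 3, 7),
    replicates: int = 3,
    *,
    n_proteins: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Proteome table with per-day replicate intensity columns.

    Returns the table and a mapping day -> replicate column names, the
    structure the per-protein ANOVA over days consumes.
    """
    if replicates < 2:
        raise ValueError("need >=2 replicates per day")
    if rng is None:
        rng = truth.rng("replicates")
    table = gen_proteome_table(truth, days, n_proteins=n_proteins,
                               rng=truth.rng("proteome"))
    cv = truth.noise_cv["intensity"]
    day_cols: dict[int, list[str]] = {}
    for day in days:
        cols = []
        mean = table[f"intensity_day{day}"].to_numpy()
        for r in range(1, replicates + 1):
            col = f"intensity_day{day}_rep{r}"
            table[col] = mean * lognormal_factors(rng, cv, mean.size)
            cols.append(col)
        day_cols[day] = cols
    return table, day_cols


def write_manifest(path: str | Path, truth: GroundTruth, **extra) -> None:
    """Record seed and generator parameters next to a written dataset."""
    payload = {
        "seed": truth.seed,
        "params": _jsonable(dataclasses.asdict(truth)),
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
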