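"""ER stereology: area fractions -> volumes -> lumenal concentrations.

Electron micrographs of DAB-stained (APEX-KDEL) cells yield the percentage
of cytoplasmic area occupied by ER.  Under a cuboid approximation the
volume fraction is the area fraction raised to the power 3/2; multiplied by
the cytoplasm volume (~2e3 fl for HeLa) this gives an absolute ER volume,
which in turn converts copies-per-cell into molar and mass concentrations
in the ER lumen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .quantitation import AVOGADRO

DEFAULT_CYTOPLASM_VOLUME_FL = 2000.0

__all__ = [
    "DEFAULT_CYTOPLASM_VOLUME_FL",
    "MicrographMeasurement",
    "VolumeEstimate",
    "ConcentrationEstimate",
    "area_fraction_from_image",
    "area_to_volume_fraction",
    "er_volume",
    "volume_estimate",
    "molar_concentration",
    "mass_concentration",
    "lumenal_concentration",
    "condition_summary",
]


@dataclass(frozen=True)
class MicrographMeasurement:
    """ER and cytoplasm areas (in pixels) segmented from one cell."""

    cell_id: str
    condition: str
    cytoplasm_area: float
    er_area: float

    def __post_init__(self) -> None:
        if self.cytoplasm_area <= 0:
            raise ValueError("cytoplasm area must be positive")
        if not (0 <= self.er_area <= self.cytoplasm_area):
            raise ValueError("ER area must lie within [0, cytoplasm area]")

    @property
    def area_fraction(self) -> float:
        return self.er_area / self.cytoplasm_area


@dataclass(frozen=True)
class VolumeEstimate:
    """Area fraction with its derived volume fraction and absolute volume."""

    area_fraction: float
    volume_fraction: float
    cytoplasm_volume_fl: float
    er_volume_fl: float


@dataclass(frozen=True)
class ConcentrationEstimate:
    copies_per_cell: float
    compartment_volume_fl: float
    molecular_weight_kda: float
    molar_mm: float
    mass_mg_ml: float


def area_fraction_from_image(
    image: np.ndarray,
    cytoplasm_mask: np.ndarray,
    *,
    threshold: float | None = None,
    cell_id: str = "cell",
    condition: str = "unknown",
) -> MicrographMeasurement:
    """Segment dark (DAB-stained) ER pixels within the cytoplasm mask.

    Pixels strictly darker than the threshold count as ER.  By default the
    threshold is Otsu's on the masked intensities; pass ``threshold`` for a
    fixed cutoff.  A contrast-free (constant) masked region yields zero ER
    under the Otsu rule.
    """
    image = np.asarray(image)
    mask = np.asarray(cytoplasm_mask, bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("cytoplasm mask is empty")
    pixels = image[mask].astype(float)
    if threshold is None:
        if np.ptp(pixels) == 0:
            threshold = float(pixels[0])  # no contrast: nothing below it
        else:
            threshold = float(threshold_otsu(pixels))
    er_area = float(np.count_nonzero(pixels < threshold))
    return MicrographMeasurement(cell_id, condition, float(mask.sum()), er_area)


def area_to_volume_fraction(area_fraction: float) -> float:
    """Cuboid stereology: volume fraction = area fraction^(3/2).

    Applied to fractions in [0, 1] (so the fixed points 0 and 1 are
    preserved), not to percent values.
    """
    af = np.asarray(area_fraction, float)
    if np.any((af < 0) | (af > 1)):
        raise ValueError("area fraction must lie in [0, 1]")
    vf = af**1.5
    return vf if vf.ndim else float(vf)


def er_volume(
    volume_fraction: float,
    cytoplasm_volume_fl: float = DEFAULT_CYTOPLASM_VOLUME_FL,
) -> float:
    """Absolute ER volume in femtoliters."""
    if volume_fraction < 0 or cytoplasm_volume_fl < 0:
        raise ValueError("inputs must be non-negative")
    return float(volume_fraction * cytoplasm_volume_fl)


def volume_estimate(
    area_fraction: float,
    cytoplasm_volume_fl: float = DEFAULT_CYTOPLASM_VOLUME_FL,
) -> VolumeEstimate:
    vf = area_to_volume_fraction(area_fraction)
    return VolumeEstimate(
        float(area_fraction), vf, float(cytoplasm_volume_fl),
        er_volume(vf, cytoplasm_volume_fl),
    )


def molar_concentration(copies: float, volume_fl: float) -> float:
    """Concentration in mM of ``copies`` molecules in ``volume_fl`` fl."""
    if volume_fl <= 0:
        raise ZeroDivisionError("compartment volume must be positive")
    if copies < 0:
        raise ValueError("copies must be non-negative")
    return copies / (AVOGADRO * volume_fl * 1e-15) * 1e3


def mass_concentration(molar_mm: float, molecular_weight_kda: float) -> float:
    """mg/ml from mM and kDa (mmol/L x kg/mol collapses to mg/ml)."""
    if molar_mm < 0 or molecular_weight_kda < 0:
        raise ValueError("inputs must be non-negative")
    return molar_mm * molecular_weight_kda


def lumenal_concentration(
    copies: float,
    volume_fl: float,
    molecular_weight_kda: float,
) -> ConcentrationEstimate:
    molar = molar_concentration(copies, volume_fl)
    return ConcentrationEstimate(
        float(copies), float(volume_fl), float(molecular_weight_kda),
        molar, mass_concentration(molar, molecular_weight_kda),
    )


def condition_summary(
    measurements: pd.DataFrame,
    *,
    condition_col: str = "condition",
    value_col: str = "area_fraction",
) -> tuple[pd.DataFrame, float | None]:
    """Per-condition mean and s.e.m. plus a one-way ANOVA across conditions.

    Returns (summary table, ANOVA p).  With a single condition the ANOVA is
    skipped (p is None) with a notice.
    """
    groups = [g[value_col].to_numpy(float)
              for _, g in measurements.groupby(condition_col)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 cells per condition")
    summary = (
        measurements.groupby(condition_col)[value_col]
        .agg(mean="mean", sem="sem", n="count")
        .reset_index()
    )
    if len(groups) < 2:
        warnings.warn("single condition: ANOVA skipped", UserWarning,
                      stacklevel=2)
        return summary, None
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return summary, 1.0  # identical constant groups: no effect
    _, p = stats.f_oneway(*groups)
    return summary, float(p)
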