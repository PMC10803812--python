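"""Derived water-quality metrics for flow-cytometry and ATP time series.

Bulk drinking-water monitoring in this package revolves around four paired
measurements: total and intact cell counts from flow cytometry (TCC, ICC;
cells/mL in bulk water, cells/cm^2 in biofilm) and total and intracellular
ATP (ATPt, ATPi; nM in bulk, nmol/cm^2 in biofilm). The functions here
compute the derived quantities a reactor study reports from those series:
intact fractions, ATP partitioning, ATP per intact cell, the biofilm share
of the whole-reactor cell pool, hydraulic residence times, geometric
summary statistics, and tie-corrected rank correlation.

Cell counts and ATP are lognormally distributed in practice, so summary
statistics are geometric: the geometric mean exp(mean(ln x)) and the
geometric coefficient of variation gCV = exp(sd(ln x)) - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import OutOfRangeError, UndefinedResultError

__all__ = [
    "WaterSample",
    "BiofilmSample",
    "CHLORINE_LOD_MG_L",
    "intact_fraction",
    "intracellular_atp_fraction",
    "extracellular_atp",
    "ExtracellularAtp",
    "atp_per_intact_cell",
    "biofilm_fraction_of_whole",
    "hydraulic_residence_time",
    "geometric_summary",
    "GeometricSummary",
    "kendall_tau_b",
    "ratio_of_geometric_means",
    "mean_of_ratios",
]

#: Limit of detection for total chlorine (mg/L as Cl2, DPD method).
CHLORINE_LOD_MG_L = 0.02


@dataclass
class WaterSample:
    """One bulk-water sampling event.

    ``source`` identifies where the sample was drawn (the tap reservoir
    feeding the reactors, conventionally ``"tapres"``, or a reactor such
    as ``"AR1"``). Counts are cells/mL, ATP in nM. Chlorine measured below
    the limit of detection is stored as 0 with ``chlorine_below_lod=True``.
    Missing measurements are ``None``.
    """

    day: float
    source: str
    phase: Optional[str] = None
    tcc: Optional[float] = None
    icc: Optional[float] = None
    atpt: Optional[float] = None
    atpi: Optional[float] = None
    chlorine_total: Optional[float] = None
    temperature: Optional[float] = None
    ph: Optional[float] = None
    chlorine_below_lod: bool = False

    def __post_init__(self) -> None:
        if self.day < 0:
            raise OutOfRangeError("day must be >= 0")
        for name in ("tcc", "icc", "atpt", "atpi", "chlorine_total"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise OutOfRangeError(f"{name} must be >= 0, got {v!r}")
        if self.icc is not None and self.tcc is not None and self.icc > self.tcc:
            raise OutOfRangeError(
                f"icc ({self.icc}) exceeds tcc ({self.tcc}) on day {self.day}"
            )


@dataclass
class BiofilmSample:
    """One biofilm sampling event, per unit coupon area (cells/cm^2, nmol/cm^2)."""

    day: float
    reactor: str
    tcc_area: Optional[float] = None
    icc_area: Optional[float] = None
    atpt_area: Optional[float] = None
    atpi_area: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tcc_area", "icc_area", "atpt_area", "atpi_area"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise OutOfRangeError(f"{name} must be >= 0, got {v!r}")
        if (
            self.icc_area is not None
            and self.tcc_area is not None
            and self.icc_area > self.tcc_area
        ):
            raise OutOfRangeError("icc_area exceeds tcc_area")


def intact_fraction(icc: float, tcc: float) -> float:
    """Fraction of cells with intact membranes, ICC/TCC, in [0, 1]."""
    if tcc <= 0:
        raise UndefinedResultError("intact fraction undefined for tcc <= 0")
    if icc < 0:
        raise OutOfRangeError("icc must be >= 0")
    if icc > tcc:
        raise OutOfRangeError(f"icc ({icc}) exceeds tcc ({tcc})")
    return icc / tcc


def intracellular_atp_fraction(atpi: float, atpt: float) -> float:
    """Fraction of ATP that is intracellular (or cell-bound), ATPi/ATPt."""
    if atpt <= 0:
        raise UndefinedResultError("ATPi/ATPt undefined for atpt <= 0")
    if atpi < 0:
        raise OutOfRangeError("atpi must be >= 0")
    if atpi > atpt:
        raise OutOfRangeError(f"atpi ({atpi}) exceeds atpt ({atpt})")
    return atpi / atpt


class ExtracellularAtp(NamedTuple):
    """Extracellular ATP with a flag marking a negative difference clamped to 0."""

    value: float
    clamped: bool


def extracellular_atp(atpt: float, atpi: float) -> ExtracellularAtp:
    """Extracellular ATP, ATPe = ATPt - ATPi (nM).

    Triplicate luminescence measurements occasionally yield ATPi slightly
    above ATPt; the physically impossible negative difference is clamped to
    0 and flagged rather than raised.
    """
    if atpt < 0 or atpi < 0:
        raise OutOfRangeError("ATP concentrations must be >= 0")
    diff = atpt - atpi
    if diff < 0:
        return ExtracellularAtp(0.0, True)
    return ExtracellularAtp(diff, False)


def atp_per_intact_cell(atpi: float, icc: float) -> float:
    """ATPi per intact cell (nmol/cell).

    ``atpi`` is nM (= nmol/L); ``icc`` is cells/mL, converted to cells/L.
    """
    if icc <= 0:
        raise UndefinedResultError("ATP per cell undefined for icc <= 0")
    if atpi < 0:
        raise OutOfRangeError("atpi must be >= 0")
    return atpi / (icc * 1000.0)


def biofilm_fraction_of_whole(
    c_bf: float, area_cm2: float, c_ar: float, volume_ml: float
) -> float:
    """Fraction of whole-reactor cells residing in the biofilm.

    (C_BF * A) / (C_BF * A + C_AR * V) for areal biofilm concentration
    ``c_bf`` (cells/cm^2) over area ``area_cm2`` and bulk concentration
    ``c_ar`` (cells/mL) in volume ``volume_ml``.
    """
    for name, v in (("c_bf", c_bf), ("area_cm2", area_cm2),
                    ("c_ar", c_ar), ("volume_ml", volume_ml)):
        if v < 0:
            raise OutOfRangeError(f"{name} must be >= 0")
    biofilm = c_bf * area_cm2
    bulk = c_ar * volume_ml
    if biofilm + bulk <= 0:
        raise UndefinedResultError("both cell pools are zero")
    return biofilm / (biofilm + bulk)


def hydraulic_residence_time(volume_ml: float, flow_ml_min: float) -> float:
    """Mean hydraulic residence time V/Q, in hours."""
    if flow_ml_min <= 0:
        raise UndefinedResultError("HRT undefined for flow <= 0")
    if volume_ml < 0:
        raise OutOfRangeError("volume must be >= 0")
    return volume_ml / flow_ml_min / 60.0


class GeometricSummary(NamedTuple):
    geometric_mean: float
    gcv: float


def geometric_summary(values: Sequence[float]) -> GeometricSummary:
    """Geometric mean and geometric coefficient of variation.

    geomean = exp(mean(ln x)); gCV = exp(sd(ln x)) - 1, with the sample
    (n-1) standard deviation of the log values. A single value yields
    gCV = 0. Zeros and negatives are rejected: substituting e.g. LoQ/2 for
    censored values is the caller's explicit decision, never silent.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise UndefinedResultError("empty series")
    if np.any(arr <= 0):
        raise OutOfRangeError("geometric summary requires strictly positive values")
    logs = np.log(arr)
    geomean = float(np.exp(logs.mean()))
    if arr.size == 1:
        return GeometricSummary(geomean, 0.0)
    gcv = float(np.exp(logs.std(ddof=1)) - 1.0)
    return GeometricSummary(geomean, gcv)


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b rank correlation with tie correction.

    Used instead of Pearson/Spearman because monitoring series contain
    many tied values (censored chlorine, duplicate counts).
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise OutOfRangeError("x and y must be 1-D of equal length")
    if x_arr.size < 2:
        raise UndefinedResultError("need at least two observations")
    tau = stats.kendalltau(x_arr, y_arr, variant="b").statistic
    if math.isnan(tau):
        raise UndefinedResultError("tau-b undefined (a variable is constant)")
    return float(tau)


def ratio_of_geometric_means(
    numerators: Sequence[float], denominators: Sequence[float]
) -> float:
    """Phase-level ratio as geomean(num)/geomean(den).

    Equals the geometric mean of per-sample ratios when the series are
    paired. This is the convention matching tables of geometric means.
    """
    return (
        geometric_summary(numerators).geometric_mean
        / geometric_summary(denominators).geometric_mean
    )


def mean_of_ratios(
    numerators: Sequence[float], denominators: Sequence[float]
) -> float:
    """Phase-level ratio as the arithmetic mean of per-sample ratios.

    The alternative averaging convention; reported alongside
    :func:`ratio_of_geometric_means` because phase summaries in the
    literature do not always state which was used.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    if num.shape != den.shape or num.size == 0:
        raise OutOfRangeError("paired series of equal nonzero length required")
    if np.any(den <= 0):
        raise UndefinedResultError("denominator <= 0 in a pair")
    return float(np.mean(num / den))
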