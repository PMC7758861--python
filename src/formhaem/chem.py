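"""Internal-standard calibration quantification and Beer-Lambert kinetics.

Calibration: analyte peak areas are ratioed to internal-standard areas
and regressed (ordinary least squares, unweighted) on nominal
concentration; unknowns are back-calculated from the fitted line and
converted between mg/l and µM with the analyte molar mass. Enzyme
activity: NADH production follows A = ε·c·L with ε = 6220 l·mol⁻¹·cm⁻¹
at 340 nm; the pre-addition baseline slope is subtracted from the
post-addition slope before conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from formhaem.errors import InputError
from formhaem.simulate.chemistry import FORMALDEHYDE_MW, MG_PER_L_TO_UM

NADH_EXTINCTION = 6220.0  # l mol^-1 cm^-1 at 340 nm


@dataclass
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float
    range_mg_per_l: tuple[float, float]
    level_cv: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class ActivityParams:
    epsilon: float = NADH_EXTINCTION
    path_length_cm: float = 1.0
    reaction_volume_l: float = 0.002
    protein_mass_mg: float = 0.5

    def __post_init__(self) -> None:
        if min(self.epsilon, self.path_length_cm, self.reaction_volume_l, self.protein_mass_mg) <= 0:
            raise InputError("all activity parameters must be > 0")


def _ratios(records: pd.DataFrame) -> pd.Series:
    if (records["analyte_area"] <= 0).any() or (records["is_area"] <= 0).any():
        raise InputError("peak areas must be positive")
    return records["analyte_area"] / records["is_area"]


def fit_calibration(standards: pd.DataFrame) -> CalibrationCurve:
    """OLS of area ratio on nominal concentration, with per-level CVs."""
    standards = standards[standards["role"] == "standard"] if "role" in standards else standards
    if standards.empty:
        raise InputError("no standards provided")
    conc = standards["nominal_mg_per_l"].to_numpy(dtype=float)
    levels = np.unique(conc)
    if len(levels) < 2:
        raise InputError("at least two distinct calibration levels required")
    ratio = _ratios(standards).to_numpy()
    fit = scipy.stats.linregress(conc, ratio)
    cv_rows = []
    for level in levels:
        r = ratio[conc == level]
        cv = float(r.std(ddof=1) / r.mean()) if len(r) > 1 else 0.0
        cv_rows.append(dict(level_mg_per_l=level, n=len(r), cv=cv))
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        range_mg_per_l=(float(levels.min()), float(levels.max())),
        level_cv=pd.DataFrame(cv_rows),
    )


def quantify_samples(
    samples: pd.DataFrame,
    curve: CalibrationCurve,
    output_unit: str = "uM",
    molar_mass: float = FORMALDEHYDE_MW,
) -> pd.DataFrame:
    """Back-calculate concentrations from area ratios via the fitted line.

    Adds ``conc_mg_per_l``, ``conc_uM`` (mg/l × 1000/molar_mass) and an
    ``in_range`` flag for values inside the calibration range.
    """
    if curve.slope == 0:
        raise InputError("calibration slope is zero")
    if output_unit not in ("uM", "mg_per_l"):
        raise InputError(f"unknown output unit {output_unit!r}")
    out = samples.copy()
    ratio = _ratios(out)
    conc = (ratio - curve.intercept) / curve.slope
    out["ratio"] = ratio
    out["conc_mg_per_l"] = conc
    out["conc_uM"] = conc * 1000.0 / molar_mass
    lo, hi = curve.range_mg_per_l
    out["in_range"] = (conc >= lo) & (conc <= hi)
    out["concentration"] = out["conc_uM"] if output_unit == "uM" else out["conc_mg_per_l"]
    return out


def group_fold_change(
    concentrations: pd.DataFrame,
    reference_group: str,
    value_col: str = "concentration",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group mean, SEM and fold-change over the reference group mean."""
    if reference_group not in set(concentrations[group_col]):
        raise InputError(f"reference group {reference_group!r} is empty")
    stats = (
        concentrations.groupby(group_col)[value_col]
        .agg(
            mean="mean",
            sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            n="size",
        )
        .reset_index()
    )
    ref_mean = float(stats.loc[stats[group_col] == reference_group, "mean"].iloc[0])
    if ref_mean <= 0:
        raise InputError("reference group mean must be > 0")
    stats["fold_change"] = stats["mean"] / ref_mean
    return stats


def calibration_precision(
    curve: CalibrationCurve, bound: float = 0.15
) -> tuple[float, bool]:
    """Maximum per-level CV of replicate standards and a pass flag."""
    if curve.level_cv.empty:
        raise InputError("curve carries no per-level CV table")
    max_cv = float(curve.level_cv["cv"].max())
    return max_cv, max_cv <= bound


def _segment_slope(t: np.ndarray, a: np.ndarray) -> float:
    if len(t) < 2:
        raise InputError("each trace segment needs at least 2 points")
    return float(np.polyfit(t, a, 1)[0])


def aldh_activity(
    trace: pd.DataFrame,
    substrate_addition_time: float,
    params: ActivityParams | None = None,
    unit_mode: str = "uM_per_min_per_mg",
) -> float:
    """Enzymatic rate from a two-segment absorbance trace.

    Baseline and reaction slopes are fit by least squares before and after
    substrate addition; the net ΔA/min is converted to a concentration
    rate via A = ε·c·L. Unit modes: ``uM_per_min_per_mg`` (µM NADH per
    minute per mg protein, the default) or ``mol_per_min_per_mg``
    (moles per minute per mg, using the reaction volume).
    """
    params = params or ActivityParams()
    t = trace["time_s"].to_numpy(dtype=float)
    a = trace["absorbance"].to_numpy(dtype=float)
    pre = t <= substrate_addition_time
    post = t > substrate_addition_time
    slope_pre = _segment_slope(t[pre], a[pre])
    slope_post = _segment_slope(t[post], a[post])
    delta_a_per_min = (slope_post - slope_pre) * 60.0
    conc_rate = delta_a_per_min / (params.epsilon * params.path_length_cm)  # mol/l/min
    if unit_mode == "uM_per_min_per_mg":
        return conc_rate * 1e6 / params.protein_mass_mg
    if unit_mode == "mol_per_min_per_mg":
        return conc_rate * params.reaction_volume_l / params.protein_mass_mg
    raise InputError(f"unknown unit mode {unit_mode!r}")


def extinction_coefficient(
    absorbance: float,
    mass_concentration_g_per_l: float,
    molar_mass: float,
    path_length_cm: float = 1.0,
) -> float:
    """Beer-Lambert inversion: ε = A / (c·L) with c in mol/l from a mass concentration."""
    if min(absorbance, mass_concentration_g_per_l, molar_mass, path_length_cm) <= 0:
        raise InputError("all inputs must be > 0")
    molar_conc = mass_concentration_g_per_l / molar_mass
    return absorbance / (molar_conc * path_length_cm)
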