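"""Synthetic GC-MS calibration batches and spectrophotometer traces.

The GC-MS generator emulates an internal-standard workflow: each
calibration standard and serum sample yields an analyte peak area and an
internal-standard peak area whose ratio sits on a true line
``ratio = slope·conc + intercept`` perturbed by multiplicative log-normal
noise of a given coefficient of variation. Sample concentrations are
planted per group in µM and converted to mg/l with the formaldehyde molar
mass. The absorbance generator emulates an NADH-production assay: a
baseline segment before substrate addition and a linear reaction segment
after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from formhaem.errors import ConfigurationError
from formhaem.truth import TruthBundle

#: Molar mass of formaldehyde (g/mol); 1 mg/l = 1000/30.026 = 33.30 µM.
FORMALDEHYDE_MW = 30.026
MG_PER_L_TO_UM = 1000.0 / FORMALDEHYDE_MW


@dataclass
class ChemScenario:
    """Study conditions for one simulated GC-MS calibration batch."""

    calib_levels_mg_per_l: list[float] = field(
        default_factory=lambda: [0.1, 0.2, 0.5, 1.0, 2.0, 5.0]
    )
    n_replicates: int = 3
    noise_cv: float = 0.10
    group_true_means_uM: dict[str, float] = field(default_factory=dict)
    group_n: dict[str, int] = field(default_factory=dict)
    slope_true: float = 2.0
    intercept_true: float = 0.05
    is_area: float = 1.0e5
    seed: int = 0

    def __post_init__(self) -> None:
        levels = self.calib_levels_mg_per_l
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if len(levels) < 2:
            raise ConfigurationError("at least two calibration levels required")
        if any(l <= 0 for l in levels) or any(
            b <= a for a, b in zip(levels, levels[1:])
        ):
            raise ConfigurationError("calibration levels must be positive and strictly increasing")
        if set(self.group_true_means_uM) != set(self.group_n):
            raise ConfigurationError("group_true_means_uM and group_n must list the same groups")


def _multiplicative_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean log-normal factors with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-sigma**2 / 2.0, sigma, size)


def generate_gcms_batch(scenario: ChemScenario) -> tuple[pd.DataFrame, TruthBundle]:
    """Generate area records for standards and samples plus ground truth.

    Returns a DataFrame with columns ``sample_id, role, group,
    nominal_mg_per_l, analyte_area, is_area`` and a truth bundle holding
    each sample's true concentration (µM and mg/l) and the true line.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for level in scenario.calib_levels_mg_per_l:
        true_ratio = scenario.slope_true * level + scenario.intercept_true
        noise = _multiplicative_noise(rng, scenario.noise_cv, scenario.n_replicates)
        for r in range(scenario.n_replicates):
            rows.append(
                dict(
                    sample_id=f"std-{level:g}-r{r + 1}",
                    role="standard",
                    group="",
                    nominal_mg_per_l=level,
                    analyte_area=true_ratio * noise[r] * scenario.is_area,
                    is_area=scenario.is_area,
                )
            )
    truth_conc = []
    for group, mean_uM in scenario.group_true_means_uM.items():
        n = scenario.group_n[group]
        conc_mg_l = mean_uM / MG_PER_L_TO_UM
        noise = _multiplicative_noise(rng, scenario.noise_cv, n)
        for i in range(n):
            true_ratio = scenario.slope_true * conc_mg_l + scenario.intercept_true
            sample_id = f"{group}-s{i + 1}"
            rows.append(
                dict(
                    sample_id=sample_id,
                    role="sample",
                    group=group,
                    nominal_mg_per_l=np.nan,
                    analyte_area=true_ratio * noise[i] * scenario.is_area,
                    is_area=scenario.is_area,
                )
            )
            truth_conc.append(
                dict(
                    sample_id=sample_id,
                    group=group,
                    true_uM=mean_uM,
                    true_mg_per_l=conc_mg_l,
                )
            )
    records = pd.DataFrame(rows)
    truth = TruthBundle(
        concentrations=pd.DataFrame(
            truth_conc, columns=["sample_id", "group", "true_uM", "true_mg_per_l"]
        ),
        rates={"slope_true": scenario.slope_true, "intercept_true": scenario.intercept_true},
    )
    return records, truth


def generate_absorbance_trace(
    baseline_slope: float,
    reaction_slope: float,
    duration_s: float = 650.0,
    noise_sd: float = 0.0,
    substrate_addition_time: float = 300.0,
    initial_absorbance: float = 0.05,
    dt: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate a two-segment absorbance recording (baseline, then reaction).

    The baseline segment absorbs endogenous-substrate turnover; at
    ``substrate_addition_time`` the reaction slope takes over. Returns a
    time/absorbance DataFrame (with the addition time in ``attrs``) and the
    planted slopes.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    if not 0 < substrate_addition_time < duration_s:
        raise ConfigurationError("duration must cover baseline and reaction segments")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt / 2, dt)
    absorbance = np.where(
        t <= substrate_addition_time,
        initial_absorbance + baseline_slope * t,
        initial_absorbance
        + baseline_slope * substrate_addition_time
        + reaction_slope * (t - substrate_addition_time),
    )
    if noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, noise_sd, len(t))
    trace = pd.DataFrame({"time_s": t, "absorbance": absorbance})
    trace.attrs["substrate_addition_time"] = substrate_addition_time
    truth = TruthBundle(
        rates={"baseline_slope": baseline_slope, "reaction_slope": reaction_slope}
    )
    return trace, truth
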