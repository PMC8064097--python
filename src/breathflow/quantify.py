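"""Quantification: primary-ion normalization, first-order kinetic
concentration calculation, detection limits, and the group-wise retention
filter.

The instrument reports counts per second (cps) per integrated peak.  A
product-ion signal is first normalized to counts per 10^6 primary
(reagent) ions using the two isotopologue channels (m/z 21.02 x 500 and
m/z 39.03 x 250), then converted to a volume mixing ratio via first-order
proton-transfer kinetics::

    [VOC] = I_RH+ / (I_H3O+ . k . t)      (number density in the drift tube)
    ppbv  = [VOC] / N * 1e9,   N = p / (kB T)

with reaction-rate coefficient ``k`` (compound specific where known,
2e-9 cm^3/s otherwise) and reaction time ``t`` in the drift tube.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GROUPS, IonChannel, primary_channels

logger = logging.getLogger(__name__)

#: Boltzmann constant, J/K.
K_BOLTZMANN = 1.380649e-23

#: 1 Townsend in V cm^2.
TOWNSEND = 1e-17


@dataclass
class KineticConfig:
    """Drift-tube operating point and kinetic constants.

    Defaults reflect a standard breath operating point: 600 V drift
    voltage, 2.6 mbar and 60 C in the drift tube (E/N close to 120 Td for
    the default 8.85 cm drift length) and a 100 us reaction time.
    Compound-specific rate coefficients override the 2e-9 cm^3/s default
    for ions where experimentally determined values exist.
    """

    k_default: float = 2.0e-9          # cm^3 s^-1
    k_overrides: dict[str, float] = field(default_factory=lambda: {
        "mz59.05": 3.00e-9,            # acetone
        "mz69.07": 1.94e-9,            # isoprene
        "mz33.03": 2.33e-9,            # methanol
    })
    reaction_time_s: float = 100e-6
    drift_voltage_v: float = 600.0
    drift_pressure_mbar: float = 2.6
    drift_temperature_c: float = 60.0
    drift_length_m: float | None = 0.0885
    normalization_target: float = 1e6  # primary-ion-equivalent counts
    lod_sigma: float = 3.0             # IUPAC blank criterion multiplier

    def __post_init__(self) -> None:
        for name, value in (("k_default", self.k_default),
                            ("reaction_time_s", self.reaction_time_s),
                            ("drift_voltage_v", self.drift_voltage_v),
                            ("drift_pressure_mbar", self.drift_pressure_mbar),
                            ("normalization_target", self.normalization_target)):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.drift_temperature_c <= -273.15:
            raise ValueError("drift temperature below absolute zero")
        for k in self.k_overrides.values():
            if k <= 0:
                raise ValueError("rate coefficients must be positive")

    def rate_coefficient(self, ion: str) -> float:
        return self.k_overrides.get(ion, self.k_default)

    def number_density_cm3(self) -> float:
        """Gas number density in the drift tube, cm^-3."""
        p_pa = self.drift_pressure_mbar * 100.0
        t_k = self.drift_temperature_c + 273.15
        return p_pa / (K_BOLTZMANN * t_k) / 1e6

    def ppbv_per_ncps(self, ion: str) -> float:
        """ppbv corresponding to 1 normalized count (per 10^6 primary ions)."""
        k = self.rate_coefficient(ion)
        ratio = 1.0 / self.normalization_target
        density = ratio / (k * self.reaction_time_s)      # cm^-3
        return density / self.number_density_cm3() * 1e9


def normalize_primary_ions(cps_ion, cps_mz21, cps_mz39,
                           target: float = 1e6):
    """Normalize product-ion cps to counts per ``target`` primary ions.

    The reagent-ion signal is reconstructed from its isotopologues as
    500 x cps(21.02) + 250 x cps(39.03).  Accepts scalars or arrays.
    """
    denom = 500.0 * np.asarray(cps_mz21, dtype=float) \
        + 250.0 * np.asarray(cps_mz39, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("zero primary-ion signal; sample invalid")
    out = np.asarray(cps_ion, dtype=float) * target / denom
    return float(out) if np.isscalar(cps_ion) else out


def cps_to_concentration(ncps, config: KineticConfig, ion: str):
    """Convert normalized counts to ppbv via first-order kinetics."""
    return np.asarray(ncps, dtype=float) * config.ppbv_per_ncps(ion) \
        if not np.isscalar(ncps) else float(ncps) * config.ppbv_per_ncps(ion)


def compute_reduced_field(config: KineticConfig,
                          nominal_td: float = 120.0,
                          warn_fraction: float = 0.10) -> float | None:
    """Reduced electric field E/N in Townsend; a configuration sanity check.

    Returns ``None`` (with a warning) when the drift length is unset.
    Logs a warning when the result is more than ``warn_fraction`` away
    from the nominal operating point.
    """
    if config.drift_length_m is None:
        logger.warning("drift length unset; E/N unavailable")
        return None
    e_field = config.drift_voltage_v / (config.drift_length_m * 100.0)  # V/cm
    en = e_field / config.number_density_cm3() / TOWNSEND
    if abs(en - nominal_td) > warn_fraction * nominal_td:
        logger.warning("E/N = %.1f Td differs from the nominal %.0f Td; "
                       "check drift settings", en, nominal_td)
    return en


@dataclass
class ConcentrationMatrix:
    """Samples x ions concentration matrix with LoD bookkeeping.

    ``values`` rows are indexed by (participant, timepoint, replicate);
    ``below_lod`` marks entries that were strictly below the ion's LoD
    before replacement, ``replaced`` marks entries that were set to the
    LoD value, ``lods`` holds per-ion LoDs in ppbv and ``retained`` the
    ions surviving the group-wise retention filter.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    replaced: pd.DataFrame
    lods: pd.Series
    retained: list[str] = field(default_factory=list)

    def retained_values(self) -> pd.DataFrame:
        return self.values[self.retained]


def compute_lod(background: pd.DataFrame, config: KineticConfig,
                primary21: str = "mz21.02", primary39: str = "mz39.03",
                min_ticks: int = 10) -> pd.Series:
    """Per-ion LoD from catalyzed-air background, on the ppbv scale.

    ``background`` holds background-phase ticks (rows) by channel
    (columns) in cps, including the two primary-ion channels used to
    normalize each tick.  LoD = mean + ``lod_sigma`` x sd of the blank
    concentration series (IUPAC 3-sigma convention; no calibration slope
    exists for direct kinetic quantification).
    """
    if len(background) < min_ticks:
        raise ValueError(
            f"need >= {min_ticks} background ticks, got {len(background)}")
    for col in (primary21, primary39):
        if col not in background.columns:
            raise ValueError(f"background lacks primary channel {col}")
    lods = {}
    for ion in background.columns:
        if ion in (primary21, primary39):
            continue
        ncps = normalize_primary_ions(
            background[ion].to_numpy(), background[primary21].to_numpy(),
            background[primary39].to_numpy(), target=config.normalization_target)
        conc = ncps * config.ppbv_per_ncps(ion)
        lods[ion] = float(conc.mean() + config.lod_sigma * conc.std(ddof=1))
    return pd.Series(lods, name="lod_ppbv")


def apply_lod(values: pd.DataFrame, lods: pd.Series) -> ConcentrationMatrix:
    """Replace below-LoD entries by the LoD itself and record the masks."""
    missing = [c for c in values.columns if c not in lods.index]
    if missing:
        raise ValueError(f"no LoD available for ions: {missing}")
    lod_row = lods[values.columns]
    below = values.lt(lod_row, axis=1)
    replaced = below.copy()
    out = values.mask(below, lod_row, axis=1)
    n_rep = int(replaced.to_numpy().sum())
    if n_rep:
        logger.info("replaced %d below-LoD entries by the LoD value", n_rep)
    return ConcentrationMatrix(values=out, below_lod=below, replaced=replaced,
                               lods=lod_row)


def filter_ions(matrix: ConcentrationMatrix, groups: pd.Series,
                min_fraction: float = 0.5) -> list[str]:
    """Retain ions above LoD in more than half the samples of every group.

    ``groups`` maps each row of the matrix to its study group; the
    fraction must exceed ``min_fraction`` strictly, within each group
    separately.  Sets ``matrix.retained`` and returns it.
    """
    groups = groups.reindex(matrix.values.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    above = ~matrix.below_lod
    retained: list[str] = []
    group_levels = [g for g in GROUPS if g in set(groups)] or sorted(set(groups))
    for g in group_levels:
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g} has no samples; filter undefined")
    for ion in matrix.values.columns:
        ok = all(above.loc[groups == g, ion].mean() > min_fraction
                 for g in group_levels)
        if ok:
            retained.append(ion)
        else:
            logger.info("ion %s dropped by the %d%%-above-LoD filter", ion,
                        int(min_fraction * 100))
    matrix.retained = retained
    return retained
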