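"""Thiol–disulphide redox state: Nernst half-cell potentials and the redox environment.

Seed ageing is accompanied by oxidation of the low-molecular-weight thiol pool
(glutathione, cysteine, γ-glutamylcysteine, cysteinylglycine).  For a couple in
which one disulphide (RSSR) is reduced to two thiols (2 RSH) by a 2-electron /
2-proton transfer, the half-cell reduction potential is

    E = E°'(pH) − (R·T / 2F) · ln([RSH]² / [RSSR])

with E°'(pH) the standard potential corrected from its reference pH by the
−(ln 10 · R·T / F) mV per pH unit slope of a 2H⁺/2e⁻ couple.  The squared thiol
term makes E concentration dependent: at equal redox ratio, a more dilute pool
is more oxidising.

The aggregate "redox environment" is the sum over couples of the half-cell
potential multiplied by the molar concentration of the reduced species
(units mV·M); it weights each couple by its reducing capacity, so glutathione —
the most abundant thiol in seeds — dominates the score.

Measured amounts come in µmol per g dry weight; conversion to molarity requires
the tissue water volume per g dry weight (``hydration_mL_per_gDW``), which is a
declared parameter of the analysis, not something the chemistry fixes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.constants import R as _R_GAS  # J mol^-1 K^-1, CODATA
from scipy.constants import physical_constants

from .errors import InvalidInputError, InvalidParameterError, UndefinedPotentialError

_FARADAY = physical_constants["Faraday constant"][0]  # C mol^-1, CODATA
_LN10 = math.log(10.0)

log = logging.getLogger(__name__)

__all__ = [
    "ThiolCoupleSpec",
    "RedoxSample",
    "HalfCellPotential",
    "RedoxEnvironmentResult",
    "EnzymeAssayRecord",
    "DEFAULT_COUPLES",
    "default_couple_registry",
    "hydration_from_moisture",
    "molar_concentration",
    "half_cell_potential",
    "redox_environment",
    "enzyme_activity_nkat_per_gDW",
    "potentials_table",
    "redox_environment_table",
    "summarize_by_time",
]


@dataclass(frozen=True)
class ThiolCoupleSpec:
    """Chemical identity and standard potential of a 2-thiol/1-disulphide couple."""

    name: str
    standard_potential_mV: float
    protons_per_electron_pair: int = 2
    reference_pH: float = 7.0

    def __post_init__(self):
        if not math.isfinite(self.standard_potential_mV):
            raise InvalidParameterError(f"{self.name}: standard potential must be finite")
        if not 0.0 <= self.reference_pH <= 14.0:
            raise InvalidParameterError(f"{self.name}: reference pH outside [0, 14]")

    def standard_potential_at(self, pH: float, temperature_K: float = 298.15) -> float:
        """E°' corrected to ``pH``, in mV.

        For an m H⁺ / 2 e⁻ couple the slope is −(m/2)·(ln10·R·T/F) mV per pH unit.
        """
        slope = -(self.protons_per_electron_pair / 2.0) * 1000.0 * _LN10 * _R_GAS * temperature_K / _FARADAY
        return self.standard_potential_mV + slope * (pH - self.reference_pH)


# Standard potentials at pH 7.0, 25 °C.  The glutathione value is the widely
# used −240 mV; the minor couples default to the same placeholder until the
# user overrides them (a warning is logged once per registry construction).
_PLACEHOLDER_E0 = -240.0


def default_couple_registry(
    overrides: Mapping[str, float] | None = None, warn_placeholders: bool = True
) -> dict[str, ThiolCoupleSpec]:
    """Registry of the four couples measured in seed ageing studies.

    ``overrides`` maps couple name to standard potential (mV at pH 7, 25 °C).
    Couples left at the placeholder value are reported in the log.
    """
    names = ["GSSG/2GSH", "cystine/2Cys", "Cys-bis-Gly/2Cys-Gly", "bis-gGluCys/2gGluCys"]
    overrides = dict(overrides or {})
    registry = {}
    placeholders = []
    for name in names:
        e0 = overrides.pop(name, _PLACEHOLDER_E0)
        if name != "GSSG/2GSH" and e0 == _PLACEHOLDER_E0:
            placeholders.append(name)
        registry[name] = ThiolCoupleSpec(name=name, standard_potential_mV=e0)
    for name, e0 in overrides.items():  # user-defined extra couples
        registry[name] = ThiolCoupleSpec(name=name, standard_potential_mV=e0)
    if placeholders and warn_placeholders:
        log.warning(
            "standard potentials for %s default to the %.0f mV placeholder; "
            "override them for quantitative use",
            ", ".join(placeholders),
            _PLACEHOLDER_E0,
        )
    return registry


DEFAULT_COUPLES = default_couple_registry(warn_placeholders=False)


@dataclass
class RedoxSample:
    """Per-replicate amounts (µmol g⁻¹ DW) of each couple's thiol and disulphide."""

    time_days: float
    replicate_id: str
    amounts: Mapping[str, tuple[float, float]]  # couple -> (thiol, disulphide)
    hydration_mL_per_gDW: float = 1.0

    def __post_init__(self):
        if self.time_days < 0:
            raise InvalidParameterError("time_days must be >= 0")
        if self.hydration_mL_per_gDW <= 0:
            raise InvalidParameterError("hydration must be > 0")
        for couple, (thiol, disulphide) in self.amounts.items():
            if thiol < 0 or disulphide < 0:
                raise InvalidParameterError(f"{couple}: negative amount")


@dataclass(frozen=True)
class HalfCellPotential:
    couple: str
    E_mV: float
    thiol_M: float
    disulphide_M: float
    temperature_K: float = 298.15
    pH: float = 7.0


@dataclass(frozen=True)
class RedoxEnvironmentResult:
    value_mV_M: float
    contributions: dict[str, float]
    fractions: dict[str, float]


@dataclass(frozen=True)
class EnzymeAssayRecord:
    """Spectrophotometric NADPH/NADP⁺ assay at 340 nm."""

    delta_A_per_s: float
    epsilon_mM_cm: float = 6.22
    path_cm: float = 1.0
    assay_volume_L: float = 1e-3
    tissue_mass_gDW: float = 0.05

    def __post_init__(self):
        for attr in ("epsilon_mM_cm", "path_cm", "assay_volume_L", "tissue_mass_gDW"):
            if getattr(self, attr) <= 0:
                raise InvalidParameterError(f"{attr} must be > 0")


def hydration_from_moisture(moisture_content_fw: float) -> float:
    """Tissue water volume (mL per g DW) from fresh-weight moisture content.

    MC is water mass over fresh mass; with water density 1 g/mL,
    12% MC gives 0.12/0.88 = 0.1364 mL g⁻¹ DW.
    """
    if not 0.0 < moisture_content_fw < 1.0:
        raise InvalidParameterError("moisture content must be in (0, 1), fresh-weight basis")
    return moisture_content_fw / (1.0 - moisture_content_fw)


def molar_concentration(amount_umol_per_gDW: float, hydration_mL_per_gDW: float) -> float:
    """Convert µmol per g DW to mol L⁻¹ given the water volume per g DW."""
    if hydration_mL_per_gDW <= 0:
        raise InvalidParameterError("hydration_mL_per_gDW must be > 0")
    if amount_umol_per_gDW < 0:
        raise InvalidParameterError("amount must be >= 0")
    # µmol/gDW over mL/gDW is µmol/mL = mmol/L
    return amount_umol_per_gDW * 1e-3 / hydration_mL_per_gDW


def half_cell_potential(
    couple: ThiolCoupleSpec,
    thiol_M: float,
    disulphide_M: float,
    temperature_K: float = 298.15,
    pH: float = 7.0,
    detection_limit_M: float | None = None,
) -> HalfCellPotential:
    """Nernst half-cell reduction potential of a thiol/disulphide couple, in mV.

    ``detection_limit_M``, when given, floors zero concentrations at the limit
    (with a warning) instead of raising, so batch time-course runs proceed.
    """
    if temperature_K <= 0:
        raise InvalidParameterError("temperature_K must be > 0")
    if detection_limit_M is not None:
        if detection_limit_M <= 0:
            raise InvalidParameterError("detection_limit_M must be > 0")
        if thiol_M <= 0 or disulphide_M <= 0:
            log.warning(
                "%s: concentration at/below zero floored to detection limit %.3g M",
                couple.name,
                detection_limit_M,
            )
        thiol_M = max(thiol_M, detection_limit_M)
        disulphide_M = max(disulphide_M, detection_limit_M)
    if thiol_M <= 0 or disulphide_M <= 0:
        raise UndefinedPotentialError(
            f"{couple.name}: potential undefined for nonpositive concentration "
            f"(thiol={thiol_M!r}, disulphide={disulphide_M!r})"
        )
    e0 = couple.standard_potential_at(pH, temperature_K)
    nernst = 1000.0 * _R_GAS * temperature_K / (2.0 * _FARADAY)  # mV
    e = e0 - nernst * math.log(thiol_M * thiol_M / disulphide_M)
    return HalfCellPotential(
        couple=couple.name,
        E_mV=e,
        thiol_M=thiol_M,
        disulphide_M=disulphide_M,
        temperature_K=temperature_K,
        pH=pH,
    )


def redox_environment(potentials: Sequence[HalfCellPotential]) -> RedoxEnvironmentResult:
    """Sum of (half-cell potential × reduced-species molarity) over couples, mV·M."""
    if not potentials:
        raise InvalidInputError("redox_environment requires at least one couple")
    contributions = {p.couple: p.E_mV * p.thiol_M for p in potentials}
    value = math.fsum(contributions.values())
    if value != 0.0:
        fractions = {c: v / value for c, v in contributions.items()}
    else:
        fractions = {c: float("nan") for c in contributions}
    return RedoxEnvironmentResult(value_mV_M=value, contributions=contributions, fractions=fractions)


def enzyme_activity_nkat_per_gDW(record: EnzymeAssayRecord) -> float:
    """Enzyme activity in nkat per g DW from an A340 rate.

    1 katal = 1 mol substrate converted per second.  Beer–Lambert gives the
    molar rate as ΔA/(ε·l); multiplied by the assay volume and divided by the
    tissue mass this is mol s⁻¹ g⁻¹, reported ×10⁹ as nkat g⁻¹ DW.
    """
    rate_M_per_s = record.delta_A_per_s / (record.epsilon_mM_cm * record.path_cm) * 1e-3
    mol_per_s = rate_M_per_s * record.assay_volume_L
    return mol_per_s / record.tissue_mass_gDW * 1e9


# --------------------------------------------------------------------------
# batch helpers over tidy tables


def potentials_table(
    samples: Sequence[RedoxSample],
    registry: Mapping[str, ThiolCoupleSpec] | None = None,
    temperature_K: float = 298.15,
    pH: float = 7.0,
    detection_limit_M: float | None = None,
) -> pd.DataFrame:
    """Per-replicate, per-couple half-cell potentials for a set of samples.

    Returns a tidy frame with columns ``time_days, replicate, couple, thiol_M,
    disulphide_M, E_mV``.  Couples absent from the registry raise; couples with
    undefined potentials are skipped with a warning unless a detection limit is
    configured.
    """
    registry = dict(registry or DEFAULT_COUPLES)
    rows = []
    for sample in samples:
        for couple_name, (thiol_amt, dis_amt) in sample.amounts.items():
            if couple_name not in registry:
                raise InvalidInputError(f"couple '{couple_name}' not in registry")
            thiol_M = molar_concentration(thiol_amt, sample.hydration_mL_per_gDW)
            dis_M = molar_concentration(dis_amt, sample.hydration_mL_per_gDW)
            try:
                p = half_cell_potential(
                    registry[couple_name], thiol_M, dis_M, temperature_K, pH, detection_limit_M
                )
            except UndefinedPotentialError:
                log.warning(
                    "skipping %s (t=%g d, rep %s): zero concentration and no detection limit",
                    couple_name,
                    sample.time_days,
                    sample.replicate_id,
                )
                continue
            rows.append(
                {
                    "time_days": sample.time_days,
                    "replicate": sample.replicate_id,
                    "couple": couple_name,
                    "thiol_M": p.thiol_M,
                    "disulphide_M": p.disulphide_M,
                    "E_mV": p.E_mV,
                }
            )
    return pd.DataFrame(rows)


def redox_environment_table(potentials: pd.DataFrame) -> pd.DataFrame:
    """Redox environment per (time, replicate) from a `potentials_table` frame."""
    rows = []
    for (t, rep), grp in potentials.groupby(["time_days", "replicate"], sort=True):
        ps = [
            HalfCellPotential(couple=r.couple, E_mV=r.E_mV, thiol_M=r.thiol_M, disulphide_M=r.disulphide_M)
            for r in grp.itertuples()
        ]
        res = redox_environment(ps)
        rows.append({"time_days": t, "replicate": rep, "redox_environment_mV_M": res.value_mV_M})
    return pd.DataFrame(rows)


def summarize_by_time(table: pd.DataFrame, value_col: str, by: Sequence[str] = ("time_days",)) -> pd.DataFrame:
    """Mean ± SE of ``value_col`` per group; no imputation of missing replicates."""
    g = table.groupby(list(by))[value_col]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")
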