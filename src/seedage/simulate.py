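"""Synthetic ageing-time-course generator.

Emulates the four data streams of a seed artificial-ageing experiment so the
whole pipeline is testable without any external download:

* **redox** — thiol/disulphide amounts (µmol g⁻¹ DW) for four couples across
  the ageing time course.  The non-aged glutathione pool is 1.9 µmol g⁻¹ DW
  with an 11% disulphide share, moving to roughly half the pool and a 37%
  disulphide share in fully aged seeds; the trajectory between the two anchors
  is a normalised logistic in time (the anchors are the claim, the shape is a
  generator convenience).  Replicates get lognormal noise at a stated CV.
* **germination** — binomial counts with P(germinate) = Φ(β·(E − dose50))
  linked to the pre-noise glutathione half-cell potential, dose50 = −185 mV.
* **qPCR** — logistic fluorescence curves with growth rate k = 1/ln(E_true),
  a stable spiked-in reference gene and target genes whose fold change
  declines (1.0 → 0.5 → 0.25) over the course; Gaussian fluorescence noise.
* **arrays** — 5,220 probes × 3 replicate spots × 3 arrays per ageing time
  point; per-probe variances drawn from a scaled inverse-χ² prior
  (d0 = 4, s0² = 0.09), a DE fraction with |log₂ FC| ∈ {1.0, 1.5, 2.0}, and
  sinusoidal intensity-dependent print-tip block bias.

Every generator is a pure function of (scenario, seed): identical inputs give
bit-identical tables.  Pre-noise truth tables are returned alongside the data
so downstream stages always have a recovery oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import redox as _redox
from .errors import InvalidParameterError

__all__ = [
    "CoupleTrajectory",
    "RedoxParams",
    "ViabilityParams",
    "GeneParams",
    "QpcrParams",
    "ArrayParams",
    "AgeingScenario",
    "DEFAULT_SPECIES_MAP",
    "redox_truth",
    "gen_redox_timecourse",
    "gen_germination",
    "gen_qpcr_curves",
    "gen_two_color_arrays",
]

# couple -> (thiol species name, disulphide species name) in long-format tables
DEFAULT_SPECIES_MAP: dict[str, tuple[str, str]] = {
    "GSSG/2GSH": ("GSH", "GSSG"),
    "cystine/2Cys": ("Cys", "cystine"),
    "Cys-bis-Gly/2Cys-Gly": ("Cys-Gly", "Cys-bis-Gly"),
    "bis-gGluCys/2gGluCys": ("gGlu-Cys", "bis-gGlu-Cys"),
}

_STREAMS = {"redox": 0, "germination": 1, "qpcr": 2, "array": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


def _logistic_interp(t: np.ndarray, start: float, end: float, midpoint: float, rate: float) -> np.ndarray:
    """Logistic interpolation anchored exactly at t[0] -> start, t[-1] -> end."""
    t = np.asarray(t, dtype=float)
    f = 1.0 / (1.0 + np.exp(-rate * (t - midpoint)))
    f0, f1 = f.min(), f.max()
    if f1 == f0:
        return np.full_like(t, start)
    g = (f - f0) / (f1 - f0)
    return start + (end - start) * g


@dataclass(frozen=True)
class CoupleTrajectory:
    """Pre-noise endpoint anchors (µmol g⁻¹ DW) for one redox couple."""

    thiol_start: float
    thiol_end: float
    disulphide_start: float
    disulphide_end: float


@dataclass(frozen=True)
class RedoxParams:
    # Non-aged glutathione: 1.9 µmol/g DW total, 11% GSSG; aged (55 d): half
    # the total, 37% GSSG.  Minor couples are an order of magnitude smaller,
    # with disulphides rising.
    couples: Mapping[str, CoupleTrajectory] = field(
        default_factory=lambda: {
            "GSSG/2GSH": CoupleTrajectory(1.9 * 0.89, 0.95 * 0.63, 1.9 * 0.11, 0.95 * 0.37),
            "cystine/2Cys": CoupleTrajectory(0.05, 0.09, 0.01, 0.03),
            "Cys-bis-Gly/2Cys-Gly": CoupleTrajectory(0.03, 0.035, 0.005, 0.015),
            "bis-gGluCys/2gGluCys": CoupleTrajectory(0.06, 0.04, 0.008, 0.04),
        }
    )
    midpoint_days: float = 28.0
    rate_per_day: float = 0.12
    replicate_cv: float = 0.10
    n_replicates: int = 5
    hydration_mL_per_gDW: float = 0.12 / 0.88  # 12% fresh-weight moisture content


@dataclass(frozen=True)
class ViabilityParams:
    dose50_mV: float = -185.0
    slope_per_mV: float = -0.25
    seeds_per_test: int = 20
    n_replicates: int = 3


@dataclass(frozen=True)
class GeneParams:
    efficiency: float = 2.0
    base_c_half: float = 24.0
    # fold change relative to the non-aged control at each qPCR time point
    fold_by_time: Mapping[float, float] = field(default_factory=lambda: {0.0: 1.0, 25.0: 0.5, 55.0: 0.25})
    is_reference: bool = False


@dataclass(frozen=True)
class QpcrParams:
    genes: Mapping[str, GeneParams] = field(
        default_factory=lambda: {
            "PBGD": GeneParams(
                efficiency=2.0,
                base_c_half=21.0,
                fold_by_time={0.0: 1.0, 25.0: 1.0, 55.0: 1.0},
                is_reference=True,
            ),
            "GR": GeneParams(efficiency=1.9, base_c_half=25.0),
            "VDAC": GeneParams(efficiency=2.0, base_c_half=24.0),
        }
    )
    reference_gene: str = "PBGD"
    time_points_days: tuple[float, ...] = (0.0, 25.0, 55.0)
    n_cycles: int = 45
    n_replicates: int = 5
    noise_sigma: float = 0.05
    baseline: float = 0.1
    plateau: float = 10.0


@dataclass(frozen=True)
class ArrayParams:
    n_probes: int = 5220
    spots_per_probe: int = 3
    n_arrays: int = 3
    time_points_days: tuple[float, ...] = (8.0, 12.0, 15.0)
    de_fraction: float = 0.05
    de_magnitudes: tuple[float, ...] = (1.0, 1.5, 2.0)
    d0: float = 4.0
    s0_sq: float = 0.09
    spot_sigma: float = 0.1
    n_blocks: int = 16
    block_bias_amplitude: float = 0.5
    a_range: tuple[float, float] = (6.0, 16.0)


@dataclass(frozen=True)
class AgeingScenario:
    """All knobs of the synthetic experiment; the defaults are the study design."""

    time_points_days: tuple[float, ...] = (0.0, 8.0, 10.0, 12.0, 13.0, 15.0, 25.0, 31.0, 55.0)
    seed: int = 0
    redox_params: RedoxParams = field(default_factory=RedoxParams)
    viability_params: ViabilityParams = field(default_factory=ViabilityParams)
    qpcr_params: QpcrParams = field(default_factory=QpcrParams)
    array_params: ArrayParams = field(default_factory=ArrayParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        # mappings with float keys are not JSON/YAML friendly; stringify
        for gene, gp in d["qpcr_params"]["genes"].items():
            gp["fold_by_time"] = {str(k): v for k, v in gp["fold_by_time"].items()}
        return d


# --------------------------------------------------------------------------
# redox stream


def redox_truth(scenario: AgeingScenario) -> pd.DataFrame:
    """Pre-noise amounts, molarities, potentials and environment per time point."""
    rp = scenario.redox_params
    t = np.asarray(scenario.time_points_days, dtype=float)
    registry = _redox.DEFAULT_COUPLES
    rows = []
    for name, traj in rp.couples.items():
        thiol = _logistic_interp(t, traj.thiol_start, traj.thiol_end, rp.midpoint_days, rp.rate_per_day)
        dis = _logistic_interp(t, traj.disulphide_start, traj.disulphide_end, rp.midpoint_days, rp.rate_per_day)
        for ti, th, di in zip(t, thiol, dis):
            thiol_M = _redox.molar_concentration(th, rp.hydration_mL_per_gDW)
            dis_M = _redox.molar_concentration(di, rp.hydration_mL_per_gDW)
            p = _redox.half_cell_potential(registry[name], thiol_M, dis_M)
            rows.append(
                {
                    "time_days": ti,
                    "couple": name,
                    "thiol_umol_per_gDW": th,
                    "disulphide_umol_per_gDW": di,
                    "thiol_M": thiol_M,
                    "disulphide_M": dis_M,
                    "E_mV": p.E_mV,
                }
            )
    truth = pd.DataFrame(rows)
    env = (
        truth.assign(contrib=truth["E_mV"] * truth["thiol_M"])
        .groupby("time_days")["contrib"]
        .sum()
        .rename("redox_environment_mV_M")
    )
    return truth.merge(env, on="time_days")


def gen_redox_timecourse(scenario: AgeingScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format species amounts with lognormal replicate noise, plus truth.

    Returns ``(data, truth)``; data columns are
    ``time_days, replicate, species, amount_umol_per_gDW``.
    """
    rp = scenario.redox_params
    if rp.replicate_cv < 0:
        raise InvalidParameterError("replicate_cv must be >= 0")
    rng = _rng(scenario.seed, "redox")
    truth = redox_truth(scenario)
    sigma = math.sqrt(math.log(1.0 + rp.replicate_cv**2)) if rp.replicate_cv > 0 else 0.0
    rows = []
    for row in truth.itertuples():
        couple = row.couple
        thiol_species, dis_species = DEFAULT_SPECIES_MAP[couple]
        for rep in range(1, rp.n_replicates + 1):
            for species, amount in ((thiol_species, row.thiol_umol_per_gDW), (dis_species, row.disulphide_umol_per_gDW)):
                noisy = amount * math.exp(rng.normal(0.0, sigma) - 0.5 * sigma**2) if sigma > 0 else amount
                rows.append(
                    {
                        "time_days": row.time_days,
                        "replicate": f"R{rep}",
                        "species": species,
                        "amount_umol_per_gDW": noisy,
                    }
                )
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# germination stream


def gen_germination(
    scenario: AgeingScenario,
    doses: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Binomial germination counts probit-linked to the redox dose.

    With ``doses=None`` the doses are the pre-noise glutathione half-cell
    potentials of the scenario's time points (the default study design);
    explicit doses let callers span the viability-loss zone directly.
    Returns ``(data, truth)``; data columns ``dose, n_tested, n_germinated``
    (one row per replicate test).
    """
    vp = scenario.viability_params
    rng = _rng(scenario.seed, "germination")
    truth_redox = redox_truth(scenario)
    if doses is None:
        gsh = truth_redox[truth_redox["couple"] == "GSSG/2GSH"].sort_values("time_days")
        doses = gsh["E_mV"].to_numpy()
        times = gsh["time_days"].to_numpy()
    else:
        doses = np.asarray(doses, dtype=float)
        times = np.full(doses.shape, np.nan)
    alpha = -vp.slope_per_mV * vp.dose50_mV
    rows = []
    for t, d in zip(times, doses):
        p = float(norm.cdf(alpha + vp.slope_per_mV * d))
        for rep in range(1, vp.n_replicates + 1):
            k = int(rng.binomial(vp.seeds_per_test, p))
            rows.append(
                {"time_days": t, "replicate": f"R{rep}", "dose": d, "n_tested": vp.seeds_per_test, "n_germinated": k}
            )
    truth = {
        "alpha": alpha,
        "beta": vp.slope_per_mV,
        "dose50": vp.dose50_mV,
        "doses": [float(d) for d in doses],
        "p_germinate": [float(norm.cdf(alpha + vp.slope_per_mV * d)) for d in doses],
    }
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# qPCR stream


def gen_qpcr_curves(scenario: AgeingScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format fluorescence-by-cycle curves plus the fold-change truth.

    Curve model: F(c) = Fb + Fmax / (1 + exp(−(c − c_half)/k)) with
    k = 1/ln(E_true); a fold change φ shifts the midpoint by −log_E(φ)
    cycles.  The reference gene is emitted only for spiked samples (all
    samples are spiked in the default design).  Data columns:
    ``sample_id, gene, time_days, replicate, cycle, fluorescence, spiked``.
    """
    qp = scenario.qpcr_params
    rng = _rng(scenario.seed, "qpcr")
    cycles = np.arange(1, qp.n_cycles + 1, dtype=float)
    rows = []
    truth_rows = []
    for gene, gp in qp.genes.items():
        k = 1.0 / math.log(gp.efficiency)
        for t in qp.time_points_days:
            fold = gp.fold_by_time.get(t, 1.0)
            c_half = gp.base_c_half - math.log(fold) / math.log(gp.efficiency)
            truth_rows.append(
                {
                    "gene": gene,
                    "time_days": t,
                    "true_fold": fold,
                    "true_efficiency": gp.efficiency,
                    "true_c_half": c_half,
                    "true_ct": c_half - k * math.log(2.0 + math.sqrt(3.0)),
                }
            )
            for rep in range(1, qp.n_replicates + 1):
                clean = qp.baseline + qp.plateau / (1.0 + np.exp(-(cycles - c_half) / k))
                noisy = clean + rng.normal(0.0, qp.noise_sigma, size=cycles.size) if qp.noise_sigma > 0 else clean
                noisy = np.clip(noisy, 0.0, None)
                sample_id = f"t{t:g}_R{rep}"
                for c, fl in zip(cycles, noisy):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "gene": gene,
                            "time_days": t,
                            "replicate": f"R{rep}",
                            "cycle": int(c),
                            "fluorescence": float(fl),
                            "spiked": True,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# array stream


def gen_two_color_arrays(scenario: AgeingScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spot-level M/A table for the aged-vs-control comparisons, plus truth.

    Per probe and time point a true log₂ fold change is drawn (0 for nulls,
    sign ± and magnitude from the stated set for the DE fraction), a per-probe
    variance from s0²·d0/χ²_d0, then per array M = FC + N(0, σ_probe) and per
    spot M = array M + N(0, σ_spot).  A is uniform over the stated range and a
    per-block sinusoidal intensity-dependent bias of the stated amplitude is
    added to M.  Data columns:
    ``probe_id, array_id, time_days, block, spot_index, M, A``.
    """
    ap = scenario.array_params
    rng = _rng(scenario.seed, "array")
    probes = np.array([f"P{i:05d}" for i in range(1, ap.n_probes + 1)])
    a_lo, a_hi = ap.a_range

    data_frames = []
    truth_rows = []
    for t in ap.time_points_days:
        n_de = int(round(ap.de_fraction * ap.n_probes))
        de_idx = rng.choice(ap.n_probes, size=n_de, replace=False)
        fc = np.zeros(ap.n_probes)
        if n_de:
            mags = rng.choice(np.asarray(ap.de_magnitudes, dtype=float), size=n_de)
            signs = rng.choice(np.array([-1.0, 1.0]), size=n_de)
            fc[de_idx] = mags * signs
        sigma2 = ap.s0_sq * ap.d0 / rng.chisquare(ap.d0, size=ap.n_probes)
        for p_i in range(ap.n_probes):
            truth_rows.append(
                {
                    "probe_id": probes[p_i],
                    "time_days": t,
                    "true_log2_fc": fc[p_i],
                    "true_sigma2": sigma2[p_i],
                    "is_de": fc[p_i] != 0.0,
                }
            )
        for a_i in range(1, ap.n_arrays + 1):
            array_m = fc + rng.normal(0.0, np.sqrt(sigma2))
            n_spots = ap.n_probes * ap.spots_per_probe
            spot_m = np.repeat(array_m, ap.spots_per_probe) + rng.normal(0.0, ap.spot_sigma, size=n_spots)
            a_vals = rng.uniform(a_lo, a_hi, size=n_spots)
            blocks = np.arange(n_spots) % ap.n_blocks
            if ap.block_bias_amplitude != 0.0:
                phase = 2.0 * np.pi * blocks / ap.n_blocks
                a_scaled = 2.0 * np.pi * (a_vals - a_lo) / (a_hi - a_lo)
                spot_m = spot_m + ap.block_bias_amplitude * np.sin(a_scaled + phase)
            data_frames.append(
                pd.DataFrame(
                    {
                        "probe_id": np.repeat(probes, ap.spots_per_probe),
                        "array_id": a_i,
                        "time_days": t,
                        "block": blocks,
                        "spot_index": np.tile(np.arange(1, ap.spots_per_probe + 1), ap.n_probes),
                        "M": spot_m,
                        "A": a_vals,
                    }
                )
            )
    return pd.concat(data_frames, ignore_index=True), pd.DataFrame(truth_rows)
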