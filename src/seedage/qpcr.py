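"""qRT-PCR quantification against an exogenous spike-in reference.

RNA from ageing seeds is progressively degraded, so endogenous housekeeping
genes drift and cannot normalise expression.  The workflow modelled here spikes
each RNA sample with a fixed amount of foreign (human) RNA before reverse
transcription and uses a foreign-specific amplicon (PBGD) as the reference: its
amplification reflects only the technical chain, not the biology of the aged
seed.

Per reaction, a four-parameter logistic is fitted to raw fluorescence,

    F(c) = Fb + Fmax / (1 + exp(-(c - c_half)/k)),

the cycle threshold is placed at the curve's second-derivative maximum
(closed form ct = c_half − k·ln(2+√3)), and the amplification efficiency
E ∈ (1, 2] is estimated from the fitted exponential growth rate, E = exp(1/k)
— in the low-fluorescence limit the logistic grows as exp(c/k), i.e. E-fold
per cycle.  An alternative estimator that log-linearly refits raw points in
the [ct, c_half] window is available (``method="exp-window"``); it is biased
low because the logistic already saturates noticeably over that window, and is
provided for diagnostics only.

Expression ratios are efficiency-corrected relative to the non-aged control:

    ratio = E_target^(Ct_ctrl − Ct_sample) / E_ref^(Ct_ctrl − Ct_sample)

with one efficiency per gene (median over that gene's reactions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import (
    FitError,
    InsufficientDataError,
    InvalidInputError,
    NoAmplificationError,
)

__all__ = [
    "AmplificationCurve",
    "SigmoidFit",
    "EfficiencyCt",
    "RelativeExpression",
    "StabilityReport",
    "SpikeInReport",
    "CT_OFFSET_FACTOR",
    "fit_amplification_sigmoid",
    "estimate_efficiency_ct",
    "relative_expression_ratio",
    "expression_ratios_table",
    "reference_stability",
    "spike_in_check",
]

# ct sits k*ln(2+sqrt(3)) cycles before the midpoint: the logistic's second
# derivative is maximal where exp(-(c-c_half)/k) = 2+sqrt(3).
CT_OFFSET_FACTOR = math.log(2.0 + math.sqrt(3.0))


@dataclass
class AmplificationCurve:
    sample_id: str
    gene: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    spiked: bool = True

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.size != self.fluorescence.size:
            raise InvalidInputError("cycles and fluorescence lengths differ")
        if self.cycles.size < 15:
            raise InvalidInputError("need at least 15 cycles")
        if np.any(np.diff(self.cycles) <= 0):
            raise InvalidInputError("cycles must be strictly increasing")
        if np.any(self.fluorescence < 0):
            raise InvalidInputError("fluorescence must be nonnegative")


@dataclass(frozen=True)
class SigmoidFit:
    Fb: float
    Fmax: float
    c_half: float
    k: float
    residual_sse: float


@dataclass(frozen=True)
class EfficiencyCt:
    efficiency: float
    ct: float
    window: tuple[float, float]
    flagged: bool = False  # efficiency above 2 + tolerance


@dataclass(frozen=True)
class RelativeExpression:
    gene: str
    time_days: float
    ratio: float


@dataclass(frozen=True)
class StabilityReport:
    gene: str
    slope_per_day: float
    slope_p_value: float
    r_squared: float
    stable: bool


@dataclass
class SpikeInReport:
    violations: list[str]
    normalization_possible: bool

    @property
    def ok(self) -> bool:
        return self.normalization_possible and not self.violations


def _logistic(c, Fb, Fmax, c_half, k):
    return Fb + Fmax / (1.0 + np.exp(-(c - c_half) / k))


def _baseline_noise(f: np.ndarray) -> float:
    """Noise scale of the pre-amplification baseline: residual SD of a linear
    fit over the first third of cycles (min 5 points)."""
    m = max(5, f.size // 3)
    x = np.arange(m, dtype=float)
    coef = np.polyfit(x, f[:m], 1)
    resid = f[:m] - np.polyval(coef, x)
    return float(np.std(resid))


def fit_amplification_sigmoid(
    curve: AmplificationCurve,
    min_rise_factor: float = 5.0,
) -> SigmoidFit:
    """Least-squares four-parameter logistic fit of a fluorescence curve.

    Raises :class:`NoAmplificationError` for flat curves (rise below
    ``min_rise_factor`` × baseline noise) and :class:`FitError` when the
    optimiser fails from every start, so the two failure modes are
    distinguishable.
    """
    c = curve.cycles
    f = curve.fluorescence
    rise = float(f.max() - f.min())
    noise = _baseline_noise(f)
    floor = max(min_rise_factor * noise, 1e-9 * max(abs(f.max()), 1.0), 1e-12)
    if rise < floor:
        raise NoAmplificationError(
            f"{curve.sample_id}/{curve.gene}: rise {rise:.3g} below {floor:.3g}"
        )

    # method-of-moments starts: midpoint where F crosses half-rise, slope from
    # the 25–75% crossing distance
    fb0 = float(np.median(f[: max(5, f.size // 4)]))
    fmax0 = rise
    half = fb0 + 0.5 * fmax0
    above = np.nonzero(f >= half)[0]
    chalf0 = float(c[above[0]]) if above.size else float(c[f.size // 2])
    q1 = np.nonzero(f >= fb0 + 0.25 * fmax0)[0]
    q3 = np.nonzero(f >= fb0 + 0.75 * fmax0)[0]
    k0 = max((float(c[q3[0]]) - float(c[q1[0]])) / (2 * math.log(3.0)), 0.2) if q1.size and q3.size else 1.5

    best = None
    for k_start in (k0, 1.0 / math.log(2.0), 0.7, 2.5):
        p0 = (fb0, fmax0, chalf0, k_start)
        try:
            popt, _ = curve_fit(
                _logistic,
                c,
                f,
                p0=p0,
                bounds=([-np.inf, 1e-12, c[0] - 10, 1e-3], [np.inf, np.inf, c[-1] + 10, 50.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((f - _logistic(c, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise FitError(f"{curve.sample_id}/{curve.gene}: sigmoid fit did not converge")
    (fb, fmax, chalf, k), sse = best
    return SigmoidFit(Fb=float(fb), Fmax=float(fmax), c_half=float(chalf), k=float(k), residual_sse=sse)


def estimate_efficiency_ct(
    curve: AmplificationCurve,
    fit: SigmoidFit,
    method: str = "growth-rate",
    efficiency_tolerance: float = 0.1,
) -> EfficiencyCt:
    """Amplification efficiency and cycle threshold from a fitted sigmoid.

    ct = c_half − k·ln(2+√3), the second-derivative maximum of the logistic.
    The exponential window runs from ct to the first-derivative maximum
    (c_half).  Default efficiency is exp(1/k), the fitted per-cycle growth
    factor of the early exponential phase; ``method="exp-window"`` instead
    refits F − Fb = F0·E^c over raw points inside the window (≥3 required).
    """
    ct = fit.c_half - fit.k * CT_OFFSET_FACTOR
    window = (ct, fit.c_half)
    if method == "growth-rate":
        eff = math.exp(1.0 / fit.k)
    elif method == "exp-window":
        mask = (curve.cycles >= window[0]) & (curve.cycles <= window[1])
        if mask.sum() < 3:
            raise InsufficientDataError(
                f"exponential window [{window[0]:.2f}, {window[1]:.2f}] holds "
                f"{int(mask.sum())} points (<3)"
            )
        dy = curve.fluorescence[mask] - fit.Fb
        if np.any(dy <= 0):
            raise FitError("nonpositive baseline-corrected fluorescence in window")
        slope = linregress(curve.cycles[mask], np.log(dy)).slope
        eff = math.exp(slope)
    else:
        raise InvalidInputError(f"unknown efficiency method '{method}'")
    flagged = eff > 2.0 + efficiency_tolerance
    return EfficiencyCt(efficiency=float(eff), ct=float(ct), window=window, flagged=flagged)


def relative_expression_ratio(
    e_target: float,
    ct_target_control: float,
    ct_target_sample: float,
    e_reference: float,
    ct_reference_control: float,
    ct_reference_sample: float,
) -> float:
    """Efficiency-corrected expression ratio of target vs reference.

    ratio = E_t^(Ct_ctrl − Ct_sample) / E_r^(Ct_ctrl − Ct_sample), each ΔCt
    taken within its own gene.
    """
    for name, e in (("target", e_target), ("reference", e_reference)):
        if not 1.0 < e <= 2.1:
            raise InvalidInputError(f"{name} efficiency {e} outside (1, 2.1]")
    num = e_target ** (ct_target_control - ct_target_sample)
    den = e_reference ** (ct_reference_control - ct_reference_sample)
    return num / den


def expression_ratios_table(
    efficiency_ct: pd.DataFrame,
    reference_gene: str,
    control_time: float = 0.0,
) -> pd.DataFrame:
    """Per-replicate, per-gene expression ratios relative to the non-aged control.

    ``efficiency_ct`` is long-format with columns ``gene, time_days, replicate,
    efficiency, ct``.  One efficiency per gene is used: the median across all
    of that gene's reactions.  The control Ct per gene is the mean Ct at
    ``control_time``.  Returns columns ``gene, time_days, replicate, ratio``.
    """
    required = {"gene", "time_days", "replicate", "efficiency", "ct"}
    missing = required - set(efficiency_ct.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    if reference_gene not in set(efficiency_ct["gene"]):
        raise InvalidInputError(f"reference gene '{reference_gene}' absent from table")

    eff = efficiency_ct.groupby("gene")["efficiency"].median()
    ctrl = efficiency_ct[efficiency_ct["time_days"] == control_time]
    if ctrl.empty:
        raise InvalidInputError(f"no control reactions at time {control_time}")
    ct_ctrl = ctrl.groupby("gene")["ct"].mean()

    rows = []
    ref_eff = float(eff[reference_gene])
    for (gene, t, rep), grp in efficiency_ct.groupby(["gene", "time_days", "replicate"]):
        if gene == reference_gene:
            continue
        if gene not in ct_ctrl.index:
            raise InvalidInputError(f"gene '{gene}' lacks a control (t={control_time}) reaction")
        ref_row = efficiency_ct[
            (efficiency_ct["gene"] == reference_gene)
            & (efficiency_ct["time_days"] == t)
            & (efficiency_ct["replicate"] == rep)
        ]
        if ref_row.empty:
            raise InvalidInputError(
                f"reference gene '{reference_gene}' missing for t={t}, replicate {rep}"
            )
        ratio = relative_expression_ratio(
            float(eff[gene]),
            float(ct_ctrl[gene]),
            float(grp["ct"].mean()),
            ref_eff,
            float(ct_ctrl[reference_gene]),
            float(ref_row["ct"].mean()),
        )
        rows.append({"gene": gene, "time_days": t, "replicate": rep, "ratio": ratio})
    return pd.DataFrame(rows)


def reference_stability(
    time_days: Sequence[float],
    expression: Sequence[float],
    gene: str = "",
    p_threshold: float = 0.05,
) -> StabilityReport:
    """Regression screen for stable expression over the ageing time course.

    A gene is called stable when the OLS slope of expression vs days does not
    deviate significantly from zero (two-sided t-test at ``p_threshold``).
    """
    t = np.asarray(time_days, dtype=float)
    x = np.asarray(expression, dtype=float)
    if t.size < 3 or t.size != x.size:
        raise InsufficientDataError("need >= 3 matched (time, expression) points")
    if np.ptp(x) == 0.0:
        # exactly constant: slope 0 with undefined t; stable by construction
        return StabilityReport(gene=gene, slope_per_day=0.0, slope_p_value=1.0, r_squared=0.0, stable=True)
    res = linregress(t, x)
    return StabilityReport(
        gene=gene,
        slope_per_day=float(res.slope),
        slope_p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        stable=bool(res.pvalue >= p_threshold),
    )


def _amplifies(curve: AmplificationCurve, min_rise_factor: float = 5.0) -> bool:
    try:
        fit_amplification_sigmoid(curve, min_rise_factor=min_rise_factor)
    except NoAmplificationError:
        return False
    except FitError:
        return False
    return True


def spike_in_check(
    curves: Iterable[AmplificationCurve],
    reference_gene: str,
    ct_tolerance: float = 0.5,
) -> SpikeInReport:
    """Validate the spike-in design on a set of amplification curves.

    Checks that (a) the exogenous reference amplifies only in spiked samples,
    (b) at least one spiked reference reaction exists (else normalisation is
    impossible), and (c) where a sample was run both with and without the
    spike, the non-normalised target Cts agree within ``ct_tolerance`` cycles
    — the spike must not perturb target amplification.  Report-only: never
    raises on violations.
    """
    curves = list(curves)
    violations: list[str] = []
    ref_curves = [cv for cv in curves if cv.gene == reference_gene]
    normalization_possible = any(cv.spiked and _amplifies(cv) for cv in ref_curves)
    if not normalization_possible:
        violations.append(f"no amplifying spiked '{reference_gene}' reference curve: normalization impossible")
    for cv in ref_curves:
        if not cv.spiked and _amplifies(cv):
            violations.append(
                f"reference '{reference_gene}' amplifies in un-spiked sample '{cv.sample_id}'"
            )

    # paired spiked/unspiked targets: compare Ct
    by_key: dict[tuple[str, str], dict[bool, AmplificationCurve]] = {}
    for cv in curves:
        if cv.gene == reference_gene:
            continue
        by_key.setdefault((cv.sample_id, cv.gene), {})[cv.spiked] = cv
    for (sample, gene), pair in by_key.items():
        if True in pair and False in pair:
            cts = {}
            for spiked, cv in pair.items():
                try:
                    fit = fit_amplification_sigmoid(cv)
                except (NoAmplificationError, FitError):
                    continue
                cts[spiked] = estimate_efficiency_ct(cv, fit).ct
            if len(cts) == 2 and abs(cts[True] - cts[False]) > ct_tolerance:
                violations.append(
                    f"target '{gene}' in sample '{sample}': spike shifts Ct by "
                    f"{abs(cts[True] - cts[False]):.2f} cycles (> {ct_tolerance})"
                )
    return SpikeInReport(violations=violations, normalization_possible=normalization_possible)
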