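"""Binomial probit dose–response for seed viability.

Germination percentage is modelled as P(germinate) = Φ(α + β·dose), where the
dose is any stressor axis — here typically a glutathione half-cell potential
(mV) or the summed redox environment (mV·M).  The quantity of interest is the
dose at which 50% of seeds have lost viability, dose50 = −α/β, together with a
confidence zone.  Fitting is by iteratively reweighted least squares (Fisher
scoring) with step halving, which makes the log-likelihood non-decreasing
across iterations; the covariance is the inverse information at the optimum.

β carries no sign constraint: for redox doses viability falls as the potential
becomes more positive (β < 0), but the direction is left to the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import InvalidInputError, SeparationError, UnboundedZoneError

__all__ = [
    "GerminationRecord",
    "ProbitModel",
    "ViabilityZone",
    "total_germination",
    "fit_probit",
    "dose_at_quantile",
]


@dataclass(frozen=True)
class GerminationRecord:
    dose: float
    n_tested: int
    n_germinated: int

    def __post_init__(self):
        if self.n_tested <= 0:
            raise InvalidInputError("n_tested must be > 0")
        if not 0 <= self.n_germinated <= self.n_tested:
            raise InvalidInputError("n_germinated must be in [0, n_tested]")


@dataclass
class ProbitModel:
    alpha: float
    beta: float
    covariance: np.ndarray  # 2x2, (alpha, beta) order
    n_obs: int
    converged: bool
    n_iter: int = 0
    loglik: float = float("nan")
    loglik_path: tuple[float, ...] = ()
    diagnostics: str = ""

    @property
    def se_alpha(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def se_beta(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))


@dataclass(frozen=True)
class ViabilityZone:
    dose50: float
    lower: float
    upper: float
    level: float
    p: float = 0.5
    method: str = "delta"


def total_germination(record: GerminationRecord) -> float:
    """Total germination (TG) as a percentage of tested seeds."""
    return 100.0 * record.n_germinated / record.n_tested


def _loglik(y: np.ndarray, n: np.ndarray, eta: np.ndarray) -> float:
    mu = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (n - y) * np.log1p(-mu)))


def fit_probit(
    records: Sequence[GerminationRecord],
    max_iter: int = 100,
    tol: float = 1e-10,
    beta_bound: float = 1e6,
) -> ProbitModel:
    """Maximum-likelihood probit fit by IRLS with step halving.

    Raises nothing on separation: returns ``converged=False`` with a
    diagnostics string instead, so callers can branch.  Requires at least two
    distinct doses and at least one non-degenerate outcome pattern.
    """
    if len(records) < 2:
        raise InvalidInputError("need at least 2 records")
    dose = np.array([r.dose for r in records], dtype=float)
    n = np.array([r.n_tested for r in records], dtype=float)
    y = np.array([r.n_germinated for r in records], dtype=float)
    X = np.column_stack([np.ones_like(dose), dose])

    bad_cov = np.full((2, 2), np.nan)
    if np.unique(dose).size < 2:
        return ProbitModel(np.nan, np.nan, bad_cov, len(records), False,
                           diagnostics="all doses identical")
    if np.all(y == n) or np.all(y == 0):
        return ProbitModel(np.nan, np.nan, bad_cov, len(records), False,
                           diagnostics="degenerate outcomes: all germinated or none germinated")
    if np.all((y == 0) | (y == n)):
        # every dose is all-or-nothing; if the two groups do not overlap on the
        # dose axis the MLE does not exist (complete separation)
        full = dose[y == n]
        none = dose[y == 0]
        if full.max() < none.min() or none.max() < full.min():
            return ProbitModel(np.nan, np.nan, bad_cov, len(records), False,
                               diagnostics="complete separation: MLE does not exist")

    # start from the empirical-probit least-squares line
    p_emp = np.clip((y + 0.5) / (n + 1.0), 1e-6, 1 - 1e-6)
    theta, *_ = np.linalg.lstsq(X, norm.ppf(p_emp), rcond=None)

    ll = _loglik(y, n, X @ theta)
    path = [ll]
    converged = False
    diagnostics = ""
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ theta
        mu = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
        phi = norm.pdf(eta)
        w = n * phi**2 / (mu * (1 - mu))
        # Fisher scoring step in working-response form
        z = eta + (y / n - mu) / np.maximum(phi, 1e-300)
        WX = X * w[:, None]
        try:
            full_step = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            diagnostics = "singular information matrix"
            break
        # step halving keeps the log-likelihood monotone
        frac = 1.0
        new_theta = full_step
        new_ll = _loglik(y, n, X @ new_theta)
        while new_ll < ll and frac > 1e-8:
            frac /= 2.0
            new_theta = theta + frac * (full_step - theta)
            new_ll = _loglik(y, n, X @ new_theta)
        theta = new_theta
        path.append(new_ll)
        if abs(theta[1]) > beta_bound:
            diagnostics = "diverging slope: complete separation suspected"
            break
        if abs(new_ll - ll) <= tol * (abs(ll) + tol):
            converged = True
            ll = new_ll
            break
        ll = new_ll

    eta = X @ theta
    mu = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
    phi = norm.pdf(eta)
    w = n * phi**2 / (mu * (1 - mu))
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = bad_cov
        converged = False
        diagnostics = diagnostics or "singular information at optimum"

    return ProbitModel(
        alpha=float(theta[0]),
        beta=float(theta[1]),
        covariance=cov,
        n_obs=len(records),
        converged=converged,
        n_iter=it,
        loglik=float(path[-1]),
        loglik_path=tuple(path),
        diagnostics=diagnostics,
    )


def dose_at_quantile(
    model: ProbitModel,
    p: float = 0.5,
    level: float = 0.95,
    method: str = "delta",
    beta_tol: float = 1e-12,
) -> ViabilityZone:
    """Dose at which P(germinate) = p, with a confidence zone.

    ``method='delta'`` propagates the (α, β) covariance through
    dose_p = (Φ⁻¹(p) − α)/β; ``method='fieller'`` inverts the ratio test,
    which is preferred when β is poorly determined.
    """
    if not model.converged:
        raise SeparationError(f"model not converged: {model.diagnostics or 'unknown'}")
    if abs(model.beta) <= beta_tol:
        raise UnboundedZoneError("slope numerically zero; dose at quantile unbounded")
    if not 0 < p < 1:
        raise InvalidInputError("p must be in (0, 1)")
    zp = norm.ppf(p)
    a, b = model.alpha, model.beta
    d = (zp - a) / b
    zc = norm.ppf(0.5 + level / 2.0)
    V = model.covariance
    if method == "delta":
        grad = np.array([-1.0 / b, -d / b])
        var = float(grad @ V @ grad)
        half = zc * np.sqrt(max(var, 0.0))
        lower, upper = d - half, d + half
    elif method == "fieller":
        # invert the test of (zp - a - b*d0) = 0 in d0
        vaa, vab, vbb = V[0, 0], V[0, 1], V[1, 1]
        g = zc**2 * vbb / b**2
        if g >= 1:
            raise UnboundedZoneError("Fieller zone unbounded at this level")
        # Fieller for ratio r = N/b with N = zp - a: var(N)=vaa, cov(N,b) = -vab
        vnn, vnb = vaa, -vab
        mid = (d - g * vnb / vbb) / (1 - g)
        rad = (
            zc
            / (abs(b) * (1 - g))
            * np.sqrt(max(vnn - 2 * d * vnb + d**2 * vbb - g * (vnn - vnb**2 / vbb), 0.0))
        )
        lower, upper = mid - rad, mid + rad
    else:
        raise InvalidInputError(f"unknown CI method '{method}'")
    if lower > upper:
        lower, upper = upper, lower
    return ViabilityZone(dose50=d, lower=float(lower), upper=float(upper), level=level, p=p, method=method)
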