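"""Two-colour microarray statistics for ageing-vs-control comparisons.

The analysis chain implemented here follows standard two-colour practice for
spotted oligonucleotide arrays with replicate spots:

1. within-array print-tip loess normalization — per print-tip block, the log₂
   ratio M is detrended by a tricube-weighted local-linear regression of M on
   the mean log₂ intensity A, removing pin- and intensity-dependent dye bias;
2. between-array scaling with the median absolute M value as scale estimator,
   every array rescaled to the geometric mean scale;
3. per-probe empirical-Bayes moderated t-tests: per-probe sample variances s²
   are shrunk toward a prior (d0, s0²) estimated by moment matching on
   log s², giving t̃ = mean(M) / sqrt(s²_post/n) on d0 + d_g degrees of
   freedom;
4. Benjamini–Hochberg FDR adjustment;
5. differential-expression calls requiring presence in ≥2 replicates,
   q < FDR level and |mean log₂ ratio| ≥ 1 (2-fold);
6. Venn partitioning of up/down sets across the three ageing time points and
   complete-linkage hierarchical clustering of DE profiles into K (default 16)
   expression patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import polygamma
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateArrayError,
    DegenerateScaleError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "EBHyperparameters",
    "ClusterModel",
    "loess_smooth",
    "normalize_within_array",
    "scale_between_arrays",
    "estimate_eb_hyperparameters",
    "moderated_t",
    "moderated_tests",
    "adjust_fdr",
    "call_de",
    "venn_partition",
    "cluster_profiles",
    "average_replicate_spots",
]


@dataclass(frozen=True)
class EBHyperparameters:
    """Prior of the inverse-χ² variance model: s² ~ s0²·d0/χ²_d0.

    ``d0 = inf`` is the zero-spread sentinel (all variance pooled into s0²).
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise InvalidParameterError("d0 must be > 0 (inf allowed)")
        if not (self.s0_sq > 0):
            raise InvalidParameterError("s0_sq must be > 0")


@dataclass
class ClusterModel:
    assignments: dict
    K: int
    linkage_heights: np.ndarray
    excluded: list


# --------------------------------------------------------------------------
# normalization


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Tricube-weighted local-linear (loess, degree 1) fit evaluated at each x.

    At each point the ``ceil(span·n)`` nearest neighbours (by |Δx|) receive
    tricube weights scaled by the distance to the furthest neighbour; a
    weighted straight line is then fitted and evaluated at the point.  When
    the neighbourhood is x-degenerate the weighted mean is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError("loess needs at least 2 points")
    k = max(2, int(math.ceil(span * n)))
    k = min(k, n)
    fitted = np.empty(n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    for j in range(n):
        d = np.abs(xs - xs[j])
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0.0:
            w = np.ones(idx.size)
        else:
            w = _tricube(d[idx] / dmax)
        xw, yw = xs[idx], ys[idx]
        sw = w.sum()
        xbar = (w * xw).sum() / sw
        ybar = (w * yw).sum() / sw
        sxx = (w * (xw - xbar) ** 2).sum()
        if sxx <= 1e-14 * max(sw, 1.0):
            fitted[j] = ybar
        else:
            slope = (w * (xw - xbar) * (yw - ybar)).sum() / sxx
            fitted[j] = ybar + slope * (xs[j] - xbar)
    out = np.empty(n)
    out[order] = fitted
    return out


def normalize_within_array(
    spots: pd.DataFrame,
    span: float = 0.3,
    min_block_spots: int = 20,
) -> pd.DataFrame:
    """Print-tip loess normalization of one array's spots.

    ``spots`` needs columns ``M, A, print_tip_block``.  Per block, M is
    replaced by the loess residual of M on A; blocks with fewer than
    ``min_block_spots`` spots fall back to median centering.  A single-block
    array below the threshold is degenerate and raises.
    """
    for col in ("M", "A", "print_tip_block"):
        if col not in spots.columns:
            raise InvalidInputError(f"missing column '{col}'")
    blocks = spots["print_tip_block"].unique()
    if len(blocks) == 1 and len(spots) < min_block_spots:
        raise DegenerateArrayError(
            f"single block with {len(spots)} spots (< {min_block_spots})"
        )
    out = spots.copy()
    for block, grp in spots.groupby("print_tip_block", sort=False):
        m = grp["M"].to_numpy(dtype=float)
        if len(grp) < min_block_spots:
            out.loc[grp.index, "M"] = m - np.median(m)
        else:
            trend = loess_smooth(grp["A"].to_numpy(dtype=float), m, span=span)
            out.loc[grp.index, "M"] = m - trend
    return out


def scale_between_arrays(arrays: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Median-absolute-value scaling of M across arrays.

    Each array's M values are divided by that array's median |M| and
    multiplied by the geometric mean of all arrays' median |M|, so all arrays
    end up with a common scale.
    """
    if len(arrays) < 2:
        raise InvalidInputError("need at least 2 arrays to scale")
    mads = {}
    for name, m in arrays.items():
        m = np.asarray(m, dtype=float)
        mad = float(np.median(np.abs(m)))
        if mad == 0.0:
            raise DegenerateScaleError(f"array '{name}' has zero median absolute M")
        mads[name] = mad
    target = math.exp(np.mean([math.log(v) for v in mads.values()]))
    return {name: np.asarray(arrays[name], dtype=float) * (target / mads[name]) for name in arrays}


# --------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_eb_hyperparameters(s2: np.ndarray, d_g: float, min_probes: int = 50) -> EBHyperparameters:
    """Moment-matching estimate of the variance prior (d0, s0²).

    Under s² ~ s0²·d0/χ²_d0 × χ²_dg/dg, z = log s² has
    Var(z) = ψ′(d_g/2) + ψ′(d0/2), so d0 solves
    ψ′(d0/2) = Var(z) − ψ′(d_g/2) via the trigamma inverse; s0² follows from
    the mean of z with the digamma/log corrections.  When the empirical spread
    of z is at or below the sampling floor ψ′(d_g/2), d0 = ∞ and
    s0² = exp(mean z corrected) — every probe shares one variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size < min_probes:
        raise InsufficientDataError(f"need >= {min_probes} probe variances, got {s2.size}")
    if d_g < 1:
        raise InvalidParameterError("d_g must be >= 1")
    if np.all(s2 == s2[0]):
        return EBHyperparameters(d0=float("inf"), s0_sq=float(s2[0]))
    # guard zero variances for the log
    positive = s2[s2 > 0]
    z = np.log(positive)
    e = z - float(polygamma(0, d_g / 2.0)) + math.log(d_g / 2.0)
    evar = float(np.var(z, ddof=1)) - float(_trigamma(d_g / 2.0))
    if evar <= 0:
        return EBHyperparameters(d0=float("inf"), s0_sq=float(math.exp(np.mean(e))))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = math.exp(float(np.mean(e)) + float(polygamma(0, d0 / 2.0)) - math.log(d0 / 2.0))
    return EBHyperparameters(d0=d0, s0_sq=s0_sq)


def moderated_t(m_values: np.ndarray, hyper: EBHyperparameters) -> dict:
    """Moderated one-sample t-test of mean log₂ ratio = 0 for one probe.

    s²_post = (d0·s0² + d_g·s²)/(d0 + d_g) with d_g = n − 1;
    t̃ = mean / sqrt(s²_post / n), two-sided p on d0 + d_g df (normal when
    d0 = ∞).  Returns a plain dict so table-level callers can assemble frames.
    """
    m = np.asarray(m_values, dtype=float)
    m = m[np.isfinite(m)]
    n = m.size
    if n < 2:
        raise InsufficientDataError("moderated t needs >= 2 replicate values")
    mean_m = float(np.mean(m))
    s2 = float(np.var(m, ddof=1))
    dg = n - 1.0
    if math.isinf(hyper.d0):
        s2_post = hyper.s0_sq
        df_total = float("inf")
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + dg * s2) / (hyper.d0 + dg)
        df_total = hyper.d0 + dg
    t_mod = mean_m / math.sqrt(s2_post / n)
    if math.isinf(df_total):
        p = 2.0 * float(_norm.sf(abs(t_mod)))
    else:
        p = 2.0 * float(_t_dist.sf(abs(t_mod), df_total))
    return {
        "mean_M": mean_m,
        "s2": s2,
        "s2_post": s2_post,
        "t_mod": t_mod,
        "df_total": df_total,
        "p_value": p,
        "n_reps_present": n,
    }


def average_replicate_spots(spots: pd.DataFrame) -> pd.DataFrame:
    """Average the within-array replicate spots to one M per probe per array.

    Input columns: ``probe_id, array_id, time_days, M`` (spot rows).  Output:
    one row per (probe_id, time_days, array_id) with the mean M over spots.
    """
    for col in ("probe_id", "array_id", "time_days", "M"):
        if col not in spots.columns:
            raise InvalidInputError(f"missing column '{col}'")
    return (
        spots.groupby(["probe_id", "time_days", "array_id"], sort=False)["M"]
        .mean()
        .reset_index()
    )


def moderated_tests(
    per_array_m: pd.DataFrame,
    hyper: EBHyperparameters | None = None,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Moderated t-tests for every (probe, time) with ≥ ``min_reps`` arrays.

    ``per_array_m`` holds one M per probe per array (see
    :func:`average_replicate_spots`).  When ``hyper`` is None the prior is
    estimated per time point from the probes with full replication.  q-values
    are BH-adjusted within each time point.
    """
    rows = []
    for t, grp in per_array_m.groupby("time_days", sort=True):
        pivot = grp.pivot_table(index="probe_id", columns="array_id", values="M")
        counts = pivot.notna().sum(axis=1)
        usable = pivot[counts >= max(min_reps, 2)]
        if usable.empty:
            continue
        if hyper is None:
            nmode = int(usable.notna().sum(axis=1).mode().iloc[0])
            full = usable[usable.notna().sum(axis=1) == nmode]
            s2 = full.var(axis=1, ddof=1).to_numpy()
            h = estimate_eb_hyperparameters(s2, d_g=nmode - 1)
        else:
            h = hyper
        for probe_id, vals in usable.iterrows():
            res = moderated_t(vals.to_numpy(dtype=float), h)
            res.update({"probe_id": probe_id, "time_days": t})
            rows.append(res)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = np.nan
    for t, grp in out.groupby("time_days"):
        out.loc[grp.index, "q_value"] = adjust_fdr(grp["p_value"].to_numpy())
    return out


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame,
    fdr_level: float = 0.05,
    lfc_threshold: float = 1.0,
    min_reps: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-expression calls under the replicate/FDR/fold filter.

    A probe passes the filter at a time point when it is present in at least
    ``min_reps`` replicates and q < ``fdr_level``; it is called up (down) when
    additionally mean_M ≥ +threshold (≤ −threshold).  Returns the per-probe
    call table and per-time up/down counts.
    """
    req = {"probe_id", "time_days", "mean_M", "q_value", "n_reps_present"}
    missing = req - set(results.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    calls = results.copy()
    calls["passed_filter"] = (calls["n_reps_present"] >= min_reps) & (calls["q_value"] < fdr_level)
    direction = np.where(
        calls["passed_filter"] & (calls["mean_M"] >= lfc_threshold),
        "up",
        np.where(calls["passed_filter"] & (calls["mean_M"] <= -lfc_threshold), "down", "none"),
    )
    calls["direction"] = direction
    counts = (
        calls[calls["direction"] != "none"]
        .groupby(["time_days", "direction"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
        .reset_index()
    )
    return calls[["probe_id", "time_days", "mean_M", "q_value", "n_reps_present", "passed_filter", "direction"]], counts


def venn_partition(sets_by_label: Mapping[object, set]) -> dict:
    """Counts of the 7 exclusive regions of a 3-set Venn partition plus the union.

    Keys of the returned dict are tuples of labels defining each exclusive
    region (e.g. ``(8,)``, ``(8, 12)``, ``(8, 12, 15)``) plus ``"union"``.
    """
    labels = list(sets_by_label.keys())
    if len(labels) != 3:
        raise InvalidInputError("venn_partition expects exactly 3 sets")
    a, b, c = (set(sets_by_label[l]) for l in labels)
    la, lb, lc = labels
    regions = {
        (la,): a - b - c,
        (lb,): b - a - c,
        (lc,): c - a - b,
        (la, lb): (a & b) - c,
        (la, lc): (a & c) - b,
        (lb, lc): (b & c) - a,
        (la, lb, lc): a & b & c,
    }
    out = {k: len(v) for k, v in regions.items()}
    out["union"] = len(a | b | c)
    return out


def cluster_profiles(profiles: pd.DataFrame, K: int = 16) -> ClusterModel:
    """Complete-linkage Euclidean clustering of mean-M expression profiles.

    ``profiles``: index = probe ids, columns = time points, values = mean
    log₂ ratios.  Probes with missing values are excluded and reported.  The
    tree is cut to exactly K clusters; ids are renumbered contiguously in
    order of each cluster's first member in the input.
    """
    complete = profiles.dropna(axis=0)
    excluded = [p for p in profiles.index if p not in complete.index]
    n = len(complete)
    if K > n:
        raise InvalidParameterError(f"K={K} exceeds {n} complete profiles")
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    X = complete.to_numpy(dtype=float)
    if n == 1:
        raw = np.array([1])
        heights = np.array([])
    else:
        Z = linkage(X, method="complete", metric="euclidean")
        heights = Z[:, 2]
        raw = fcluster(Z, t=K, criterion="maxclust")
    # renumber clusters by first-member input order
    remap: dict[int, int] = {}
    for label in raw:
        if label not in remap:
            remap[label] = len(remap) + 1
    assignments = {probe: remap[label] for probe, label in zip(complete.index, raw)}
    n_found = len(remap)
    if n_found != K:
        # maxclust can return fewer clusters on heavily tied inputs (e.g. all
        # profiles identical); that is the honest answer, keep it.
        K = n_found
    return ClusterModel(assignments=assignments, K=K, linkage_heights=heights, excluded=excluded)
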