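"""Per-gene aging-effect estimation.

Continuous-age cohorts are fit by iteratively reweighted least squares with
the Huber loss (tuning constant c = 1.345), initialized at ordinary least
squares with equal weights; the residual scale is re-estimated every
iteration as the normalized median absolute deviation. Two-group designs
(young vs old) use a pooled-variance t test, optionally with empirical-Bayes
variance moderation. Interval fold changes (old/young over a fixed age span)
are computed on the absolute expression scale under an assumed linear
absolute-scale trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special, optimize
from statsmodels.stats.multitest import multipletests

from .io import ExpressionStudy

__all__ = [
    "RobustFit",
    "fit_robust_age_regression",
    "fit_robust_many",
    "lack_of_fit_test",
    "two_group_effect",
    "estimate_interval_fold_change",
    "adjust_bh",
    "call_directions",
    "detectable_gene_filter",
    "compute_aging_profile",
    "DEFAULT_SPAN",
]

HUBER_C = 1.345
MAD_SCALE = 1.4826  # normalizes MAD to the Gaussian standard deviation
MAX_ITER = 50
COEF_TOL = 1e-8

#: Default fold-change span per age unit: 40 years (human-like) or 24 months
#: (mouse-like, a "2-year" span).
DEFAULT_SPAN = {"years": 40.0, "months": 24.0}


@dataclass
class RobustFit:
    intercept: float
    slope: float
    weights: np.ndarray
    scale: float
    iterations: int
    converged: bool
    slope_se: float
    t_stat: float
    p_value: float


def _check_continuous(ages: np.ndarray) -> None:
    if len(ages) < 4:
        raise ValueError("continuous-age fit requires at least 4 samples")
    if len(np.unique(ages)) < 3:
        raise ValueError("continuous-age fit requires at least 3 distinct ages")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant")


def fit_robust_many(
    ages: np.ndarray, Y: np.ndarray, c: float = HUBER_C, max_iter: int = MAX_ITER, tol: float = COEF_TOL
) -> pd.DataFrame:
    """Huber IRLS simple regression of each row of ``Y`` on ``ages``.

    All genes are iterated simultaneously; a gene is converged once the
    larger of its intercept/slope updates falls below ``tol``. Genes with
    constant expression get slope 0 and p = 1 by convention.

    Returns a DataFrame with columns intercept, slope, scale, iterations,
    converged, se, t, p, and the final weight matrix under ``.attrs["weights"]``.
    """
    ages = np.asarray(ages, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    _check_continuous(ages)
    G, n = Y.shape
    x = ages

    constant = np.ptp(Y, axis=1) == 0

    def wls(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sw = W.sum(axis=1)
        xw = (W * x).sum(axis=1) / sw
        yw = (W * Y).sum(axis=1) / sw
        dx = x[None, :] - xw[:, None]
        sxx = (W * dx * dx).sum(axis=1)
        sxy = (W * dx * (Y - yw[:, None])).sum(axis=1)
        slope = np.divide(sxy, sxx, out=np.zeros(G), where=sxx > 0)
        intercept = yw - slope * xw
        return intercept, slope

    W = np.ones((G, n))
    intercept, slope = wls(W)  # OLS initialization, equal weights
    iterations = np.zeros(G, dtype=int)
    converged = np.zeros(G, dtype=bool)
    scale = np.zeros(G)

    active = ~constant
    for _ in range(max_iter):
        if not active.any():
            break
        resid = Y - intercept[:, None] - slope[:, None] * x[None, :]
        scale_new = MAD_SCALE * np.median(np.abs(resid), axis=1)
        # an essentially perfect fit: residuals at rounding level carry no
        # scale information, so nothing is downweighted
        scale_new[scale_new < 1e-10] = 0.0
        scale = np.where(active, scale_new, scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = c * scale[:, None] / np.abs(resid)
        W_new = np.minimum(1.0, np.where(np.isfinite(ratio), ratio, 1.0))
        W_new[scale == 0] = 1.0  # perfect fit: nothing to downweight
        W = np.where(active[:, None], W_new, W)
        new_int, new_slope = wls(W)
        delta = np.maximum(np.abs(new_int - intercept), np.abs(new_slope - slope))
        intercept = np.where(active, new_int, intercept)
        slope = np.where(active, new_slope, slope)
        iterations += active
        newly = active & (delta < tol)
        converged |= newly
        active = active & ~newly

    # Huber asymptotic covariance (psi-based sandwich with the small-sample
    # correction); reduces exactly to the OLS covariance when no residual is
    # downweighted
    resid = Y - intercept[:, None] - slope[:, None] * x[None, :]
    df = n - 2
    dx = x - x.mean()
    sxx = (dx**2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = resid / scale[:, None]
    psi_r = np.clip(u, -c, c) * scale[:, None]  # = w * resid
    dpsi = (np.abs(u) <= c).astype(float)
    perfect = scale == 0
    psi_r[perfect] = 0.0
    dpsi[perfect] = 1.0
    m_dpsi = dpsi.mean(axis=1)
    corr = 1.0 + 2.0 / n * dpsi.var(axis=1) / m_dpsi**2
    var_slope = corr**2 * ((psi_r**2).sum(axis=1) / df) / m_dpsi**2 / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_slope)
        t = np.where(se > 0, slope / se, np.where(slope == 0, 0.0, np.inf * np.sign(slope)))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    slope[constant] = 0.0
    t[constant] = 0.0
    se[constant] = 0.0
    p[constant] = 1.0
    converged[constant] = True
    iterations[constant] = 0

    out = pd.DataFrame(
        {
            "intercept": intercept,
            "slope": slope,
            "scale": scale,
            "iterations": iterations,
            "converged": converged,
            "se": se,
            "t": t,
            "p": p,
        }
    )
    out.attrs["weights"] = W
    return out


def fit_robust_age_regression(ages: np.ndarray, y: np.ndarray, **kwargs) -> RobustFit:
    """Huber IRLS regression of one expression vector on age."""
    table = fit_robust_many(ages, np.asarray(y, dtype=float)[None, :], **kwargs)
    row = table.iloc[0]
    return RobustFit(
        intercept=float(row["intercept"]),
        slope=float(row["slope"]),
        weights=table.attrs["weights"][0],
        scale=float(row["scale"]),
        iterations=int(row["iterations"]),
        converged=bool(row["converged"]),
        slope_se=float(row["se"]),
        t_stat=float(row["t"]),
        p_value=float(row["p"]),
    )


def lack_of_fit_test(ages: np.ndarray, Y: np.ndarray) -> pd.DataFrame:
    """F test of a quadratic age term against the linear model, per gene.

    Degenerate genes (constant expression, or a design without at least five
    distinct ages) get p = 1 with a flag.
    """
    ages = np.asarray(ages, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    degenerate_design = len(np.unique(ages)) < 5 or n < 5
    if degenerate_design:
        return pd.DataFrame({"F": np.zeros(G), "p": np.ones(G), "q": np.ones(G), "degenerate": True})

    def rss(degree: int) -> np.ndarray:
        X = np.vander(ages, degree + 1, increasing=True)
        Q, _ = np.linalg.qr(X)
        resid = Y - (Y @ Q) @ Q.T
        return (resid**2).sum(axis=1)

    rss1, rss2 = rss(1), rss(2)
    df2 = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (rss1 - rss2) / (rss2 / df2)
    F = np.where(np.isfinite(F), np.maximum(F, 0.0), 0.0)
    p = stats.f.sf(F, 1, df2)
    degenerate = np.ptp(Y, axis=1) == 0
    F[degenerate] = 0.0
    p[degenerate] = 1.0
    return pd.DataFrame({"F": F, "p": p, "q": adjust_bh(p), "degenerate": degenerate})


def _moderate_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Shrink per-gene variances toward a global prior by moments on log s2.

    Under the scaled chi-square model, Var(log s2) = trigamma(df/2) +
    trigamma(d0/2); the prior degrees of freedom d0 solve this by inversion,
    and the prior variance s0^2 matches the mean of log s2. Returns the
    posterior variances and d0 (inf when the observed spread is at or below
    the sampling floor, i.e. complete shrinkage to the pooled value).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    z = np.log(s2[positive])
    excess = np.var(z, ddof=1) - special.polygamma(1, df / 2.0)
    e_z = np.mean(z) - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    if excess <= 1e-12:
        s0_2 = np.exp(e_z)
        post = np.full_like(s2, s0_2)
        return post, np.inf
    d0 = 2.0 * optimize.brentq(lambda a: special.polygamma(1, a) - excess, 1e-6, 1e8)
    s0_2 = np.exp(e_z + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def two_group_effect(study: ExpressionStudy, moderated: bool = False) -> pd.DataFrame:
    """Pooled-variance t test of old vs young per gene (log2 difference).

    With ``moderated=True``, per-gene variances are shrunk toward a global
    prior estimated by moments on the log variances and the t degrees of
    freedom become prior df + residual df.
    """
    if study.design != "two_group":
        raise ValueError("two_group_effect requires a two_group design")
    young = study.group == "young"
    old = study.group == "old"
    Y = study.values.to_numpy()
    y_young, y_old = Y[:, young.to_numpy()], Y[:, old.to_numpy()]
    n1, n2 = y_young.shape[1], y_old.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    effect = y_old.mean(axis=1) - y_young.mean(axis=1)
    df = n1 + n2 - 2
    s2 = (((y_young - y_young.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
          + ((y_old - y_old.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)) / df
    t_df = float(df)
    if moderated:
        s2, d0 = _moderate_variances(s2, df)
        t_df = df + (d0 if np.isfinite(d0) else 1e6)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        t = effect / se
    degenerate = s2 == 0
    t = np.where(degenerate & (effect == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), t_df)
    p = np.where(degenerate & (effect == 0), 1.0, p)
    # zero variance with a nonzero difference: treat as maximally significant
    p = np.where(degenerate & (effect != 0), 0.0, p)
    return pd.DataFrame({"effect": effect, "t": t, "p": p}, index=study.gene_ids)


def estimate_interval_fold_change(study: ExpressionStudy, span: float | None = None) -> pd.DataFrame:
    """Interval (old/young) fold change over a fixed age span, absolute scale.

    Log2 values are exponentiated; for continuous designs a straight line is
    fit to absolute expression vs age and the fold change is evaluated from
    the youngest sampled age t0: fc = (yhat(t0) + b * span) / yhat(t0). For
    two-group designs the slope is (mean_old - mean_young) / (age_old -
    age_young) with the young-group mean as baseline. Non-positive baselines
    flag the fold change undefined (NaN).
    """
    if span is None:
        span = DEFAULT_SPAN[study.age_unit]
    if span <= 0:
        raise ValueError("span must be positive")
    A = np.exp2(study.values.to_numpy())
    ages = study.ages.to_numpy(dtype=float)
    if study.design == "continuous_age":
        x = ages
        t0 = x.min()
        dx = x - x.mean()
        sxx = (dx**2).sum()
        b = (A * dx[None, :]).sum(axis=1) / sxx
        a = A.mean(axis=1) - b * x.mean()
        base = a + b * t0
    else:
        young = (study.group == "young").to_numpy()
        old = (study.group == "old").to_numpy()
        age_young = ages[young].mean()
        age_old = ages[old].mean()
        if age_old == age_young:
            raise ValueError("young and old groups have the same age")
        base = A[:, young].mean(axis=1)
        b = (A[:, old].mean(axis=1) - base) / (age_old - age_young)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (base + b * span) / base
    undefined = (base <= 0) | ~np.isfinite(fc) | (fc <= 0)
    fc = np.where(undefined, np.nan, fc)
    return pd.DataFrame({"fc": fc, "fc_undefined": undefined}, index=study.gene_ids)


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_directions(p: np.ndarray, slope: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Direction calls: up / down when p < alpha with the matching sign, else ns."""
    p = np.asarray(p, dtype=float)
    slope = np.asarray(slope, dtype=float)
    out = np.full(p.shape, "ns", dtype=object)
    out[(p < alpha) & (slope > 0)] = "up"
    out[(p < alpha) & (slope < 0)] = "down"
    return out


def detectable_gene_filter(
    study: ExpressionStudy, quantile: float = 0.25, majority_fraction: float = 0.5
) -> pd.Index:
    """Genes detectably expressed in a strict majority of samples.

    A stand-in presence rule: the detection threshold is the study-wide
    expression quantile (default 0.25); a gene is kept when it exceeds that
    threshold in strictly more than ``majority_fraction`` of samples.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    vals = study.values.to_numpy()
    threshold = np.quantile(vals, quantile)
    frac_above = (vals > threshold).mean(axis=1)
    keep = study.gene_ids[frac_above > majority_fraction]
    return keep


def compute_aging_profile(
    study: ExpressionStudy,
    alpha: float = 0.05,
    span: float | None = None,
    moderated: bool = False,
) -> pd.DataFrame:
    """Full per-gene aging profile: slope, p, BH q, interval fc, direction.

    The slope is log2 per age unit (robust IRLS for continuous designs, the
    group difference divided by the age gap for two-group designs).
    """
    if study.design == "continuous_age":
        fits = fit_robust_many(study.ages.to_numpy(dtype=float), study.values.to_numpy())
        slope = fits["slope"].to_numpy()
        p = fits["p"].to_numpy()
    else:
        res = two_group_effect(study, moderated=moderated)
        ages = study.ages.to_numpy(dtype=float)
        gap = ages[(study.group == "old").to_numpy()].mean() - ages[(study.group == "young").to_numpy()].mean()
        slope = res["effect"].to_numpy() / gap
        p = res["p"].to_numpy()
    q = adjust_bh(p)
    fc = estimate_interval_fold_change(study, span=span)
    direction = call_directions(p, slope, alpha=alpha)
    return pd.DataFrame(
        {
            "slope": slope,
            "p": p,
            "q": q,
            "fc": fc["fc"].to_numpy(),
            "fc_undefined": fc["fc_undefined"].to_numpy(),
            "direction": direction,
        },
        index=study.gene_ids,
    )
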