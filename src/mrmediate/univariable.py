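"""Univariable two-sample MR estimators and diagnostics.

All estimators consume per-variant exposure effects (bx, sx) and outcome
effects (by, sy) on harmonized alleles.  The inverse-variance weighted (IVW)
estimator — a zero-intercept weighted regression of by on bx with weights
1/sy^2 — is the primary analysis; MR-Egger (free intercept, directional
pleiotropy), the weighted median (valid if >=50% of weight is valid) and the
contamination mixture (profile likelihood with per-variant valid/invalid
classification) serve as sensitivity analyses.  Random-effects uncertainty is
multiplicative: the fixed-effect SE is inflated by max(1, sqrt(Q/df)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInstrumentError,
    GridCoverageError,
    InsufficientInstrumentsError,
)
from .sumstats import HarmonizedData

Z95 = stats.norm.ppf(0.975)
#: chi2(1)/2 cutoff for a 95% profile-likelihood interval
PROFILE_CUTOFF = stats.chi2.ppf(0.95, df=1) / 2  # = 1.9207...


@dataclass
class MREstimate:
    """A causal-effect estimate with uncertainty, method label and diagnostics."""

    method: str
    theta: float
    se: float | None
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    Q: float | None = None
    i2: float | None = None
    valid_set: list[str] | None = None
    multimodal: bool | None = None
    psi: float | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class StrengthRecord:
    """Per-variant and summary first-stage F statistics, F_j = (bx_j/sx_j)^2."""

    f_stats: np.ndarray
    mean_f: float
    min_f: float


def _normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def _heterogeneity(Q: float, df: int) -> tuple[float, float]:
    """(i2, Q p-value); i2 = max(0, (Q - df)/Q)."""
    i2 = 0.0 if (Q <= 0 or df <= 0) else max(0.0, (Q - df) / Q)
    pq = float(stats.chi2.sf(Q, df)) if df > 0 else np.nan
    return i2, pq


def wald_ratio(bx: float, by: float, sy: float) -> MREstimate:
    """Single-variant causal estimate by/bx with first-order SE sy/|bx|."""
    if bx == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for bx = 0")
    theta = by / bx
    se = sy / abs(bx)
    return MREstimate(
        method="wald",
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=_normal_p(theta / se),
        n_snps=1,
    )


def ivw(data: HarmonizedData, effects_model: str = "multiplicative") -> MREstimate:
    """Inverse-variance weighted estimate (zero-intercept WLS, weights 1/sy^2).

    ``effects_model`` 'fixed' uses the fixed-effect SE; 'multiplicative'
    (default, the random-effects model) inflates it by max(1, sqrt(Q/(k-1))).
    """
    bx, sx, by, sy = data.require_single()
    k = bx.size
    if k < 1:
        raise InsufficientInstrumentsError(1, k, "ivw")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise DegenerateInstrumentError("all exposure betas are zero")
    theta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    Q = float(np.sum(w * (by - theta * bx) ** 2))
    scale = 1.0
    if effects_model == "multiplicative" and k > 1:
        scale = max(1.0, np.sqrt(Q / (k - 1)))
    elif effects_model not in ("fixed", "multiplicative"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    se = se_fixed * scale
    i2, _ = _heterogeneity(Q, k - 1)
    return MREstimate(
        method="ivw",
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=_normal_p(theta / se),
        n_snps=k,
        Q=Q,
        i2=i2,
    )


def mr_egger(data: HarmonizedData) -> MREstimate:
    """MR-Egger regression: WLS of by on bx with a free intercept.

    Variants are first oriented so every bx >= 0 (joint sign flip of each
    (bx, by) pair); the intercept estimates directional pleiotropy and its
    p-value is the Egger-intercept diagnostic.
    """
    bx, sx, by, sy = data.require_single()
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "mr_egger")
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    XtWX = XtW @ X
    coef = np.linalg.solve(XtWX, XtW @ by)
    resid = by - X @ coef
    Q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(Q / (k - 2)))
    cov = np.linalg.inv(XtWX) * scale**2
    intercept, theta = float(coef[0]), float(coef[1])
    se_int, se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    i2, _ = _heterogeneity(Q, k - 2)
    return MREstimate(
        method="egger",
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=_normal_p(theta / se),
        n_snps=k,
        intercept=intercept,
        intercept_se=se_int,
        intercept_pval=_normal_p(intercept / se_int),
        Q=Q,
        i2=i2,
    )


def ratio_estimates(data: HarmonizedData) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios r_j = by/bx and first-order SEs sy/|bx|."""
    bx, sx, by, sy = data.require_single()
    if np.any(bx == 0):
        raise DegenerateInstrumentError("ratio estimates undefined for bx = 0")
    return by / bx, sy / np.abs(bx)


def _interpolated_weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median: value where normalized cumulative weight crosses 0.5,
    linearly interpolated between adjacent order statistics."""
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= p[0]:
        return float(v[0])
    if 0.5 >= p[-1]:
        return float(v[-1])
    j = int(np.searchsorted(p, 0.5, side="right")) - 1
    frac = (0.5 - p[j]) / (p[j + 1] - p[j])
    return float(v[j] + frac * (v[j + 1] - v[j]))


def weighted_median(
    data: HarmonizedData, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimate over per-variant ratios, weights 1/se_ratio^2.

    The SE comes from a seeded parametric bootstrap: by_j and bx_j are
    resampled from Normal(beta, se) ``n_boot`` times and the weighted median
    recomputed per draw.
    """
    bx, sx, by, sy = data.require_single()
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "weighted_median")
    r, s = ratio_estimates(data)
    theta = _interpolated_weighted_median(r, 1.0 / s**2)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    r_b = by_b / bx_b
    w_b = (np.abs(bx_b) / sy) ** 2
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _interpolated_weighted_median(r_b[i], w_b[i])
    se = float(np.std(boots, ddof=1))
    if se == 0:
        ci_low = ci_high = theta
        pval = 1.0 if theta == 0 else 0.0
    else:
        ci_low, ci_high = theta - Z95 * se, theta + Z95 * se
        pval = _normal_p(theta / se)
    return MREstimate(
        method="weighted_median",
        theta=theta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        pval=pval,
        n_snps=k,
    )


def contamination_mixture_loglik(
    grid: np.ndarray, r: np.ndarray, s: np.ndarray, psi: float
) -> np.ndarray:
    """Profile log-likelihood L(theta) over the grid.

    Each variant contributes the larger of its valid log-density
    Normal(r_j; theta, s_j^2) and invalid log-density
    Normal(r_j; theta, s_j^2 + psi^2); the wider invalid component only wins
    for ratios far from theta, so invalid assignment carries the intended
    penalty near the consensus.
    """
    diff = r[None, :] - grid[:, None]  # grid x variants
    v_var = s**2
    i_var = s**2 + psi**2
    ll_valid = -0.5 * (np.log(2 * np.pi * v_var) + diff**2 / v_var)
    ll_invalid = -0.5 * (np.log(2 * np.pi * i_var) + diff**2 / i_var)
    return np.sum(np.maximum(ll_valid, ll_invalid), axis=1)


def contamination_mixture(
    data: HarmonizedData,
    psi: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 10001,
) -> MREstimate:
    """Contamination-mixture estimate by profile likelihood over a theta grid.

    ``psi`` (invalid-effect scale) defaults to 1.5x the SD of the ratio
    estimates; the default grid spans mean +/- 6 SD of the ratios with
    ``n_grid`` points.  The 95% set {theta : L* - L(theta) < 1.92} may be a
    union of intervals; the enclosing hull is reported with a multimodality
    flag.  Variants are classified valid where the valid log-density is at
    least the invalid one at the optimum.
    """
    bx, sx, by, sy = data.require_single()
    k = bx.size
    if k < 2:
        raise InsufficientInstrumentsError(2, k, "contamination_mixture")
    r, s = ratio_estimates(data)
    sd_r = float(np.std(r))
    span = max(sd_r, float(np.max(s)), 1e-6)
    if psi is None:
        psi = 1.5 * sd_r if sd_r > 0 else 1.5 * span
    if grid is None:
        center = float(np.mean(r))
        grid = np.linspace(center - 6 * span, center + 6 * span, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() > r.min() or grid.max() < r.max():
            raise GridCoverageError(
                f"grid [{grid.min()}, {grid.max()}] does not span ratio estimates "
                f"[{r.min()}, {r.max()}]"
            )

    L = contamination_mixture_loglik(grid, r, s, psi)
    best = int(np.argmax(L))
    theta = float(grid[best])
    in_ci = L[best] - L < PROFILE_CUTOFF
    idx = np.flatnonzero(in_ci)
    ci_low, ci_high = float(grid[idx[0]]), float(grid[idx[-1]])
    multimodal = bool(np.any(np.diff(idx) > 1))

    diff = r - theta
    ll_valid = -0.5 * (np.log(2 * np.pi * s**2) + diff**2 / s**2)
    ll_invalid = -0.5 * (np.log(2 * np.pi * (s**2 + psi**2)) + diff**2 / (s**2 + psi**2))
    valid_mask = ll_valid >= ll_invalid
    valid_set = [v for v, m in zip(data.variant_ids, valid_mask) if m]

    # likelihood-ratio p-value against theta = 0 (when the grid covers 0)
    if grid[0] <= 0 <= grid[-1]:
        L0 = float(np.interp(0.0, grid, L))
        pval = float(stats.chi2.sf(2 * (L[best] - L0), df=1))
    else:
        pval = np.nan
    return MREstimate(
        method="contamination_mixture",
        theta=theta,
        se=None,
        ci_low=ci_low,
        ci_high=ci_high,
        pval=pval,
        n_snps=k,
        valid_set=valid_set,
        multimodal=multimodal,
        psi=float(psi),
    )


def instrument_strength(data: HarmonizedData) -> StrengthRecord:
    """Per-variant F statistics (bx/sx)^2 with mean and minimum."""
    bx, sx, by, sy = data.require_single()
    if bx.size < 1:
        raise InsufficientInstrumentsError(1, 0, "instrument_strength")
    f = (bx / sx) ** 2
    return StrengthRecord(f_stats=f, mean_f=float(np.mean(f)), min_f=float(np.min(f)))


def all_estimators(data: HarmonizedData, seed: int = 0) -> dict[str, MREstimate]:
    """IVW plus every sensitivity estimator the instrument count allows."""
    out = {"ivw": ivw(data)}
    k = data.n_snps
    if k >= 3:
        out["egger"] = mr_egger(data)
        out["weighted_median"] = weighted_median(data, seed=seed)
    if k >= 2:
        out["contamination_mixture"] = contamination_mixture(data)
    return out
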