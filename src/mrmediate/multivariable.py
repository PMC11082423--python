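"""Multivariable MR: direct effects, MV-Egger and conditional instrument strength.

The multivariable IVW model regresses outcome betas on the matrix of exposure
betas with the intercept fixed to zero, weighted by outcome precision
(1/sy^2); each coefficient is the direct effect of that exposure holding the
co-exposures fixed.  MV-Egger frees the intercept as a directional-pleiotropy
check.  The conditional F-statistic measures how much independent variation an
exposure's instruments retain given the co-exposures; >10 is the conventional
adequacy threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CollinearityError, InsufficientInstrumentsError
from .sumstats import AssociationSet, HarmonizedData, LDMatrix, harmonize, select_instruments
from .univariable import Z95, _heterogeneity, _normal_p


@dataclass
class MVMRResult:
    """Direct effects of each exposure on the outcome with diagnostics."""

    exposure_ids: list[str]
    direct_effects: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    n_snps: int
    Q: float | None = None
    i2: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    f_cond: dict[str, float] | None = None
    q_strength: dict[str, float] | None = None

    def __post_init__(self):
        self.direct_effects = np.asarray(self.direct_effects, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        self.pvals = np.asarray(self.pvals, dtype=float)
        p = len(self.exposure_ids)
        if not (self.direct_effects.size == self.ses.size == self.pvals.size == p):
            raise ValueError("per-exposure vectors must match exposure_ids length")

    def effect(self, exposure_id: str) -> tuple[float, float, float]:
        """(direct effect, se, pval) for one exposure."""
        i = self.exposure_ids.index(exposure_id)
        return (
            float(self.direct_effects[i]),
            float(self.ses[i]),
            float(self.pvals[i]),
        )


@dataclass
class ConditionalStrength:
    """Conditional instrument strength for one exposure given the others."""

    exposure_id: str
    f_cond: float
    q: float
    df: int
    converged: bool
    n_iter: int


def _check_rank(X: np.ndarray, exposure_ids) -> None:
    if X.shape[0] < X.shape[1]:
        raise InsufficientInstrumentsError(X.shape[1] + 1, X.shape[0], "mvmr")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns that add no rank beyond the preceding ones
        offending = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                offending.append(exposure_ids[j])
        raise CollinearityError(offending or list(exposure_ids))


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, df_resid: int):
    """Weighted LS with multiplicative random-effects SE scaling."""
    XtW = X.T * w
    XtWX = XtW @ X
    coef = np.linalg.solve(XtWX, XtW @ y)
    resid = y - X @ coef
    Q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(Q / df_resid)) if df_resid > 0 else 1.0
    cov = np.linalg.inv(XtWX) * scale**2
    ses = np.sqrt(np.diag(cov))
    return coef, ses, Q


def mvmr_ivw(data: HarmonizedData) -> MVMRResult:
    """Multivariable IVW: zero-intercept WLS of by on bx, weights 1/sy^2.

    An exposure whose beta column is exactly zero carries no information: its
    direct effect is reported as 0 with undefined uncertainty and the model
    is fitted on the remaining exposures (with one exposure left, this
    reduces exactly to the univariable IVW estimate).
    """
    k, p = data.n_snps, data.n_exposures
    if k <= p:
        raise InsufficientInstrumentsError(p + 1, k, "mvmr_ivw")
    nonzero = [j for j in range(p) if np.any(data.bx[:, j] != 0)]
    X = data.bx[:, nonzero]
    _check_rank(X, [data.exposure_ids[j] for j in nonzero])
    w = 1.0 / data.sy**2
    coef_nz, ses_nz, Q = _wls(X, data.by, w, k - len(nonzero))
    coef = np.zeros(p)
    ses = np.full(p, np.nan)
    coef[nonzero], ses[nonzero] = coef_nz, ses_nz
    i2, _ = _heterogeneity(Q, k - len(nonzero))
    pvals = np.array(
        [_normal_p(c / s) if np.isfinite(s) else np.nan for c, s in zip(coef, ses)]
    )
    return MVMRResult(
        exposure_ids=list(data.exposure_ids),
        direct_effects=coef,
        ses=ses,
        pvals=pvals,
        n_snps=k,
        Q=Q,
        i2=i2,
    )


def mvmr_egger(data: HarmonizedData, orient_on: str | None = None) -> MVMRResult:
    """Multivariable MR-Egger: free intercept, variants oriented on one exposure.

    Rows (whole variants, all exposures and the outcome jointly) are sign
    flipped so the ``orient_on`` exposure's betas are non-negative; the
    intercept p-value is the directional-pleiotropy diagnostic.
    """
    k, p = data.n_snps, data.n_exposures
    if k < p + 2:
        raise InsufficientInstrumentsError(p + 2, k, "mvmr_egger")
    _check_rank(data.bx, data.exposure_ids)
    j = data.exposure_ids.index(orient_on) if orient_on else 0
    flip = np.where(data.bx[:, j] < 0, -1.0, 1.0)
    bx = data.bx * flip[:, None]
    by = data.by * flip
    w = 1.0 / data.sy**2
    X = np.column_stack([np.ones(k), bx])
    coef, ses, Q = _wls(X, by, w, k - p - 1)
    i2, _ = _heterogeneity(Q, k - p - 1)
    pvals = np.array([_normal_p(c / s) for c, s in zip(coef[1:], ses[1:])])
    return MVMRResult(
        exposure_ids=list(data.exposure_ids),
        direct_effects=coef[1:],
        ses=ses[1:],
        pvals=pvals,
        n_snps=k,
        Q=Q,
        i2=i2,
        intercept=float(coef[0]),
        intercept_se=float(ses[0]),
        intercept_pval=_normal_p(coef[0] / ses[0]),
    )


def conditional_f(
    data: HarmonizedData,
    target: str,
    cov_assumption: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ConditionalStrength:
    """Conditional F-statistic for ``target`` given the other exposures.

    The target's instrument betas are regressed on the co-exposures' betas by
    iterated WLS; per-variant weights come from the delta-method variance of
    the residual, sx_t^2 + sum_c delta_c^2 sx_c^2 (zero cross-trait
    covariance by default; ``cov_assumption`` supplies a variants x others
    covariance contribution otherwise).  F_cond = Q/(k - p + 1) with p the
    number of exposures in the model.
    """
    p = data.n_exposures
    if p < 2:
        raise ValueError("conditional_f requires at least two exposures")
    k = data.n_snps
    if k <= p - 1:
        raise InsufficientInstrumentsError(p, k, "conditional_f")
    t = data.exposure_ids.index(target)
    others = [i for i in range(p) if i != t]
    y = data.bx[:, t]
    sy_t = data.sx[:, t]
    Z = data.bx[:, others]
    sZ = data.sx[:, others]

    # initial unweighted fit
    delta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    Q_prev = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        var = sy_t**2 + (sZ**2) @ (delta**2)
        if cov_assumption is not None:
            var = var - 2 * np.asarray(cov_assumption) @ delta
        w = 1.0 / var
        ZtW = Z.T * w
        delta = np.linalg.solve(ZtW @ Z, ZtW @ y)
        resid = y - Z @ delta
        Q = float(np.sum(w * resid**2))
        if abs(Q - Q_prev) < tol:
            converged = True
            break
        Q_prev = Q
    if not converged:
        warnings.warn(
            f"conditional_f for {target!r} did not converge in {max_iter} iterations",
            stacklevel=2,
        )
    df = k - p + 1
    return ConditionalStrength(
        exposure_id=target,
        f_cond=Q / df if df > 0 else np.nan,
        q=Q,
        df=df,
        converged=converged,
        n_iter=n_iter,
    )


def conditional_f_all(data: HarmonizedData, **kwargs) -> dict[str, ConditionalStrength]:
    return {e: conditional_f(data, e, **kwargs) for e in data.exposure_ids}


def combined_instruments(
    exposures: list[AssociationSet],
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
) -> list[str]:
    """Union of per-exposure significant variants, greedily pruned by each
    variant's minimum p-value across exposures."""
    min_p: dict[str, float] = {}
    for expo in exposures:
        sig = expo.table[expo.table["pval"] < p_threshold]
        for vid, pv in zip(sig["variant_id"], sig["pval"]):
            min_p[vid] = min(pv, min_p.get(vid, np.inf))
    ordered = sorted(min_p, key=lambda v: (min_p[v], v))
    if ld is None:
        if len(ordered) > 1:
            warnings.warn(
                "no LD matrix supplied: combined instrument skipped LD pruning",
                stacklevel=2,
            )
        return ordered
    sub = ld.submatrix(ordered)
    kept: list[int] = []
    for i in range(len(ordered)):
        if all(sub.r2[i, j] < r2_threshold for j in kept):
            kept.append(i)
    return [ordered[i] for i in kept]


def build_mvmr_data(
    exposures: list[AssociationSet],
    outcome: AssociationSet,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedData:
    """Harmonize all traits over the combined (union, pruned) instrument set."""
    instruments = combined_instruments(exposures, p_threshold, ld, r2_threshold)
    subsets = [e.subset(instruments) for e in exposures]
    return harmonize(subsets, outcome.subset(instruments), palindromic_eaf_window)


@dataclass
class RefitResult:
    """MVMR rerun with substituted exposure instruments, vs. the baseline."""

    result: MVMRResult
    f_cond: dict[str, float]
    f_cond_change: dict[str, float]
    data: HarmonizedData = field(repr=False, default=None)


def refit_with_alternative_instruments(
    exposures: list[AssociationSet],
    outcome: AssociationSet,
    alt_exposure: AssociationSet,
    exposure_index: int = 0,
    baseline: MVMRResult | None = None,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
) -> RefitResult:
    """Rebuild the combined instrument with an alternative exposure set and
    rerun MVMR + conditional F; reports the change in F_cond per exposure.

    Used when an exposure's instruments are conditionally weak (F_cond < 10):
    a sparser or stronger alternative instrument set for that exposure can
    raise the conditional strength of the co-exposures.
    """
    substituted = list(exposures)
    substituted[exposure_index] = alt_exposure
    if baseline is None:
        base_data = build_mvmr_data(exposures, outcome, p_threshold, ld, r2_threshold)
        base_f = {e: cs.f_cond for e, cs in conditional_f_all(base_data).items()}
    else:
        base_f = dict(baseline.f_cond or {})
    data = build_mvmr_data(substituted, outcome, p_threshold, ld, r2_threshold)
    result = mvmr_ivw(data)
    f_cond = {e: cs.f_cond for e, cs in conditional_f_all(data).items()}
    result.f_cond = f_cond
    change = {
        e: f_cond[e] - base_f.get(e, np.nan)
        for e in f_cond
        if e != data.exposure_ids[exposure_index]
    }
    return RefitResult(result=result, f_cond=f_cond, f_cond_change=change, data=data)
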