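"""Difference-in-coefficients mediation on the log-odds scale.

The total effect of the exposure on the outcome comes from univariable IVW on
the exposure's own instruments; the direct effect from a multivariable model
adjusting for the mediator.  The indirect (mediated) effect is their
difference, expressed as the proportion attenuated = indirect/total.  For a
binary outcome the decomposition is on log odds ratios; odds-ratio
non-collapsibility makes this an approximation, accepted and documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, UndefinedProportionError
from .multivariable import MVMRResult, mvmr_ivw
from .sumstats import HarmonizedData
from .univariable import Z95, MREstimate, _normal_p, ivw


@dataclass
class MethodFlags:
    f_cond_pass: bool | None = None
    egger_intercept_pass: bool | None = None


@dataclass
class MediationResult:
    """Total/direct/indirect effects and the proportion attenuated."""

    exposure_id: str
    mediator_ids: list[str]
    outcome_id: str
    total: float
    total_se: float
    direct: float
    direct_se: float
    indirect: float
    indirect_se: float
    prop_mediated: float
    prop_se: float
    prop_ci_low: float
    prop_ci_high: float
    prop_pval: float
    prop_out_of_range: bool = False
    method_flags: MethodFlags = field(default_factory=MethodFlags)

    def __post_init__(self):
        if abs(self.indirect - (self.total - self.direct)) > 1e-12 * max(
            1.0, abs(self.total), abs(self.direct)
        ):
            raise ValueError("indirect must equal total - direct")


def difference_mediation(
    total: MREstimate,
    mvmr: MVMRResult,
    exposure: str,
    cov_total_direct: float = 0.0,
    outcome_id: str = "outcome",
    f_cond_min: float = 10.0,
    egger_intercept_pval: float | None = None,
    egger_alpha: float = 0.1,
    tol: float = 1e-8,
) -> MediationResult:
    """Indirect effect and proportion mediated by the difference method.

    indirect = total - direct with SE sqrt(se_T^2 + se_D^2 - 2 cov); the
    proportion's SE is the first-order delta approximation for a ratio of
    correlated normals.  ``cov_total_direct`` defaults to 0; the total and
    direct estimators share instruments, so the rigorous choice is
    :func:`bootstrap_total_direct_cov`.  A proportion outside [0, 1] is
    reported unclipped with ``prop_out_of_range`` set.
    """
    T, vT = total.theta, total.se**2
    direct, d_se, _ = mvmr.effect(exposure)
    vD = d_se**2
    c = cov_total_direct
    if abs(T) < tol:
        raise UndefinedProportionError(
            f"total effect {T} too close to zero for a proportion mediated"
        )
    indirect = T - direct
    var_I = max(vT + vD - 2 * c, 0.0)
    indirect_se = float(np.sqrt(var_I))
    prop = indirect / T
    # delta method for I/T: var = var_I/T^2 + I^2 var_T/T^4 - 2 I cov(I,T)/T^3,
    # with cov(I, T) = var_T - cov(T, D)
    cov_IT = vT - c
    var_p = var_I / T**2 + indirect**2 * vT / T**4 - 2 * indirect * cov_IT / T**3
    prop_se = float(np.sqrt(max(var_p, 0.0)))
    prop_pval = _normal_p(indirect / indirect_se) if indirect_se > 0 else (
        1.0 if indirect == 0 else 0.0
    )
    flags = MethodFlags(
        f_cond_pass=(
            None
            if not mvmr.f_cond
            else all(f >= f_cond_min for f in mvmr.f_cond.values())
        ),
        egger_intercept_pass=(
            None if egger_intercept_pval is None else egger_intercept_pval > egger_alpha
        ),
    )
    return MediationResult(
        exposure_id=exposure,
        mediator_ids=[e for e in mvmr.exposure_ids if e != exposure],
        outcome_id=outcome_id,
        total=T,
        total_se=total.se,
        direct=direct,
        direct_se=d_se,
        indirect=indirect,
        indirect_se=indirect_se,
        prop_mediated=prop,
        prop_se=prop_se,
        prop_ci_low=prop - Z95 * prop_se,
        prop_ci_high=prop + Z95 * prop_se,
        prop_pval=prop_pval,
        prop_out_of_range=not (0.0 <= prop <= 1.0),
        method_flags=flags,
    )


def bootstrap_total_direct_cov(
    uni_data: HarmonizedData,
    mv_data: HarmonizedData,
    exposure: str,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Joint parametric-bootstrap covariance of the total and direct estimates.

    The variance of the indirect effect (total - direct) is built from three
    parts and converted to the variance-matched covariance
    (var_T + var_D - var_I)/2, so the downstream difference formula
    sqrt(var_T + var_D - 2 cov) reproduces it exactly:

    1. outcome-noise part, exact: both estimators are linear in the outcome
       betas (T = u.by, D = v.by), so this part is
       sum_shared (u_j - v_j)^2 sy_j^2 plus the unshared u^2/v^2 terms;
    2. exposure/mediator-beta noise, from a seeded parametric bootstrap that
       resamples bx only (outcome betas fixed), sharing the exposure column's
       draws between the two models;
    3. the mediator-specific-effect channel: variants' mediator effects not
       proportional to their exposure effects act as balanced pleiotropy in
       the univariable total (contributing b_m * sum_j u_j delta_j, which the
       multivariable model adjusts away), so the total and direct estimates
       differ by a term of variance b_m^2 var(delta) sum_j u_j^2.  var(delta)
       is estimated from the precisely measured mediator betas as the
       measurement-corrected residual variance of the mediator column
       regressed on the exposure column.
    """
    rng = np.random.default_rng(seed)
    t = mv_data.exposure_ids.index(exposure)
    k_u, k_m = uni_data.n_snps, mv_data.n_snps

    # linear weights of the two estimators on the outcome betas
    w_u = 1.0 / uni_data.sy**2
    w_m = 1.0 / mv_data.sy**2
    bx_u0 = uni_data.bx[:, 0]
    u = w_u * bx_u0 / np.sum(w_u * bx_u0**2)  # total = u . by_u
    X = mv_data.bx
    XtW = X.T * w_m
    v = (np.linalg.inv(XtW @ X) @ XtW)[t]  # direct = v . by_m

    # index shared variants so identical draws/noise feed both estimators
    uni_idx = {vid: i for i, vid in enumerate(uni_data.variant_ids)}
    shared = [
        (i, uni_idx[vid]) for i, vid in enumerate(mv_data.variant_ids) if vid in uni_idx
    ]
    mi = np.array([m for m, _ in shared], dtype=int)
    ui = np.array([i for _, i in shared], dtype=int)
    only_u = np.setdiff1d(np.arange(k_u), ui)
    only_m = np.setdiff1d(np.arange(k_m), mi)
    var_by = float(
        np.sum((u[ui] - v[mi]) ** 2 * uni_data.sy[ui] ** 2)
        + np.sum(u[only_u] ** 2 * uni_data.sy[only_u] ** 2)
        + np.sum(v[only_m] ** 2 * mv_data.sy[only_m] ** 2)
    )

    # exposure/mediator-beta noise: bx-only bootstrap, by fixed
    bx_u = rng.normal(bx_u0, uni_data.sx[:, 0], size=(n_boot, k_u))
    X_m = rng.normal(X, mv_data.sx, size=(n_boot, k_m, mv_data.n_exposures))
    if len(mi):
        X_m[:, mi, t] = bx_u[:, ui]
    totals = bx_u @ (w_u * uni_data.by) / np.sum(w_u * bx_u**2, axis=1)
    XtWX = np.einsum("bkp,k,bkq->bpq", X_m, w_m, X_m)
    XtWy = np.einsum("bkp,k->bp", X_m, w_m * mv_data.by)
    directs = np.linalg.solve(XtWX, XtWy[..., None])[:, t, 0]
    var_bx = float(np.var(totals - directs, ddof=1))

    # mediator-specific-effect channel, per co-exposure
    mv_res = mvmr_ivw(mv_data)
    sum_u2 = float(np.sum(u**2))
    var_panel = 0.0
    for j, eid in enumerate(mv_data.exposure_ids):
        if j == t:
            continue
        med, s_med = mv_data.bx[:, j], mv_data.sx[:, j]
        expo, s_exp = mv_data.bx[:, t], mv_data.sx[:, t]
        w_a = 1.0 / s_med**2
        a_hat = float(np.sum(w_a * expo * med) / np.sum(w_a * expo**2))
        resid2 = (med - a_hat * expo) ** 2
        delta_var = max(0.0, float(np.mean(resid2 - s_med**2 - a_hat**2 * s_exp**2)))
        b_med = mv_res.direct_effects[j]
        var_panel += b_med**2 * delta_var * sum_u2

    var_indirect = var_by + var_bx + var_panel
    v_t_model = ivw(uni_data).se ** 2
    v_d_model = mv_res.effect(exposure)[1] ** 2
    return (v_t_model + v_d_model - var_indirect) / 2.0


@dataclass
class SensitivityComparison:
    """Unrestricted vs dual-instrument-excluded MVMR + mediation, side by side."""

    original_mvmr: MVMRResult
    original_mediation: MediationResult
    reduced_mvmr: MVMRResult
    reduced_mediation: MediationResult
    dropped_variants: list[str]


def pleiotropy_exclusion_sensitivity(
    data: HarmonizedData,
    total: MREstimate,
    exposure: str,
    alpha: float = 5e-8,
    cov_total_direct: float = 0.0,
    outcome_id: str = "outcome",
) -> SensitivityComparison:
    """Rerun MVMR + mediation excluding variants significant for both the
    exposure and a mediator, to separate mediation from horizontal pleiotropy.

    Per-variant p-values are computed from the harmonized betas (normal
    z = bx/sx); a variant is excluded when p < ``alpha`` for the exposure AND
    for at least one mediator.
    """
    t = data.exposure_ids.index(exposure)
    z = np.abs(data.bx / data.sx)
    pvals = 2 * stats.norm.sf(z)
    sig = pvals < alpha
    others = [i for i in range(data.n_exposures) if i != t]
    dual = sig[:, t] & sig[:, others].any(axis=1)
    dropped = [v for v, d in zip(data.variant_ids, dual) if d]
    keep = [v for v, d in zip(data.variant_ids, dual) if not d]
    if len(keep) <= data.n_exposures:
        raise InsufficientInstrumentsError(
            data.n_exposures + 1, len(keep), "pleiotropy_exclusion_sensitivity"
        )
    original_mvmr = mvmr_ivw(data)
    original_med = difference_mediation(
        total, original_mvmr, exposure, cov_total_direct, outcome_id
    )
    reduced = data.subset(keep)
    reduced_mvmr = mvmr_ivw(reduced)
    reduced_med = difference_mediation(
        total, reduced_mvmr, exposure, cov_total_direct, outcome_id
    )
    return SensitivityComparison(
        original_mvmr=original_mvmr,
        original_mediation=original_med,
        reduced_mvmr=reduced_mvmr,
        reduced_mediation=reduced_med,
        dropped_variants=dropped,
    )
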