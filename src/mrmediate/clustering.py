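"""EM-based clustered-heterogeneity detection over per-variant ratio estimates.

When the per-variant causal estimates for an exposure-mediator pair are
heterogeneous, distinct groups of variants may act through distinct pathways
with different (even opposite-direction) effects.  The mixture model has k
substantive Normal components with free means, a null component fixed at mean
zero, and a uniform "junk" component absorbing outliers; component variances
are the per-variant squared SEs.  Models for k = 0..k_max are fitted by EM
with seeded restarts and compared by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import HarmonizedData
from .univariable import ivw, ratio_estimates


@dataclass
class ClusterModel:
    """Selected mixture model over per-variant ratio estimates.

    Cluster labels 0..k-1 are substantive; "null" and "junk" are the fixed
    components.  ``inclusion_probs`` columns follow [clusters..., null, junk].
    """

    k_substantive: int
    means: np.ndarray
    proportions: np.ndarray
    assignments: list[str]
    inclusion_probs: np.ndarray
    bic: float
    converged: bool
    loglik: float
    loglik_trace: np.ndarray = field(repr=False, default=None)
    bic_table: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.proportions.sum() - 1.0) > 1e-8:
            raise ValueError("mixing weights must sum to 1")
        rows = self.inclusion_probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("inclusion probability rows must sum to 1")


def _component_densities(r, s2, means, junk_density):
    """variants x (k substantive + null + junk) density matrix."""
    k = len(means)
    dens = np.empty((r.size, k + 2))
    for c, mu in enumerate(means):
        dens[:, c] = np.exp(-0.5 * (r - mu) ** 2 / s2) / np.sqrt(2 * np.pi * s2)
    dens[:, k] = np.exp(-0.5 * r**2 / s2) / np.sqrt(2 * np.pi * s2)  # null
    dens[:, k + 1] = junk_density
    return dens


def _fit_em(r, s2, means0, junk_density, tol=1e-8, max_iter=2000):
    """One EM run; returns (means, weights, loglik, trace, converged, gamma)."""
    k = len(means0)
    means = np.array(means0, dtype=float)
    pi = np.full(k + 2, 1.0 / (k + 2))
    prev_ll = -np.inf
    trace = []
    converged = False
    inv_s2 = 1.0 / s2
    for _ in range(max_iter):
        dens = _component_densities(r, s2, means, junk_density)
        weighted = dens * pi
        total = weighted.sum(axis=1)
        total = np.maximum(total, 1e-300)
        ll = float(np.sum(np.log(total)))
        # EM guarantees a monotone likelihood; a decrease signals a defect
        if trace and ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise AssertionError("EM log-likelihood decreased")
        trace.append(ll)
        gamma = weighted / total[:, None]
        if k:
            num = gamma[:, :k].T @ (r * inv_s2)
            den = gamma[:, :k].T @ inv_s2
            means = np.where(den > 0, num / np.maximum(den, 1e-300), means)
        pi = gamma.mean(axis=0)
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
    return means, pi, trace[-1], np.array(trace), converged, gamma


def em_cluster(
    ratios,
    ses,
    k_max: int = 3,
    n_restarts: int = 20,
    seed: int = 0,
) -> ClusterModel:
    """Fit mixture models with 0..k_max substantive clusters and select by BIC.

    Restart c starts substantive means at the (i+0.5)/k ratio quantiles with
    seeded jitter.  BIC counts k free means plus k+1 free mixing weights.
    """
    r = np.asarray(ratios, dtype=float)
    s = np.asarray(ses, dtype=float)
    if r.size < 3:
        raise ValueError("em_cluster requires at least 3 variants")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    s2 = s**2
    lo = r.min() - 2 * s.max()
    hi = r.max() + 2 * s.max()
    junk_density = 1.0 / max(hi - lo, 1e-12)
    n = r.size
    rng = np.random.default_rng(seed)
    spread = max(r.max() - r.min(), 1e-6)

    best = None
    bic_table: dict[int, float] = {}
    for k in range(0, k_max + 1):
        best_k = None
        restarts = 1 if k == 0 else n_restarts
        for rep in range(restarts):
            if k:
                q = np.quantile(r, (np.arange(k) + 0.5) / k)
                jitter = rng.normal(0, 0.1 * spread, k) if rep else np.zeros(k)
                means0 = q + jitter
            else:
                means0 = np.empty(0)
            fit = _fit_em(r, s2, means0, junk_density)
            if best_k is None or fit[2] > best_k[2]:
                best_k = fit
        means, pi, ll, trace, converged, gamma = best_k
        n_par = k + (k + 1)  # free means + free mixing weights
        bic = -2 * ll + n_par * np.log(n)
        bic_table[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, means, pi, ll, trace, converged, gamma)

    bic, k, means, pi, ll, trace, converged, gamma = best
    labels = [str(c) for c in range(k)] + ["null", "junk"]
    assignments = [labels[i] for i in np.argmax(gamma, axis=1)]
    return ClusterModel(
        k_substantive=k,
        means=means,
        proportions=pi,
        assignments=assignments,
        inclusion_probs=gamma,
        bic=float(bic),
        converged=converged,
        loglik=ll,
        loglik_trace=trace,
        bic_table=bic_table,
    )


@dataclass
class ScreenRecord:
    """Heterogeneity screen for one exposure-mediator pair."""

    Q: float
    i2: float
    pval: float
    flagged: bool


def heterogeneity_screen(data: HarmonizedData) -> ScreenRecord:
    """Flag a pair for clustering when Cochran's Q has p < 0.05."""
    est = ivw(data)
    k = data.n_snps
    pval = float(stats.chi2.sf(est.Q, k - 1)) if k > 1 else 1.0
    return ScreenRecord(Q=est.Q, i2=est.i2, pval=pval, flagged=pval < 0.05)


def is_discrepant(
    exposure_to_mediator: float,
    mediator_to_outcome: float,
    exposure_to_outcome: float,
) -> bool:
    """True when the mediated path's sign contradicts the marginal direction.

    The mediated contribution has sign sign(a)*sign(b) for exposure->mediator
    effect a and mediator->outcome effect b; discrepancy means it opposes the
    sign of the exposure->outcome effect (e.g. BMI lowers IGF1, IGF1 raises
    CRC risk, yet BMI raises CRC risk).
    """
    sab = np.sign(exposure_to_mediator) * np.sign(mediator_to_outcome)
    return bool(sab != 0 and np.sign(exposure_to_outcome) != 0 and sab != np.sign(exposure_to_outcome))


def cluster_ratio_estimates(data: HarmonizedData, **kwargs) -> ClusterModel:
    """Convenience: em_cluster on the pair's per-variant ratio estimates."""
    r, s = ratio_estimates(data)
    return em_cluster(r, s, **kwargs)
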