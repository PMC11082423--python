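import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrmediate.sumstats import AssociationSet, HarmonizedData

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_assoc(
    trait_id,
    beta,
    se,
    variant_ids=None,
    effect_allele=None,
    other_allele=None,
    eaf=None,
    pval=None,
    n=None,
):
    """Build a small AssociationSet from arrays with sensible defaults."""
    beta = np.asarray(beta, dtype=float)
    k = beta.size
    se = np.broadcast_to(np.asarray(se, dtype=float), (k,))
    if variant_ids is None:
        variant_ids = [f"rs{i}" for i in range(k)]
    if effect_allele is None:
        effect_allele = ["A"] * k
    if other_allele is None:
        other_allele = ["G"] * k
    if pval is None:
        from scipy import stats

        pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-320, 1.0)
    return AssociationSet(
        trait_id,
        pd.DataFrame(
            {
                "variant_id": variant_ids,
                "effect_allele": effect_allele,
                "other_allele": other_allele,
                "eaf": np.full(k, np.nan) if eaf is None else eaf,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": np.full(k, np.nan) if n is None else n,
            }
        ),
    )


def make_harmonized(bx, sx, by, sy, exposure_ids=("x",), variant_ids=None):
    bx = np.asarray(bx, dtype=float)
    if bx.ndim == 1:
        bx = bx[:, None]
    k = bx.shape[0]
    sx = np.asarray(sx, dtype=float)
    if sx.ndim == 1 and sx.size == k:
        sx = sx[:, None]
    sx = np.broadcast_to(sx, bx.shape).copy()
    by = np.broadcast_to(np.asarray(by, dtype=float), (k,)).copy()
    sy = np.broadcast_to(np.asarray(sy, dtype=float), (k,)).copy()
    if variant_ids is None:
        variant_ids = [f"rs{i}" for i in range(k)]
    return HarmonizedData(variant_ids, bx, sx, by, sy, list(exposure_ids))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
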