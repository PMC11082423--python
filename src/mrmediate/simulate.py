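"""Seeded generator of two-sample GWAS summary statistics with known truth.

The causal diagram: variants affect the exposure (per-variant effects gamma),
the exposure affects the mediator (alpha, optionally cluster-structured), the
mediator carries its own variant-specific effects (delta, giving it
independent instruments), and the binary outcome's log-odds effects compose a
direct path (tau_direct) and the mediated path (b_m times the mediator
effect) plus optional per-variant pleiotropy.  Observed betas are the truth
plus estimation noise with SE 1/sqrt(2 n maf (1-maf)) per trait sample size.
Statistics are generated directly at the summary level — no individual-level
genotypes — which suffices for every estimator in the package.

The `valid` preset anchors the default magnitudes to the motivating study:
total exposure->outcome log odds ratio ln(1.16) per SD, proportion mediated
~0.07, 400 exposure variants, GWAS-scale sample sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigurationError
from .sumstats import AssociationSet, LDMatrix

_TOTAL_ANCHOR = float(np.log(1.16))  # total log-OR per SD of exposure
_PI_ANCHOR = 0.07

#: named scenario presets; each fully determines all unset fields
PRESETS = {
    "valid": {},
    "directional_pleiotropy": {
        "invalid_fraction": 1.0,
        "pleio_mean": 0.002,
        "pleio_sd": 0.001,
    },
    # invalid instruments carry outcome-side offsets large relative to the
    # per-variant ratio noise, so the contamination is clearly identifiable
    "contaminated": {
        "n_snps": 100,
        "invalid_fraction": 0.3,
        "pleio_mean": 0.03,
        "pleio_sd": 0.01,
    },
    "two_cluster": {
        "n_snps": 20,
        "sig_gamma": 0.1,
        "alpha": None,
        "cluster_spec": [(-0.3, 0.5), (0.3, 0.5)],
        "delta_sd": 0.0,
        "palindromic_fraction": 0.0,
    },
    "weak_mediator": {"delta_sd": 0.002},
    "bidirectional_confounder": {"reverse_alpha": 0.3, "delta_sd": 0.03},
}


@dataclass
class ScenarioConfig:
    """A named preset plus overridable generating parameters."""

    preset: str = "valid"
    n_snps: int = 400
    sig_gamma: float = 0.02
    alpha: float | None = -0.13
    cluster_spec: list[tuple[float, float]] | None = None
    delta_sd: float = 0.02
    b_m: float = -0.08
    tau_direct: float = _TOTAL_ANCHOR - (-0.13) * (-0.08)
    invalid_fraction: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    reverse_alpha: float = 0.0
    n_exp: int = 700_000
    n_med: int = 400_000
    n_out: int = 120_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.15
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ConfigurationError("invalid_fraction must lie in [0, 1]")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ConfigurationError("palindromic_fraction must lie in [0, 1]")
        if self.cluster_spec is not None:
            total = sum(f for _, f in self.cluster_spec)
            if abs(total - 1.0) > 1e-8:
                raise ConfigurationError("cluster_spec fractions must sum to 1")
        elif self.alpha is None:
            raise ConfigurationError("either alpha or cluster_spec must be set")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ScenarioConfig":
        if name not in PRESETS:
            raise ConfigurationError(
                f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
            )
        params = dict(PRESETS[name])
        params.update(overrides)
        return cls(preset=name, **params)


@dataclass
class TruthRecord:
    """Ground-truth parameters of one generated study, for recovery testing."""

    n_snps: int
    gamma: np.ndarray
    alpha: float | None
    b_m: float
    tau_direct: float
    delta: np.ndarray
    pleio: np.ndarray
    invalid_fraction: float
    cluster_spec: list[tuple[float, float]] | None
    n_exp: int
    n_med: int
    n_out: int
    seed: int
    total: float = field(init=False)
    prop_mediated: float = field(init=False)

    def __post_init__(self):
        if self.alpha is not None:
            self.total = self.tau_direct + self.alpha * self.b_m
            self.prop_mediated = (
                (self.alpha * self.b_m) / self.total if self.total != 0 else np.nan
            )
        else:  # cluster-structured alpha: no single proportion is defined
            self.total = np.nan
            self.prop_mediated = np.nan

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("gamma", "delta", "pleio"):
            d[key] = [float(x) for x in d[key]]
        if d["cluster_spec"] is not None:
            d["cluster_spec"] = [[float(m), float(f)] for m, f in d["cluster_spec"]]
        return d


@dataclass
class SimulatedStudy:
    """Generated exposure/mediator/outcome association sets plus their truth."""

    exposure: AssociationSet
    mediator: AssociationSet
    outcome: AssociationSet
    truth: TruthRecord

    def __iter__(self):
        return iter((self.exposure, self.mediator, self.outcome, self.truth))


_NONPALINDROMIC_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and b != {"A": "T", "T": "A", "C": "G", "G": "C"}[a]
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def generate(config: ScenarioConfig) -> SimulatedStudy:
    """Draw one study's summary statistics under ``config`` (fully seeded)."""
    rng = np.random.default_rng(config.seed)
    m = config.n_snps

    maf = rng.uniform(*config.maf_range, m)
    gamma = rng.normal(0.0, config.sig_gamma, m)
    if config.cluster_spec is not None:
        means = np.array([mu for mu, _ in config.cluster_spec])
        fracs = np.array([f for _, f in config.cluster_spec])
        counts = np.round(fracs * m).astype(int)
        counts[-1] = m - counts[:-1].sum()
        comp = np.repeat(np.arange(len(means)), counts)
        rng.shuffle(comp)
        alpha_j = means[comp]
    else:
        alpha_j = np.full(m, config.alpha)
    delta = (
        rng.normal(0.0, config.delta_sd, m) if config.delta_sd > 0 else np.zeros(m)
    )
    pleio = np.zeros(m)
    n_invalid = int(round(config.invalid_fraction * m))
    if n_invalid:
        invalid = rng.choice(m, size=n_invalid, replace=False)
        pleio[invalid] = rng.normal(config.pleio_mean, max(config.pleio_sd, 1e-300), n_invalid)

    exposure_true = gamma + config.reverse_alpha * delta
    mediator_true = alpha_j * gamma + delta
    outcome_true = (
        config.tau_direct * exposure_true + config.b_m * mediator_true + pleio
    )

    # allele assignment: a controllable fraction palindromic, eaf = minor allele
    n_pal = int(round(config.palindromic_fraction * m))
    pal_idx = rng.choice(m, size=n_pal, replace=False)
    pal_mask = np.zeros(m, dtype=bool)
    pal_mask[pal_idx] = True
    pair_np = rng.integers(0, len(_NONPALINDROMIC_PAIRS), m)
    pair_p = rng.integers(0, len(_PALINDROMIC_PAIRS), m)
    ea = np.where(
        pal_mask,
        [_PALINDROMIC_PAIRS[i][0] for i in pair_p],
        [_NONPALINDROMIC_PAIRS[i][0] for i in pair_np],
    )
    oa = np.where(
        pal_mask,
        [_PALINDROMIC_PAIRS[i][1] for i in pair_p],
        [_NONPALINDROMIC_PAIRS[i][1] for i in pair_np],
    )
    variant_ids = [f"rs{config.seed % 1000:03d}{j:05d}" for j in range(m)]

    def _observe(true_beta, n_sample, trait_id):
        se = 1.0 / np.sqrt(2.0 * n_sample * maf * (1.0 - maf))
        beta = true_beta if config.noiseless else true_beta + rng.normal(0.0, se)
        pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-320, 1.0)
        return AssociationSet(
            trait_id,
            pd.DataFrame(
                {
                    "variant_id": variant_ids,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": maf,
                    "beta": beta,
                    "se": se,
                    "pval": pval,
                    "n": float(n_sample),
                }
            ),
        )

    truth = TruthRecord(
        n_snps=m,
        gamma=gamma,
        alpha=config.alpha if config.cluster_spec is None else None,
        b_m=config.b_m,
        tau_direct=config.tau_direct,
        delta=delta,
        pleio=pleio,
        invalid_fraction=config.invalid_fraction,
        cluster_spec=config.cluster_spec,
        n_exp=config.n_exp,
        n_med=config.n_med,
        n_out=config.n_out,
        seed=config.seed,
    )
    return SimulatedStudy(
        exposure=_observe(exposure_true, config.n_exp, "exposure"),
        mediator=_observe(mediator_true, config.n_med, "mediator"),
        outcome=_observe(outcome_true, config.n_out, "outcome"),
        truth=truth,
    )


def write_fixture(
    study: SimulatedStudy,
    out_dir,
    ld: str = "identity",
    block_size: int = 5,
    block_r2: float = 0.9,
) -> dict[str, Path]:
    """Write the three summary tables, an LD matrix and the truth record.

    ``ld`` is 'identity' (no correlation) or 'block' (r2 = ``block_r2``
    within consecutive blocks of ``block_size`` variants).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, assoc in (
        ("exposure", study.exposure),
        ("mediator", study.mediator),
        ("outcome", study.outcome),
    ):
        path = out_dir / f"{name}.tsv"
        assoc.write(path)
        paths[name] = path

    ids = study.exposure.variant_ids
    if ld == "identity":
        mat = LDMatrix.identity(ids)
    elif ld == "block":
        mat = LDMatrix.block(ids, block_size, block_r2)
    else:
        raise ConfigurationError(f"unknown ld mode {ld!r}")
    paths["ld"] = out_dir / "ld.tsv"
    mat.write(paths["ld"])

    paths["truth"] = out_dir / "truth.yaml"
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(study.truth.to_dict(), fh, sort_keys=False)
    return paths
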