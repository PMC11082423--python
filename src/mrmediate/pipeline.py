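"""End-to-end orchestration of the MR mediation analysis matrix.

Given one exposure, a panel of candidate mediators and one or more outcomes,
the pipeline runs all univariable directions (exposure->outcome,
exposure->mediator, mediator->outcome and, bidirectionally,
mediator->exposure), gates mediators on robustness (IVW p < 0.05 with
sensitivity estimators qualitatively consistent, operationalized as point-
estimate sign agreement), and for the robust mediators runs the multivariable
model, conditional instrument-strength diagnostics, difference-in-coefficients
mediation, the dual-instrument exclusion sensitivity analysis and — for pairs
whose marginal directions are discrepant and heterogeneous — EM effect
clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, mediation, multivariable, univariable
from .errors import MRMediateError
from .sumstats import (
    AssociationSet,
    HarmonizedData,
    LDMatrix,
    harmonize,
    load_column_map,
    read_gwas_table,
    select_instruments,
)

log = logging.getLogger("mrmediate")


@dataclass
class Thresholds:
    """Decision thresholds for instrument selection and gating."""

    p_instrument: float = 5e-8
    r2: float = 0.001
    alpha_ivw: float = 0.05
    egger_int: float = 0.1
    f_cond_min: float = 10.0

    def __post_init__(self):
        for name in ("p_instrument", "r2", "alpha_ivw", "egger_int", "f_cond_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class TraitSpec:
    """A trait: identifier, table path, optional column map."""

    trait_id: str
    path: str | None = None
    column_map: dict | None = None


@dataclass
class AnalysisPlan:
    exposure: TraitSpec
    mediators: list[TraitSpec]
    outcomes: list[TraitSpec]
    thresholds: Thresholds = field(default_factory=Thresholds)
    bidirectional: bool = True
    bonferroni: bool = False
    seed: int = 0
    ld_path: str | None = None
    palindromic_window: float = 0.08
    cov_method: str = "zero"  # or "bootstrap"
    n_boot_cov: int = 200

    def __post_init__(self):
        if not self.mediators:
            raise ValueError("at least one mediator is required")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def spec(entry):
            if isinstance(entry, str):
                return TraitSpec(trait_id=Path(entry).stem, path=entry)
            cmap = entry.get("column_map")
            if isinstance(cmap, str):
                cmap = load_column_map(cmap)
            return TraitSpec(entry["trait_id"], entry.get("path"), cmap)

        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            exposure=spec(raw["exposure"]),
            mediators=[spec(m) for m in raw["mediators"]],
            outcomes=[spec(o) for o in raw["outcomes"]],
            thresholds=thresholds,
            bidirectional=raw.get("bidirectional", True),
            bonferroni=raw.get("bonferroni", False),
            seed=raw.get("seed", 0),
            ld_path=raw.get("ld_path"),
            palindromic_window=raw.get("palindromic_window", 0.08),
            cov_method=raw.get("cov_method", "zero"),
            n_boot_cov=raw.get("n_boot_cov", 200),
        )


@dataclass
class PipelineReport:
    univariable: pd.DataFrame
    mvmr: pd.DataFrame
    mediation: pd.DataFrame
    clusters: pd.DataFrame
    flags: pd.DataFrame
    failures: pd.DataFrame

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("univariable", "mvmr", "mediation", "clusters", "flags", "failures"):
            path = out_dir / f"{name}.tsv"
            getattr(self, name).to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths


def robustness_flag(
    ivw_est: univariable.MREstimate,
    sensitivity: list[univariable.MREstimate],
    alpha: float = 0.05,
) -> bool:
    """Robust iff IVW p < alpha and every sensitivity point estimate shares
    the IVW estimate's sign (qualitative consistency; sensitivity p-values
    are not required)."""
    if not sensitivity:
        raise ValueError("at least one sensitivity estimate is required")
    if not ivw_est.pval < alpha:
        return False
    s = np.sign(ivw_est.theta)
    return all(np.sign(est.theta) == s for est in sensitivity)


def _estimate_row(pair: str, est: univariable.MREstimate) -> dict:
    return {
        "pair": pair,
        "method": est.method,
        "theta": est.theta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pval": est.pval,
        "n_snps": est.n_snps,
        "intercept": est.intercept,
        "intercept_pval": est.intercept_pval,
        "Q": est.Q,
        "i2": est.i2,
    }


def _format_percent(prop: float, lo: float, hi: float) -> str:
    """Integer-percent attenuation label, e.g. '7% (2-13%)'."""
    return f"{round(prop * 100):d}% ({round(lo * 100):d}–{round(hi * 100):d}%)"


@dataclass
class _PairAnalysis:
    harmonized: HarmonizedData
    estimates: dict[str, univariable.MREstimate]
    robust: bool
    screen: clustering.ScreenRecord


def analyze(
    exposure: AssociationSet,
    mediators: list[AssociationSet],
    outcome: AssociationSet,
    ld: LDMatrix | None = None,
    thresholds: Thresholds | None = None,
    bidirectional: bool = True,
    bonferroni: bool = False,
    seed: int = 0,
    palindromic_window: float = 0.08,
    cov_method: str = "zero",
    n_boot_cov: int = 200,
) -> PipelineReport:
    """Run the full analysis matrix on in-memory association sets.

    ``bonferroni`` divides the robustness-gate significance level by the
    number of mediators in the panel (off by default: per-pair gating, no
    multiple-testing correction, is the conventional choice here).
    """
    th = thresholds or Thresholds()
    gate_alpha = th.alpha_ivw / len(mediators) if bonferroni else th.alpha_ivw
    uni_rows, mvmr_rows, med_rows, cluster_rows, flag_rows, failures = (
        [],
        [],
        [],
        [],
        [],
        [],
    )

    def run_pair(name: str, frm: AssociationSet, to: AssociationSet) -> _PairAnalysis:
        instruments = select_instruments(frm, th.p_instrument, ld, th.r2)
        data = harmonize([instruments], to.subset(instruments.variant_ids), palindromic_window)
        estimates = univariable.all_estimators(data, seed=seed)
        for est in estimates.values():
            uni_rows.append(_estimate_row(name, est))
        sens = [v for k, v in estimates.items() if k != "ivw"]
        robust = robustness_flag(estimates["ivw"], sens, gate_alpha) if sens else False
        screen = clustering.heterogeneity_screen(data)
        return _PairAnalysis(data, estimates, robust, screen)

    try:
        xy = {o.trait_id: run_pair(f"{exposure.trait_id}->{o.trait_id}", exposure, o) for o in [*_as_list(outcome)]}
    except MRMediateError as exc:
        raise  # the total effect is required for everything downstream

    for out in _as_list(outcome):
        total = xy[out.trait_id].estimates["ivw"]
        for med in mediators:
            pair_flags = {
                "exposure": exposure.trait_id,
                "mediator": med.trait_id,
                "outcome": out.trait_id,
            }
            try:
                xm = run_pair(f"{exposure.trait_id}->{med.trait_id}", exposure, med)
                my = run_pair(f"{med.trait_id}->{out.trait_id}", med, out)
            except MRMediateError as exc:
                failures.append(
                    {"stage": "univariable", "pair": med.trait_id, "error": str(exc)}
                )
                continue

            bidir = None
            if bidirectional:
                try:
                    mx = run_pair(
                        f"{med.trait_id}->{exposure.trait_id}", med, exposure
                    )
                    bidir = mx.estimates["ivw"].pval < th.alpha_ivw
                except MRMediateError as exc:
                    failures.append(
                        {"stage": "bidirectional", "pair": med.trait_id, "error": str(exc)}
                    )

            robust_pair = xm.robust and my.robust
            pair_flags.update(
                robust_exposure_to_mediator=xm.robust,
                robust_mediator_to_outcome=my.robust,
                robust=robust_pair,
                bidirectional_with_exposure=bidir,
            )

            # EM clustering for discrepant, heterogeneous exposure->mediator pairs
            discrepant = clustering.is_discrepant(
                xm.estimates["ivw"].theta,
                my.estimates["ivw"].theta,
                total.theta,
            )
            pair_flags["discrepant"] = discrepant
            if discrepant and xm.screen.flagged:
                try:
                    model = clustering.cluster_ratio_estimates(
                        xm.harmonized, seed=seed
                    )
                    cluster_rows.append(
                        {
                            "pair": f"{exposure.trait_id}->{med.trait_id}",
                            "k_substantive": model.k_substantive,
                            "means": ";".join(f"{m:.4g}" for m in model.means),
                            "bic": model.bic,
                            "converged": model.converged,
                        }
                    )
                except (MRMediateError, ValueError) as exc:
                    failures.append(
                        {"stage": "clustering", "pair": med.trait_id, "error": str(exc)}
                    )

            if not robust_pair:
                pair_flags.update(f_cond_pass=None, egger_pass=None)
                flag_rows.append(pair_flags)
                continue

            try:
                mv_data = multivariable.build_mvmr_data(
                    [exposure, med], out, th.p_instrument, ld, th.r2, palindromic_window
                )
                mv = multivariable.mvmr_ivw(mv_data)
                strengths = multivariable.conditional_f_all(mv_data)
                mv.f_cond = {e: cs.f_cond for e, cs in strengths.items()}
                mv.q_strength = {e: cs.q for e, cs in strengths.items()}
                mv_egger = multivariable.mvmr_egger(mv_data, orient_on=exposure.trait_id)

                cov = 0.0
                if cov_method == "bootstrap":
                    cov = mediation.bootstrap_total_direct_cov(
                        xy[out.trait_id].harmonized,
                        mv_data,
                        exposure.trait_id,
                        n_boot=n_boot_cov,
                        seed=seed,
                    )
                med_res = mediation.difference_mediation(
                    total,
                    mv,
                    exposure.trait_id,
                    cov_total_direct=cov,
                    outcome_id=out.trait_id,
                    f_cond_min=th.f_cond_min,
                    egger_intercept_pval=mv_egger.intercept_pval,
                    egger_alpha=th.egger_int,
                )
                try:
                    sens_cmp = mediation.pleiotropy_exclusion_sensitivity(
                        mv_data, total, exposure.trait_id, th.p_instrument, cov,
                        outcome_id=out.trait_id,
                    )
                    reduced_prop = sens_cmp.reduced_mediation.prop_mediated
                    n_dropped_dual = len(sens_cmp.dropped_variants)
                except MRMediateError as exc:
                    reduced_prop, n_dropped_dual = np.nan, np.nan
                    failures.append(
                        {"stage": "exclusion_sensitivity", "pair": med.trait_id, "error": str(exc)}
                    )

                for i, eid in enumerate(mv.exposure_ids):
                    mvmr_rows.append(
                        {
                            "mediator_model": med.trait_id,
                            "outcome": out.trait_id,
                            "exposure": eid,
                            "direct_effect": mv.direct_effects[i],
                            "se": mv.ses[i],
                            "pval": mv.pvals[i],
                            "n_snps": mv.n_snps,
                            "f_cond": mv.f_cond[eid],
                            "f_cond_pass": mv.f_cond[eid] > th.f_cond_min,
                            "egger_intercept": mv_egger.intercept,
                            "egger_intercept_pval": mv_egger.intercept_pval,
                        }
                    )
                med_rows.append(
                    {
                        "exposure": exposure.trait_id,
                        "mediator": med.trait_id,
                        "outcome": out.trait_id,
                        "total": med_res.total,
                        "total_se": med_res.total_se,
                        "direct": med_res.direct,
                        "direct_se": med_res.direct_se,
                        "indirect": med_res.indirect,
                        "indirect_se": med_res.indirect_se,
                        "prop_mediated": med_res.prop_mediated,
                        "prop_ci_low": med_res.prop_ci_low,
                        "prop_ci_high": med_res.prop_ci_high,
                        "prop_pval": med_res.prop_pval,
                        "percent_attenuated": _format_percent(
                            med_res.prop_mediated,
                            med_res.prop_ci_low,
                            med_res.prop_ci_high,
                        ),
                        "prop_out_of_range": med_res.prop_out_of_range,
                        "f_cond_pass": med_res.method_flags.f_cond_pass,
                        "egger_pass": med_res.method_flags.egger_intercept_pass,
                        "prop_mediated_excl_dual": reduced_prop,
                        "n_dual_excluded": n_dropped_dual,
                    }
                )
                pair_flags.update(
                    f_cond_pass=med_res.method_flags.f_cond_pass,
                    egger_pass=med_res.method_flags.egger_intercept_pass,
                )
            except MRMediateError as exc:
                pair_flags.update(f_cond_pass=None, egger_pass=None)
                failures.append(
                    {"stage": "mvmr", "pair": med.trait_id, "error": str(exc)}
                )
            flag_rows.append(pair_flags)

    return PipelineReport(
        univariable=pd.DataFrame(uni_rows),
        mvmr=pd.DataFrame(mvmr_rows),
        mediation=pd.DataFrame(med_rows),
        clusters=pd.DataFrame(
            cluster_rows, columns=["pair", "k_substantive", "means", "bic", "converged"]
        ),
        flags=pd.DataFrame(flag_rows),
        failures=pd.DataFrame(failures, columns=["stage", "pair", "error"]),
    )


def _as_list(outcome):
    return outcome if isinstance(outcome, list) else [outcome]


def run_pipeline(plan: AnalysisPlan, data_dir=None) -> PipelineReport:
    """Load the plan's trait tables and LD matrix, then :func:`analyze`."""
    base = Path(data_dir) if data_dir else Path(".")

    def load(spec: TraitSpec) -> AssociationSet:
        path = Path(spec.path) if spec.path else base / f"{spec.trait_id}.tsv"
        if not path.is_absolute():
            path = base / path
        return read_gwas_table(path, spec.column_map, spec.trait_id)

    exposure = load(plan.exposure)
    mediators = [load(m) for m in plan.mediators]
    outcomes = [load(o) for o in plan.outcomes]
    ld = None
    if plan.ld_path:
        ld_path = Path(plan.ld_path)
        if not ld_path.is_absolute():
            ld_path = base / ld_path
        ld = LDMatrix.read(ld_path)
    log.info(
        "running plan: exposure=%s mediators=%d outcomes=%d",
        exposure.trait_id,
        len(mediators),
        len(outcomes),
    )
    return analyze(
        exposure,
        mediators,
        outcomes,
        ld=ld,
        thresholds=plan.thresholds,
        bidirectional=plan.bidirectional,
        bonferroni=plan.bonferroni,
        seed=plan.seed,
        palindromic_window=plan.palindromic_window,
        cov_method=plan.cov_method,
        n_boot_cov=plan.n_boot_cov,
    )
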