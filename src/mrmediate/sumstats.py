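"""GWAS summary-statistic I/O, validation, harmonization and instrument selection.

Summary association tables carry, per variant: the effect and other allele,
effect-allele frequency, the per-allele effect estimate (log odds ratio for
binary traits), its standard error, the association p-value and optionally the
sample size.  Two-sample MR consumes pairs (and, multivariably, matrices) of
such estimates aligned to a common effect allele, which is what
:func:`harmonize` produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import (
    ConfigurationError,
    EmptyInputError,
    EmptyOverlapError,
    LDCoverageError,
)

CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
#: columns that must resolve for a table to be readable (eaf and n may be absent)
MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_ALLELES = frozenset(_COMPLEMENT)

#: drop reasons recorded during harmonization
REASON_ALLELE_MISMATCH = "allele_mismatch"
REASON_PALINDROMIC = "palindromic_ambiguous"
REASON_MISSING_IN_OUTCOME = "missing_in_outcome"
REASON_MISSING_IN_EXPOSURE = "missing_in_exposure"


@dataclass
class LoadReport:
    """Counts of rows read, kept and rejected (by reason) while loading a table."""

    n_read: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    reasons: dict = field(default_factory=dict)


def _validate_table(df: pd.DataFrame) -> None:
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].unique()
        raise ValueError(f"duplicate variant_ids: {list(dups[:5])}")
    if not df["effect_allele"].isin(VALID_ALLELES).all():
        raise ValueError("effect_allele must be one of A/C/G/T")
    if not df["other_allele"].isin(VALID_ALLELES).all():
        raise ValueError("other_allele must be one of A/C/G/T")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValueError("effect and other allele must differ")
    if not (df["se"] > 0).all():
        raise ValueError("standard errors must be strictly positive")
    if not ((df["pval"] > 0) & (df["pval"] <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    eaf = df["eaf"]
    ok = eaf.isna() | ((eaf > 0) & (eaf < 1))
    if not ok.all():
        raise ValueError("eaf must lie in (0, 1) or be missing")


@dataclass
class AssociationSet:
    """Per-variant summary association estimates for one trait.

    ``table`` holds the canonical columns; invariants (unique variant ids,
    positive SEs, valid alleles, p-values in (0, 1]) are enforced at
    construction.
    """

    trait_id: str
    table: pd.DataFrame
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self):
        df = self.table.copy()
        for col in ("eaf", "n"):
            if col not in df.columns:
                df[col] = np.nan
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing mandatory column(s): {missing}")
        df = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
        df["other_allele"] = df["other_allele"].astype(str).str.upper()
        for col in ("eaf", "beta", "se", "pval", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        _validate_table(df)
        self.table = df

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def subset(self, variant_ids) -> "AssociationSet":
        keep = self.table[self.table["variant_id"].isin(set(variant_ids))]
        return AssociationSet(self.trait_id, keep.reset_index(drop=True))

    def significant(self, p_threshold: float) -> "AssociationSet":
        keep = self.table[self.table["pval"] < p_threshold]
        return AssociationSet(self.trait_id, keep.reset_index(drop=True))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class LDMatrix:
    """Pairwise r-squared between variants; symmetric, unit diagonal, in [0, 1]."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if r2.shape != (k, k):
            raise ValueError(f"r2 matrix shape {r2.shape} does not match {k} variants")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be exactly 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self.r2 = np.clip(r2, 0.0, 1.0)

    @classmethod
    def identity(cls, variant_ids) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(list(variant_ids))))

    @classmethod
    def block(cls, variant_ids, block_size: int, within_r2: float = 0.9) -> "LDMatrix":
        ids = list(variant_ids)
        k = len(ids)
        r2 = np.zeros((k, k))
        for start in range(0, k, block_size):
            stop = min(start + block_size, k)
            r2[start:stop, start:stop] = within_r2
        np.fill_diagonal(r2, 1.0)
        return cls(ids, r2)

    def submatrix(self, variant_ids) -> "LDMatrix":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in variant_ids if v not in index]
        if missing:
            raise LDCoverageError(missing)
        idx = [index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r2[np.ix_(idx, idx)])

    @classmethod
    def read(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(df.index.astype(str).tolist(), df.to_numpy(dtype=float))

    def write(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t"
        )


def load_column_map(path) -> dict:
    """Load a canonical-name -> file-header column map from a YAML file."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ConfigurationError("column map YAML must be a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_gwas_table(
    path,
    column_map: dict | None = None,
    trait_id: str | None = None,
    beta_is_or: bool = False,
) -> AssociationSet:
    """Read a delimited (tab or comma) GWAS summary table into an AssociationSet.

    ``column_map`` maps canonical column names to the file's header names.
    Rows violating the record invariants (non-positive SE, invalid alleles,
    p-value outside (0, 1], allele equal to other allele) are skipped and
    tallied in the returned set's ``load_report``.  ``beta_is_or`` interprets
    the beta column as an odds ratio and takes its natural log.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    column_map = column_map or {}
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon in MANDATORY_COLUMNS:
            raise ConfigurationError(
                f"mandatory column {canon!r} (file header {src!r}) not found in {path}"
            )
    df = df.rename(columns=rename)
    report = LoadReport(n_read=len(df))

    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    if beta_is_or:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["beta"] = np.log(df["beta"])

    def _tally(mask, reason):
        n = int(mask.sum())
        if n:
            report.reasons[reason] = report.reasons.get(reason, 0) + n
        return mask

    bad = _tally(df["beta"].isna() | df["se"].isna() | df["pval"].isna(), "missing_value")
    bad |= _tally(~df["se"].gt(0) & df["se"].notna(), "nonpositive_se")
    bad |= _tally(
        df["pval"].notna() & ~((df["pval"] > 0) & (df["pval"] <= 1)), "invalid_pval"
    )
    bad |= _tally(
        ~df["effect_allele"].isin(VALID_ALLELES)
        | ~df["other_allele"].isin(VALID_ALLELES),
        "invalid_allele",
    )
    bad |= _tally(df["effect_allele"] == df["other_allele"], "identical_alleles")
    bad |= _tally(
        df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1)), "invalid_eaf"
    )
    bad |= _tally(df["variant_id"].duplicated(), "duplicate_variant")

    kept = df[~bad].reset_index(drop=True)
    report.n_kept = len(kept)
    report.n_rejected = int(bad.sum())
    if report.n_kept == 0:
        raise EmptyInputError(f"no valid rows in {path}")
    trait = trait_id if trait_id is not None else Path(path).stem
    return AssociationSet(trait, kept, load_report=report)


def select_instruments(
    assoc: AssociationSet,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
) -> AssociationSet:
    """Select independent instruments: significance filter then greedy LD pruning.

    Variants with p below ``p_threshold`` are retained, then visited in order
    of ascending p-value (ties broken by variant id so the result is
    independent of input row order); a variant is kept iff its r-squared with
    every already-kept variant is below ``r2_threshold``.  Without an LD
    matrix, pruning is skipped with a warning.
    """
    if not (0 < p_threshold < 1):
        raise ConfigurationError("p_threshold must be in (0, 1)")
    sig = assoc.table[assoc.table["pval"] < p_threshold]
    sig = sig.sort_values(["pval", "variant_id"], kind="mergesort").reset_index(drop=True)
    if ld is None:
        if len(sig) > 1:
            warnings.warn(
                "no LD matrix supplied: instrument selection skipped LD pruning",
                stacklevel=2,
            )
        return AssociationSet(assoc.trait_id, sig)

    sub = ld.submatrix(sig["variant_id"].tolist())  # raises LDCoverageError
    kept_idx: list[int] = []
    for i in range(len(sig)):
        if all(sub.r2[i, j] < r2_threshold for j in kept_idx):
            kept_idx.append(i)
    return AssociationSet(assoc.trait_id, sig.iloc[kept_idx].reset_index(drop=True))


@dataclass
class HarmonizedData:
    """Allele-aligned exposure/outcome effects over a shared variant set.

    ``bx``/``sx`` are variants x exposures matrices; ``by``/``sy`` the outcome
    vectors; all aligned to the first exposure's effect allele.  ``dropped``
    records (variant_id, reason) pairs for excluded variants.
    """

    variant_ids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    exposure_ids: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)
    outcome_id: str = "outcome"
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    eaf: np.ndarray | None = None

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_2d(np.asarray(self.sx, dtype=float))
        if self.bx.shape[0] == 1 and len(self.variant_ids) != 1:
            self.bx = self.bx.T
            self.sx = self.sx.T
        self.by = np.asarray(self.by, dtype=float).ravel()
        self.sy = np.asarray(self.sy, dtype=float).ravel()
        k = len(self.variant_ids)
        if not (self.bx.shape[0] == self.sx.shape[0] == self.by.size == self.sy.size == k):
            raise ValueError("row counts of variant_ids, bx, sx, by, sy must agree")
        if self.bx.shape[1] != len(self.exposure_ids):
            raise ValueError("bx column count must equal number of exposure_ids")

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.bx.shape[1]

    def require_single(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if self.n_exposures != 1:
            raise ValueError("operation requires a single-exposure HarmonizedData")
        return self.bx[:, 0], self.sx[:, 0], self.by, self.sy

    def subset(self, variant_ids) -> "HarmonizedData":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [index[v] for v in variant_ids if v in index]
        return HarmonizedData(
            [self.variant_ids[i] for i in idx],
            self.bx[idx],
            self.sx[idx],
            self.by[idx],
            self.sy[idx],
            list(self.exposure_ids),
            list(self.dropped),
            self.outcome_id,
            None if self.effect_allele is None else self.effect_allele[idx],
            None if self.other_allele is None else self.other_allele[idx],
            None if self.eaf is None else self.eaf[idx],
        )

    def exposure_columns(self, exposure_ids) -> "HarmonizedData":
        idx = [self.exposure_ids.index(e) for e in exposure_ids]
        return HarmonizedData(
            list(self.variant_ids),
            self.bx[:, idx],
            self.sx[:, idx],
            self.by,
            self.sy,
            [self.exposure_ids[i] for i in idx],
            list(self.dropped),
            self.outcome_id,
            self.effect_allele,
            self.other_allele,
            self.eaf,
        )

    def _alleles(self, k):
        ea = self.effect_allele if self.effect_allele is not None else np.repeat("A", k)
        oa = self.other_allele if self.other_allele is not None else np.repeat("G", k)
        eaf = self.eaf if self.eaf is not None else np.full(k, np.nan)
        return ea, oa, eaf

    def exposure_as_association_set(self, i: int = 0) -> AssociationSet:
        k = self.n_snps
        ea, oa, eaf = self._alleles(k)
        z = np.divide(self.bx[:, i], self.sx[:, i])
        pval = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-320, 1.0)
        return AssociationSet(
            self.exposure_ids[i],
            pd.DataFrame(
                {
                    "variant_id": self.variant_ids,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": eaf,
                    "beta": self.bx[:, i],
                    "se": self.sx[:, i],
                    "pval": pval,
                    "n": np.nan,
                }
            ),
        )

    def outcome_as_association_set(self) -> AssociationSet:
        k = self.n_snps
        ea, oa, eaf = self._alleles(k)
        z = np.divide(self.by, self.sy)
        pval = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-320, 1.0)
        return AssociationSet(
            self.outcome_id,
            pd.DataFrame(
                {
                    "variant_id": self.variant_ids,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": eaf,
                    "beta": self.by,
                    "se": self.sy,
                    "pval": pval,
                    "n": np.nan,
                }
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"variant_id": self.variant_ids}
        for i, eid in enumerate(self.exposure_ids):
            data[f"beta_{eid}"] = self.bx[:, i]
            data[f"se_{eid}"] = self.sx[:, i]
        data[f"beta_{self.outcome_id}"] = self.by
        data[f"se_{self.outcome_id}"] = self.sy
        return pd.DataFrame(data)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_drop_log(self, path) -> None:
        pd.DataFrame(self.dropped, columns=["variant_id", "reason"]).to_csv(
            path, sep="\t", index=False
        )


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def _ambiguous_eaf(eaf: pd.Series, window: float) -> pd.Series:
    return eaf.isna() | ((eaf - 0.5).abs() <= window)


def harmonize(
    exposures: list[AssociationSet] | AssociationSet,
    outcome: AssociationSet,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedData:
    """Align exposure(s) and outcome summary statistics to a shared effect allele.

    The first exposure's alleles are the reference.  For every other set a
    variant is aligned by direct match, allele swap (beta negated, eaf
    complemented) or strand complement; palindromic variants (A/T, C/G) are
    resolved by allele frequency and dropped when any frequency is missing or
    within ``palindromic_eaf_window`` of 0.5; irreconcilable allele pairs are
    dropped as ``allele_mismatch``.
    """
    if isinstance(exposures, AssociationSet):
        exposures = [exposures]
    if not exposures:
        raise ValueError("at least one exposure is required")

    ref = exposures[0].table
    dropped: list[tuple[str, str]] = []

    out_ids = set(outcome.table["variant_id"])
    for vid in ref["variant_id"]:
        if vid not in out_ids:
            dropped.append((vid, REASON_MISSING_IN_OUTCOME))
    common = set(ref["variant_id"]) & out_ids
    for expo in exposures[1:]:
        ids = set(expo.table["variant_id"])
        for vid in sorted(common - ids):
            dropped.append((vid, REASON_MISSING_IN_EXPOSURE))
        common &= ids
    if not common:
        raise EmptyOverlapError(
            f"no shared variants between {[e.trait_id for e in exposures]} "
            f"and {outcome.trait_id}"
        )

    base = ref[ref["variant_id"].isin(common)].set_index("variant_id")
    base = base.loc[sorted(common)]

    def _align(other: pd.DataFrame):
        """Return (sign, eaf_aligned, ok) for `other` rows vs the reference."""
        oth = other.set_index("variant_id").loc[base.index]
        ea, oa = oth["effect_allele"], oth["other_allele"]
        r_ea, r_oa = base["effect_allele"], base["other_allele"]
        pal = _is_palindromic(r_ea, r_oa)

        same = (ea == r_ea) & (oa == r_oa)
        swap = (ea == r_oa) & (oa == r_ea)
        comp = (ea.map(_COMPLEMENT) == r_ea) & (oa.map(_COMPLEMENT) == r_oa)
        comp_swap = (ea.map(_COMPLEMENT) == r_oa) & (oa.map(_COMPLEMENT) == r_ea)

        sign = pd.Series(np.nan, index=base.index)
        flip = (swap | comp_swap) & ~(same | comp)
        keep_dir = same | comp
        sign[keep_dir] = 1.0
        sign[flip] = -1.0

        # palindromic variants: allele labels cannot fix strand; use frequency
        amb = pal & (
            _ambiguous_eaf(oth["eaf"], palindromic_eaf_window)
            | _ambiguous_eaf(base["eaf"], palindromic_eaf_window)
        )
        pal_ok = pal & ~amb & (same | swap | comp | comp_swap)
        freq_agree = (oth["eaf"] < 0.5) == (base["eaf"] < 0.5)
        sign[pal_ok & freq_agree] = 1.0
        sign[pal_ok & ~freq_agree] = -1.0

        mismatch = sign.isna() & ~(pal & amb)
        eaf_aligned = oth["eaf"].where(sign > 0, 1 - oth["eaf"])
        return sign, eaf_aligned, oth, pal & amb, mismatch

    # classify every non-reference set; a variant survives only if all sets align
    drop_mask = pd.Series(False, index=base.index)
    aligned = []
    ref_pal_amb = _is_palindromic(base["effect_allele"], base["other_allele"]) & _ambiguous_eaf(
        base["eaf"], palindromic_eaf_window
    )
    reasons = pd.Series("", index=base.index)
    reasons[ref_pal_amb] = REASON_PALINDROMIC
    drop_mask |= ref_pal_amb

    others = [e.table for e in exposures[1:]] + [outcome.table]
    for other in others:
        sign, eaf_al, oth, pal_amb, mismatch = _align(other)
        new_pal = pal_amb & (reasons == "")
        reasons[new_pal] = REASON_PALINDROMIC
        new_mis = mismatch & (reasons == "")
        reasons[new_mis] = REASON_ALLELE_MISMATCH
        drop_mask |= pal_amb | mismatch
        aligned.append((sign, oth))

    keep = ~drop_mask
    for vid in base.index[drop_mask]:
        dropped.append((vid, reasons[vid]))

    kept_index = base.index[keep]
    bx_cols = [base.loc[kept_index, "beta"].to_numpy()]
    sx_cols = [base.loc[kept_index, "se"].to_numpy()]
    for sign, oth in aligned[:-1]:
        bx_cols.append((sign[keep] * oth.loc[kept_index, "beta"]).to_numpy())
        sx_cols.append(oth.loc[kept_index, "se"].to_numpy())
    sign_y, oth_y = aligned[-1]
    by = (sign_y[keep] * oth_y.loc[kept_index, "beta"]).to_numpy()
    sy = oth_y.loc[kept_index, "se"].to_numpy()

    return HarmonizedData(
        variant_ids=list(kept_index),
        bx=np.column_stack(bx_cols),
        sx=np.column_stack(sx_cols),
        by=by,
        sy=sy,
        exposure_ids=[e.trait_id for e in exposures],
        dropped=dropped,
        outcome_id=outcome.trait_id,
        effect_allele=base.loc[kept_index, "effect_allele"].to_numpy(),
        other_allele=base.loc[kept_index, "other_allele"].to_numpy(),
        eaf=base.loc[kept_index, "eaf"].to_numpy(dtype=float),
    )
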