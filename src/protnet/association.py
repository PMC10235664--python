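"""Covariate-adjusted linear-contrast scans of eigenproteins.

Linear models with an eigenprotein as outcome and either the three-level
diagnosis status or a four-level per-symptom factor (control / remitted /
current with low endorsement / current with high endorsement) as exposure,
under tiered covariate adjustment.  Contrasts are coefficient t-tests under
treatment coding with the control group as reference.  Multiple testing is
controlled by Bonferroni multiplication (clipped at 1): across modules for
the status scan, across symptoms x selected modules for the symptom scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import (
    CATEGORICAL_COVARIATES,
    IDS_ITEMS,
    PhenotypeTable,
    ValidationError,
)

log = logging.getLogger(__name__)

SYMPTOM_LEVELS = ("control", "remitted", "current_low", "current_high")

_TIER_COVARIATES = {
    "base": ("batch", "site", "sex", "age", "education"),
    "lifestyle": (
        "batch", "site", "sex", "age", "education",
        "chronic_diseases", "smoking", "alcohol", "physical_activity",
    ),
    "bmi": (
        "batch", "site", "sex", "age", "education",
        "chronic_diseases", "smoking", "alcohol", "physical_activity", "bmi",
    ),
}


@dataclass(frozen=True)
class AdjustmentTier:
    """Named covariate tier: base, lifestyle (base + health/lifestyle) or
    bmi (lifestyle + body-mass index)."""

    tier: str

    def __post_init__(self) -> None:
        if self.tier not in _TIER_COVARIATES:
            raise ValidationError(f"unknown tier {self.tier!r}")

    @property
    def covariates(self) -> tuple:
        return _TIER_COVARIATES[self.tier]


@dataclass
class AssociationResult:
    module: str
    factor_name: str
    contrast: str
    estimate: float
    se: float
    t: float
    p: float
    p_bonferroni: float
    multiplier: int
    tier: str
    n_used: int
    min_p_flag: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def bonferroni_adjust(p: float, multiplier: int) -> float:
    """min(1, p * multiplier)."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if multiplier < 1 or int(multiplier) != multiplier:
        raise ValidationError("multiplier must be a positive integer")
    return min(1.0, p * multiplier)


def build_symptom_factor(
    pheno: PhenotypeTable, item: str | int
) -> pd.Series:
    """Four-level per-symptom factor.

    Controls and remitted subjects keep their status; current subjects are
    split by the item score: >= 2 is high endorsement, <= 1 low.  Current
    subjects with a missing item score are dropped (logged).
    """
    if isinstance(item, int):
        item = IDS_ITEMS[item]
    if item not in pheno.data.columns:
        raise ValidationError(f"unknown symptom item {item!r}")
    status = pheno.status
    score = pheno.data[item]
    out = pd.Series(index=pheno.subject_ids, dtype=object, name=f"factor_{item}")
    out[status == "control"] = "control"
    out[status == "remitted"] = "remitted"
    cur = status == "current"
    out[cur & (score >= 2)] = "current_high"
    out[cur & (score <= 1)] = "current_low"
    dropped = cur & score.isna()
    if dropped.any():
        log.warning("%d current subjects dropped (missing %s)", int(dropped.sum()), item)
        out[dropped] = np.nan
    return out.dropna()


def _design_matrix(
    factor: pd.Series, contrast_level: str, pheno: PhenotypeTable, tier: AdjustmentTier
) -> tuple[pd.DataFrame, pd.Index]:
    """Treatment-coded design: intercept, non-reference factor dummies,
    tier covariates (categoricals dummy-coded, first level dropped)."""
    canonical = ("control", "remitted", "current", "current_low", "current_high")
    present = set(factor)
    levels = [lv for lv in canonical if lv in present]
    levels += sorted(present - set(canonical))
    if "control" not in levels:
        raise ValidationError("factor must contain the control reference level")
    if contrast_level not in levels:
        raise ValidationError(
            f"contrast level {contrast_level!r} absent from the factor"
        )
    cov = pheno.covariates(tier.covariates).loc[factor.index]
    complete = cov.notna().all(axis=1)
    idx = factor.index[complete]
    factor = factor.loc[idx]
    cov = cov.loc[idx]

    parts = [pd.Series(1.0, index=idx, name="intercept")]
    for lv in levels:
        if lv == "control":
            continue
        parts.append(pd.Series((factor == lv).astype(float), name=lv))
    for name in tier.covariates:
        if name in CATEGORICAL_COVARIATES:
            dummies = pd.get_dummies(
                cov[name].astype("category"), prefix=name, drop_first=True, dtype=float
            )
            parts.append(dummies)
        else:
            parts.append(cov[name].astype(float))
    X = pd.concat(parts, axis=1)
    return X, idx


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, R = np.linalg.qr(arr)
        diag = np.abs(np.diag(R))
        aliased = [X.columns[j] for j in range(len(diag)) if diag[j] < 1e-8 * diag.max()]
        raise ValidationError(f"rank-deficient design; aliased columns: {aliased}")


def fit_contrast(
    y: pd.Series,
    factor: pd.Series,
    tier: AdjustmentTier,
    pheno: PhenotypeTable,
    contrast_level: str,
    *,
    module: str = "",
    factor_name: str = "",
) -> AssociationResult:
    """OLS contrast of one factor level against the control reference.

    Returns the contrasted coefficient's estimate, standard error, t and
    two-sided p.  Complete cases only (subjects with any missing covariate
    are dropped, with the n used recorded).
    """
    common = factor.index.intersection(y.dropna().index)
    factor = factor.loc[common]
    X, idx = _design_matrix(factor, contrast_level, pheno, tier)
    counts = factor.loc[idx].value_counts()
    if counts.get(contrast_level, 0) < 2 or counts.get("control", 0) < 2:
        raise ValidationError(
            "need >= 2 subjects in both the contrast and the control group"
        )
    _check_rank(X)
    yv = y.loc[idx].astype(float)
    fit = sm.OLS(yv.to_numpy(), X.to_numpy(dtype=float)).fit()
    j = list(X.columns).index(contrast_level)
    return AssociationResult(
        module=module,
        factor_name=factor_name,
        contrast=f"{contrast_level}_vs_control",
        estimate=float(fit.params[j]),
        se=float(fit.bse[j]),
        t=float(fit.tvalues[j]),
        p=float(fit.pvalues[j]),
        p_bonferroni=float("nan"),
        multiplier=1,
        tier=tier.tier,
        n_used=int(len(idx)),
    )


def scan_clusters_vs_status(
    eigenproteins: pd.DataFrame,
    pheno: PhenotypeTable,
    tier: AdjustmentTier | str = "base",
) -> list[AssociationResult]:
    """Current-vs-control contrast of every module eigenprotein.

    The Bonferroni multiplier is the number of modules tested; the
    minimum-p module is flagged.
    """
    if isinstance(tier, str):
        tier = AdjustmentTier(tier)
    if eigenproteins.shape[1] < 1:
        raise ValidationError("no modules to scan")
    factor = pheno.status.dropna()
    results = []
    k = eigenproteins.shape[1]
    for col in eigenproteins.columns:
        res = fit_contrast(
            eigenproteins[col], factor, tier, pheno, "current",
            module=str(col), factor_name="status",
        )
        res.multiplier = k
        res.p_bonferroni = bonferroni_adjust(res.p, k)
        results.append(res)
    best = min(range(len(results)), key=lambda i: results[i].p)
    results[best].min_p_flag = True
    return results


def scan_symptoms(
    eigenproteins: pd.DataFrame,
    pheno: PhenotypeTable,
    tier: AdjustmentTier | str = "base",
    contrast: str = "high",
    items: list | None = None,
) -> list[AssociationResult]:
    """Per-symptom contrast scan for the selected module eigenproteins.

    ``contrast`` is "high" (current with high endorsement vs control) or
    "low".  The Bonferroni multiplier is n_items x n_modules.  Results are
    sorted by nominal p.
    """
    if isinstance(tier, str):
        tier = AdjustmentTier(tier)
    if contrast not in ("high", "low"):
        raise ValidationError("contrast must be 'high' or 'low'")
    contrast_level = f"current_{contrast}"
    from .containers import DEFAULT_SCAN_ITEMS

    items = list(items) if items is not None else list(DEFAULT_SCAN_ITEMS)
    log.info("symptom scan: %d items, %d modules, tier=%s, contrast=%s",
             len(items), eigenproteins.shape[1], tier.tier, contrast)
    multiplier = len(items) * eigenproteins.shape[1]
    results = []
    for item in items:
        factor = build_symptom_factor(pheno, item)
        for col in eigenproteins.columns:
            res = fit_contrast(
                eigenproteins[col], factor, tier, pheno, contrast_level,
                module=str(col), factor_name=item,
            )
            res.multiplier = multiplier
            res.p_bonferroni = bonferroni_adjust(res.p, multiplier)
            results.append(res)
    results.sort(key=lambda r: r.p)
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
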