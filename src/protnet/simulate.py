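"""Synthetic cohort generator.

Generates serum-panel-like data with the statistical structure the analysis
assumes: blocks of analytes sharing a latent factor (with mixed-sign
loadings), background analytes of pure noise, a three-level diagnosis
status, 30 ordinal symptom items, and the usual clinical covariates.

The symptom-effect mechanism emulates an immuno-metabolic subgroup: a small
latent "affected" state, present throughout the population, shifts the
factor of a designated module; its symptomatic expression (high endorsement
of designated items) occurs only in subjects with a current diagnosis.
Because the affected state is equally prevalent in every status group, the
module factor of non-designated items is identical in distribution across
the contrast groups, so association scans of those items are exactly null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import (
    CENSOR_LOW,
    ENERGY_ITEMS,
    IDS_ITEMS,
    STATUS_LEVELS,
    ModulePartition,
    PhenotypeTable,
    ProteinMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

# Ordered-logit thresholds turning a liability into a 0-3 item score.
# Category >= 2 ("high endorsement") requires liability > _TAU[1].
_TAU = (0.0, 2.5, 4.5)

# Status effects on symptom liability (control, remitted, current).
_STATUS_LIABILITY = {"control": 0.0, "remitted": 1.0, "current": 2.2}


@dataclass(frozen=True)
class ModuleSpec:
    """One planted block: number of analytes, mean loading, fraction of
    analytes whose loading sign is flipped."""

    size: int
    loading_mean: float = 0.55
    frac_negative_loadings: float = 0.2


@dataclass(frozen=True)
class PlantedEffect:
    """Effect of one module's latent factor on one symptom item.

    ``effect_size`` is the standardized mean difference on the latent module
    factor between affected and unaffected subjects.  All entries that share
    a module must share its effect size (one latent shift per module).
    """

    module_index: int
    symptom: str
    effect_size: float = 3.2


def _default_modules() -> list:
    sizes = (24, 21, 13, 10, 7, 6)
    return [ModuleSpec(size=s) for s in sizes]


def _default_planted() -> list:
    return [PlantedEffect(module_index=2, symptom=it) for it in ENERGY_ITEMS]


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the cohort layout the analysis is designed for: 1621
    subjects (426 controls / 483 remitted / 712 current), a 171-analyte
    panel organised in six correlated blocks of sizes 24/21/13/10/7/6 with
    90 background analytes, within-block mean |r| near 0.23 (loading 0.55,
    unit noise), and an immuno-metabolic effect of module 2 on the five
    energy-related symptoms.
    """

    n_subjects: int = 1621
    n_analytes: int = 171
    module_spec: list = field(default_factory=_default_modules)
    noise_sd: float = 1.0
    missing_rate_range: tuple = (0.0, 0.05)
    lod_censor_rate: float = 0.02
    planted_effects: list = field(default_factory=_default_planted)
    prevalence: tuple = (426 / 1621, 483 / 1621, 712 / 1621)
    #: prevalence of the latent affected (dysregulated) state in controls
    #: and remitted subjects
    affected_prevalence: float = 0.015
    #: prevalence of the affected state among current MDD (None: uniform);
    #: the excess over ``affected_prevalence`` produces the modest overall
    #: case-control elevation of the planted module
    affected_prevalence_current: float | None = 0.06
    #: P(item >= 2) for a planted item in affected, currently depressed subjects
    affected_high_rate: float = 0.95
    #: P(item >= 2) for a planted item in unaffected, currently depressed subjects
    planted_base_rate: float = 0.001
    #: ordered-logit liability boost of every non-planted item for affected
    #: current subjects (the dysregulated subgroup is generally more
    #: symptomatic, which empties its members out of the low-endorsement
    #: groups of all items)
    affected_item_boost: float = 0.8
    #: additional direct shift (in factor SD) of planted-module factors in
    #: current MDD, applied uniformly; 0 keeps the elevation subgroup-borne
    status_factor_effect: float = 0.0
    #: kg/m^2 of BMI per SD of a planted module's factor (mediated path)
    bmi_coupling: float = 1.5
    n_batches: int = 26
    n_sites: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        total = sum(m.size for m in self.module_spec)
        if total > self.n_analytes:
            raise ValidationError(
                f"module_spec: module sizes sum to {total} > n_analytes={self.n_analytes}"
            )
        for m in self.module_spec:
            if not 0 < m.loading_mean <= 1:
                raise ValidationError("module_spec: loading_mean must be in (0, 1]")
            if not 0 <= m.frac_negative_loadings <= 1:
                raise ValidationError(
                    "module_spec: frac_negative_loadings must be in [0, 1]"
                )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.missing_rate_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("missing_rate_range must satisfy 0 <= lo <= hi <= 1")
        if not 0 <= self.lod_censor_rate < 1:
            raise ValidationError("lod_censor_rate must be in [0, 1)")
        if abs(sum(self.prevalence) - 1) > 1e-8 or min(self.prevalence) < 0:
            raise ValidationError("prevalence must be non-negative and sum to 1")
        per_module: dict = {}
        for pe in self.planted_effects:
            if not np.isfinite(pe.effect_size):
                raise ValidationError("planted_effects: effect_size must be finite")
            if not 1 <= pe.module_index <= len(self.module_spec):
                raise ValidationError(
                    f"planted_effects: module_index {pe.module_index} out of range"
                )
            if pe.symptom not in IDS_ITEMS:
                raise ValidationError(f"planted_effects: unknown symptom {pe.symptom!r}")
            prev = per_module.setdefault(pe.module_index, pe.effect_size)
            if prev != pe.effect_size:
                raise ValidationError(
                    "planted_effects: effect sizes within one module must agree"
                )
        if not 0 <= self.affected_prevalence < 1:
            raise ValidationError("affected_prevalence must be in [0, 1)")
        if self.affected_prevalence_current is not None and not (
            0 <= self.affected_prevalence_current < 1
        ):
            raise ValidationError("affected_prevalence_current must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    true_partition: ModulePartition
    true_factor_scores: pd.DataFrame
    planted_effects: list
    affected: pd.DataFrame | None = None


def _seed_streams(seed: int, n: int, key: int = 0) -> list:
    """Independent child generators from a single global seed.

    ``key`` separates the sub-streams of distinct operations (cohort
    generation vs. missingness injection) that share one config seed.
    """
    return [
        np.random.default_rng(s) for s in np.random.SeedSequence([seed, key]).spawn(n)
    ]


def _assign_status(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    counts = [int(round(p * cfg.n_subjects)) for p in cfg.prevalence]
    counts[-1] = cfg.n_subjects - sum(counts[:-1])
    status = np.repeat(np.array(STATUS_LEVELS, dtype=object), counts)
    rng.shuffle(status)
    return status


def _ordinal_from_liability(liability: np.ndarray) -> np.ndarray:
    score = np.zeros(liability.shape, dtype=np.int64)
    for tau in _TAU:
        score += (liability > tau).astype(np.int64)
    return score


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ProteinMatrix, PhenotypeTable, GroundTruth]:
    """Generate one cohort: protein panel, phenotypes and ground truth.

    Deterministic given ``config.seed``.  The returned matrix is complete
    (stage ``raw``, no missingness); apply :func:`inject_missingness` to add
    MCAR gaps and detection-limit censoring.
    """
    config.validate()
    cfg = config
    (
        rng_status,
        rng_factor,
        rng_affect,
        rng_noise,
        rng_items,
        rng_covar,
        rng_scale,
    ) = _seed_streams(cfg.seed, 7)

    n = cfg.n_subjects
    subject_ids = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="subject_id")
    status = _assign_status(cfg, rng_status)
    is_current = status == "current"

    n_modules = len(cfg.module_spec)
    factors = rng_factor.standard_normal((n, n_modules))

    planted_modules = sorted({pe.module_index for pe in cfg.planted_effects})
    effect_by_module = {
        m: next(pe.effect_size for pe in cfg.planted_effects if pe.module_index == m)
        for m in planted_modules
    }
    prev = np.full(n, cfg.affected_prevalence)
    if cfg.affected_prevalence_current is not None:
        prev[is_current] = cfg.affected_prevalence_current
    affected = pd.DataFrame(index=subject_ids)
    for m in planted_modules:
        a = rng_affect.random(n) < prev
        factors[:, m - 1] = factors[:, m - 1] + effect_by_module[m] * a
        factors[:, m - 1] = factors[:, m - 1] + cfg.status_factor_effect * is_current
        affected[f"M{m}"] = a

    # analyte values: lambda * factor + noise, then per-analyte affine scale
    blocks = []
    truth_labels = []
    analyte_names = []
    for mi, spec in enumerate(cfg.module_spec, start=1):
        lam = np.full(spec.size, spec.loading_mean)
        n_neg = int(round(spec.frac_negative_loadings * spec.size))
        lam[:n_neg] *= -1.0
        eps = rng_noise.standard_normal((n, spec.size))
        blocks.append(lam * factors[:, mi - 1][:, None] + cfg.noise_sd * eps)
        truth_labels += [mi] * spec.size
        analyte_names += [f"A{mi:02d}_{j + 1:03d}" for j in range(spec.size)]
    n_bg = cfg.n_analytes - sum(m.size for m in cfg.module_spec)
    if n_bg:
        blocks.append(rng_noise.standard_normal((n, n_bg)))
        truth_labels += [0] * n_bg
        analyte_names += [f"BG_{j + 1:03d}" for j in range(n_bg)]
    X = np.hstack(blocks)
    # assay-like units: analyte-specific location and scale
    loc = rng_scale.uniform(1.0, 10.0, cfg.n_analytes)
    scale = rng_scale.uniform(0.5, 2.0, cfg.n_analytes)
    X = loc + scale * X

    analyte_index = pd.Index(analyte_names, name="analyte")
    proteins = ProteinMatrix(
        values=pd.DataFrame(X, index=subject_ids, columns=analyte_index), stage="raw"
    )

    # symptom items via ordered logit on a status-driven liability
    planted_items = {
        pe.symptom: pe.module_index for pe in cfg.planted_effects
    }
    base_intercepts = np.linspace(-1.5, 1.0, len(IDS_ITEMS))
    status_eff = np.vectorize(_STATUS_LIABILITY.get)(status).astype(float)
    items = {}
    any_affected = (
        affected.any(axis=1).to_numpy() if planted_modules else np.zeros(n, bool)
    )
    # liability boosts express the affected state in current MDD only
    logit = lambda p: float(np.log(p / (1 - p)))  # noqa: E731
    for k, item in enumerate(IDS_ITEMS):
        if item in planted_items:
            # intercept set so unaffected current subjects reach >=2 at
            # planted_base_rate; affected current subjects at affected_high_rate
            icpt = logit(cfg.planted_base_rate) + _TAU[1] - _STATUS_LIABILITY["current"]
            boost_amt = logit(cfg.affected_high_rate) - logit(cfg.planted_base_rate)
            a = affected[f"M{planted_items[item]}"].to_numpy()
            boost = boost_amt * (a & is_current)
        else:
            icpt = base_intercepts[k]
            boost = cfg.affected_item_boost * (any_affected & is_current)
        noise = rng_items.logistic(size=n)
        items[item] = _ordinal_from_liability(icpt + status_eff + boost + noise)

    # covariates with plausible marginals, some correlated with status
    cur = is_current.astype(float)
    rem = (status == "remitted").astype(float)
    covar = {}
    covar["batch"] = rng_covar.integers(1, cfg.n_batches + 1, n)
    covar["site"] = rng_covar.integers(1, cfg.n_sites + 1, n)
    covar["sex"] = (rng_covar.random(n) < (0.60 + 0.08 * rem + 0.10 * cur)).astype(int)
    covar["age"] = np.clip(rng_covar.normal(42, 13, n), 18, 65).round(1)
    covar["education"] = np.clip(
        rng_covar.normal(12.5 - 0.5 * cur, 3.2, n), 5, 22
    ).round(1)
    covar["chronic_diseases"] = rng_covar.poisson(0.5 + 0.15 * rem + 0.25 * cur)
    covar["smoking"] = (rng_covar.random(n) < (0.25 + 0.08 * rem + 0.15 * cur)).astype(int)
    covar["alcohol"] = np.clip(np.exp(rng_covar.normal(1.2, 0.9, n)), 0, 60).round(1)
    covar["physical_activity"] = np.clip(
        np.exp(rng_covar.normal(8.0, 0.8, n)), 100, 20000
    ).round(0)
    bmi = rng_covar.normal(25.0 + 0.8 * cur, 3.5, n)
    for m in planted_modules:
        bmi = bmi + cfg.bmi_coupling * factors[:, m - 1]
    covar["bmi"] = np.clip(bmi, 15, 55).round(1)

    pheno_df = pd.DataFrame({"status": status}, index=subject_ids)
    for item in IDS_ITEMS:
        pheno_df[item] = items[item]
    for name, vals in covar.items():
        pheno_df[name] = vals
    phenotypes = PhenotypeTable(pheno_df)

    truth = GroundTruth(
        true_partition=ModulePartition(
            assignment=pd.Series(truth_labels, index=analyte_index, name="module")
        ),
        true_factor_scores=pd.DataFrame(
            factors, index=subject_ids, columns=[f"M{i + 1}" for i in range(n_modules)]
        ),
        planted_effects=list(cfg.planted_effects),
        affected=affected if planted_modules else None,
    )
    return proteins, phenotypes, truth


def inject_missingness(matrix: ProteinMatrix, config: SimulationConfig) -> ProteinMatrix:
    """Add per-analyte MCAR missingness and lower-tail detection censoring.

    Missing rates are drawn per analyte from ``config.missing_rate_range``.
    When ``lod_censor_rate > 0``, each analyte's lower detection limit is set
    at that empirical quantile; values below it are flagged censored-low and
    replaced with the limit.  Deterministic given ``config.seed``.
    """
    config.validate()
    if matrix.values.isna().any().any() or (matrix.censor != 0).any().any():
        raise ValidationError("matrix already carries missingness or censor flags")
    rng_missing, rng_rates = _seed_streams(config.seed, 2, key=1)

    out = matrix.copy()
    n, p = out.values.shape
    lo, hi = config.missing_rate_range
    rates = rng_rates.uniform(lo, hi, p)

    values = out.values.to_numpy(copy=True)
    censor = out.censor.to_numpy(copy=True)
    limits = pd.DataFrame(
        np.nan, index=out.analyte_ids.copy(), columns=["lower", "upper"]
    )
    limits.index.name = "analyte"

    if config.lod_censor_rate > 0:
        lower = np.quantile(values, config.lod_censor_rate, axis=0)
        for j in range(p):
            below = values[:, j] < lower[j]
            censor[below, j] = CENSOR_LOW
            values[below, j] = lower[j]
            limits.iloc[j, 0] = lower[j]

    mask = rng_missing.random((n, p)) < rates[None, :]
    mask &= censor == 0  # censored cells stay censored, not missing
    values[mask] = np.nan

    out.values = pd.DataFrame(values, index=out.subject_ids, columns=out.analyte_ids)
    out.censor = pd.DataFrame(
        censor, index=out.subject_ids, columns=out.analyte_ids, dtype=np.int8
    )
    out.limits = limits.dropna(how="all")
    log.info(
        "injected missingness: mean rate %.3f, %d censored cells",
        float(mask.mean()),
        int((censor != 0).sum()),
    )
    return out
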