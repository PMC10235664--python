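"""Core data containers shared across the pipeline stages.

All containers are thin, validated wrappers around pandas objects so that
every stage (simulation, preprocessing, network construction, association,
stability) exchanges the same well-defined structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Censoring codes used in :class:`ProteinMatrix.censor`.
CENSOR_NONE = 0
CENSOR_LOW = -1
CENSOR_HIGH = 1

STATUS_LEVELS = ("control", "remitted", "current")

#: The 30 self-report depressive-symptom items (IDS-SR30), each scored 0-3.
IDS_ITEMS = (
    "falling_asleep",
    "sleep_during_night",
    "waking_early",
    "sleeping_too_much",
    "feeling_sad",
    "irritable",
    "anxious_tense",
    "reactivity_of_mood",
    "mood_time_of_day",
    "quality_of_mood",
    "appetite_decreased",
    "appetite_increased",
    "weight_decrease",
    "weight_increase",
    "concentration",
    "self_outlook",
    "future_outlook",
    "suicidal_thoughts",
    "involvement",
    "energy_level",
    "pleasure_enjoyment",
    "sexual_interest",
    "slowed_down",
    "restless",
    "aches_pains",
    "other_bodily_symptoms",
    "panic_phobic",
    "constipation_diarrhea",
    "interpersonal_sensitivity",
    "leaden_paralysis",
)

#: The five atypical, energy-related symptoms (immuno-metabolic profile).
ENERGY_ITEMS = (
    "appetite_increased",
    "weight_increase",
    "sleeping_too_much",
    "leaden_paralysis",
    "energy_level",
)

#: Default symptom subset for symptom-level scans: the two "decrease"
#: counterparts of the appetite/weight item pairs are left out, giving 28
#: items.  The list is configuration; any subset of :data:`IDS_ITEMS` may be
#: scanned instead.
DEFAULT_SCAN_ITEMS = tuple(
    it for it in IDS_ITEMS if it not in ("appetite_decreased", "weight_decrease")
)

COVARIATE_COLUMNS = (
    "batch",
    "site",
    "sex",
    "age",
    "education",
    "chronic_diseases",
    "smoking",
    "alcohol",
    "physical_activity",
    "bmi",
)

CATEGORICAL_COVARIATES = ("batch", "site")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class ProteinMatrix:
    """Subjects x analytes panel with missingness and censoring state.

    Parameters
    ----------
    values
        Numeric frame, one row per subject, one column per analyte.  ``NaN``
        encodes a missing measurement (only legal at ``stage='raw'``).
    censor
        Integer frame of the same shape: 0 = not censored, -1 = below the
        lower detection limit, +1 = above the upper limit.
    limits
        Per-analyte detection limits, columns ``lower`` / ``upper`` (``NaN``
        where no limit exists).  May cover a subset of analytes.
    stage
        One of ``raw``, ``imputed``, ``transformed``.
    """

    values: pd.DataFrame
    censor: pd.DataFrame | None = None
    limits: pd.DataFrame | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.censor is None:
            self.censor = pd.DataFrame(
                np.zeros(self.values.shape, dtype=np.int8),
                index=self.values.index,
                columns=self.values.columns,
            )
        if self.limits is None:
            self.limits = pd.DataFrame(
                np.nan, index=pd.Index([], name="analyte"), columns=["lower", "upper"]
            )
        if self.stage not in ("raw", "imputed", "transformed"):
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.censor.shape != self.values.shape:
            raise ValidationError("censor flags must match the value matrix shape")
        if self.stage != "raw" and self.values.isna().any().any():
            raise ValidationError(f"missing cells are not allowed at stage={self.stage!r}")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def analyte_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-analyte fraction of cells that carry no usable observation.

        Censored cells count as observed when a detection limit is on file
        for the analyte (they are imputable), and as missing otherwise.
        """
        missing = self.values.isna()
        flagged = self.censor != CENSOR_NONE
        if flagged.any().any():
            has_lower = self.values.columns.isin(
                self.limits.index[self.limits["lower"].notna()]
            )
            has_upper = self.values.columns.isin(
                self.limits.index[self.limits["upper"].notna()]
            )
            low_bad = (self.censor == CENSOR_LOW) & ~has_lower[np.newaxis, :]
            high_bad = (self.censor == CENSOR_HIGH) & ~has_upper[np.newaxis, :]
            missing = missing | low_bad | high_bad
        return missing.mean(axis=0)

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            values=self.values.copy(),
            censor=self.censor.copy(),
            limits=self.limits.copy(),
            stage=self.stage,
        )


@dataclass
class PhenotypeTable:
    """Per-subject diagnosis status, 30 symptom items and covariates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "status" not in df.columns:
            raise ValidationError("phenotype table needs a 'status' column")
        bad = set(df["status"].dropna()) - set(STATUS_LEVELS)
        if bad:
            raise ValidationError(f"unknown status levels: {sorted(bad)}")
        for it in IDS_ITEMS:
            if it in df.columns:
                vals = df[it].dropna()
                if not vals.isin([0, 1, 2, 3]).all():
                    raise ValidationError(f"item {it!r} has scores outside 0-3")

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def status(self) -> pd.Series:
        return self.data["status"]

    @property
    def ids_items(self) -> pd.DataFrame:
        cols = [c for c in IDS_ITEMS if c in self.data.columns]
        return self.data[cols]

    @property
    def total_ids(self) -> pd.Series:
        return self.ids_items.sum(axis=1)

    def covariates(self, names) -> pd.DataFrame:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks covariates: {missing}")
        return self.data[list(names)]


@dataclass
class ModulePartition:
    """Analyte -> module assignment; label 0 marks unassigned analytes.

    Labels are contiguous ``1..K`` ordered by descending module size.
    """

    assignment: pd.Series
    linkage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.assignment = self.assignment.astype(int)
        labels = sorted(set(self.assignment) - {0})
        if labels and labels != list(range(1, len(labels) + 1)):
            raise ValidationError("module labels must be contiguous 1..K")

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) if len(self.assignment) else 0

    @property
    def module_sizes(self) -> pd.Series:
        sizes = self.assignment[self.assignment > 0].value_counts().sort_index()
        sizes.name = "size"
        return sizes

    def analytes_in(self, label: int) -> list:
        return list(self.assignment.index[self.assignment == label])

    @property
    def n_unassigned(self) -> int:
        return int((self.assignment == 0).sum())


@dataclass
class EigenproteinSet:
    """Per-module summary scores (first principal component of the module).

    ``scores`` columns are named ``M1..MK``; each column has mean 0 / SD 1.
    ``kme`` / ``kme_p`` hold module membership: the correlation between each
    analyte and each eigenprotein, with two-sided p-values.
    """

    scores: pd.DataFrame
    variance_explained: pd.Series
    kme: pd.DataFrame | None = None
    kme_p: pd.DataFrame | None = None

    @property
    def module_labels(self) -> list:
        return [int(c[1:]) for c in self.scores.columns]


@dataclass
class StabilityReport:
    """Outcome of split-half resampling of the network analysis.

    ``records`` has one row per half-sample clustering: iteration, half,
    best-overlap module label (-1 when no module overlapped), its size and
    the overlap count.  ``frequencies`` gives, per analyte, the fraction of
    the ``2 * iterations`` clusterings whose best-overlap module contained
    the analyte.
    """

    records: pd.DataFrame
    frequencies: pd.Series
    reference: list = field(default_factory=list)
    n_failures: int = 0

    def _ok(self) -> pd.DataFrame:
        if "failed" in self.records.columns:
            return self.records[~self.records["failed"]]
        return self.records

    @property
    def mean_size(self) -> float:
        return float(self._ok()["module_size"].mean())

    @property
    def sd_size(self) -> float:
        return float(self._ok()["module_size"].std(ddof=1))

    @property
    def mean_overlap(self) -> float:
        return float(self._ok()["overlap"].mean())

    @property
    def sd_overlap(self) -> float:
        return float(self._ok()["overlap"].std(ddof=1))

    def summary(self) -> dict:
        return {
            "iterations": int(self.records["iteration"].max()) + 1,
            "n_records": int(len(self.records)),
            "mean_size": self.mean_size,
            "sd_size": self.sd_size,
            "mean_overlap": self.mean_overlap,
            "sd_overlap": self.sd_overlap,
            "n_failures": self.n_failures,
        }
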