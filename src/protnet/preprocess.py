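"""Analyte filtering, imputation and the rank-based inverse-normal transform.

The preprocessing chain is: drop analytes with more than a threshold
fraction of missing data (strictly greater than 30 % by default), impute
censored cells at their detection limit and remaining gaps at the analyte
median, then quantile-normal transform each analyte (Blom ranks) to
stabilise the variance before correlation-network construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CENSOR_HIGH, CENSOR_LOW, ProteinMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    #: analytes with missing fraction strictly above this are excluded
    missing_threshold: float = 0.30
    #: rank offset of the inverse-normal transform; 3/8 is the Blom choice
    blom_offset: float = 0.375

    def __post_init__(self) -> None:
        if not 0 < self.missing_threshold < 1:
            raise ValidationError("missing_threshold must be in (0, 1)")


def filter_by_missingness(
    matrix: ProteinMatrix, config: PreprocessConfig | None = None
) -> tuple[ProteinMatrix, list]:
    """Drop analytes whose missing fraction exceeds the threshold.

    The rule is strict: an analyte at exactly the threshold is retained.
    Censored cells with a recorded detection limit count as observed (they
    are imputable); censored cells without one count as missing.

    Returns the filtered matrix (surviving analyte order preserved) and the
    list of excluded analytes.
    """
    config = config or PreprocessConfig()
    if matrix.stage != "raw":
        raise ValidationError(f"filter expects stage='raw', got {matrix.stage!r}")
    frac = matrix.missing_fraction()
    excluded = list(frac.index[frac > config.missing_threshold])
    if len(excluded) == matrix.n_analytes:
        raise ValidationError("no analytes survive filter")
    keep = [a for a in matrix.analyte_ids if a not in set(excluded)]
    out = ProteinMatrix(
        values=matrix.values[keep],
        censor=matrix.censor[keep],
        limits=matrix.limits.loc[matrix.limits.index.intersection(keep)],
        stage="raw",
    )
    if excluded:
        log.info("excluded %d analytes above missing threshold %.2f",
                 len(excluded), config.missing_threshold)
    return out, excluded


def impute(matrix: ProteinMatrix) -> ProteinMatrix:
    """Resolve censored cells at their detection limit, then fill missing
    cells with the analyte median.

    Censored cells are resolved first and excluded from the median, which is
    computed over the observed, uncensored values only (an even count takes
    the mean of the two central order statistics).
    """
    if matrix.stage != "raw":
        raise ValidationError(f"impute expects stage='raw', got {matrix.stage!r}")
    values = matrix.values.to_numpy(copy=True)
    censor = matrix.censor.to_numpy()
    limits = matrix.limits

    for j, analyte in enumerate(matrix.analyte_ids):
        col = values[:, j]
        cen = censor[:, j]
        low = cen == CENSOR_LOW
        high = cen == CENSOR_HIGH
        if low.any():
            if analyte not in limits.index or np.isnan(limits.at[analyte, "lower"]):
                raise ValidationError(
                    f"analyte {analyte!r}: censored-low cells but no lower limit"
                )
            col[low] = limits.at[analyte, "lower"]
        if high.any():
            if analyte not in limits.index or np.isnan(limits.at[analyte, "upper"]):
                raise ValidationError(
                    f"analyte {analyte!r}: censored-high cells but no upper limit"
                )
            col[high] = limits.at[analyte, "upper"]
        missing = np.isnan(col)
        if missing.any():
            observed = col[~missing & (cen == 0)]
            if observed.size == 0:
                raise ValidationError(
                    f"analyte {analyte!r}: no observed values to impute from"
                )
            col[missing] = np.median(observed)
        values[:, j] = col

    return ProteinMatrix(
        values=pd.DataFrame(values, index=matrix.subject_ids, columns=matrix.analyte_ids),
        censor=matrix.censor.copy(),
        limits=matrix.limits.copy(),
        stage="imputed",
    )


def inverse_normal_transform(
    matrix: ProteinMatrix, config: PreprocessConfig | None = None
) -> ProteinMatrix:
    """Blom rank-based inverse-normal transform, per analyte.

    value <- Phi^{-1}((rank - c) / (n - 2c + 1)) with c = 3/8 and average
    ranks for ties.  Raises on zero-variance analytes (all values tied),
    whose transform would be degenerate.
    """
    config = config or PreprocessConfig()
    if matrix.stage != "imputed":
        raise ValidationError(
            f"inverse_normal_transform expects stage='imputed', got {matrix.stage!r}"
        )
    X = matrix.values.to_numpy()
    transformed = transform_array(X, offset=config.blom_offset,
                                  names=list(matrix.analyte_ids))
    return ProteinMatrix(
        values=pd.DataFrame(
            transformed, index=matrix.subject_ids, columns=matrix.analyte_ids
        ),
        censor=matrix.censor.copy(),
        limits=matrix.limits.copy(),
        stage="transformed",
    )


def transform_array(
    X: np.ndarray, offset: float = 0.375, names: list | None = None
) -> np.ndarray:
    """Column-wise rank-based inverse-normal transform of a complete array.

    Used directly by the stability resampler, where the transform is
    recomputed inside each half-sample.
    """
    if np.isnan(X).any():
        raise ValidationError("transform requires a complete matrix")
    n = X.shape[0]
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            name = names[j] if names else f"column {j}"
            raise ValidationError(f"zero-variance analyte {name!r} cannot be transformed")
        ranks = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    return out
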