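"""Split-half resampling stability of a reference module.

The cohort is repeatedly divided into two disjoint near-equal halves; the
full network analysis (inverse-normal transform, adjacency, topological
overlap, dynamic tree cut) is re-run inside each half, and the detected
module with the largest overlap with the reference module is recorded.
Per-analyte inclusion frequencies across the ``2 x iterations`` half-sample
clusterings quantify how reliably each analyte co-clusters with the
reference module's members.

The transform is recomputed within each half because ranks are
sample-relative; the imputed full-sample matrix is reused (the missingness
filter and imputation are not re-run per half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ModulePartition, ProteinMatrix, StabilityReport, ValidationError
from .network import (
    NetworkConfig,
    detect_modules,
    soft_threshold_adjacency,
    topological_overlap,
)
from .preprocess import transform_array

log = logging.getLogger(__name__)


@dataclass
class StabilityConfig:
    iterations: int = 1000
    seed: int = 0
    reference_module: list = field(default_factory=list)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def validate(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not self.reference_module:
            raise ValidationError("reference module must not be empty")


def split_half(n_subjects: int, seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive split into sizes ceil(n/2) and floor(n/2)."""
    if n_subjects < 4:
        raise ValidationError("need at least 4 subjects to split")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    perm = rng.permutation(n_subjects)
    n_a = (n_subjects + 1) // 2
    return np.sort(perm[:n_a]), np.sort(perm[n_a:])


def best_overlap(
    reference: list, partition: ModulePartition
) -> tuple[int | None, int, int]:
    """Module with the largest overlap with the reference analyte list.

    Returns (label or None, overlap count, module size).  Ties are broken
    toward the smaller module (higher precision), then the lower label.
    """
    universe = set(partition.assignment.index)
    missing = [a for a in reference if a not in universe]
    if missing:
        raise ValidationError(f"reference analytes absent from partition: {missing[:5]}")
    ref = set(reference)
    best: tuple[int, int, int] | None = None  # (-overlap, size, label)
    for label in sorted(set(partition.assignment) - {0}):
        members = set(partition.analytes_in(label))
        ov = len(ref & members)
        if ov == 0:
            continue
        key = (-ov, len(members), label)
        if best is None or key < best:
            best = key
    if best is None:
        return None, 0, 0
    ov, size, label = -best[0], best[1], best[2]
    return label, ov, size


def _cluster_half(
    values: np.ndarray, analytes: pd.Index, config: NetworkConfig
) -> ModulePartition:
    X = transform_array(values, names=list(analytes))
    C = np.corrcoef(X, rowvar=False)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    A = soft_threshold_adjacency(C, config)
    if config.dissimilarity == "tom":
        D = 1.0 - topological_overlap(A)
    else:
        D = 1.0 - A
    D_df = pd.DataFrame(D, index=analytes, columns=analytes)
    return detect_modules(D_df, config, cor=C, n_subjects=values.shape[0])


def run_stability(
    matrix: ProteinMatrix, config: StabilityConfig
) -> StabilityReport:
    """Split-half resampling of the network analysis.

    ``matrix`` must be the imputed (complete, untransformed) full-sample
    panel.  Deterministic given ``config.seed``.  Half-sample clusterings
    that fail (e.g. a zero-variance analyte inside a half) are recorded and
    skipped; more than 10 % failures raise.
    """
    config.validate()
    if matrix.stage != "imputed":
        raise ValidationError("stability expects the imputed full-sample matrix")
    values = matrix.values.to_numpy(dtype=float)
    analytes = matrix.analyte_ids
    ref = list(config.reference_module)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    records = []
    counts = pd.Series(0, index=analytes, dtype=float)
    n_failures = 0
    for it in range(config.iterations):
        halves = split_half(matrix.n_subjects, rng)
        for half_id, idx in enumerate(halves):
            try:
                part = _cluster_half(values[idx], analytes, config.network)
            except ValidationError as exc:
                n_failures += 1
                log.warning("iteration %d half %d failed: %s", it, half_id, exc)
                records.append(
                    {"iteration": it, "half": half_id, "module_label": -1,
                     "module_size": 0, "overlap": 0, "failed": True}
                )
                continue
            label, ov, size = best_overlap(ref, part)
            records.append(
                {"iteration": it, "half": half_id,
                 "module_label": -1 if label is None else label,
                 "module_size": size, "overlap": ov, "failed": False}
            )
            if label is not None:
                counts[part.assignment == label] += 1.0
    if n_failures > 0.10 * 2 * config.iterations:
        raise ValidationError(
            f"{n_failures} of {2 * config.iterations} half-sample clusterings failed"
        )
    rec = pd.DataFrame.from_records(records)
    freqs = counts / (2.0 * config.iterations)
    freqs.name = "frequency"
    return StabilityReport(
        records=rec, frequencies=freqs, reference=ref, n_failures=n_failures
    )
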