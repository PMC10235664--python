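"""Input validation for the pipeline entry points."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import COVARIATE_COLUMNS, IDS_ITEMS, STATUS_LEVELS


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    proteins: pd.DataFrame,
    phenotypes: pd.DataFrame,
    limits: pd.DataFrame | None = None,
) -> ValidationReport:
    """Cross-check the three input tables before running the pipeline.

    Fatal: subject mismatch between tables, duplicate analyte IDs, status or
    item values outside their domains.  Warnings: unexpected extra columns,
    covariate missingness, limits for unknown analytes.
    """
    rep = ValidationReport()

    if proteins.columns.duplicated().any():
        dups = list(proteins.columns[proteins.columns.duplicated()])
        rep.errors.append(f"duplicate analyte IDs: {dups[:5]}")
    if proteins.index.duplicated().any():
        rep.errors.append("duplicate subject IDs in protein table")

    missing_subjects = proteins.index.difference(phenotypes.index)
    if len(missing_subjects):
        rep.errors.append(
            "subjects in protein table missing from phenotypes: "
            f"{list(missing_subjects[:5])}"
        )
    extra_subjects = phenotypes.index.difference(proteins.index)
    if len(extra_subjects):
        rep.warnings.append(
            f"{len(extra_subjects)} phenotype subjects have no protein data"
        )

    if "status" not in phenotypes.columns:
        rep.errors.append("phenotype table lacks 'status'")
    else:
        bad = set(phenotypes["status"].dropna()) - set(STATUS_LEVELS)
        if bad:
            rep.errors.append(f"unknown status levels: {sorted(bad)}")

    for item in IDS_ITEMS:
        if item not in phenotypes.columns:
            rep.warnings.append(f"symptom item missing: {item}")
            continue
        vals = phenotypes[item].dropna()
        if not vals.isin([0, 1, 2, 3]).all():
            rep.errors.append(f"item {item!r} has scores outside 0-3")

    for cov in COVARIATE_COLUMNS:
        if cov not in phenotypes.columns:
            rep.warnings.append(f"covariate missing: {cov}")
        elif phenotypes[cov].isna().any():
            rep.warnings.append(
                f"covariate {cov!r}: {int(phenotypes[cov].isna().sum())} missing values"
            )

    known = set(IDS_ITEMS) | set(COVARIATE_COLUMNS) | {"status"}
    extra_cols = [c for c in phenotypes.columns if c not in known]
    if extra_cols:
        rep.warnings.append(f"unexpected phenotype columns: {extra_cols[:5]}")

    if limits is not None:
        unknown = limits.index.difference(proteins.columns)
        if len(unknown):
            rep.warnings.append(
                f"detection limits for unknown analytes: {list(unknown[:5])}"
            )

    return rep
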