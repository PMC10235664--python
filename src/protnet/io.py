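"""Reading and writing the pipeline's TSV/JSON artifacts.

Conventions: all tables are tab-separated with a header row; the protein
table has subject IDs in the first column and one analyte per remaining
column, with empty cells for missing values; detection limits live in a
three-column table (analyte, lower, upper).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import PhenotypeTable, ProteinMatrix
from .simulate import GroundTruth


def write_proteins(matrix: ProteinMatrix, path: Path | str) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="")


def read_proteins(
    path: Path | str, limits: pd.DataFrame | None = None, stage: str = "raw"
) -> ProteinMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "subject_id"
    df.columns.name = "analyte"
    return ProteinMatrix(values=df.astype(float), limits=limits, stage=stage)


def write_phenotypes(pheno: PhenotypeTable, path: Path | str) -> None:
    pheno.data.to_csv(path, sep="\t")


def read_phenotypes(path: Path | str) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "subject_id"
    return PhenotypeTable(df)


def write_limits(limits: pd.DataFrame, path: Path | str) -> None:
    limits.to_csv(path, sep="\t", na_rep="")


def read_limits(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "analyte"
    return df[["lower", "upper"]] if "upper" in df.columns else df


def write_truth(truth: GroundTruth, path: Path | str) -> None:
    payload = {
        "assignment": {
            str(a): int(m) for a, m in truth.true_partition.assignment.items()
        },
        "planted_effects": [
            {"module_index": pe.module_index, "symptom": pe.symptom,
             "effect_size": pe.effect_size}
            for pe in truth.planted_effects
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_config_file(path: Path | str) -> dict:
    """YAML or JSON mapping; file suffix decides the parser."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _to_jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_json(payload: dict, path: Path | str) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(payload), indent=2, sort_keys=True))
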