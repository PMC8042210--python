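"""Dataset loading, run configuration and result serialization.

Matrices are CSV/TSV with attribute ids in the first row and object ids
in the first column; rows are samples and columns are attributes (a
``transpose`` flag handles attribute-major files).  Labels come either
from a designated column of the matrix or from a separate single-column
file.  Attribute indices in all output files are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .granulation import DecisionTable, normalize_table

__all__ = [
    "RunConfig",
    "load_decision_table",
    "write_decision_table",
    "selection_result_to_dict",
    "write_json",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated run parameters, embedded verbatim in every result file."""

    sigma: float = 0.5
    bins: int = 4
    tol: float = 1e-10
    normalize: bool = True
    label_source: str = "class"
    skip_core: bool = False
    prune: bool = False
    max_features: int | None = None
    transpose: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("nonpositive kernel width")
        if self.bins < 2:
            raise ValueError("bins must be ≥ 2")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be ≥ 1")

    def to_json_dict(self) -> dict:
        return asdict(self)


def _read_matrix(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_decision_table(
    matrix_path, config: RunConfig, labels_path=None
) -> DecisionTable:
    """Load and validate a decision table from a CSV/TSV matrix.

    When ``labels_path`` is given it must be a single-column file (with
    header) aligned with the matrix rows; otherwise the label column
    named by ``config.label_source`` is popped out of the matrix.
    """
    path = Path(matrix_path)
    df = _read_matrix(path)
    if config.transpose:
        df = df.T

    if labels_path is not None:
        lab_df = pd.read_csv(Path(labels_path))
        if lab_df.shape[1] != 1:
            raise ValueError("label file must have exactly one column")
        labels = lab_df.iloc[:, 0].to_numpy()
        if len(labels) != len(df):
            raise ValueError(
                f"label count {len(labels)} does not match {len(df)} samples"
            )
    else:
        if config.label_source not in df.columns:
            raise ValueError(f"label column {config.label_source!r} absent")
        labels = df.pop(config.label_source).to_numpy()

    missing = df.isna().to_numpy()
    if missing.any():
        rows, cols = np.nonzero(missing)
        cells = [
            f"(sample {df.index[r]!r}, attribute {df.columns[c]!r})"
            for r, c in zip(rows, cols)
        ]
        raise ValueError("missing values at " + ", ".join(cells[:10]))
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric attribute values: {exc}") from exc

    table = DecisionTable(
        values,
        labels,
        tuple(str(c) for c in df.columns),
        tuple(str(i) for i in df.index),
    )
    return normalize_table(table) if config.normalize else table


def write_decision_table(table: DecisionTable, path, label_col: str = "class"):
    """Write a table as CSV with the label as the last column."""
    df = pd.DataFrame(
        table.values, index=list(table.object_ids), columns=list(table.attribute_ids)
    )
    df[label_col] = table.labels
    df.to_csv(Path(path), index_label="sample")


def selection_result_to_dict(result, table: DecisionTable, config: RunConfig) -> dict:
    """JSON-ready selection report with 1-based indices and full provenance."""
    d = result.to_json_dict()
    d["selected"] = [a + 1 for a in d["selected"]]
    d["core"] = [a + 1 for a in d["core"]]
    for t in d["trace"]:
        t["attribute"] += 1
    d["selected_ids"] = [table.attribute_ids[a] for a in result.selected]
    d["config"] = config.to_json_dict()
    d["version"] = __version__
    return d


def write_json(obj: dict, path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
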