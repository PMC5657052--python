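"""TSV readers/writers and result serialization.

Formats are plain tab-delimited UTF-8 text with Unix newlines:

* expression TSV — first column = feature ID, header row = sample IDs,
  cells numeric or empty/"NA" for missing (mirrors TCGA miRNASeq
  matrices);
* clinical TSV — columns ``sample_id`` and ``pathologic_stage``
  (case-insensitive; extra columns ignored);
* result tables — ``unified_model.tsv`` (effect_type, feature_1,
  feature_2, beta, se, t, p), ``edges.tsv`` (epistatic rows only, for
  network import), plus a run-provenance JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FitResult
from .preprocess import NormalizedExpressionMatrix, RawExpressionTable
from .workflow import WorkflowResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_normalized_tsv",
    "write_normalized_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "write_fit_tsv",
    "write_results",
    "read_unified_tsv",
]

_NA_VALUES = ["", "NA", "na", "NaN", "nan"]


def _format_beta(x: float) -> str:
    return f"{x:.4f}"


def _format_p(x: float) -> str:
    return f"{x:.5e}"


def read_expression_tsv(path) -> RawExpressionTable:
    """Read a feature x sample expression TSV; ""/"NA" cells are missing."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0,
            na_values=_NA_VALUES, keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression TSV {path}: {exc}") from exc
    ids = [str(i) for i in frame.index]
    dup = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature ID {dup[0]!r} in {path}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression TSV {path}: {exc}") from exc
    return RawExpressionTable(
        feature_ids=ids,
        sample_ids=[str(c) for c in frame.columns],
        values=values,
    )


def write_expression_tsv(table: RawExpressionTable, path) -> None:
    frame = table.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")


def read_clinical_tsv(path) -> list[tuple[str, str]]:
    """Read (sample_id, stage_label) pairs; column match is
    case-insensitive and extra columns are ignored."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in frame.columns}
    missing = [c for c in ("sample_id", "pathologic_stage") if c not in lower]
    if missing:
        raise ValueError(
            f"clinical TSV {path} lacks required column(s) {missing}; "
            f"available: {list(frame.columns)}"
        )
    return list(
        zip(frame[lower["sample_id"]].astype(str), frame[lower["pathologic_stage"]].astype(str))
    )


def write_clinical_tsv(rows: list[tuple[str, str]], path) -> None:
    pd.DataFrame(rows, columns=["sample_id", "pathologic_stage"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_normalized_tsv(path) -> NormalizedExpressionMatrix:
    """Read a samples x features normalized matrix (sample_id first column)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return NormalizedExpressionMatrix(
        sample_ids=[str(i) for i in frame.index],
        feature_ids=[str(c) for c in frame.columns],
        X=frame.to_numpy(dtype=float),
    )


def write_normalized_tsv(matrix: NormalizedExpressionMatrix, path) -> None:
    frame = pd.DataFrame(matrix.X, index=matrix.sample_ids, columns=matrix.feature_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_phenotype_tsv(path) -> tuple[list[str], np.ndarray]:
    """Read a continuous phenotype TSV with columns sample_id, y."""
    frame = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in frame.columns}
    missing = [c for c in ("sample_id", "y") if c not in lower]
    if missing:
        raise ValueError(
            f"phenotype TSV {path} lacks required column(s) {missing}; "
            f"available: {list(frame.columns)}"
        )
    return (
        [str(s) for s in frame[lower["sample_id"]]],
        frame[lower["y"]].to_numpy(dtype=float),
    )


def write_phenotype_tsv(sample_ids, y, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "y": np.asarray(y, dtype=float)}).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_unified_tsv(path) -> WorkflowResult:
    """Re-parse a unified_model.tsv written by :func:`write_results`."""
    from .workflow import WorkflowRow

    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    main_rows, epi_rows = [], []
    for _, rec in frame.iterrows():
        row = WorkflowRow(
            effect_type=str(rec["effect_type"]),
            feature_1=str(rec["feature_1"]),
            feature_2=str(rec["feature_2"]) or None,
            beta=float(rec["beta"]),
            se=float(rec["se"]),
            t=float(rec["t"]),
            p=float(rec["p"]),
        )
        (main_rows if row.effect_type == "main" else epi_rows).append(row)
    return WorkflowResult(main_rows, epi_rows, provenance={})


def write_fit_tsv(fit: FitResult, path) -> None:
    """Serialize one EBEN fit: feature_key, beta, se, t, p, significant."""
    frame = fit.to_frame()
    frame["beta"] = frame["beta"].map(_format_beta)
    frame["se"] = frame["se"].map(lambda x: f"{x:.6g}")
    frame["t"] = frame["t"].map(lambda x: f"{x:.6g}")
    frame["p"] = frame["p"].map(_format_p)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _rows_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "effect_type": [r.effect_type for r in rows],
            "feature_1": [r.feature_1 for r in rows],
            "feature_2": [r.feature_2 if r.feature_2 is not None else "" for r in rows],
            "beta": [_format_beta(r.beta) for r in rows],
            "se": [f"{r.se:.6g}" for r in rows],
            "t": [f"{r.t:.6g}" for r in rows],
            "p": [_format_p(r.p) for r in rows],
        }
    )


def write_results(result: WorkflowResult, out_dir) -> dict[str, Path]:
    """Write unified_model.tsv, edges.tsv and provenance.json.

    Re-running with an identical configuration overwrites the same files
    deterministically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    unified = out_dir / "unified_model.tsv"
    _rows_frame(result.rows).to_csv(unified, sep="\t", index=False, lineterminator="\n")
    paths["unified_model"] = unified

    edges = out_dir / "edges.tsv"
    pd.DataFrame(
        {
            "feature_1": [r.feature_1 for r in result.epistasis_rows],
            "feature_2": [r.feature_2 for r in result.epistasis_rows],
            "beta": [_format_beta(r.beta) for r in result.epistasis_rows],
            "p": [_format_p(r.p) for r in result.epistasis_rows],
        }
    ).to_csv(edges, sep="\t", index=False, lineterminator="\n")
    paths["edges"] = edges

    prov = out_dir / "provenance.json"
    with open(prov, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(result.provenance), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["provenance"] = prov
    logger.info("wrote %s", ", ".join(str(p) for p in paths.values()))
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
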