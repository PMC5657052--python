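"""Expression-matrix and phenotype preprocessing.

Turns a raw feature x sample expression table (e.g. a TCGA miRNASeq
extract) and a clinical staging table into the inputs the epistasis
workflow consumes: each feature is rank-mapped onto standard-normal
quantiles (inverse quantile normalization), and the ordinal pathological
stage (I-IV) becomes y = ln(stage).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RawExpressionTable",
    "NormalizedExpressionMatrix",
    "StagePhenotype",
    "filter_features_by_missingness",
    "impute_missing",
    "inverse_quantile_normalize",
    "encode_stage_phenotype",
    "align_samples",
]


@dataclass
class RawExpressionTable:
    """Feature x sample expression values with NaN as the missing marker."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_features, n_samples), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.feature_ids)} features, {len(self.sample_ids)} samples)"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = next(i for i in ids if ids.count(i) > 1)
                raise ValueError(f"duplicate {name} identifier {dup!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-feature fraction of missing cells."""
        return np.isnan(self.values).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RawExpressionTable":
        return cls(
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class NormalizedExpressionMatrix:
    """Samples x features design matrix after inverse quantile normalization."""

    sample_ids: list[str]
    feature_ids: list[str]
    X: np.ndarray  # (n, k)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("X shape does not match the identifier lists")
        if np.isnan(self.X).any():
            raise ValueError("normalized matrix must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def k(self) -> int:
        return len(self.feature_ids)

    def subset_samples(self, sample_ids: list[str]) -> "NormalizedExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return NormalizedExpressionMatrix(
            sample_ids=list(sample_ids),
            feature_ids=list(self.feature_ids),
            X=self.X[idx],
        )


@dataclass
class StagePhenotype:
    """Per-sample ordinal pathological stage and its natural-log transform."""

    sample_ids: list[str]
    stage_labels: list[str]
    ordinal: np.ndarray  # integers in {1,2,3,4}
    y: np.ndarray  # ln(ordinal)
    excluded: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ordinal = np.asarray(self.ordinal, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.sample_ids) == len(self.stage_labels) == len(self.ordinal) == len(self.y)):
            raise ValueError("phenotype fields have inconsistent lengths")
        if self.ordinal.size and not np.allclose(self.y, np.log(self.ordinal)):
            raise ValueError("y must equal ln(ordinal) elementwise")

    def subset_samples(self, sample_ids: list[str]) -> "StagePhenotype":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return StagePhenotype(
            sample_ids=list(sample_ids),
            stage_labels=[self.stage_labels[i] for i in idx],
            ordinal=self.ordinal[idx],
            y=self.y[idx],
            excluded=list(self.excluded),
        )


def filter_features_by_missingness(
    table: RawExpressionTable, max_missing_frac: float = 0.2
) -> RawExpressionTable:
    """Drop features missing in strictly more than ``max_missing_frac`` of
    samples (a feature missing in exactly the threshold fraction is kept).
    Feature order and the sample set are preserved."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    frac = table.missing_fraction()
    keep = frac <= max_missing_frac
    if not keep.any():
        raise ValueError(
            f"no features remain after the {max_missing_frac:.0%} missingness filter"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("missingness filter dropped %d of %d features", dropped, len(keep))
    return RawExpressionTable(
        feature_ids=[f for f, k in zip(table.feature_ids, keep) if k],
        sample_ids=list(table.sample_ids),
        values=table.values[keep],
    )


def impute_missing(table: RawExpressionTable) -> RawExpressionTable:
    """Replace each missing cell by its feature's median over observed
    samples, so imputed cells share the median's rank downstream."""
    values = table.values.copy()
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        fid = table.feature_ids[int(np.where(all_missing)[0][0])]
        raise ValueError(f"feature {fid!r} has no observed values to impute from")
    medians = np.nanmedian(values, axis=1)
    rows, cols = np.where(np.isnan(values))
    values[rows, cols] = medians[rows]
    return RawExpressionTable(
        feature_ids=list(table.feature_ids),
        sample_ids=list(table.sample_ids),
        values=values,
    )


def inverse_quantile_normalize(table: RawExpressionTable) -> NormalizedExpressionMatrix:
    """Map each feature onto standard-normal quantiles.

    Within a feature, value of rank r (average rank for ties) becomes
    Phi^-1(r/(n+1)).  A constant feature has all ranks tied at (n+1)/2
    and maps to a zero column (warned, not an error: downstream selection
    simply never picks it).  The output is transposed to samples x
    features, the orientation the solver consumes.
    """
    if np.isnan(table.values).any():
        raise ValueError("missing values present; run impute_missing first")
    n = table.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    constant = np.all(table.values == table.values[:, :1], axis=1)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) map to all-zero columns",
            RuntimeWarning,
            stacklevel=2,
        )
    ranks = stats.rankdata(table.values, axis=1, method="average")
    Z = stats.norm.ppf(ranks / (n + 1.0))
    return NormalizedExpressionMatrix(
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
        X=Z.T,
    )


_STAGE_RE = re.compile(r"^\s*stage\s+([ivx]+)\s*([abc])?\s*$", re.IGNORECASE)
_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


def encode_stage_phenotype(
    clinical: list[tuple[str, str]],
) -> StagePhenotype:
    """Map AJCC-style stage labels to y = ln(ordinal stage).

    Substage suffixes (A/B/C) collapse to the parent stage ("Stage IIA"
    -> 2); Roman numerals I..IV map to 1..4.  Samples with unmappable
    labels are excluded and reported in the returned exclusion log.
    """
    sample_ids: list[str] = []
    labels: list[str] = []
    ordinals: list[int] = []
    excluded: list[tuple[str, str, str]] = []
    for sample_id, label in clinical:
        m = _STAGE_RE.match(str(label))
        if not m or m.group(1).lower() not in _ROMAN:
            reason = "unrecognized stage label"
            excluded.append((str(sample_id), str(label), reason))
            logger.info("excluding sample %s: %s (%r)", sample_id, reason, label)
            continue
        sample_ids.append(str(sample_id))
        labels.append(str(label))
        ordinals.append(_ROMAN[m.group(1).lower()])
    if not sample_ids:
        raise ValueError("no samples with a mappable pathological stage")
    ordinal = np.array(ordinals, dtype=int)
    return StagePhenotype(
        sample_ids=sample_ids,
        stage_labels=labels,
        ordinal=ordinal,
        y=np.log(ordinal),
        excluded=excluded,
    )


def align_samples(
    expression: NormalizedExpressionMatrix, phenotype: StagePhenotype
) -> tuple[NormalizedExpressionMatrix, StagePhenotype]:
    """Restrict both tables to their common samples, in the expression
    table's order; every fit asserts this alignment first."""
    common = [s for s in expression.sample_ids if s in set(phenotype.sample_ids)]
    if not common:
        raise ValueError("expression and phenotype tables share no samples")
    expr = expression.subset_samples(common)
    pheno = phenotype.subset_samples(common)
    assert expr.sample_ids == pheno.sample_ids
    return expr, pheno
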