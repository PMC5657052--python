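"""Four-step main-effect and epistasis scan.

The model is y = mu + X beta_m + X_i X_j beta_e + e, e ~ N(0, sigma^2):
a linear phenotype model over single features plus pairwise product
(epistasis) terms.  Because strong main effects can mask interaction
signals in a joint scan, detection proceeds in four steps:

1. scan main-effect columns only; keep features with p < alpha;
2. correct the phenotype: y' = y - X'_m beta'_m over the significant
   main effects;
3. scan all pairwise product columns against y' (no main columns);
4. refit the selected main + pair columns jointly against the ORIGINAL
   y and report the terms that remain significant.

Each scanning step runs its own hyperparameter cross-validation, since
the candidate designs have very different dimensionality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Hashable, Sequence

import numpy as np

from .core import (
    ConcatDesign,
    DenseDesign,
    Design,
    FitResult,
    SolverConfig,
    eben_fit,
)
from .cv import DEFAULT_LAMBDA_GRID, CVGrid, select_hyperparams

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionKey",
    "CorrectedPhenotype",
    "WorkflowConfig",
    "WorkflowRow",
    "WorkflowResult",
    "PairDesign",
    "enumerate_interactions",
    "build_interaction_column",
    "scan_main_effects",
    "correct_phenotype",
    "scan_epistasis",
    "fit_unified_model",
    "run_workflow",
    "joint_scan",
]

_SEED_MOD = 2**31


@dataclass(frozen=True, order=True)
class InteractionKey:
    """Canonical unordered feature pair, stored with i < j."""

    i: int
    j: int

    def __init__(self, i: int, j: int):
        if i == j:
            raise ValueError("an interaction needs two distinct features")
        lo, hi = (i, j) if i < j else (j, i)
        object.__setattr__(self, "i", int(lo))
        object.__setattr__(self, "j", int(hi))


@dataclass(frozen=True)
class CorrectedPhenotype:
    """Phenotype with significant main-effect contributions subtracted."""

    y_prime: np.ndarray
    removed: tuple[tuple[Hashable, float], ...] = ()


@dataclass(frozen=True)
class WorkflowConfig:
    alpha_level: float = 0.05
    n_folds: int = 5
    lambda1_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    lambda2_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    seed: int = 0
    block_size: int = 1000
    fdr: bool = False
    solver: SolverConfig = field(default_factory=SolverConfig)
    min_samples: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie in (0, 1)")

    def solver_config(self) -> SolverConfig:
        return replace(self.solver, p_threshold=self.alpha_level, seed=self.seed)

    def grid(self, step_seed: int) -> CVGrid:
        return CVGrid(
            lambda1_values=tuple(self.lambda1_grid),
            lambda2_values=tuple(self.lambda2_grid),
            n_folds=self.n_folds,
            seed=step_seed % _SEED_MOD,
        )


@dataclass(frozen=True)
class WorkflowRow:
    effect_type: str  # 'main' | 'epistatic'
    feature_1: str
    feature_2: str | None
    beta: float
    se: float
    t: float
    p: float


@dataclass
class WorkflowResult:
    """Final unified-model table: one row per step-4-significant term."""

    main_rows: list[WorkflowRow]
    epistasis_rows: list[WorkflowRow]
    provenance: dict
    step1: FitResult | None = None
    step3: FitResult | None = None
    step4: FitResult | None = None

    @property
    def rows(self) -> list[WorkflowRow]:
        return list(self.main_rows) + list(self.epistasis_rows)


# ---------------------------------------------------------------------------
# Interaction design
# ---------------------------------------------------------------------------


def enumerate_interactions(k: int) -> list[InteractionKey]:
    """All k(k-1)/2 canonical pairs in lexicographic order."""
    if k < 2:
        raise ValueError("need at least 2 features to form a pair")
    ii, jj = np.triu_indices(k, 1)
    return [InteractionKey(int(a), int(b)) for a, b in zip(ii, jj)]


def build_interaction_column(X: np.ndarray, key: InteractionKey) -> np.ndarray:
    """Centered elementwise product of two normalized feature columns."""
    X = np.asarray(X, dtype=float)
    if not (0 <= key.i < X.shape[1] and 0 <= key.j < X.shape[1]):
        raise IndexError(f"pair {key} outside the design's {X.shape[1]} columns")
    col = X[:, key.i] * X[:, key.j]
    return col - col.mean()


class PairDesign(Design):
    """All pairwise product columns of a base matrix, streamed in blocks.

    Products are centered with the design's own row means (or, for
    prediction columns, the training rows' means).  Small designs are
    materialized once and cached; large ones never exist in full, so the
    scan's working set stays bounded by block_size x n.
    """

    MATERIALIZE_LIMIT = 5_000_000  # elements

    def __init__(self, X: np.ndarray, block_size: int = 1000):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need an (n, k>=2) base matrix")
        self.X = X
        self.n = X.shape[0]
        self.base_k = X.shape[1]
        self._pi, self._pj = np.triu_indices(self.base_k, 1)
        self.k = len(self._pi)
        self.keys = [
            InteractionKey(int(a), int(b)) for a, b in zip(self._pi, self._pj)
        ]
        self.block_size = block_size
        self._dense: np.ndarray | None = None
        if self.n * self.k <= self.MATERIALIZE_LIMIT:
            raw = self.X[:, self._pi] * self.X[:, self._pj]
            self._dense = raw - raw.mean(axis=0)

    def _raw(self, idx: np.ndarray) -> np.ndarray:
        return self.X[:, self._pi[idx]] * self.X[:, self._pj[idx]]

    def columns(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        if self._dense is not None:
            return self._dense[:, idx]
        raw = self._raw(idx)
        return raw - raw.mean(axis=0)

    def subset_rows(self, rows: np.ndarray) -> "PairDesign":
        return PairDesign(self.X[rows], self.block_size)

    def prediction_columns(self, rows_test, idx, rows_train):
        idx = np.asarray(idx, dtype=int)
        rows_test = np.asarray(rows_test)
        rows_train = np.asarray(rows_train)
        raw_te = self.X[rows_test][:, self._pi[idx]] * self.X[rows_test][:, self._pj[idx]]
        raw_tr = self.X[rows_train][:, self._pi[idx]] * self.X[rows_train][:, self._pj[idx]]
        return raw_te - raw_tr.mean(axis=0)

    def matmat_t(self, m: np.ndarray) -> np.ndarray:
        if self._dense is not None:
            return self._dense.T @ m
        return super().matmat_t(m)

    def colnorms_sq(self) -> np.ndarray:
        if self._dense is not None and getattr(self, "_colnorms", None) is None:
            self._colnorms = np.einsum("ij,ij->j", self._dense, self._dense)
        return super().colnorms_sq()


# ---------------------------------------------------------------------------
# Workflow steps
# ---------------------------------------------------------------------------


def _resolve_inputs(X, y, feature_ids):
    """Accept either a NormalizedExpressionMatrix/StagePhenotype pair or
    plain arrays (plus optional feature ids)."""
    if hasattr(X, "X") and hasattr(X, "feature_ids"):
        feature_ids = list(X.feature_ids)
        X = X.X
    X = np.asarray(X, dtype=float)
    if hasattr(y, "y"):
        y = y.y
    y = np.asarray(y, dtype=float)
    if feature_ids is None:
        feature_ids = [f"feature_{i}" for i in range(X.shape[1])]
    return X, y, [str(f) for f in feature_ids]


def scan_main_effects(
    X, y, cfg: WorkflowConfig | None = None, feature_ids=None
) -> FitResult:
    """Step 1: CV-tuned EBEN fit over main-effect columns only."""
    cfg = cfg or WorkflowConfig()
    X, y, feature_ids = _resolve_inputs(X, y, feature_ids)
    design = DenseDesign(X, keys=feature_ids)
    solver_cfg = cfg.solver_config()
    hp, report = select_hyperparams(design, y, cfg.grid(cfg.seed), solver_cfg)
    fit = eben_fit(design, y, hp, solver_cfg)
    fit.cv_report = report
    logger.info(
        "step 1: %d features selected, %d significant at p<%g",
        len(fit.rows), len(fit.significant), cfg.alpha_level,
    )
    return fit


def correct_phenotype(
    y: np.ndarray, X: np.ndarray, main_fit: FitResult
) -> CorrectedPhenotype:
    """Step 2: y' = y - X'_m beta'_m over the significant main effects.

    Only the significant features' fitted contributions are subtracted;
    the mean mu is left in place (the step-3 fit re-estimates its own).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sig = main_fit.significant
    if not sig:
        return CorrectedPhenotype(y_prime=y.copy(), removed=())
    idx = np.array([r.index for r in sig], dtype=int)
    if idx.max() >= X.shape[1]:
        raise ValueError(
            f"main fit refers to feature index {int(idx.max())} outside X's "
            f"{X.shape[1]} columns"
        )
    betas = np.array([r.beta for r in sig])
    y_prime = y - X[:, idx] @ betas
    return CorrectedPhenotype(
        y_prime=y_prime, removed=tuple((r.key, r.beta) for r in sig)
    )


def scan_epistasis(
    X, y_prime, cfg: WorkflowConfig | None = None
) -> FitResult:
    """Step 3: CV-tuned EBEN fit over all pairwise product columns only,
    against the corrected phenotype."""
    cfg = cfg or WorkflowConfig()
    X = np.asarray(X, dtype=float)
    if isinstance(y_prime, CorrectedPhenotype):
        y_prime = y_prime.y_prime
    design = PairDesign(X, block_size=cfg.block_size)
    solver_cfg = cfg.solver_config()
    hp, report = select_hyperparams(design, y_prime, cfg.grid(cfg.seed + 1), solver_cfg)
    fit = eben_fit(design, y_prime, hp, solver_cfg)
    fit.cv_report = report
    logger.info(
        "step 3: %d pairs selected, %d significant at p<%g",
        len(fit.rows), len(fit.significant), cfg.alpha_level,
    )
    return fit


def fit_unified_model(
    X,
    main_selected: Sequence[int],
    pairs_selected: Sequence[InteractionKey],
    y,
    cfg: WorkflowConfig | None = None,
    feature_ids=None,
) -> WorkflowResult:
    """Step 4: joint CV-tuned refit of the selected main and pair columns
    against the original phenotype; only terms with p < alpha survive."""
    cfg = cfg or WorkflowConfig()
    X, y, feature_ids = _resolve_inputs(X, y, feature_ids)
    main_selected = [int(m) for m in main_selected]
    pairs_selected = list(pairs_selected)
    provenance: dict = {"seed": cfg.seed, "alpha_level": cfg.alpha_level}
    if not main_selected and not pairs_selected:
        warnings.warn("no features selected in steps 1 and 3; empty unified model",
                      RuntimeWarning, stacklevel=2)
        return WorkflowResult([], [], provenance)
    cols = []
    keys: list[tuple] = []
    for m in main_selected:
        cols.append(X[:, m])
        keys.append(("main", feature_ids[m]))
    for pair in pairs_selected:
        cols.append(build_interaction_column(X, pair))
        keys.append(("epistatic", feature_ids[pair.i], feature_ids[pair.j]))
    design = DenseDesign(np.column_stack(cols), keys=keys)
    solver_cfg = cfg.solver_config()
    hp, report = select_hyperparams(design, y, cfg.grid(cfg.seed + 2), solver_cfg)
    fit = eben_fit(design, y, hp, solver_cfg)
    fit.cv_report = report
    rows = fit.rows
    pvals = np.array([r.p for r in rows])
    if cfg.fdr and len(rows):
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    main_rows, epi_rows = [], []
    for row, p_adj in zip(rows, pvals):
        if p_adj >= cfg.alpha_level:
            continue
        key = row.key
        if key[0] == "main":
            main_rows.append(WorkflowRow("main", key[1], None,
                                         row.beta, row.se, row.t, row.p))
        else:
            epi_rows.append(WorkflowRow("epistatic", key[1], key[2],
                                        row.beta, row.se, row.t, row.p))
    provenance["step4_hyperparams"] = {"lambda1": hp.lambda1, "lambda2": hp.lambda2}
    result = WorkflowResult(main_rows, epi_rows, provenance, step4=fit)
    logger.info(
        "step 4: %d main and %d epistatic terms significant at p<%g",
        len(main_rows), len(epi_rows), cfg.alpha_level,
    )
    return result


def run_workflow(X, y, cfg: WorkflowConfig | None = None, feature_ids=None) -> WorkflowResult:
    """Execute steps 1-4 in order with per-step cross-validation.

    Deterministic given cfg.seed; the provenance dict records the chosen
    hyperparameters of each step.
    """
    cfg = cfg or WorkflowConfig()
    X, y, feature_ids = _resolve_inputs(X, y, feature_ids)
    if X.shape[0] < cfg.min_samples:
        raise ValueError(
            f"refusing to run on {X.shape[0]} samples (need >= {cfg.min_samples})"
        )
    step1 = scan_main_effects(X, y, cfg, feature_ids)
    corrected = correct_phenotype(y, X, step1)
    step3 = scan_epistasis(X, corrected, cfg)
    result = fit_unified_model(
        X,
        [r.index for r in step1.significant],
        [r.key for r in step3.significant],
        y,
        cfg,
        feature_ids,
    )
    result.step1 = step1
    result.step3 = step3
    result.provenance.update(
        {
            "n_samples": int(X.shape[0]),
            "n_features": int(X.shape[1]),
            "n_folds": cfg.n_folds,
            "lambda1_grid": list(cfg.lambda1_grid),
            "lambda2_grid": list(cfg.lambda2_grid),
            "block_size": cfg.block_size,
            "alpha_level": cfg.alpha_level,
            "package_version": __import__("eben").__version__,
            "fdr": cfg.fdr,
            "step1_hyperparams": {
                "lambda1": step1.hyperparams.lambda1,
                "lambda2": step1.hyperparams.lambda2,
            },
            "step1_significant": [r.key for r in step1.significant],
            "step2_removed": [
                [str(k), float(b)] for k, b in corrected.removed
            ],
            "step3_hyperparams": {
                "lambda1": step3.hyperparams.lambda1,
                "lambda2": step3.hyperparams.lambda2,
            },
            "step3_significant": [
                [feature_ids[r.key.i], feature_ids[r.key.j]]
                for r in step3.significant
            ],
        }
    )
    return result


def joint_scan(X, y, cfg: WorkflowConfig | None = None, feature_ids=None) -> FitResult:
    """Single CV-tuned scan over all main + pair columns together.

    This is the one-shot alternative the multi-step workflow is designed
    to beat when strong main effects mask interactions; kept as a
    comparator for calibration studies.
    """
    cfg = cfg or WorkflowConfig()
    X, y, feature_ids = _resolve_inputs(X, y, feature_ids)
    mains = DenseDesign(X, keys=[("main", f) for f in feature_ids])
    pairs = PairDesign(X, block_size=cfg.block_size)
    pairs.keys = [
        ("epistatic", feature_ids[key.i], feature_ids[key.j], key)
        for key in pairs.keys
    ]
    design = ConcatDesign([mains, pairs])
    solver_cfg = cfg.solver_config()
    hp, report = select_hyperparams(design, y, cfg.grid(cfg.seed), solver_cfg)
    fit = eben_fit(design, y, hp, solver_cfg)
    fit.cv_report = report
    return fit
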