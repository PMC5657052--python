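"""Synthetic datasets with known main and epistatic effects.

The generator emulates the workflow's input distribution: columns are
drawn i.i.d. standard normal (optionally with an equicorrelation rho)
and then inverse-quantile-normalized per column, so each feature is an
exact set of standard-normal quantiles just like a normalized
expression matrix.  The phenotype is assembled from the linear model

    y = mu + X beta_m + X_i X_j beta_e + e,  e ~ N(0, sigma^2),

with the planted main effects beta_m, planted pair effects beta_e, and
Gaussian noise, fully reproducible from the seed.  ``evaluate_recovery``
scores a workflow result against the planted truth (power and empirical
false-discovery rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import NormalizedExpressionMatrix, RawExpressionTable, inverse_quantile_normalize
from .workflow import InteractionKey, WorkflowResult

__all__ = [
    "SyntheticTruth",
    "RecoveryReport",
    "standard_truth",
    "null_truth",
    "masking_truth",
    "simulate_dataset",
    "discretize_phenotype",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted generative model for one synthetic dataset."""

    n: int = 300
    k: int = 30
    mu: float = 0.0
    main_effects: tuple[tuple[int, float], ...] = ()
    pair_effects: tuple[tuple[InteractionKey, float], ...] = ()
    noise_sd: float = 1.0
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10 or self.k < 2:
            raise ValueError("need n >= 10 and k >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        for idx, _ in self.main_effects:
            if not 0 <= idx < self.k:
                raise ValueError(f"main-effect index {idx} outside [0, {self.k})")
        seen = set()
        for key, _ in self.pair_effects:
            if not 0 <= key.i < key.j < self.k:
                raise ValueError(f"pair {key} outside the feature range")
            if key in seen:
                raise ValueError(f"pair {key} planted twice")
            seen.add(key)


def standard_truth(seed: int = 0) -> SyntheticTruth:
    """The default recovery scenario: n=300, k=30, three main effects of
    0.8 and two pair effects of 0.6 on disjoint features, noise sd 1."""
    return SyntheticTruth(
        n=300,
        k=30,
        main_effects=((2, 0.8), (10, 0.8), (17, 0.8)),
        pair_effects=((InteractionKey(4, 21), 0.6), (InteractionKey(8, 27), 0.6)),
        noise_sd=1.0,
        seed=seed,
    )


def null_truth(seed: int = 0, n: int = 200, k: int = 30) -> SyntheticTruth:
    """No planted effects: pure noise phenotype for calibration."""
    return SyntheticTruth(n=n, k=k, noise_sd=1.0, seed=seed)


def masking_truth(seed: int = 0) -> SyntheticTruth:
    """One strong main effect (beta = 2) next to one modest pair effect
    (beta_e = 0.6) on unrelated features — the masking scenario the
    multi-step workflow exists for."""
    return SyntheticTruth(
        n=300,
        k=20,
        main_effects=((0, 2.0),),
        pair_effects=((InteractionKey(5, 12), 0.6),),
        noise_sd=1.0,
        seed=seed,
    )


def simulate_dataset(
    truth: SyntheticTruth,
) -> tuple[NormalizedExpressionMatrix, np.ndarray, SyntheticTruth]:
    """Draw (X, y) from the planted model; bitwise-reproducible from seed."""
    rng = np.random.default_rng(truth.seed)
    raw = rng.standard_normal((truth.n, truth.k))
    if truth.rho > 0:
        shared = rng.standard_normal((truth.n, 1))
        raw = np.sqrt(truth.rho) * shared + np.sqrt(1.0 - truth.rho) * raw
    table = RawExpressionTable(
        feature_ids=[f"feat_{i:03d}" for i in range(truth.k)],
        sample_ids=[f"s{j:04d}" for j in range(truth.n)],
        values=raw.T,
    )
    norm = inverse_quantile_normalize(table)
    X = norm.X
    y = np.full(truth.n, truth.mu)
    for idx, beta in truth.main_effects:
        y = y + beta * X[:, idx]
    for key, beta in truth.pair_effects:
        y = y + beta * X[:, key.i] * X[:, key.j]
    y = y + rng.normal(0.0, truth.noise_sd, size=truth.n)
    return norm, y, truth


def discretize_phenotype(y: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Quartile-bin a continuous phenotype into four ordinal stages,
    mimicking ln{1..4} responses; returns (stage labels, ln(stage))."""
    y = np.asarray(y, dtype=float)
    edges = np.quantile(y, [0.25, 0.5, 0.75])
    ordinal = 1 + np.searchsorted(edges, y, side="left")
    labels = ["Stage " + "I II III IV".split()[o - 1] for o in ordinal]
    return labels, np.log(ordinal.astype(float))


@dataclass
class RecoveryReport:
    """Detection power, empirical FDR and estimation error vs the truth."""

    power_main: float
    power_pairs: float
    fdr: float
    n_discoveries: int
    recovered_main: list[int] = field(default_factory=list)
    recovered_pairs: list[InteractionKey] = field(default_factory=list)
    beta_errors: dict = field(default_factory=dict)  # key -> (estimate, truth)

    @property
    def power(self) -> float:
        """Pooled power over all planted terms."""
        n_true = len(self.beta_errors)
        n_planted = getattr(self, "_n_planted", None)
        if n_planted:
            return n_true / n_planted
        return float("nan")


def evaluate_recovery(
    result: WorkflowResult,
    truth: SyntheticTruth,
    feature_ids: list[str],
) -> RecoveryReport:
    """Score a workflow result: a planted main effect counts as recovered
    iff its feature appears in the final main table; a planted pair iff
    its canonical key appears in the final epistasis table.  Everything
    else discovered is a false positive.  Vacuously empty truth sides
    score power 1."""
    feature_ids = [str(f) for f in feature_ids]
    true_main = {feature_ids[i]: b for i, b in truth.main_effects}
    true_pairs = {
        (feature_ids[key.i], feature_ids[key.j]): b for key, b in truth.pair_effects
    }
    found_main = {r.feature_1: r.beta for r in result.main_rows}
    found_pairs = {(r.feature_1, r.feature_2): r.beta for r in result.epistasis_rows}

    rec_main = sorted(set(true_main) & set(found_main))
    rec_pairs = sorted(set(true_pairs) & set(found_pairs))
    n_disc = len(found_main) + len(found_pairs)
    n_false = (len(found_main) - len(rec_main)) + (len(found_pairs) - len(rec_pairs))

    beta_errors = {}
    for f in rec_main:
        beta_errors[f] = (found_main[f], true_main[f])
    for pr in rec_pairs:
        beta_errors[pr] = (found_pairs[pr], true_pairs[pr])

    pos = {f: i for i, f in enumerate(feature_ids)}
    report = RecoveryReport(
        power_main=len(rec_main) / len(true_main) if true_main else 1.0,
        power_pairs=len(rec_pairs) / len(true_pairs) if true_pairs else 1.0,
        fdr=n_false / max(1, n_disc),
        n_discoveries=n_disc,
        recovered_main=[pos[f] for f in rec_main],
        recovered_pairs=[InteractionKey(pos[a], pos[b]) for a, b in rec_pairs],
        beta_errors=beta_errors,
    )
    report._n_planted = len(true_main) + len(true_pairs)
    return report
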