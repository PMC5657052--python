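"""Empirical Bayesian Elastic Net (EBEN) solver.

Sparse Bayesian linear regression with a two-level prior on the
coefficients: each beta_k is normal with its own variance 1/alpha_k, and
the alpha_k carry a generalized-Gamma hyperprior controlled by two
elastic-net-like hyperparameters lambda1 and lambda2.  The model is fit
by greedy coordinate ascent on the marginal log posterior of alpha_k,

    L(alpha) = 1/2 [ log( alpha / (alpha + 1 + s) )
                     + q^2 / (alpha + 1 + s) ] - lambda2 / alpha,

where the sparsity/quality statistics (s_k, q_k) of each candidate
feature are derived from the marginal covariance of the response.
The coefficient prior is noise-scaled, beta_k ~ N(0, sigma0^2/alpha_k),
so C = sigma0^2 (I + X_A A^-1 X_A^T) and the statistics

    s_k = x_k^T C0^-1 x_k,   q_k = x_k^T C0^-1 y~ / sigma0,
    C0 = I + X_A A^-1 X_A^T,

are exactly invariant under rescaling of the response.  A feature can
carry a finite alpha (and hence a non-zero coefficient) only when

    q_k^2 - s_k > lambda1 + 2 lambda2 ,

otherwise its optimal alpha is infinite and the feature is pruned.  Each
iteration either adds, re-estimates, or deletes the single feature with
the largest ascent gain, until no positive-gain move remains or the
alpha vector stops changing.  Selected coefficients are then tested with
posterior t-tests (beta / posterior SE against a Student-t reference).

The solver consumes a :class:`Design` (a column provider), so the same
machinery drives plain expression matrices and streamed pairwise
interaction columns without materializing the full pair design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Hashable, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "NumericalError",
    "EBENHyperparams",
    "SolverConfig",
    "Design",
    "DenseDesign",
    "ConcatDesign",
    "ActiveSetState",
    "Action",
    "FitRow",
    "FitResult",
    "initialize_state",
    "compute_s_q",
    "log_posterior_alpha",
    "optimal_alpha",
    "select_update",
    "apply_update",
    "update_noise_variance",
    "check_convergence",
    "posterior_t_tests",
    "eben_fit",
]

#: floor applied to the noise variance so a perfect fit never divides by zero
SIGMA_SQ_FLOOR = 1e-12

#: bracket for the 1-D numeric search over alpha (log-spaced)
ALPHA_BRACKET = (1e-6, 1e6)

_GRID_POINTS = 61
_GOLDEN_ITERS = 48
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


class NumericalError(RuntimeError):
    """The solver's linear algebra lost numerical validity."""


@dataclass(frozen=True)
class EBENHyperparams:
    """Elastic-net-like hyperparameters of the coefficient hyperprior.

    ``lambda1`` enters only the inclusion gate (q^2 - s > lambda1 +
    2*lambda2); ``lambda2`` additionally penalizes the log posterior
    through the -lambda2/alpha term.  Both are chosen by cross-validation
    in practice (see :mod:`eben.cv`).
    """

    lambda1: float = 0.0
    lambda2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class SolverConfig:
    """Convergence tolerances and testing options for the greedy solver."""

    alpha_change_tol: float = 1e-6
    norm_change_tol: float = 1e-6
    max_iterations: int = 1000
    p_threshold: float = 0.05
    df_rule: str = "n_minus_active_minus_1"
    seed: int = 0
    #: rescale candidate columns to unit L2 norm inside the solver (the
    #: scale the alpha objective is written for); reported beta/se are
    #: always in the caller's units
    unit_scale: bool = True

    def __post_init__(self) -> None:
        if self.alpha_change_tol <= 0 or self.norm_change_tol <= 0:
            raise ValueError("convergence tolerances must be strictly positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.df_rule != "n_minus_active_minus_1":
            raise ValueError(f"unknown df_rule {self.df_rule!r}")


# ---------------------------------------------------------------------------
# Designs: column providers
# ---------------------------------------------------------------------------


class Design:
    """Abstract provider of model-ready design columns.

    Concrete designs expose ``n`` samples, ``k`` candidate columns and a
    ``keys`` sequence naming them.  Columns are fetched on demand so that
    very wide designs (all pairwise products) never need to exist in
    memory at once; block size bounds the scan's working set.
    """

    n: int
    k: int
    keys: Sequence[Hashable]
    block_size: int = 1000

    def columns(self, idx: np.ndarray) -> np.ndarray:
        """Return the (n, len(idx)) model-ready columns at ``idx``."""
        raise NotImplementedError

    def subset_rows(self, rows: np.ndarray) -> "Design":
        """A design over the same columns restricted to ``rows``."""
        raise NotImplementedError

    def prediction_columns(
        self, rows_test: np.ndarray, idx: np.ndarray, rows_train: np.ndarray
    ) -> np.ndarray:
        """Columns for held-out rows, with any centering taken from the
        training rows (no information leaks from the test fold)."""
        raise NotImplementedError

    def iter_blocks(self):
        for start in range(0, self.k, self.block_size):
            stop = min(start + self.block_size, self.k)
            yield start, self.columns(np.arange(start, stop))

    def matmat_t(self, m: np.ndarray) -> np.ndarray:
        """Blockwise X^T @ m (m is (n,) or (n, j))."""
        vec = m.ndim == 1
        mm = m[:, None] if vec else m
        out = np.empty((self.k, mm.shape[1]))
        for start, block in self.iter_blocks():
            out[start : start + block.shape[1]] = block.T @ mm
        return out[:, 0] if vec else out

    def colnorms_sq(self) -> np.ndarray:
        cached = getattr(self, "_colnorms", None)
        if cached is None:
            cached = np.empty(self.k)
            for start, block in self.iter_blocks():
                cached[start : start + block.shape[1]] = np.einsum(
                    "ij,ij->j", block, block
                )
            self._colnorms = cached
        return cached


class DenseDesign(Design):
    """Design backed by an in-memory (n, k) array, used as provided."""

    def __init__(self, X: np.ndarray, keys: Sequence[Hashable] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("design matrix must be 2-D (samples x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix contains non-finite entries")
        self.X = X
        self.n, self.k = X.shape
        self.keys = list(keys) if keys is not None else list(range(self.k))
        if len(self.keys) != self.k:
            raise ValueError("keys length does not match the column count")

    def columns(self, idx: np.ndarray) -> np.ndarray:
        return self.X[:, np.asarray(idx, dtype=int)]

    def subset_rows(self, rows: np.ndarray) -> "DenseDesign":
        return DenseDesign(self.X[rows], self.keys)

    def prediction_columns(self, rows_test, idx, rows_train):
        return self.X[np.asarray(rows_test)][:, np.asarray(idx, dtype=int)]

    def matmat_t(self, m: np.ndarray) -> np.ndarray:
        return self.X.T @ m

    def colnorms_sq(self) -> np.ndarray:
        cached = getattr(self, "_colnorms", None)
        if cached is None:
            cached = np.einsum("ij,ij->j", self.X, self.X)
            self._colnorms = cached
        return cached


class ColumnScaledDesign(Design):
    """View of a design with every column rescaled to unit L2 norm.

    The alpha objective and its lambda gates are calibrated for O(1)
    sparsity/quality statistics, i.e. unit-norm columns; the solver fits
    in this scale and converts coefficients back afterwards.  Zero-norm
    columns keep scale 1 (they stay zero and are never selectable).
    """

    def __init__(self, base: Design):
        self.base = base
        self.n, self.k = base.n, base.k
        self.keys = base.keys
        self.block_size = base.block_size
        norms = np.sqrt(base.colnorms_sq())
        self.scale = np.where(norms > 0, norms, 1.0)

    def columns(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        return self.base.columns(idx) / self.scale[idx]

    def subset_rows(self, rows: np.ndarray) -> "ColumnScaledDesign":
        return ColumnScaledDesign(self.base.subset_rows(rows))

    def prediction_columns(self, rows_test, idx, rows_train):
        return self.base.prediction_columns(rows_test, idx, rows_train)

    def matmat_t(self, m: np.ndarray) -> np.ndarray:
        out = self.base.matmat_t(m)
        return out / (self.scale if out.ndim == 1 else self.scale[:, None])

    def colnorms_sq(self) -> np.ndarray:
        return self.base.colnorms_sq() / self.scale**2


class ConcatDesign(Design):
    """Column-wise concatenation of designs over the same samples."""

    def __init__(self, parts: Sequence[Design]):
        if not parts:
            raise ValueError("need at least one part")
        if len({p.n for p in parts}) != 1:
            raise ValueError("parts disagree on the sample count")
        self.parts = list(parts)
        self.n = parts[0].n
        self.offsets = np.cumsum([0] + [p.k for p in parts])
        self.k = int(self.offsets[-1])
        self.keys = [key for p in parts for key in p.keys]

    def _split(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=int)
        part_of = np.searchsorted(self.offsets, idx, side="right") - 1
        return idx, part_of

    def columns(self, idx: np.ndarray) -> np.ndarray:
        idx, part_of = self._split(idx)
        out = np.empty((self.n, len(idx)))
        for pi, part in enumerate(self.parts):
            sel = np.where(part_of == pi)[0]
            if sel.size:
                out[:, sel] = part.columns(idx[sel] - self.offsets[pi])
        return out

    def subset_rows(self, rows: np.ndarray) -> "ConcatDesign":
        return ConcatDesign([p.subset_rows(rows) for p in self.parts])

    def prediction_columns(self, rows_test, idx, rows_train):
        idx, part_of = self._split(idx)
        out = np.empty((len(np.asarray(rows_test)), len(idx)))
        for pi, part in enumerate(self.parts):
            sel = np.where(part_of == pi)[0]
            if sel.size:
                out[:, sel] = part.prediction_columns(
                    rows_test, idx[sel] - self.offsets[pi], rows_train
                )
        return out

    def matmat_t(self, m: np.ndarray) -> np.ndarray:
        return np.concatenate([p.matmat_t(m) for p in self.parts], axis=0)

    def colnorms_sq(self) -> np.ndarray:
        return np.concatenate([p.colnorms_sq() for p in self.parts])


def as_design(X: Any, keys: Sequence[Hashable] | None = None) -> Design:
    if isinstance(X, Design):
        return X
    return DenseDesign(np.asarray(X, dtype=float), keys)


# ---------------------------------------------------------------------------
# Solver state
# ---------------------------------------------------------------------------


@dataclass
class ActiveSetState:
    """The evolving model: active features, their alphas, and the posterior.

    With the noise-scaled prior beta ~ N(0, sigma0^2/alpha), the
    posterior mean is beta = (X_A^T X_A + diag(alpha_A))^-1 X_A^T y~ and
    the posterior covariance is sigma0^2 * Sigma with Sigma =
    (X_A^T X_A + diag(alpha_A))^-1.  ``posterior_cov`` stores the
    noise-free Sigma (neither it nor beta depends on sigma0^2);
    ``s_cache``/``q_cache`` hold the most recent candidate statistics
    over all design columns.
    """

    design: Design
    mu: float
    y_centered: np.ndarray
    sigma0_sq: float
    active: list[int]
    alpha: dict[int, float]
    beta: np.ndarray
    posterior_cov: np.ndarray
    X_active: np.ndarray
    gram: np.ndarray  # (k, |active|): X^T X_active, maintained incrementally
    xty: np.ndarray
    colnorms: np.ndarray
    initial_candidate: int
    #: raw S/Q statistics over all candidates (before in-model deflation),
    #: maintained by rank-one updates and recomputed at pass boundaries
    S_raw: np.ndarray | None = None
    Q_raw: np.ndarray | None = None
    s_cache: np.ndarray | None = None
    q_cache: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def n_active(self) -> int:
        return len(self.active)

    def alpha_vector(self) -> np.ndarray:
        return np.array([self.alpha[m] for m in self.active])


def initialize_state(X: Any, y: np.ndarray, keys=None) -> ActiveSetState:
    """Center the phenotype, set the initial noise variance, and nominate
    the highest-|correlation| feature as the first candidate.

    mu = mean(y); y_centered = y - mu; sigma0^2 = 0.1 * (y~^T y~)/n; the
    initial candidate is argmax_i |x_i^T y~| (lowest index on ties).
    """
    design = as_design(X, keys)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != design.n:
        raise ValueError("y must be a 1-D vector aligned with the design rows")
    if design.n < 3:
        raise ValueError("need at least 3 samples")
    if design.k < 1:
        raise ValueError("need at least one candidate feature")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite entries")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; nothing to fit")
    mu = float(y.mean())
    yc = y - mu
    sigma0_sq = float(0.1 * (yc @ yc) / design.n)
    xty = design.matmat_t(yc)
    colnorms = design.colnorms_sq()
    j0 = int(np.argmax(np.abs(xty)))
    state = ActiveSetState(
        design=design,
        mu=mu,
        y_centered=yc,
        sigma0_sq=sigma0_sq,
        active=[],
        alpha={},
        beta=np.zeros(0),
        posterior_cov=np.zeros((0, 0)),
        X_active=np.zeros((design.n, 0)),
        gram=np.zeros((design.k, 0)),
        xty=xty,
        colnorms=colnorms,
        initial_candidate=j0,
    )
    _recompute_stats(state)
    return state


# ---------------------------------------------------------------------------
# s/q statistics
# ---------------------------------------------------------------------------


def compute_s_q(
    state: ActiveSetState,
    x: np.ndarray,
    in_model: bool = False,
    alpha: float | None = None,
) -> tuple[float, float]:
    """Sparsity/quality statistics of one column against the current model.

    For a column outside the model these are the raw statistics
    S = x^T C0^-1 x and Q = x^T C0^-1 y~ / sigma0 with C0 = I +
    X_A A^-1 X_A^T, evaluated through the Woodbury identity
    (C0^-1 = I - X_A Sigma X_A^T).  For an in-model column they are
    deflated so the column's own contribution to C0 is removed:
    s = alpha S/(alpha - S), q = alpha Q/(alpha - S).
    """
    x = np.asarray(x, dtype=float)
    sigma0 = np.sqrt(state.sigma0_sq)
    S = float(x @ x)
    Q = float(x @ state.y_centered) / sigma0
    if state.active:
        g = state.X_active.T @ x
        S -= float(g @ state.posterior_cov @ g)
        Q -= float(g @ state.beta) / sigma0
    if in_model:
        if alpha is None:
            raise ValueError("alpha is required for an in-model column")
        denom = alpha - S
        if denom <= 0:
            return np.inf, np.inf
        S, Q = alpha * S / denom, alpha * Q / denom
    if np.isnan(S) or np.isnan(Q) or (
        not in_model and not (np.isfinite(S) and np.isfinite(Q))
    ):
        raise NumericalError(f"non-finite s/q statistics (s={S!r}, q={Q!r})")
    return S, Q


def _recompute_stats(state: ActiveSetState) -> None:
    """Exact raw S/Q over every design column (Woodbury, from scratch)."""
    sigma0 = np.sqrt(state.sigma0_sq)
    S = state.colnorms.copy()
    Q = state.xty / sigma0
    if state.active:
        G = state.gram  # (k, a), cached incrementally
        S = S - np.einsum("ka,ka->k", G @ state.posterior_cov, G)
        Q = Q - (G @ state.beta) / sigma0
    state.S_raw, state.Q_raw = S, Q


def _deflated_stats(state: ActiveSetState) -> tuple[np.ndarray, np.ndarray]:
    """(s, q) per candidate: raw stats outside the model, own-contribution
    deflated for active features; refreshes the s/q caches."""
    S, Q = state.S_raw, state.Q_raw
    s, q = S.copy(), Q.copy()
    if state.active:
        act = np.array(state.active, dtype=int)
        av = state.alpha_vector()
        denom = av - S[act]
        good = denom > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            s[act] = np.where(good, av * S[act] / denom, np.inf)
            q[act] = np.where(good, av * Q[act] / denom, np.inf)
    inactive = np.ones(state.design.k, dtype=bool)
    if state.active:
        inactive[np.array(state.active)] = False
    bad = inactive & ~(np.isfinite(s) & np.isfinite(q))
    if bad.any():
        raise NumericalError(
            f"non-finite s/q statistics at feature index {int(np.where(bad)[0][0])}"
        )
    state.s_cache, state.q_cache = s, q
    return s, q


# ---------------------------------------------------------------------------
# The alpha objective and its maximizer
# ---------------------------------------------------------------------------


def log_posterior_alpha(alpha: float, s: float, q: float, lambda2: float) -> float:
    """L(alpha) = 1/2[log(alpha/(alpha+1+s)) + q^2/(alpha+1+s)] - lambda2/alpha."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha!r}")
    denom = alpha + 1.0 + s
    return 0.5 * (np.log(alpha / denom) + q * q / denom) - lambda2 / alpha


def _log_posterior_vec(alpha, s, q, lambda2):
    denom = alpha + 1.0 + s
    return 0.5 * (np.log(alpha / denom) + q * q / denom) - lambda2 / alpha


def optimal_alpha(s: float, q: float, hp: EBENHyperparams) -> float:
    """Maximizer of L(alpha), or inf when the inclusion gate fails.

    The gate is strict: a feature enters only when q^2 - s > lambda1 +
    2*lambda2.  With lambda2 = 0 the stationary point has the closed form
    (1+s)^2 / (q^2 - 1 - s); otherwise the maximizer is found numerically
    in log-alpha space (grid bracket over [1e-6, 1e6], bounded refinement).
    A boundary-attained "maximum" means the supremum sits at alpha = inf,
    so inf is returned.
    """
    if s < 0:
        raise ValueError("s must be non-negative")
    if not (np.isfinite(s) and np.isfinite(q)):
        return np.inf
    if q * q - s <= hp.lambda1 + 2.0 * hp.lambda2:
        return np.inf
    if hp.lambda2 == 0.0:
        d = q * q - 1.0 - s
        if d <= 0:
            return np.inf
        return (1.0 + s) ** 2 / d
    lo, hi = np.log(ALPHA_BRACKET[0]), np.log(ALPHA_BRACKET[1])
    t = np.linspace(lo, hi, 241)
    vals = _log_posterior_vec(np.exp(t), s, q, hp.lambda2)
    b = int(np.argmax(vals))
    if b == 0 or b == len(t) - 1:
        return np.inf
    res = minimize_scalar(
        lambda u: -_log_posterior_vec(np.exp(u), s, q, hp.lambda2),
        bounds=(t[b - 1], t[b + 1]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(np.exp(res.x))


def _optimal_alpha_vec(s, q, lambda1, lambda2):
    """Vectorized optimal_alpha via the exact stationarity solution.

    dL/dalpha = 0 reduces to the quadratic A a^2 + B a + C = 0 with
    A = (1+s)/2 - q^2/2 + lambda2, B = (1+s)^2/2 + 2 lambda2 (1+s),
    C = lambda2 (1+s)^2; a positive (maximizing) root exists iff A < 0,
    and for lambda2 = 0 it collapses to (1+s)^2/(q^2-1-s).  The Eq. 3
    gate q^2 - s > lambda1 + 2 lambda2 is applied first.
    """
    out = np.full(s.shape, np.inf)
    finite = np.isfinite(s) & np.isfinite(q)
    gate = np.zeros(s.shape, dtype=bool)
    gate[finite] = q[finite] ** 2 - s[finite] > lambda1 + 2.0 * lambda2
    if not gate.any():
        return out
    sp1 = 1.0 + s[gate]
    q2 = q[gate] ** 2
    A = 0.5 * sp1 - 0.5 * q2 + lambda2
    ok = A < 0
    if lambda2 == 0.0:
        root = np.where(ok, sp1**2 / np.where(ok, q2 - sp1, 1.0), np.inf)
    else:
        B = 0.5 * sp1**2 + 2.0 * lambda2 * sp1
        C = lambda2 * sp1**2
        disc = np.sqrt(np.maximum(B * B - 4.0 * A * C, 0.0))
        root = np.where(ok, (-B - disc) / np.where(ok, 2.0 * A, 1.0), np.inf)
    out[gate] = root
    return out


# ---------------------------------------------------------------------------
# Greedy selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Action:
    """One greedy move: add/re-estimate/delete a feature, or a no-op."""

    kind: str  # 'add' | 'reestimate' | 'delete' | 'noop'
    feature: int | None = None
    alpha_new: float = np.inf
    gain: float = 0.0


NOOP = Action("noop")


def select_update(state: ActiveSetState, hp: EBENHyperparams) -> Action:
    """Pick the single feature move with the largest ascent gain.

    For every candidate the gain is dL = L(alpha*) - L(alpha_current),
    with L(inf) = 0 for features outside the model (and for deletions).
    Returns a no-op when no candidate offers dL > 0, which feeds the
    first convergence criterion.
    """
    s, q = _deflated_stats(state)
    astar = _optimal_alpha_vec(s, q, hp.lambda1, hp.lambda2)
    k = state.design.k
    finite = np.isfinite(astar)
    L_new = np.zeros(k)
    if finite.any():
        L_new[finite] = _log_posterior_vec(astar[finite], s[finite], q[finite], hp.lambda2)
    L_cur = np.zeros(k)
    active_mask = np.zeros(k, dtype=bool)
    degenerate = np.zeros(k, dtype=bool)
    if state.active:
        act = np.array(state.active, dtype=int)
        active_mask[act] = True
        defined = np.isfinite(s[act]) & np.isfinite(q[act])
        vals = np.zeros(len(act))
        if defined.any():
            vals[defined] = _log_posterior_vec(
                state.alpha_vector()[defined], s[act][defined], q[act][defined],
                hp.lambda2,
            )
        # numerically degenerate deflation (alpha - S <= 0 in floats, e.g.
        # a perfectly fit column at the noise floor): no reliable action
        # for this feature this iteration
        degenerate[act[~defined]] = True
        L_cur[act] = vals
    gain = L_new - L_cur
    candidate = (finite | active_mask) & ~degenerate
    gain = np.where(candidate, gain, -np.inf)
    j = int(np.argmax(gain))  # argmax returns the lowest index on ties
    if not gain[j] > 0:
        return NOOP
    if active_mask[j]:
        kind = "reestimate" if finite[j] else "delete"
    else:
        kind = "add"
    return Action(kind, j, float(astar[j]), float(gain[j]))


def _refit_posterior(state: ActiveSetState) -> None:
    """Recompute Sigma and beta exactly for the current alphas.

    The active-set Gram X_A^T X_A is read off the cached ``gram`` rows, so
    the per-iteration cost is O(a^3) regardless of n or k.
    """
    a = state.n_active
    if a == 0:
        state.X_active = np.zeros((state.n, 0))
        state.gram = np.zeros((state.design.k, 0))
        state.posterior_cov = np.zeros((0, 0))
        state.beta = np.zeros(0)
        return
    act = np.array(state.active, dtype=int)
    av = state.alpha_vector()
    M = np.diag(av) + state.gram[act]
    M = 0.5 * (M + M.T)
    try:
        factor = cho_factor(M)
    except LinAlgError as exc:
        raise NumericalError(
            "posterior covariance lost positive-definiteness: "
            f"active={state.active}, alpha={state.alpha}, "
            f"sigma0_sq={state.sigma0_sq}"
        ) from exc
    Sig = cho_solve(factor, np.eye(a))
    Sig = 0.5 * (Sig + Sig.T)
    state.posterior_cov = Sig
    state.beta = Sig @ state.xty[act]


def apply_update(state: ActiveSetState, action: Action) -> ActiveSetState:
    """Apply one greedy move; Sigma, beta and the raw S/Q caches are kept
    consistent by the standard rank-one update formulas (an exact
    from-scratch recompute happens at every noise-variance update, and
    the two paths agree to within accumulation error)."""
    if action.kind == "noop":
        return state
    j = action.feature
    sigma0 = np.sqrt(state.sigma0_sq)
    Sig, beta, G = state.posterior_cov, state.beta, state.gram

    if action.kind == "add":
        if j in state.alpha:
            raise ValueError(f"feature {j} is already active")
        x_new = state.design.columns(np.array([j]))
        m = state.design.matmat_t(x_new)[:, 0]  # x_k^T x_j for all k
        b = G[j] if state.active else np.zeros(0)
        c = action.alpha_new + state.colnorms[j]
        u = Sig @ b
        schur = c - float(b @ u)
        if schur <= 0:
            raise NumericalError(
                f"posterior covariance lost positive-definiteness adding "
                f"feature {j} (schur={schur:.3e})"
            )
        sjj = 1.0 / schur
        Qj = state.Q_raw[j]
        w = m - G @ u
        state.S_raw = state.S_raw - sjj * w**2
        state.Q_raw = state.Q_raw - sjj * Qj * w
        a = len(state.active)
        new_Sig = np.empty((a + 1, a + 1))
        new_Sig[:a, :a] = Sig + sjj * np.outer(u, u)
        new_Sig[:a, a] = -sjj * u
        new_Sig[a, :a] = -sjj * u
        new_Sig[a, a] = sjj
        state.posterior_cov = new_Sig
        state.beta = np.concatenate(
            [beta - sjj * sigma0 * Qj * u, [sjj * sigma0 * Qj]]
        )
        state.X_active = np.hstack([state.X_active, x_new])
        state.gram = np.hstack([G, m[:, None]])
        state.active.append(j)
        state.alpha[j] = action.alpha_new

    elif action.kind == "reestimate":
        if j not in state.alpha:
            raise ValueError(f"feature {j} is not active")
        p = state.active.index(j)
        delta = action.alpha_new - state.alpha[j]
        sj = Sig[:, p]
        denom = 1.0 + delta * Sig[p, p]
        if denom <= 0:
            raise NumericalError(
                f"posterior covariance lost positive-definiteness "
                f"re-estimating feature {j}"
            )
        kappa = delta / denom
        w = G @ sj
        state.S_raw = state.S_raw + kappa * w**2
        state.Q_raw = state.Q_raw + kappa * (beta[p] / sigma0) * w
        state.posterior_cov = Sig - kappa * np.outer(sj, sj)
        state.beta = beta - kappa * beta[p] * sj
        state.alpha[j] = action.alpha_new

    elif action.kind == "delete":
        if j not in state.alpha:
            raise ValueError(f"feature {j} is not active")
        p = state.active.index(j)
        sp = Sig[:, p]
        spp = Sig[p, p]
        w = G @ sp
        state.S_raw = state.S_raw + w**2 / spp
        state.Q_raw = state.Q_raw + (beta[p] / sigma0) * w / spp
        keep = [i for i in range(len(state.active)) if i != p]
        state.posterior_cov = (Sig - np.outer(sp, sp) / spp)[np.ix_(keep, keep)]
        state.beta = (beta - beta[p] * sp / spp)[keep]
        state.X_active = np.delete(state.X_active, p, axis=1)
        state.gram = np.delete(G, p, axis=1)
        state.active.remove(j)
        del state.alpha[j]

    else:
        raise ValueError(f"unknown action kind {action.kind!r}")
    return state


def update_noise_variance(state: ActiveSetState) -> ActiveSetState:
    """Evidence-style noise update, applied once per outer pass:

    sigma0^2 <- ||y~ - X_A beta||^2 / (n - sum_k gamma_k),
    gamma_k = 1 - alpha_k * Sigma_kk.

    A non-positive denominator keeps the previous value with a warning;
    a perfect fit is floored at SIGMA_SQ_FLOOR.  The posterior and all
    S/Q statistics are then recomputed exactly from scratch.
    """
    if not state.active:
        return state
    resid = state.y_centered - state.X_active @ state.beta
    av = state.alpha_vector()
    gamma = 1.0 - av * np.diag(state.posterior_cov)
    denom = state.n - float(gamma.sum())
    if denom <= 0:
        warnings.warn(
            "noise-variance denominator non-positive; keeping previous sigma0_sq",
            RuntimeWarning,
            stacklevel=2,
        )
        return state
    state.sigma0_sq = max(float(resid @ resid) / denom, SIGMA_SQ_FLOOR)
    # Sigma and beta are sigma0-free; only the Q statistics rescale
    _recompute_stats(state)
    return state


def check_convergence(
    prev_alpha: dict[int, float],
    new_alpha: dict[int, float],
    had_candidate: bool,
    cfg: SolverConfig,
) -> bool:
    """Stop when (i) no positive-gain candidate was proposed, or
    (ii) the largest per-feature |d alpha| and (iii) the Euclidean norm
    of the change are both below their tolerances.  A membership change
    (a finite alpha appearing or vanishing) never counts as converged."""
    if not had_candidate:
        return True
    if set(prev_alpha) != set(new_alpha):
        return False
    if not prev_alpha:
        return True
    d = np.array([new_alpha[m] - prev_alpha[m] for m in prev_alpha])
    return bool(
        np.max(np.abs(d)) < cfg.alpha_change_tol
        and np.linalg.norm(d) < cfg.norm_change_tol
    )


# ---------------------------------------------------------------------------
# Posterior t-tests and the fit driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitRow:
    key: Hashable
    index: int
    beta: float
    se: float
    t: float
    p: float


@dataclass
class FitResult:
    """One converged EBEN fit: selected features with beta, SE, t, p."""

    mu: float
    rows: list[FitRow]
    sigma0_sq: float
    hyperparams: EBENHyperparams
    p_threshold: float
    n_samples: int
    n_iterations: int = 0
    converged: bool = True
    history: list = field(default_factory=list)
    cv_report: Any = None
    #: converged alpha per selected design index (solver scale)
    alpha: dict[int, float] = field(default_factory=dict)
    #: L2 norm each selected column was divided by inside the solver
    column_scales: dict[int, float] = field(default_factory=dict)

    @property
    def significant(self) -> list[FitRow]:
        return [r for r in self.rows if r.p < self.p_threshold]

    @property
    def active_indices(self) -> np.ndarray:
        return np.array([r.index for r in self.rows], dtype=int)

    @property
    def betas(self) -> np.ndarray:
        return np.array([r.beta for r in self.rows])

    def predict(self, columns: np.ndarray) -> np.ndarray:
        """mu + columns @ beta, where ``columns`` are the model-ready
        design columns of the selected features (in row order)."""
        if len(self.rows) == 0:
            n = columns.shape[0] if hasattr(columns, "shape") else len(columns)
            return np.full(n, self.mu)
        return self.mu + np.asarray(columns) @ self.betas

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_key": [r.key for r in self.rows],
                "beta": [r.beta for r in self.rows],
                "se": [r.se for r in self.rows],
                "t": [r.t for r in self.rows],
                "p": [r.p for r in self.rows],
                "significant": [r.p < self.p_threshold for r in self.rows],
            }
        )


def posterior_t_tests(
    state: ActiveSetState,
    cfg: SolverConfig,
    hyperparams: EBENHyperparams | None = None,
) -> FitResult:
    """t-tests on the selected coefficients from the posterior covariance.

    The posterior covariance of beta is sigma0^2 * Sigma, so se_k =
    sigma0 * sqrt(Sigma_kk); t = beta/se; two-sided p from a Student-t
    with df = n - |active| - 1 (the intercept is absorbed in mu).
    """
    a = state.n_active
    df = state.n - a - 1
    if df <= 0:
        raise ValueError(
            f"model over-saturated: n={state.n}, active={a} leaves df={df}"
        )
    se = (
        np.sqrt(state.sigma0_sq * np.diag(state.posterior_cov))
        if a
        else np.zeros(0)
    )
    t = np.where(se > 0, state.beta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    rows = [
        FitRow(
            key=state.design.keys[m],
            index=m,
            beta=float(state.beta[i]),
            se=float(se[i]),
            t=float(t[i]),
            p=float(p[i]),
        )
        for i, m in enumerate(state.active)
    ]
    return FitResult(
        mu=state.mu,
        rows=rows,
        sigma0_sq=state.sigma0_sq,
        hyperparams=hyperparams or EBENHyperparams(),
        p_threshold=cfg.p_threshold,
        n_samples=state.n,
        alpha=dict(state.alpha),
        column_scales={m: 1.0 for m in state.active},
    )


def eben_fit(
    X: Any,
    y: np.ndarray,
    hp: EBENHyperparams | None = None,
    cfg: SolverConfig | None = None,
    keys: Sequence[Hashable] | None = None,
) -> FitResult:
    """Run the full greedy coordinate-ascent fit.

    initialize -> (select_update -> apply_update -> update_noise_variance
    -> check_convergence) loop -> posterior t-tests.  Deterministic given
    (X, y, hp, cfg).
    """
    hp = hp or EBENHyperparams()
    cfg = cfg or SolverConfig()
    design = as_design(X, keys)
    if cfg.unit_scale:
        design = ColumnScaledDesign(design)
    state = initialize_state(design, y)
    history: list[tuple[str, int, float]] = []

    # seed the model with the highest-correlation candidate when it helps
    x0 = state.design.columns(np.array([state.initial_candidate]))[:, 0]
    s0, q0 = compute_s_q(state, x0)
    a0 = optimal_alpha(s0, q0, hp)
    if np.isfinite(a0):
        g0 = log_posterior_alpha(a0, s0, q0, hp.lambda2)
        if g0 > 0:
            apply_update(state, Action("add", state.initial_candidate, a0, g0))
            update_noise_variance(state)
            history.append(("add", state.initial_candidate, float(g0)))

    # outer passes: greedy actions at fixed sigma0^2 until no positive-gain
    # move (or the alpha-change criteria), then one noise update; converged
    # when a pass proposes nothing and sigma0^2 is at its fixed point
    converged = False
    iterations = 0
    while iterations < cfg.max_iterations:
        pass_actions = 0
        while iterations < cfg.max_iterations:
            iterations += 1
            prev = dict(state.alpha)
            action = select_update(state, hp)
            had = action.kind != "noop"
            if had:
                apply_update(state, action)
                pass_actions += 1
                history.append((action.kind, action.feature, action.gain))
            if check_convergence(prev, state.alpha, had, cfg):
                break
        prev_sigma = state.sigma0_sq
        update_noise_variance(state)
        sigma_stable = (
            abs(state.sigma0_sq - prev_sigma) <= 1e-8 * max(prev_sigma, SIGMA_SQ_FLOOR)
        )
        if pass_actions == 0 and sigma_stable:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"solver stopped at max_iterations={cfg.max_iterations} "
            "without meeting the convergence criteria",
            RuntimeWarning,
            stacklevel=2,
        )
    fit = posterior_t_tests(state, cfg, hp)
    fit.n_iterations = iterations
    fit.converged = converged
    fit.history = history
    if cfg.unit_scale:
        # convert beta/se back to the caller's column units (t, p invariant)
        from dataclasses import replace as _replace

        scales = design.scale
        fit.rows = [
            _replace(r, beta=r.beta / scales[r.index], se=r.se / scales[r.index])
            for r in fit.rows
        ]
        fit.column_scales = {r.index: float(scales[r.index]) for r in fit.rows}
    return fit
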