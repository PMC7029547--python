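"""Graph-regularized L2,1 nonnegative matrix factorization.

The association matrix Y (n miRNAs x m diseases, entries in [0,1] after
WKNKN) is approximated as W @ H.T with nonnegative factors W (n x k) and
H (m x k) minimizing

    ||Y - W H^T||_F^2
      + lambda_l (||W||_F^2 + ||H||_F^2)        Tikhonov smoothness
      + lambda_l ||H||_{2,1}                    row sparsity of H
      + lambda_m Tr(W^T L_m W)                  miRNA graph smoothness
      + lambda_d Tr(H^T L_d H)                  disease graph smoothness

where L = D - S are the graph Laplacians of the integrated similarity
matrices.  The problem is solved by multiplicative updates that split each
Laplacian into its positive (S) and degree (D) parts, with the L2,1 term
handled by iterative reweighting through a diagonal matrix A of inverse row
norms of H.  Every update preserves nonnegativity and the objective is
non-increasing along the trajectory.  Predicted association scores are the
entries of Y* = W @ H.T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "NMFConfig",
    "GraphPair",
    "FactorizationResult",
    "GraphRegularizedL21NMF",
    "graph_laplacian",
    "l21_norm",
    "row_weight_matrix",
    "objective",
    "update_W",
    "update_H",
    "fit_grl21nmf",
    "predict_scores",
]


@dataclass(frozen=True)
class NMFConfig:
    """Hyperparameters of the factorization.

    ``lambda_21`` defaults to ``lambda_l``: the printed objective ties the
    Tikhonov and row-sparsity terms to a single coefficient, but they can be
    decoupled for sensitivity analysis.
    """

    rank: int = 50
    lambda_l: float = 1.0
    lambda_m: float = 0.01
    lambda_d: float = 0.01
    lambda_21: float | None = None
    max_iter: int = 500
    tol: float = 1e-6
    eps: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if min(self.lambda_l, self.lambda_m, self.lambda_d) < 0:
            raise ValueError("regularization coefficients must be >= 0")
        if self.tol <= 0 or self.eps <= 0:
            raise ValueError("tol and eps must be positive")

    @property
    def l21(self) -> float:
        return self.lambda_l if self.lambda_21 is None else self.lambda_21


@dataclass(frozen=True)
class GraphPair:
    """Similarity matrix with its degree matrix and Laplacian L = D - S."""

    S: np.ndarray
    D: np.ndarray
    L: np.ndarray


@dataclass
class FactorizationResult:
    W: np.ndarray
    H: np.ndarray
    scores: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def graph_laplacian(S: np.ndarray) -> GraphPair:
    """Degree matrix and unnormalized Laplacian of a symmetric similarity matrix."""
    S = np.asarray(S, float)
    if np.abs(S - S.T).max() > 1e-8:
        raise ValueError("similarity matrix must be symmetric")
    D = np.diag(S.sum(axis=1))
    return GraphPair(S=S, D=D, L=D - S)


def l21_norm(H: np.ndarray) -> float:
    """Sum of the Euclidean norms of the rows."""
    return float(np.linalg.norm(np.asarray(H, float), axis=1).sum())


def row_weight_matrix(H: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Diagonal of the reweighting matrix A: A_ss = 1 / max(||H_s||_2, eps)."""
    norms = np.linalg.norm(np.asarray(H, float), axis=1)
    return 1.0 / np.maximum(norms, eps)


def objective(Y, W, H, graph_m: GraphPair | None, graph_d: GraphPair | None,
              config: NMFConfig) -> float:
    Y, W, H = (np.asarray(a, float) for a in (Y, W, H))
    val = np.linalg.norm(Y - W @ H.T, "fro") ** 2
    val += config.lambda_l * (np.linalg.norm(W, "fro") ** 2 + np.linalg.norm(H, "fro") ** 2)
    val += config.l21 * l21_norm(H)
    if graph_m is not None and config.lambda_m > 0:
        val += config.lambda_m * np.trace(W.T @ graph_m.L @ W)
    if graph_d is not None and config.lambda_d > 0:
        val += config.lambda_d * np.trace(H.T @ graph_d.L @ H)
    return float(val)


def _check_finite(M: np.ndarray, name: str, iteration: int) -> None:
    if not np.isfinite(M).all():
        raise FloatingPointError(
            f"non-finite values in {name} at iteration {iteration}"
        )


def update_W(Y, W, H, S_m, D_m, config: NMFConfig, iteration: int = 0) -> np.ndarray:
    """One multiplicative step on W; numerator carries S_m, denominator D_m."""
    num = Y @ H
    den = W @ (H.T @ H) + config.lambda_l * W
    if S_m is not None and config.lambda_m > 0:
        num = num + config.lambda_m * (S_m @ W)
        den = den + config.lambda_m * (D_m @ W)
    W_new = W * num / (den + config.eps)
    _check_finite(W_new, "W", iteration)
    return W_new


def update_H(Y, W, H, S_d, D_d, A_diag, config: NMFConfig, iteration: int = 0) -> np.ndarray:
    """One multiplicative step on H; A_diag is the diagonal of the L2,1 reweighting.

    The L2,1 term enters the denominator as (l21/2) * A * H: the derivative
    of ||H||_{2,1} is A @ H (no factor 2, unlike the squared-norm terms), so
    halving the gradient for the multiplicative split halves this term too.
    This is what makes the objective non-increasing along the iteration.
    """
    num = Y.T @ W
    den = H @ (W.T @ W) + config.lambda_l * H + 0.5 * config.l21 * (A_diag[:, None] * H)
    if S_d is not None and config.lambda_d > 0:
        num = num + config.lambda_d * (S_d @ H)
        den = den + config.lambda_d * (D_d @ H)
    H_new = H * num / (den + config.eps)
    _check_finite(H_new, "H", iteration)
    return H_new


class GraphRegularizedL21NMF(BaseEstimator):
    """Graph-regularized L2,1-NMF estimator for bipartite link prediction.

    Parameters
    ----------
    rank : int
        Latent dimension k.
    lambda_l : float
        Coefficient of both the Tikhonov term and (by default) the
        L2,1 row-sparsity term on H.
    lambda_m, lambda_d : float
        Graph-Laplacian coefficients for the miRNA and disease similarity
        graphs.
    lambda_21 : float or None
        Optional decoupled L2,1 coefficient; ``None`` ties it to lambda_l.
    max_iter, tol : int, float
        Stop after ``max_iter`` iterations or when the relative objective
        change drops below ``tol``.
    eps : float
        Guard added to update denominators and floored row norms.
    random_state : int
        Seed for the uniform(0,1) factor initialization.

    Attributes
    ----------
    W_ : ndarray of shape (n, rank)
    H_ : ndarray of shape (m, rank)
    scores_ : ndarray of shape (n, m)
        Predicted association scores W_ @ H_.T.
    objective_trace_ : list of float
        Objective value at initialization and after every iteration.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, rank: int = 50, lambda_l: float = 1.0,
                 lambda_m: float = 0.01, lambda_d: float = 0.01,
                 lambda_21: float | None = None, max_iter: int = 500,
                 tol: float = 1e-6, eps: float = 1e-12, random_state: int = 0):
        self.rank = rank
        self.lambda_l = lambda_l
        self.lambda_m = lambda_m
        self.lambda_d = lambda_d
        self.lambda_21 = lambda_21
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps
        self.random_state = random_state

    def _config(self) -> NMFConfig:
        return NMFConfig(rank=self.rank, lambda_l=self.lambda_l,
                         lambda_m=self.lambda_m, lambda_d=self.lambda_d,
                         lambda_21=self.lambda_21, max_iter=self.max_iter,
                         tol=self.tol, eps=self.eps, seed=self.random_state)

    def fit(self, Y, mirna_similarity=None, disease_similarity=None):
        config = self._config()
        Y = np.asarray(Y, dtype=float)
        n, m = Y.shape
        if config.rank > min(n, m):
            raise ValueError(f"rank {config.rank} exceeds min(n, m) = {min(n, m)}")
        if Y.min() < 0:
            raise ValueError("Y must be nonnegative")

        graph_m = graph_laplacian(mirna_similarity) if mirna_similarity is not None else None
        graph_d = graph_laplacian(disease_similarity) if disease_similarity is not None else None
        S_m = graph_m.S if graph_m is not None else None
        D_m = graph_m.D if graph_m is not None else None
        S_d = graph_d.S if graph_d is not None else None
        D_d = graph_d.D if graph_d is not None else None

        rng = np.random.default_rng(config.seed)
        W = rng.uniform(size=(n, config.rank))
        H = rng.uniform(size=(m, config.rank))

        trace = [objective(Y, W, H, graph_m, graph_d, config)]
        converged = False
        iteration = 0
        for iteration in range(1, config.max_iter + 1):
            A_diag = row_weight_matrix(H, config.eps)
            H = update_H(Y, W, H, S_d, D_d, A_diag, config, iteration)
            W = update_W(Y, W, H, S_m, D_m, config, iteration)
            obj = objective(Y, W, H, graph_m, graph_d, config)
            if not np.isfinite(obj):
                raise FloatingPointError(f"non-finite objective at iteration {iteration}")
            trace.append(obj)
            prev = trace[-2]
            if abs(prev - obj) / max(abs(prev), config.eps) < config.tol:
                converged = True
                break

        self.W_, self.H_ = W, H
        self.scores_ = W @ H.T
        self.objective_trace_ = trace
        self.n_iter_ = iteration
        self.converged_ = converged
        return self

    def predict(self, Y=None, mirna_similarity=None, disease_similarity=None):
        """Return the fitted score matrix Y* = W_ @ H_.T."""
        if not hasattr(self, "scores_"):
            raise RuntimeError("estimator is not fitted")
        return self.scores_


def fit_grl21nmf(Y, mirna_similarity=None, disease_similarity=None,
                 config: NMFConfig | None = None) -> FactorizationResult:
    """Functional wrapper returning a :class:`FactorizationResult`."""
    config = config or NMFConfig()
    est = GraphRegularizedL21NMF(
        rank=config.rank, lambda_l=config.lambda_l, lambda_m=config.lambda_m,
        lambda_d=config.lambda_d, lambda_21=config.lambda_21,
        max_iter=config.max_iter, tol=config.tol, eps=config.eps,
        random_state=config.seed,
    ).fit(Y, mirna_similarity, disease_similarity)
    return FactorizationResult(
        W=est.W_, H=est.H_, scores=est.scores_,
        objective_trace=est.objective_trace_,
        iterations=est.n_iter_, converged=est.converged_,
    )


def predict_scores(result: FactorizationResult) -> np.ndarray:
    """Score matrix Y* = W @ H.T; larger entries mean stronger predictions."""
    return result.W @ result.H.T
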