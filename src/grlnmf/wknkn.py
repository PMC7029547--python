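"""Weighted K-nearest-known-neighbors (WKNKN) imputation.

Replaces the zeros of a sparse binary association matrix with a likelihood
score built from the K most similar miRNAs (resp. diseases) that have at
least one known association.  Neighbor i contributes its profile weighted by
decay**(i-1) * similarity, normalized by the sum of the neighbor
similarities; the miRNA-side and disease-side estimates are averaged and the
result is merged with the original matrix by an elementwise max, so known
entries stay at 1 and the output never falls below the input.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["WknknConfig", "WKNKN", "known_neighbors", "knn_profile", "wknkn_update"]


from dataclasses import dataclass


@dataclass(frozen=True)
class WknknConfig:
    """Neighbor count K, geometric decay, and side weights a1 (miRNA), a2 (disease)."""

    n_neighbors: int = 5
    decay: float = 0.7
    a1: float = 1.0
    a2: float = 1.0

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if not 0 <= self.decay <= 1:
            raise ValueError("decay must lie in [0, 1]")
        if self.a1 < 0 or self.a2 < 0 or self.a1 + self.a2 <= 0:
            raise ValueError("side weights must be nonnegative with a1 + a2 > 0")


def known_neighbors(index: int, S: np.ndarray, Y: np.ndarray, k: int,
                    axis: str) -> list[int]:
    """Indices of the up-to-k most similar *known* entities, self excluded.

    A miRNA (row) or disease (column) is "known" when it has at least one
    association in the current Y.  Sorted by similarity descending; ties are
    broken by ascending index so results are reproducible.
    """
    S = np.asarray(S, float)
    Y = np.asarray(Y, float)
    has_known = (Y.sum(axis=1) if axis == "mirna" else Y.sum(axis=0)) > 0
    candidates = [i for i in range(S.shape[0]) if i != index and has_known[i]]
    candidates.sort(key=lambda i: (-S[index, i], i))
    return candidates[:k]


def knn_profile(index: int, S: np.ndarray, Y: np.ndarray, config: WknknConfig,
                axis: str) -> np.ndarray:
    """Decayed similarity-weighted average of the nearest known profiles.

    Returns a zero vector when no known neighbor exists or when the
    similarities of all selected neighbors are zero.
    """
    S = np.asarray(S, float)
    Y = np.asarray(Y, float)
    profiles = Y if axis == "mirna" else Y.T
    neighbors = known_neighbors(index, S, Y, config.n_neighbors, axis)
    out = np.zeros(profiles.shape[1])
    if not neighbors:
        return out
    sims = np.array([S[index, i] for i in neighbors])
    Q = sims.sum()
    if Q == 0:
        warnings.warn(f"all neighbor similarities of index {index} are zero")
        return out
    weights = config.decay ** np.arange(len(neighbors)) * sims
    return weights @ profiles[neighbors] / Q


def wknkn_update(Y: np.ndarray, SM: np.ndarray, SD: np.ndarray,
                 config: WknknConfig | None = None) -> np.ndarray:
    """Impute zeros of the binary matrix Y from both similarity sides.

    Y_m averages known miRNA neighbors' rows, Y_d known disease neighbors'
    columns; Y_md = (a1*Y_m + a2*Y_d)/(a1+a2) and the result is
    max(Y, Y_md) elementwise.
    """
    config = config or WknknConfig()
    Y = np.asarray(Y, float)
    SM = np.asarray(SM, float)
    SD = np.asarray(SD, float)
    n, m = Y.shape
    if SM.shape != (n, n) or SD.shape != (m, m):
        raise ValueError(
            f"dimension mismatch: Y {Y.shape}, SM {SM.shape}, SD {SD.shape}"
        )
    Y_m = np.vstack([knn_profile(i, SM, Y, config, "mirna") for i in range(n)])
    Y_d = np.vstack([knn_profile(j, SD, Y, config, "disease") for j in range(m)]).T
    Y_md = (config.a1 * Y_m + config.a2 * Y_d) / (config.a1 + config.a2)
    return np.maximum(Y, Y_md)


class WKNKN(BaseEstimator):
    """Transformer-style wrapper around :func:`wknkn_update`.

    Parameters mirror :class:`WknknConfig`; ``transform`` needs the two
    integrated similarity matrices alongside the association matrix, so it
    takes them explicitly instead of the plain sklearn signature.
    """

    def __init__(self, n_neighbors: int = 5, decay: float = 0.7,
                 a1: float = 1.0, a2: float = 1.0):
        self.n_neighbors = n_neighbors
        self.decay = decay
        self.a1 = a1
        self.a2 = a2

    def _config(self) -> WknknConfig:
        return WknknConfig(self.n_neighbors, self.decay, self.a1, self.a2)

    def fit(self, Y, mirna_similarity=None, disease_similarity=None):
        self._config()  # validate parameters
        return self

    def transform(self, Y, mirna_similarity, disease_similarity):
        return wknkn_update(Y, mirna_similarity, disease_similarity, self._config())

    def fit_transform(self, Y, mirna_similarity, disease_similarity):
        return self.fit(Y).transform(Y, mirna_similarity, disease_similarity)
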