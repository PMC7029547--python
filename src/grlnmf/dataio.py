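"""Reading, writing and synthesizing the matrices the pipeline consumes.

The on-disk dialect mirrors the supplementary material of the HMDD v2.0
miRNA-disease benchmark: dense whitespace-delimited numeric text with rows =
miRNAs (n = 495) and columns = diseases (m = 383), one-id-per-line name lists,
and a two-column child<TAB>parent edge list for the MeSH-style disease DAG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SyntheticScenario",
    "read_association_matrix",
    "read_similarity_matrix",
    "read_dag_edges",
    "read_id_list",
    "write_matrix",
    "write_association_matrix",
    "write_rankings",
    "generate_synthetic",
]


class FormatError(ValueError):
    """Malformed matrix text (ragged rows, non-numeric tokens)."""


class DataError(ValueError):
    """Well-formed text whose values violate a domain contract."""


@dataclass
class AssociationMatrix:
    """miRNA x disease association evidence.

    ``values`` is binary {0,1} before WKNKN and lives in [0,1] after it.
    Rows are miRNAs, columns are diseases.
    """

    values: np.ndarray
    mirna_ids: list[str] = field(default_factory=list)
    disease_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("association matrix must be 2-dimensional")
        n, m = self.values.shape
        if not self.mirna_ids:
            self.mirna_ids = [f"miRNA_{i}" for i in range(n)]
        if not self.disease_ids:
            self.disease_ids = [f"disease_{j}" for j in range(m)]
        if len(self.mirna_ids) != n or len(self.disease_ids) != m:
            raise DataError("id list lengths do not match matrix shape")
        if len(set(self.mirna_ids)) != n or len(set(self.disease_ids)) != m:
            raise DataError("duplicate identifiers in id lists")
        if self.values.min() < 0 or self.values.max() > 1:
            raise DataError("association entries must lie in [0, 1]")

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_known(self) -> int:
        """Number of strictly positive (known) associations."""
        return int(np.count_nonzero(self.values))

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of a planted low-rank association benchmark."""

    n: int = 100
    m: int = 80
    rank: int = 5
    density: float = 0.05
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if self.rank > min(self.n, self.m) or self.rank < 1:
            raise ValueError("rank must satisfy 1 <= rank <= min(n, m)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _parse_dense(path) -> np.ndarray:
    """Parse whitespace-delimited numeric text into a dense float array.

    Hand-rolled rather than ``np.loadtxt`` so that ragged rows and bad tokens
    are reported with the offending line number, per the I/O contract.
    """
    rows: list[list[float]] = []
    width: int | None = None
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                row = [float(t) for t in tokens]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric token on line {lineno}") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(row)} fields, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def read_association_matrix(path, mirna_ids=None, disease_ids=None) -> AssociationMatrix:
    """Read a dense association matrix (rows = miRNAs, columns = diseases).

    Identifier lists default to positional labels. Entries outside [0,1]
    raise :class:`DataError`.
    """
    values = _parse_dense(path)
    return AssociationMatrix(
        values=values,
        mirna_ids=list(mirna_ids) if mirna_ids else [],
        disease_ids=list(disease_ids) if disease_ids else [],
    )


def read_similarity_matrix(path) -> np.ndarray:
    """Read a dense square similarity matrix.

    Asymmetry up to 1e-8 is repaired as (S + S.T) / 2; larger asymmetry is a
    data error.  An off-unit diagonal within 1e-6 is forced to 1 with a
    warning; beyond that it is left for the caller to reject.
    """
    S = _parse_dense(path)
    if S.shape[0] != S.shape[1]:
        raise DataError(f"{path}: similarity matrix must be square, got {S.shape}")
    asym = np.abs(S - S.T).max()
    if asym > 1e-8:
        raise DataError(f"{path}: asymmetry {asym:.3g} exceeds tolerance 1e-8")
    S = (S + S.T) / 2.0
    diag_err = np.abs(np.diag(S) - 1.0).max()
    if diag_err > 0:
        if diag_err <= 1e-6:
            warnings.warn(f"{path}: forcing diagonal to 1 (max deviation {diag_err:.3g})")
            np.fill_diagonal(S, 1.0)
    return S


def read_id_list(path) -> list[str]:
    """One identifier per line, UTF-8, blank lines ignored."""
    with open(path, "rt", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def read_dag_edges(path):
    """Read a child<TAB>parent edge list into a :class:`~grlnmf.similarity.DiseaseDAG`.

    Nodes with no parent are roots.  Cycles are rejected with one cycle
    member named.
    """
    from .similarity import DiseaseDAG

    edges: list[tuple[str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno} is not a two-column edge")
            edges.append((parts[0], parts[1]))
    return DiseaseDAG.from_edges(edges)


def write_matrix(values: np.ndarray, path, fmt: str = "%.10g") -> None:
    np.savetxt(path, np.asarray(values, dtype=float), fmt=fmt, delimiter="\t")


def write_association_matrix(assoc: AssociationMatrix, path) -> None:
    write_matrix(assoc.values, path, fmt="%.12g")


def write_rankings(rankings, path) -> None:
    """Write per-disease ranked candidate lists as a TSV table.

    ``rankings`` maps disease_id -> ordered list of (mirna_id, score).
    Rows are ordered by disease id, then rank; score ties inside a list are
    assumed already broken deterministically upstream.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("disease_id\trank\tmirna_id\tscore\n")
        for disease_id in sorted(rankings):
            for rank, (mirna_id, score) in enumerate(rankings[disease_id], start=1):
                fh.write(f"{disease_id}\t{rank}\t{mirna_id}\t{score:.10g}\n")


def generate_synthetic(scenario: SyntheticScenario):
    """Generate a planted low-rank benchmark instance.

    Draws nonnegative latent factors U (n x rank), V (m x rank) from a seeded
    uniform distribution, plants ones at the top ``density`` fraction of
    U @ V.T + Gaussian noise, and derives both similarity matrices as the
    cosine similarity of the latent rows (clipped to [0,1], unit diagonal) so
    that they satisfy the symmetry/bounds invariants the pipeline assumes.
    A random rooted tree over the disease ids serves as the DAG fixture.

    Returns ``(assoc, mirna_sim, disease_sim, dag)``; identical seeds give
    bit-identical outputs.
    """
    from .similarity import DiseaseDAG

    rng = np.random.default_rng(scenario.seed)
    U = rng.uniform(size=(scenario.n, scenario.rank))
    V = rng.uniform(size=(scenario.m, scenario.rank))
    signal = U @ V.T
    if scenario.noise_sd > 0:
        signal = signal + rng.normal(scale=scenario.noise_sd, size=signal.shape)

    n_ones = int(round(scenario.density * scenario.n * scenario.m))
    if n_ones == 0:
        raise ValueError("density too small: no planted associations")
    flat = signal.ravel()
    top = np.argpartition(flat, -n_ones)[-n_ones:]
    Y = np.zeros(scenario.n * scenario.m)
    Y[top] = 1.0
    Y = Y.reshape(scenario.n, scenario.m)

    def _cosine(F: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(F, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        C = (F / norms) @ (F / norms).T
        C = np.clip((C + C.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(C, 1.0)
        return C

    mirna_sim = _cosine(U)
    disease_sim = _cosine(V)

    disease_ids = [f"disease_{j}" for j in range(scenario.m)]
    edges = []
    for j in range(1, scenario.m):
        parent = int(rng.integers(0, j))  # attach under an earlier node: rooted tree
        edges.append((disease_ids[j], disease_ids[parent]))
    dag = DiseaseDAG.from_edges(edges, nodes=disease_ids)

    assoc = AssociationMatrix(values=Y, disease_ids=disease_ids)
    return assoc, mirna_sim, disease_sim, dag
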