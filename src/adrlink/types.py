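"""Core containers for bipartite drug-ADR link prediction.

The central object is the binary incidence matrix ``Y`` (drugs x ADRs) of a
bipartite association network, together with square per-side similarity
matrices (drug-drug or ADR-ADR) and the dense prediction-score matrix ``F``
produced by the predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SYMMETRY_TOL = 1e-9

#: similarity sources whose entries are expected to lie in [0, 1] with unit
#: diagonal (normalized features and intrinsic/blended similarities)
NORMALIZED_SOURCES = frozenset(
    {"jaccard", "gip", "allali", "j2", "chemical", "atc", "meddra", "blended"}
)


def _check_unique(labels: Sequence[str], what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")
    if not labels:
        raise ValueError(f"empty {what} label list")
    return labels


@dataclass
class BipartiteNetwork:
    """Bipartite drug-ADR network with incidence matrix ``Y`` (n x m, 0/1).

    ``Y[i, j] == 1`` means drug ``drug_ids[i]`` has a known association with
    ADR ``adr_ids[j]``.  The neighbour set of a drug is the nonzero support
    of its row; of an ADR, of its column.
    """

    drug_ids: tuple[str, ...]
    adr_ids: tuple[str, ...]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.adr_ids = _check_unique(self.adr_ids, "ADR")
        Y = np.asarray(self.Y)
        if Y.ndim != 2 or Y.shape != (len(self.drug_ids), len(self.adr_ids)):
            raise ValueError(
                f"Y shape {Y.shape} does not match "
                f"({len(self.drug_ids)}, {len(self.adr_ids)})"
            )
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("Y must be binary (0/1)")
        self.Y = Y.astype(np.float64)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_adrs(self) -> int:
        return len(self.adr_ids)

    @property
    def n_edges(self) -> int:
        return int(self.Y.sum())

    def drug_degrees(self) -> np.ndarray:
        return self.Y.sum(axis=1)

    def adr_degrees(self) -> np.ndarray:
        return self.Y.sum(axis=0)

    def with_matrix(self, Y: np.ndarray) -> "BipartiteNetwork":
        """Same node universe, different incidence matrix."""
        return BipartiteNetwork(self.drug_ids, self.adr_ids, Y)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one side of the network.

    Parameters
    ----------
    side
        ``"drug"`` or ``"adr"`` - which node class the matrix describes.
    source
        Feature tag, e.g. ``"jaccard"``, ``"gip"``, ``"chemical"``,
        ``"blended"``.  Tags listed in :data:`NORMALIZED_SOURCES` are
        range-checked to [0, 1] with unit diagonal.
    ids
        Node labels in matrix order.
    S
        The similarity values.
    """

    side: str
    source: str
    ids: tuple[str, ...]
    S: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in ("drug", "adr"):
            raise ValueError(f"side must be 'drug' or 'adr', got {self.side!r}")
        self.ids = _check_unique(self.ids, self.side)
        S = np.asarray(self.S, dtype=np.float64)
        k = len(self.ids)
        if S.shape != (k, k):
            raise ValueError(f"S shape {S.shape} does not match {k} ids")
        if not np.isfinite(S).all():
            raise ValueError("similarity matrix has non-finite entries")
        if np.abs(S - S.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric")
        S = (S + S.T) / 2.0
        if self.source in NORMALIZED_SOURCES:
            if S.min() < -SYMMETRY_TOL or S.max() > 1 + SYMMETRY_TOL:
                raise ValueError(
                    f"{self.source} similarity entries must lie in [0, 1]"
                )
            if np.abs(np.diag(S) - 1.0).max() > SYMMETRY_TOL:
                raise ValueError(f"{self.source} similarity diagonal must be 1")
        self.S = S

    @property
    def n(self) -> int:
        return len(self.ids)

    def retagged(self, source: str) -> "SimilarityMatrix":
        return SimilarityMatrix(self.side, source, self.ids, self.S)


@dataclass
class ScoreMatrix:
    """Dense n x m matrix ``F`` of per-pair prediction scores."""

    drug_ids: tuple[str, ...]
    adr_ids: tuple[str, ...]
    F: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.adr_ids = _check_unique(self.adr_ids, "ADR")
        F = np.asarray(self.F, dtype=np.float64)
        if F.shape != (len(self.drug_ids), len(self.adr_ids)):
            raise ValueError("F shape does not match id lists")
        if not np.isfinite(F).all():
            raise ValueError("score matrix has non-finite entries")
        self.F = F


@dataclass
class NetworkStats:
    """Edge/node counts and average degrees of a bipartite network."""

    n_drugs: int
    n_adrs: int
    n_edges: int
    avg_drug_degree: float
    avg_adr_degree: float
    drug_degrees: np.ndarray = field(repr=False, default=None)
    adr_degrees: np.ndarray = field(repr=False, default=None)
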