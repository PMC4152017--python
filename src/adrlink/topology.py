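"""Topological node-pair similarity features on a bipartite network.

Seven features over homologous node pairs (drug-drug or ADR-ADR), each
computed from the interaction profiles of the chosen side (rows of ``Y``
for drugs, columns for ADRs):

``jaccard``
    |G(x) & G(y)| / |G(x) | G(y)| - intersection over union of neighbour
    sets (0 when both are empty).
``gip``
    Gaussian interaction profile kernel, exp(-gamma * ||y_x - y_y||^2)
    with the bandwidth normalized by the mean squared profile norm of the
    side (van Laarhoven-style construction).
``allali``
    Overlap coefficient |G(x) & G(y)| / min(|G(x)|, |G(y)|).
``np``
    Neighbours product |G(x)| * |G(y)|.
``cn``
    Common neighbours |G(x) & G(y)|.
``aa``
    Adamic-Adar: sum over common neighbours z of 1/ln(deg(z)); common
    neighbours of degree <= 1 contribute 0.
``j2``
    Dice coefficient 2|G(x) & G(y)| / (|G(x)| + |G(y)|), a smoothed
    variant of the Jaccard coefficient.

The overlap/Dice forms behind ``allali`` and ``j2`` are module defaults
registered in :data:`FEATURE_REGISTRY`; alternates can be plugged in
without touching callers.

Unbounded features (``cn``, ``np``, ``aa``) are min-max scaled to [0, 1]
over off-diagonal entries by default so every feature can serve as a
kernel or blend weight on a common scale; pass ``normalize=False`` for
raw values.  The diagonal is set to 1 for every feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .types import BipartiteNetwork, SimilarityMatrix

FEATURE_NAMES = ("jaccard", "gip", "allali", "np", "cn", "aa", "j2")

#: features whose raw values already lie in [0, 1]
BOUNDED_FEATURES = frozenset({"jaccard", "gip", "allali", "j2"})


@dataclass(frozen=True)
class GipParams:
    """Bandwidth multiplier for the Gaussian interaction profile kernel.

    The kernel is exp(-gamma ||y_x - y_y||^2) with
    gamma = gamma_prime / mean_i(||y_i||^2); gamma falls back to
    gamma_prime itself when every profile is empty.
    """

    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0:
            raise ValueError("gamma_prime must be positive")


def _profiles(net: BipartiteNetwork, side: str) -> np.ndarray:
    if side == "drug":
        return net.Y
    if side == "adr":
        return net.Y.T
    raise ValueError(f"side must be 'drug' or 'adr', got {side!r}")


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den > 0)
    return out


def _jaccard(P: np.ndarray) -> np.ndarray:
    inter = P @ P.T
    deg = P.sum(axis=1)
    union = deg[:, None] + deg[None, :] - inter
    return _safe_div(inter, union)


def _gip(P: np.ndarray, params: GipParams) -> np.ndarray:
    sq_norms = (P * P).sum(axis=1)
    mean_norm = sq_norms.mean()
    gamma = params.gamma_prime / mean_norm if mean_norm > 0 else params.gamma_prime
    # ||x - y||^2 = ||x||^2 + ||y||^2 - 2 x.y
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-gamma * d2)


def _overlap(P: np.ndarray) -> np.ndarray:
    inter = P @ P.T
    deg = P.sum(axis=1)
    return _safe_div(inter, np.minimum(deg[:, None], deg[None, :]))


def _neighbors_product(P: np.ndarray) -> np.ndarray:
    deg = P.sum(axis=1)
    return deg[:, None] * deg[None, :]


def _common_neighbors(P: np.ndarray) -> np.ndarray:
    return P @ P.T


def _adamic_adar(P: np.ndarray) -> np.ndarray:
    # degree of the heterologous common neighbour z = column sum of P
    z_deg = P.sum(axis=0)
    w = np.zeros_like(z_deg)
    np.divide(1.0, np.log(z_deg, where=z_deg > 1, out=np.ones_like(z_deg)),
              out=w, where=z_deg > 1)
    return (P * w) @ P.T


def _dice(P: np.ndarray) -> np.ndarray:
    inter = P @ P.T
    deg = P.sum(axis=1)
    return _safe_div(2.0 * inter, deg[:, None] + deg[None, :])


FEATURE_REGISTRY: dict[str, Callable[..., np.ndarray]] = {
    "jaccard": lambda P, params: _jaccard(P),
    "gip": lambda P, params: _gip(P, params),
    "allali": lambda P, params: _overlap(P),
    "np": lambda P, params: _neighbors_product(P),
    "cn": lambda P, params: _common_neighbors(P),
    "aa": lambda P, params: _adamic_adar(P),
    "j2": lambda P, params: _dice(P),
}


def _minmax_offdiag(S: np.ndarray) -> np.ndarray:
    k = S.shape[0]
    if k < 2:
        return np.zeros_like(S)
    mask = ~np.eye(k, dtype=bool)
    vals = S[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        out = np.zeros_like(S)
    else:
        out = (S - lo) / (hi - lo)
    return out


def topological_similarity(
    net: BipartiteNetwork,
    side: str,
    feature: str,
    params: GipParams | None = None,
    normalize: bool = True,
) -> SimilarityMatrix:
    """Compute one topological similarity feature for one network side.

    Parameters
    ----------
    net
        The bipartite network whose incidence matrix supplies the
        interaction profiles.
    side
        ``"drug"`` (profiles = rows of Y) or ``"adr"`` (columns).
    feature
        One of :data:`FEATURE_NAMES`.
    params
        Gaussian-kernel bandwidth settings; only consulted for ``gip``.
    normalize
        Min-max scale the unbounded features (``cn``, ``np``, ``aa``) to
        [0, 1] over off-diagonal entries.  Bounded features are unaffected.

    Returns
    -------
    SimilarityMatrix
        Symmetric matrix over the side's nodes with unit diagonal.
    """
    if feature not in FEATURE_REGISTRY:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURE_NAMES}")
    P = _profiles(net, side)
    S = FEATURE_REGISTRY[feature](P, params or GipParams())
    S = (S + S.T) / 2.0
    if normalize and feature not in BOUNDED_FEATURES:
        S = _minmax_offdiag(S)
    np.fill_diagonal(S, 1.0)
    ids = net.drug_ids if side == "drug" else net.adr_ids
    return SimilarityMatrix(side=side, source=feature, ids=ids, S=S)
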