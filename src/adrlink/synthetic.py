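"""Synthetic bipartite networks with correlated side similarities.

A latent-factor Bernoulli generator: drugs and ADRs receive unit latent
vectors drawn around a small set of archetype directions, with skewed
archetype popularity so that node degrees come out right-skewed (a few
promiscuous hubs, many sparsely connected nodes, as in real
pharmacovigilance networks).  Edges are sampled independently with
probability ``g(u_d . v_a)`` where ``g`` is a logistic link whose offset
is calibrated by bisection so the realized edge density matches the
requested target.  Intrinsic-style similarity matrices are built from the
same latent vectors (``clamp(u_i . u_j + noise, 0, 1)``), so they carry
genuine signal about the structure that generated the edges - exactly
what the intrinsic-feature blending and the predictors assume about real
chemical/taxonomy similarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

from .types import BipartiteNetwork, SimilarityMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    n_drugs, n_adrs: node counts.  latent_dim: number of archetype
    directions.  density: target fraction of (drug, ADR) pairs that are
    edges.  sim_noise: sd of the additive noise on the similarity
    entries.  seed: RNG seed (bit-identical outputs under the same seed).
    """

    n_drugs: int = 80
    n_adrs: int = 90
    latent_dim: int = 10
    density: float = 0.05
    sim_noise: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie strictly between 0 and 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be at least 1")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be non-negative")
        if self.n_drugs < 1 or self.n_adrs < 1:
            raise ValueError("need at least one node per side")


#: sd of the isotropic scatter of node vectors around their archetype
ARCHETYPE_SPREAD = 0.25
#: logistic link temperature: smaller = edges more determined by the latents
LINK_TAU = 0.08


def _latent_vectors(
    rng: np.random.Generator, n: int, archetypes: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Unit vectors clustered around archetypes with skewed popularity."""
    dim = archetypes.shape[1]
    choice = rng.choice(len(archetypes), size=n, p=probs)
    U = archetypes[choice] + ARCHETYPE_SPREAD * rng.standard_normal((n, dim))
    return U / np.linalg.norm(U, axis=1, keepdims=True)


def _calibrate_offset(T: np.ndarray, density: float, tau: float = LINK_TAU) -> float:
    """Bisection on the logistic offset so mean edge probability = density."""
    lo, hi = T.min() - 50 * tau, T.max() + 50 * tau
    for _ in range(200):
        mid = (lo + hi) / 2.0
        p = 1.0 / (1.0 + np.exp(-(T - mid) / tau))
        if p.mean() > density:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _similarity_from_latent(
    U: np.ndarray, noise: float, rng: np.random.Generator, side: str, ids: tuple
) -> SimilarityMatrix:
    G = U @ U.T
    if noise > 0:
        E = rng.standard_normal(G.shape) * noise
        G = G + (E + E.T) / 2.0
    S = np.clip(G, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(side=side, source="blended", ids=ids, S=S)


def generate(
    spec: SyntheticSpec,
) -> tuple[BipartiteNetwork, SimilarityMatrix, SimilarityMatrix, dict]:
    """Draw a network plus drug- and ADR-side similarities.

    Returns (network, drug similarity, ADR similarity, truth) where
    ``truth`` carries the latent factors, the edge-probability matrix and
    the realized density.  Raises if the realized density misses the
    target by more than 10% - the calibration contract.
    """
    rng = np.random.default_rng(spec.seed)
    dim = spec.latent_dim
    archetypes = rng.standard_normal((dim, dim))
    archetypes /= np.linalg.norm(archetypes, axis=1, keepdims=True)
    # geometric popularity: a few dominant archetypes drive degree skew
    probs = 0.5 ** np.arange(dim)
    probs /= probs.sum()
    U = _latent_vectors(rng, spec.n_drugs, archetypes, probs)
    V = _latent_vectors(rng, spec.n_adrs, archetypes, probs)
    T = U @ V.T
    offset = _calibrate_offset(T, spec.density)
    P = 1.0 / (1.0 + np.exp(-(T - offset) / LINK_TAU))
    if abs(P.mean() - spec.density) > 0.05 * spec.density:
        raise RuntimeError(
            f"density {spec.density:.4f} unreachable under calibration; "
            f"achieved expected density {P.mean():.4f}"
        )
    Y = (rng.random(P.shape) < P).astype(float)
    realized = Y.mean()
    if abs(realized - spec.density) > 0.1 * spec.density:
        logger.warning(
            "realized density %.4f outside 10%% of target %.4f (sampling "
            "fluctuation)", realized, spec.density
        )
    drug_ids = tuple(f"drug{i:03d}" for i in range(spec.n_drugs))
    adr_ids = tuple(f"adr{j:03d}" for j in range(spec.n_adrs))
    net = BipartiteNetwork(drug_ids, adr_ids, Y)
    Sd = _similarity_from_latent(U, spec.sim_noise, rng, "drug", drug_ids)
    Sa = _similarity_from_latent(V, spec.sim_noise, rng, "adr", adr_ids)
    truth = {
        "U": U,
        "V": V,
        "P": P,
        "offset": offset,
        "realized_density": float(realized),
    }
    return net, Sd, Sa, truth
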