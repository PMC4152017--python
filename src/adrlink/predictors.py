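"""Link predictors mapping (drug similarity, ADR similarity, Y) to scores.

All predictors share one algebraic shape: the score matrix ``F`` is a
linear function of the incidence matrix ``Y``, obtained by applying a
pair-weight operator built from the two side similarity matrices.  The
implemented families are

* ``rls`` - regularized least squares ``F = K (K + sigma I)^-1 Y`` with the
  kernel taken per side (``avg``) or over (drug, ADR) pairs via the
  Kronecker product (``kp``) or Kronecker sum (``ks``) of the side kernels;
* ``slp`` - semi-supervised link propagation minimizing
  ``||F - Y||^2 + beta vec(F)' L vec(F)`` where ``L`` is the symmetric
  normalized Laplacian of the pair-similarity graph, again with ``kp``,
  ``ks`` and per-side ``avg`` variants;
* ``nn`` - nearest-neighbour memory scores;
* ``gwpm`` / ``wp`` - the general weighted profile method: per-side
  similarity-normalized smoothing of Y, mixed by a side weight;
* ``logistic`` - a per-pair covariate logistic-regression baseline.

Kronecker solves never materialize the nm x nm pair matrix: both the
product and the sum kernel share the eigenbasis ``Vd (x) Va`` of the side
kernels, so the solve reduces to an elementwise spectral filter on the
rotated incidence matrix.  The ``vec`` convention is column-major with
pair index (drug, adr) ordered drug-major, i.e. the operators act on
``Z = Y.T`` through ``vec(Z)``; the dense-oracle tests pin this down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse.linalg as spla

from .types import BipartiteNetwork, ScoreMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

PSD_TOL = 1e-8


@dataclass
class PredictorConfig:
    """Algorithm selection and hyperparameters for :func:`predict`.

    sigma: RLS regularizer (> 0).  beta: SLP smoothness weight (>= 0).
    w_side: GWPM drug-side weight in [0, 1].  psd_fix: how to repair
    indefinite similarity matrices before kernel use.
    """

    algorithm: Literal["rls", "slp", "nn", "gwpm", "wp", "logistic"] = "gwpm"
    mode: Literal["kp", "ks", "avg"] = "avg"
    sigma: float = 1.0
    beta: float = 1.0
    w_side: float = 0.5
    psd_fix: Literal["shift", "clip", "off"] = "shift"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0.0 <= self.w_side <= 1.0:
            raise ValueError("w_side must lie in [0, 1]")


@dataclass
class KernelMatrix:
    """A similarity matrix certified positive semidefinite for kernel use."""

    side: str
    source: str
    ids: tuple[str, ...]
    K: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)


def make_kernel(S: SimilarityMatrix, psd_fix: str = "shift") -> KernelMatrix:
    """Repair a symmetric similarity matrix into a PSD kernel.

    ``shift`` adds ``(-lambda_min + 1e-8) I`` when the minimum eigenvalue is
    negative; ``clip`` zeroes negative eigenvalues and reconstructs;
    ``off`` asserts the input is already PSD (within 1e-8).
    """
    eigvals = np.linalg.eigvalsh(S.S)
    lam_min = eigvals[0]
    if psd_fix == "off":
        if lam_min < -PSD_TOL:
            raise ValueError(
                f"similarity matrix is not PSD (lambda_min={lam_min:.3e}) "
                "and psd_fix is off"
            )
        K = S.S
    elif psd_fix == "shift":
        K = S.S
        if lam_min < 0:
            K = K + (-lam_min + PSD_TOL) * np.eye(S.n)
    elif psd_fix == "clip":
        if lam_min < 0:
            w, V = np.linalg.eigh(S.S)
            w = np.maximum(w, 0.0)
            K = (V * w) @ V.T
            K = (K + K.T) / 2.0
        else:
            K = S.S
    else:
        raise ValueError(f"unknown psd_fix mode {psd_fix!r}")
    return KernelMatrix(side=S.side, source=S.source, ids=S.ids, K=K)


def _check_alignment(Sd_ids: tuple, Sa_ids: tuple, net: BipartiteNetwork) -> None:
    if Sd_ids != net.drug_ids:
        raise ValueError("drug similarity ids do not match the network")
    if Sa_ids != net.adr_ids:
        raise ValueError("ADR similarity ids do not match the network")


def _spectral_pair_solve(
    Kd: np.ndarray, Ka: np.ndarray, Y: np.ndarray, filt
) -> np.ndarray:
    """Apply an elementwise spectral filter in the joint eigenbasis.

    With ``Kd = Vd diag(ld) Vd'`` and ``Ka = Va diag(la) Va'``, any operator
    that is a scalar function ``h(ld_i, la_j)`` of the pair eigenvalues acts
    on ``Z = Y.T`` as ``Va (h * (Va' Z Vd)) Vd'``.  Returns the result as an
    n x m score matrix.
    """
    ld, Vd = np.linalg.eigh(Kd)
    la, Va = np.linalg.eigh(Ka)
    G = Va.T @ Y.T @ Vd  # m x n, rotated incidence
    H = filt(ld[None, :], la[:, None])  # m x n filter over (la_j, ld_i)
    Z = Va @ (G * H) @ Vd.T
    return Z.T


def rls_predict(
    Kd: KernelMatrix,
    Ka: KernelMatrix,
    net: BipartiteNetwork,
    mode: str = "avg",
    sigma: float = 1.0,
) -> ScoreMatrix:
    """Regularized least-squares scores ``F = K (K + sigma I)^-1 Y``.

    ``avg`` applies the smoother per side and averages; ``kp``/``ks`` use
    the Kronecker product / Kronecker sum pair kernel through the
    factorized eigensolve.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    _check_alignment(Kd.ids, Ka.ids, net)
    Y = net.Y
    n, m = Y.shape
    if mode == "avg":
        Fd = Kd.K @ np.linalg.solve(Kd.K + sigma * np.eye(n), Y)
        Fa = (Ka.K @ np.linalg.solve(Ka.K + sigma * np.eye(m), Y.T)).T
        F = 0.5 * (Fd + Fa)
    elif mode == "kp":
        F = _spectral_pair_solve(
            Kd.K, Ka.K, Y, lambda ld, la: (ld * la) / (ld * la + sigma)
        )
    elif mode == "ks":
        F = _spectral_pair_solve(
            Kd.K, Ka.K, Y, lambda ld, la: (ld + la) / (ld + la + sigma)
        )
    else:
        raise ValueError(f"unknown RLS mode {mode!r}")
    return ScoreMatrix(net.drug_ids, net.adr_ids, F)


def _normalized_adjacency(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """D^-1/2 S D^-1/2 and the degree vector (row sums, self included)."""
    d = S.sum(axis=1)
    dis = np.zeros_like(d)
    np.divide(1.0, np.sqrt(d, where=d > 0, out=np.ones_like(d)), out=dis, where=d > 0)
    return (dis[:, None] * S) * dis[None, :], d


def _side_laplacian(S: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian; zero-degree rows/columns are zeroed."""
    A, d = _normalized_adjacency(S)
    L = np.eye(S.shape[0]) - A
    zero = d == 0
    L[zero, :] = 0.0
    L[:, zero] = 0.0
    return L


def slp_predict(
    Sd: SimilarityMatrix,
    Sa: SimilarityMatrix,
    net: BipartiteNetwork,
    mode: str = "avg",
    beta: float = 1.0,
) -> ScoreMatrix:
    """Laplacian-regularized link propagation.

    Solves ``vec(F) = (I + beta L)^-1 vec(Y)`` where ``L`` is the symmetric
    normalized Laplacian of the pair-similarity graph: ``Sd (x) Sa`` for
    ``kp`` (degrees factorize, so the solve is spectral), ``Sd (+) Sa`` for
    ``ks`` (degrees do not factorize; conjugate-gradient solve with
    factorized matrix-vector products), or per-side Laplacians for ``avg``.
    Zero-degree nodes in a side's similarity graph pass their Y entries
    through unchanged.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    _check_alignment(Sd.ids, Sa.ids, net)
    Y = net.Y
    n, m = Y.shape
    if mode == "avg":
        Ld = _side_laplacian(Sd.S)
        La = _side_laplacian(Sa.S)
        Fd = np.linalg.solve(np.eye(n) + beta * Ld, Y)
        Fa = np.linalg.solve(np.eye(m) + beta * La, Y.T).T
        F = 0.5 * (Fd + Fa)
    elif mode == "kp":
        Ad, dd = _normalized_adjacency(Sd.S)
        Aa, da = _normalized_adjacency(Sa.S)
        F = _spectral_pair_solve(
            Ad, Aa, Y, lambda ld, la: 1.0 / (1.0 + beta * (1.0 - ld * la))
        )
        # pairs with a zero-degree end have an all-zero Laplacian row
        dead = (dd[:, None] == 0) | (da[None, :] == 0)
        F = np.where(dead, Y, F)
    elif mode == "ks":
        F = _slp_ks_solve(Sd.S, Sa.S, Y, beta)
    else:
        raise ValueError(f"unknown SLP mode {mode!r}")
    return ScoreMatrix(net.drug_ids, net.adr_ids, F)


def _slp_ks_solve(Sd: np.ndarray, Sa: np.ndarray, Y: np.ndarray, beta: float) -> np.ndarray:
    """CG solve of (I + beta L) vec(F) = vec(Y) for the Kronecker-sum graph.

    The pair adjacency is ``W = Sd (x) I + I (x) Sa`` with pair degree
    ``d(i,j) = deg_d(i) + deg_a(j)``; matrix-vector products are applied
    through the factorized structure at O(nm(n+m)) cost.
    """
    n, m = Y.shape
    dd = Sd.sum(axis=1)
    da = Sa.sum(axis=1)
    D = dd[None, :] + da[:, None]  # m x n, indexed (adr, drug)
    Dis = np.zeros_like(D)
    np.divide(1.0, np.sqrt(D, where=D > 0, out=np.ones_like(D)), out=Dis, where=D > 0)
    alive = D > 0

    def laplacian(Zv: np.ndarray) -> np.ndarray:
        Z = Zv.reshape((m, n), order="F")
        X = Dis * Z
        WX = X @ Sd + Sa @ X
        LZ = Z - Dis * WX
        LZ[~alive] = 0.0
        return LZ.ravel(order="F")

    op = spla.LinearOperator(
        (n * m, n * m),
        matvec=lambda v: v + beta * laplacian(v),
        dtype=np.float64,
    )
    b = Y.T.ravel(order="F")
    x, info = spla.cg(op, b, rtol=1e-12, atol=0.0, maxiter=10 * n * m)
    if info != 0:
        raise RuntimeError(f"CG failed to converge (info={info})")
    return x.reshape((m, n), order="F").T


def nn_predict(
    Sd: SimilarityMatrix, Sa: SimilarityMatrix, net: BipartiteNetwork
) -> ScoreMatrix:
    """Nearest-neighbour memory scores.

    ``F(d, e)`` averages the strongest drug-side item of evidence
    ``max_{d' != d} Sd(d, d') Y(d', e)`` with the analogous ADR-side
    maximum; a maximum over an empty or all-zero set is 0.
    """
    _check_alignment(Sd.ids, Sa.ids, net)
    Y = net.Y
    n, m = Y.shape
    Sd0 = Sd.S.copy()
    np.fill_diagonal(Sd0, 0.0)
    Sa0 = Sa.S.copy()
    np.fill_diagonal(Sa0, 0.0)
    # binary Y: the max over products equals a masked max over columns/rows
    Fd = np.zeros((n, m))
    for e in range(m):
        idx = Y[:, e] > 0
        if idx.any():
            Fd[:, e] = np.maximum(Sd0[:, idx].max(axis=1), 0.0)
    Fa = np.zeros((n, m))
    for d in range(n):
        idx = Y[d, :] > 0
        if idx.any():
            Fa[d, :] = np.maximum(Sa0[:, idx].max(axis=1), 0.0)
    return ScoreMatrix(net.drug_ids, net.adr_ids, 0.5 * (Fd + Fa))


def _row_normalized_offdiag(S: np.ndarray) -> np.ndarray:
    """Row-stochastic similarity with the diagonal excluded (zero rows stay 0)."""
    W = S.copy()
    np.fill_diagonal(W, 0.0)
    rowsum = W.sum(axis=1, keepdims=True)
    out = np.zeros_like(W)
    np.divide(W, rowsum, out=out, where=rowsum > 0)
    return out


def gwpm_predict(
    Sd: SimilarityMatrix,
    Sa: SimilarityMatrix,
    net: BipartiteNetwork,
    w_side: float = 0.5,
) -> ScoreMatrix:
    """General weighted profile scores.

    The drug-side profile ``WPd(d, e)`` is the similarity-weighted average
    of the other drugs' associations with ``e`` (self excluded, weights
    normalized to sum to 1; 0 when the weights vanish); the ADR side is
    analogous.  ``F = w_side * WPd + (1 - w_side) * WPa``.
    """
    if not 0.0 <= w_side <= 1.0:
        raise ValueError("w_side must lie in [0, 1]")
    _check_alignment(Sd.ids, Sa.ids, net)
    Y = net.Y
    WPd = _row_normalized_offdiag(Sd.S) @ Y
    WPa = Y @ _row_normalized_offdiag(Sa.S).T
    return ScoreMatrix(net.drug_ids, net.adr_ids, w_side * WPd + (1.0 - w_side) * WPa)


def weighted_profile(
    S: SimilarityMatrix, net: BipartiteNetwork, side: str
) -> np.ndarray:
    """Single-side weighted-profile score matrix (used as logistic covariates)."""
    if side == "drug":
        return _row_normalized_offdiag(S.S) @ net.Y
    if side == "adr":
        return net.Y @ _row_normalized_offdiag(S.S).T
    raise ValueError(f"side must be 'drug' or 'adr', got {side!r}")


def pair_covariates(
    net: BipartiteNetwork,
    drug_sims: list[SimilarityMatrix],
    adr_sims: list[SimilarityMatrix],
) -> np.ndarray:
    """Per-pair covariate table for the logistic baseline.

    One row per (drug, ADR) pair in drug-major order; columns are the
    drug-side weighted-profile score under each drug similarity, the
    ADR-side weighted-profile score under each ADR similarity, and the two
    node degrees.
    """
    cols = [weighted_profile(S, net, "drug").ravel() for S in drug_sims]
    cols += [weighted_profile(S, net, "adr").ravel() for S in adr_sims]
    n, m = net.Y.shape
    cols.append(np.repeat(net.drug_degrees(), m))
    cols.append(np.tile(net.adr_degrees(), n))
    return np.column_stack(cols)


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-6, maxiter: int = 100
) -> np.ndarray:
    """Ridge-stabilized iteratively reweighted least-squares logistic fit."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X.T * w) @ X + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def logistic_scores(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> np.ndarray:
    """Fit a logistic model on training pairs; return held-out probabilities.

    Uses an unpenalized maximum-likelihood fit; degenerate (separable or
    non-converging) fits fall back to a ridge-stabilized IRLS fit with
    penalty 1e-6, logged.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    Xt = sm.add_constant(X_train, has_constant="add")
    Xs = sm.add_constant(X_test, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y_train, Xt).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        if not np.isfinite(params).all() or not res.mle_retvals.get("converged", True):
            raise RuntimeError("non-converged logistic fit")
    except Exception:
        logger.warning("logistic fit degenerate; falling back to ridge-stabilized IRLS")
        params = _irls_logistic(Xt, y_train)
    eta = np.clip(Xs @ params, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def predict(
    Sd: SimilarityMatrix,
    Sa: SimilarityMatrix,
    net: BipartiteNetwork,
    config: PredictorConfig,
) -> ScoreMatrix:
    """Dispatch to the configured predictor (logistic is handled by the
    cross-validation driver, which owns the train/test split)."""
    algo = config.algorithm
    if algo == "rls":
        Kd = make_kernel(Sd, config.psd_fix)
        Ka = make_kernel(Sa, config.psd_fix)
        return rls_predict(Kd, Ka, net, mode=config.mode, sigma=config.sigma)
    if algo == "slp":
        return slp_predict(Sd, Sa, net, mode=config.mode, beta=config.beta)
    if algo == "nn":
        return nn_predict(Sd, Sa, net)
    if algo in ("gwpm", "wp"):
        return gwpm_predict(Sd, Sa, net, w_side=config.w_side)
    raise ValueError(f"predictor {algo!r} has no direct (Sd, Sa, Y) form")
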