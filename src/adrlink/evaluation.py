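"""Cross-validation and prospective evaluation of link predictors.

Ten-fold edge-masking cross validation: known drug-ADR pairs (edges) and
unknown pairs (non-edges) are each partitioned into k folds; in each round
the held-out edges are set to 0 in Y, every topological feature is
recomputed from the masked matrix, the predictor is retrained, and the
held-out edges plus held-out non-edges are scored.  Metrics are ranking
based: Mann-Whitney AUC and non-interpolated average precision (AUPR),
pooled over all folds of a repeat; the mean and standard deviation are
taken over repeated CV runs with distinct fold seeds.

Prospective evaluation trains on an earlier network snapshot and labels
all of its non-edges by their presence in a later snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import predictors as pred
from .intrinsic import blend_similarities
from .topology import GipParams, topological_similarity
from .types import BipartiteNetwork, ScoreMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

STRATA = ("low-low", "high-low", "low-high", "high-high")


@dataclass
class FoldAssignment:
    """Independent k-fold partitions of the edge and non-edge pair sets.

    ``edge_pairs``/``nonedge_pairs`` hold flat pair indices (drug-major,
    ``i * m + j``); the parallel ``*_fold`` arrays give each pair's fold.
    """

    k: int
    edge_pairs: np.ndarray
    edge_fold: np.ndarray
    nonedge_pairs: np.ndarray
    nonedge_fold: np.ndarray
    seed: int

    def fold_members(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(edge flat indices, non-edge flat indices) of fold ``i``."""
        return (
            self.edge_pairs[self.edge_fold == i],
            self.nonedge_pairs[self.nonedge_fold == i],
        )


@dataclass
class EvaluationResult:
    """AUC/AUPR summary: mean and sd over repeats, with per-repeat values."""

    auc: float
    aupr: float
    auc_sd: float = 0.0
    aupr_sd: float = 0.0
    per_repeat_auc: list[float] = field(default_factory=list)
    per_repeat_aupr: list[float] = field(default_factory=list)
    per_fold_auc: list[float] = field(default_factory=list)
    per_fold_aupr: list[float] = field(default_factory=list)
    strata: dict | None = None


@dataclass
class BlendWeights:
    """Convex blend weights: per-side topological weight and the drug
    intrinsic chemical-vs-ATC weight.

    lambda_d/lambda_a = 1 means purely topological on that side;
    0 means purely intrinsic.
    """

    lambda_d: float = 1.0
    lambda_a: float = 1.0
    omega: float = 0.5

    def __post_init__(self) -> None:
        for name in ("lambda_d", "lambda_a", "omega"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _balanced_folds(n_items: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels 0..k-1 with sizes differing by at most 1."""
    labels = np.arange(n_items) % k
    return labels[rng.permutation(n_items)]


def make_folds(net: BipartiteNetwork, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Partition edges and non-edges independently into k balanced folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    flat = net.Y.ravel()
    edge_pairs = np.flatnonzero(flat == 1)
    nonedge_pairs = np.flatnonzero(flat == 0)
    if len(edge_pairs) < k:
        raise ValueError(f"need at least {k} edges for {k}-fold CV, have {len(edge_pairs)}")
    rng = np.random.default_rng(seed)
    return FoldAssignment(
        k=k,
        edge_pairs=edge_pairs,
        edge_fold=_balanced_folds(len(edge_pairs), k, rng),
        nonedge_pairs=nonedge_pairs,
        nonedge_fold=_balanced_folds(len(nonedge_pairs), k, rng),
        seed=seed,
    )


def mask_fold(
    net: BipartiteNetwork, folds: FoldAssignment, i: int
) -> tuple[BipartiteNetwork, np.ndarray, np.ndarray]:
    """Zero out fold ``i``'s edges and return the held-out test pairs.

    Returns (train network, test flat pair indices, test labels).  The test
    set is fold i's edges (label 1) plus fold i's non-edges (label 0).
    """
    if not 0 <= i < folds.k:
        raise ValueError(f"fold index {i} out of range for k={folds.k}")
    test_edges, test_nonedges = folds.fold_members(i)
    Y = net.Y.copy()
    Y.ravel()[test_edges] = 0.0
    train = net.with_matrix(Y)
    test_pairs = np.concatenate([test_edges, test_nonedges])
    labels = np.concatenate(
        [np.ones(len(test_edges)), np.zeros(len(test_nonedges))]
    )
    return train, test_pairs, labels


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(scores, labels, method: str = "average_precision") -> float:
    """Area under the precision-recall curve.

    The default is non-interpolated average precision: walking pairs in
    descending score order, each positive contributes its precision at
    that rank, averaged over all positives.  Tied scores are processed as
    a block, with the block's positives placed at evenly spaced fractional
    ranks inside it (within-block average precision).  ``method
    ="trapezoid"`` integrates the PR curve between block boundaries
    instead.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("AUPR needs at least one positive")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # block boundaries between distinct score values
    boundaries = np.flatnonzero(np.diff(s) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(s)]])
    if method == "average_precision":
        total = 0.0
        tp_prev = 0.0
        seen_prev = 0.0
        for a, b in zip(starts, ends):
            g = b - a
            p = float(y[a:b].sum())
            if p > 0:
                j = np.arange(1, p + 1)
                positions = seen_prev + j * (g / p)
                total += ((tp_prev + j) / positions).sum()
            tp_prev += p
            seen_prev += g
        return float(total / n_pos)
    if method == "trapezoid":
        tp = 0.0
        seen = 0.0
        prev_recall = 0.0
        prev_precision = 1.0
        area = 0.0
        for a, b in zip(starts, ends):
            tp += float(y[a:b].sum())
            seen += b - a
            recall = tp / n_pos
            precision = tp / seen
            area += (recall - prev_recall) * (precision + prev_precision) / 2.0
            prev_recall, prev_precision = recall, precision
        return float(area)
    raise ValueError(f"unknown AUPR method {method!r}")


def _topological_pair(
    train: BipartiteNetwork, feature: str, gip: GipParams | None
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    return (
        topological_similarity(train, "drug", feature, gip),
        topological_similarity(train, "adr", feature, gip),
    )


def build_side_similarities(
    train: BipartiteNetwork,
    feature: str | None,
    Sd_intr: SimilarityMatrix | None,
    Sa_intr: SimilarityMatrix | None,
    weights: BlendWeights,
    gip: GipParams | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Per-side similarities for one training round.

    Topological features are computed from the (masked) training matrix
    and blended with the intrinsic similarities by the per-side lambda
    weights.  With no topological feature the intrinsic matrices are used
    directly; with no intrinsic matrix, the topological ones.
    """
    if feature is None and (Sd_intr is None or Sa_intr is None):
        raise ValueError("need a topological feature or intrinsic similarities")
    if feature is None:
        return Sd_intr, Sa_intr
    Sd_top, Sa_top = _topological_pair(train, feature, gip)
    Sd = Sd_top
    Sa = Sa_top
    if Sd_intr is not None:
        Sd = blend_similarities([Sd_top, Sd_intr], [weights.lambda_d, 1 - weights.lambda_d])
    if Sa_intr is not None:
        Sa = blend_similarities([Sa_top, Sa_intr], [weights.lambda_a, 1 - weights.lambda_a])
    return Sd, Sa


def _score_round(
    train: BipartiteNetwork,
    feature: str | None,
    Sd_intr: SimilarityMatrix | None,
    Sa_intr: SimilarityMatrix | None,
    config: pred.PredictorConfig,
    weights: BlendWeights,
    gip: GipParams | None,
) -> ScoreMatrix:
    Sd, Sa = build_side_similarities(train, feature, Sd_intr, Sa_intr, weights, gip)
    return pred.predict(Sd, Sa, train, config)


def _logistic_round(
    train: BipartiteNetwork,
    feature: str | None,
    Sd_intr: SimilarityMatrix | None,
    Sa_intr: SimilarityMatrix | None,
    test_pairs: np.ndarray,
    gip: GipParams | None,
) -> np.ndarray:
    """Cami-style logistic baseline: per-pair weighted-profile covariates
    from every topological feature plus intrinsic similarities and degrees,
    fit on non-held-out pairs, scored on the held-out pairs."""
    from .topology import FEATURE_NAMES

    drug_sims = [topological_similarity(train, "drug", f, gip) for f in FEATURE_NAMES]
    adr_sims = [topological_similarity(train, "adr", f, gip) for f in FEATURE_NAMES]
    if Sd_intr is not None:
        drug_sims.append(Sd_intr)
    if Sa_intr is not None:
        adr_sims.append(Sa_intr)
    X = pred.pair_covariates(train, drug_sims, adr_sims)
    y = train.Y.ravel()
    train_mask = np.ones(len(y), dtype=bool)
    train_mask[test_pairs] = False
    return pred.logistic_scores(X[train_mask], y[train_mask], X[test_pairs])


def cross_validate(
    net: BipartiteNetwork,
    Sd_intr: SimilarityMatrix | None = None,
    Sa_intr: SimilarityMatrix | None = None,
    feature: str | None = "jaccard",
    config: pred.PredictorConfig | None = None,
    weights: BlendWeights | None = None,
    k: int = 10,
    seed: int = 0,
    repeats: int = 5,
    gip: GipParams | None = None,
) -> EvaluationResult:
    """Repeated k-fold edge-masking cross validation.

    Per fold: mask the held-out edges, recompute topological similarity
    from the masked matrix, blend with intrinsic similarity, train the
    predictor and score the held-out pairs.  Per repeat, all folds' test
    scores are pooled into one AUC and one AUPR; the summary is the mean
    and sd across repeats (fold seeds ``seed .. seed+repeats-1``).
    """
    config = config or pred.PredictorConfig()
    weights = weights or BlendWeights()
    rep_auc: list[float] = []
    rep_aupr: list[float] = []
    fold_auc: list[float] = []
    fold_aupr: list[float] = []
    for r in range(repeats):
        folds = make_folds(net, k=k, seed=seed + r)
        all_scores: list[np.ndarray] = []
        all_labels: list[np.ndarray] = []
        for i in range(k):
            train, test_pairs, labels = mask_fold(net, folds, i)
            if config.algorithm == "logistic":
                scores = _logistic_round(
                    train, feature, Sd_intr, Sa_intr, test_pairs, gip
                )
            else:
                F = _score_round(train, feature, Sd_intr, Sa_intr, config, weights, gip)
                scores = F.F.ravel()[test_pairs]
            all_scores.append(scores)
            all_labels.append(labels)
            fold_auc.append(auc(scores, labels))
            fold_aupr.append(aupr(scores, labels))
        pooled_scores = np.concatenate(all_scores)
        pooled_labels = np.concatenate(all_labels)
        rep_auc.append(auc(pooled_scores, pooled_labels))
        rep_aupr.append(aupr(pooled_scores, pooled_labels))
    return EvaluationResult(
        auc=float(np.mean(rep_auc)),
        aupr=float(np.mean(rep_aupr)),
        auc_sd=float(np.std(rep_auc)),
        aupr_sd=float(np.std(rep_aupr)),
        per_repeat_auc=rep_auc,
        per_repeat_aupr=rep_aupr,
        per_fold_auc=fold_auc,
        per_fold_aupr=fold_aupr,
    )


def prospective_evaluate(
    train_net: BipartiteNetwork,
    test_net: BipartiteNetwork,
    Sd_intr: SimilarityMatrix | None = None,
    Sa_intr: SimilarityMatrix | None = None,
    feature: str | None = "jaccard",
    config: pred.PredictorConfig | None = None,
    weights: BlendWeights | None = None,
    gip: GipParams | None = None,
    degree_threshold: int | None = None,
) -> EvaluationResult:
    """Train on an earlier snapshot; label its non-edges by a later one.

    Both networks must share node sets (and orderings are aligned to the
    training network).  The evaluation pairs are every pair absent from
    the training network; a pair is positive when present in the testing
    network.
    """
    if set(train_net.drug_ids) != set(test_net.drug_ids) or set(
        train_net.adr_ids
    ) != set(test_net.adr_ids):
        raise ValueError("training and testing networks must share node sets")
    # align the testing network to the training order
    di = [test_net.drug_ids.index(d) for d in train_net.drug_ids]
    ai = [test_net.adr_ids.index(a) for a in train_net.adr_ids]
    Y_test = test_net.Y[np.ix_(di, ai)]
    eval_pairs = np.flatnonzero(train_net.Y.ravel() == 0)
    labels = Y_test.ravel()[eval_pairs]
    if labels.sum() == 0:
        raise ValueError("no new associations in the testing network to evaluate")
    config = config or pred.PredictorConfig()
    weights = weights or BlendWeights()
    if config.algorithm == "logistic":
        scores = _logistic_round(train_net, feature, Sd_intr, Sa_intr, eval_pairs, gip)
        F = None
    else:
        F = _score_round(train_net, feature, Sd_intr, Sa_intr, config, weights, gip)
        scores = F.F.ravel()[eval_pairs]
    result = EvaluationResult(auc=auc(scores, labels), aupr=aupr(scores, labels))
    if degree_threshold is not None and F is not None:
        result.strata = stratify_by_degree(train_net, F, degree_threshold)
    return result


def grid_search_weights(
    net: BipartiteNetwork,
    Sd_intr: SimilarityMatrix | None,
    Sa_intr: SimilarityMatrix | None,
    feature: str,
    config: pred.PredictorConfig | None = None,
    grid_step: float = 0.1,
    k: int = 10,
    seed: int = 0,
    criterion: str = "auc",
    search_omega: bool = False,
    gip: GipParams | None = None,
) -> tuple[BlendWeights, float]:
    """Exhaustive grid search over the blend weights maximizing CV AUC.

    The grid is {0, grid_step, ..., 1} per coordinate; ties break toward
    larger lambda_d, then larger lambda_a (then larger omega).  Returns the
    winning weights and their criterion value.  ``criterion`` may be
    ``"aupr"``.  A single CV repeat per grid point keeps the search cheap;
    the fold seed is shared across grid points so candidates face the same
    splits.
    """
    n_steps = round(1.0 / grid_step)
    if abs(n_steps * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1")
    grid = np.linspace(0.0, 1.0, n_steps + 1)
    omegas = grid if search_omega else [0.5]
    best: tuple[float, float, float, float] | None = None
    best_w: BlendWeights | None = None
    for om in omegas:
        for ld in grid:
            for la in grid:
                w = BlendWeights(lambda_d=float(ld), lambda_a=float(la), omega=float(om))
                res = cross_validate(
                    net, Sd_intr, Sa_intr, feature, config, w,
                    k=k, seed=seed, repeats=1, gip=gip,
                )
                val = res.auc if criterion == "auc" else res.aupr
                key = (val, float(ld), float(la), float(om))
                if best is None or key > best:
                    best = key
                    best_w = w
    return best_w, best[0]


def stratify_by_degree(
    train_net: BipartiteNetwork, F: ScoreMatrix, threshold: int = 40
) -> dict:
    """Split non-edge pair scores into four degree strata.

    A node is high-degree when its training degree exceeds ``threshold``.
    Pairs that are edges in the training network are excluded.  Returns a
    mapping stratum -> {"scores", "n", "mean", "quantiles"} for
    low-low, high-low (drug high), low-high and high-high pairs.
    """
    dd = train_net.drug_degrees()
    da = train_net.adr_degrees()
    high_d = dd > threshold
    high_a = da > threshold
    nonedge = train_net.Y == 0
    out: dict[str, dict] = {}
    masks = {
        "low-low": np.outer(~high_d, ~high_a),
        "high-low": np.outer(high_d, ~high_a),
        "low-high": np.outer(~high_d, high_a),
        "high-high": np.outer(high_d, high_a),
    }
    for name, mask in masks.items():
        scores = F.F[mask & nonedge]
        out[name] = {
            "scores": scores,
            "n": int(scores.size),
            "mean": float(scores.mean()) if scores.size else float("nan"),
            "quantiles": (
                np.quantile(scores, [0.25, 0.5, 0.75]).tolist() if scores.size else []
            ),
        }
    return out
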