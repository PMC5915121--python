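"""Leave-one-out cross-validation (LOOCV) of the prioritizer, with ROC/AUC.

Each seed is removed in turn, the remaining seeds drive the walk, and the
held-out seed's recovery rank among the non-seed nodes (plus itself) is
recorded.  Treating each held-out seed as the sole positive in its fold, the
ranks define a ROC curve and its area (AUC): 1 means every seed outranks all
non-seeds, 0.5 means no signal.

A degree-matched random seed set of equal size serves as a null baseline:
if propagation merely chased hubs, random seeds with the same degree profile
would validate just as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph_io import IntegratedNetwork
from .rwr import (
    DEFAULT_DENSE_NODE_CAP,
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    SeedSet,
    build_transition,
    rwr_iterative,
)

logger = logging.getLogger(__name__)

__all__ = ["LoocvResult", "loocv", "roc_from_ranks", "degree_matched_null"]


@dataclass
class LoocvResult:
    """Per-held-out-seed recovery ranks plus the pooled ROC curve and AUC."""

    per_seed: list[tuple[str, int, float]]  # (held_out_id, rank, score)
    n_negatives: int
    roc: list[tuple[float, float]] = field(repr=False)
    auc: float = 0.0

    def ranks(self) -> list[int]:
        return [rank for _, rank, _ in self.per_seed]

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "n_negatives": self.n_negatives,
            "per_seed": [
                {"held_out_id": nid, "rank": rank, "score": score}
                for nid, rank, score in self.per_seed
            ],
            "roc": [[fpr, tpr] for fpr, tpr in self.roc],
        }


def roc_from_ranks(held_out_ranks: list[int],
                   n_negatives: int) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and AUC from held-out recovery ranks.

    Each fold has one positive at ``rank`` among itself plus ``n_negatives``
    negatives, so its per-fold ROC is a step jumping from 0 to 1 at
    FPR = (rank-1)/n_negatives.  Folds are combined by vertical averaging on
    the common FPR grid k/n_negatives (equivalent to the pooled rank-based
    curve since every fold contributes exactly one positive).  The curve is
    emitted with duplicated x at jumps so its trapezoidal area equals the
    rank-formula AUC

        AUC = mean over folds of (n_negatives - (rank - 1)) / n_negatives

    exactly — which is also the Mann–Whitney pairwise-comparison count.
    """
    if n_negatives < 1:
        raise ValueError("n_negatives must be at least 1")
    if not held_out_ranks:
        raise ValueError("need at least one held-out rank")
    ranks = np.asarray(held_out_ranks, dtype=int)
    if (ranks < 1).any() or (ranks > n_negatives + 1).any():
        raise ValueError(
            f"ranks must lie in [1, {n_negatives + 1}], got {ranks.tolist()}"
        )
    n_pos = len(ranks)
    # TPR at FPR = k/n_negatives: fraction of folds whose positive has at
    # most k negatives above it.
    fp_above = ranks - 1
    tpr_grid = np.array(
        [(fp_above <= k).sum() / n_pos for k in range(n_negatives + 1)]
    )
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    if tpr_grid[0] > 0.0:
        points.append((0.0, float(tpr_grid[0])))
    for k in range(1, n_negatives + 1):
        x = k / n_negatives
        if tpr_grid[k] != tpr_grid[k - 1]:
            points.append((x, float(tpr_grid[k - 1])))
        points.append((x, float(tpr_grid[k])))
    auc = float(np.mean((n_negatives - fp_above) / n_negatives))
    return points, auc


def trapezoid_area(roc: list[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC point list (for cross-checking)."""
    xs = np.array([p[0] for p in roc])
    ys = np.array([p[1] for p in roc])
    return float(np.trapezoid(ys, xs))


def _rank_among_nonseeds(scores: np.ndarray, node_index: list[str],
                         held_out_pos: int, seed_positions: set[int]) -> int:
    """Rank of the held-out node among {itself} ∪ non-seed nodes, descending
    score with ascending-id tie break (other seeds are excluded from the
    pool so they cannot crowd the top)."""
    s_held = scores[held_out_pos]
    id_held = node_index[held_out_pos]
    rank = 1
    for j, s in enumerate(scores):
        if j == held_out_pos or j in seed_positions:
            continue
        if s > s_held or (s == s_held and node_index[j] < id_held):
            rank += 1
    return rank


def loocv(network: IntegratedNetwork, seeds: SeedSet,
          r: float = DEFAULT_RESTART,
          normalization: str = "column-stochastic",
          tol: float = DEFAULT_TOL,
          max_iter: int = DEFAULT_MAX_ITER,
          dense_node_cap: int = DEFAULT_DENSE_NODE_CAP) -> LoocvResult:
    """Leave-one-out cross-validation of seed recovery.

    For each seed ``s`` the restart vector is rebuilt uniformly over the
    remaining seeds, RWR scores are computed, and ``s`` is ranked among the
    non-seed nodes plus itself.  ``n_negatives = N - |seeds|``.

    For networks up to ``dense_node_cap`` nodes the per-fold scores come
    from single-seed direct solves sharing one sparse LU factorization,
    combined by linearity of the fixed point in the restart vector (exactly
    equivalent to re-solving each fold); larger networks fall back to one
    power iteration per fold.
    """
    if len(seeds) < 2:
        raise ValueError("LOOCV needs at least 2 seeds (holding out from a "
                         "singleton leaves an empty restart vector)")
    model = build_transition(network, normalization=normalization, r=r)
    node_index = network.node_index
    members = sorted(seeds.members)
    seed_positions = {network.position(m) for m in members}
    n = network.n_nodes
    n_negatives = n - len(members)
    if n_negatives < 1:
        raise ValueError("no non-seed nodes to rank against")

    if n <= dense_node_cap:
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        lu = spla.splu(
            (sp.identity(n, format="csc") - (1.0 - r) * model.W).tocsc()
        )
        basis = np.zeros((n, len(members)))
        for j, m in enumerate(members):
            basis[network.position(m), j] = 1.0
        cols = r * lu.solve(basis)  # column j: single-seed scores for member j
        total = cols.sum(axis=1)
        fold_scores = {
            m: (total - cols[:, j]) / (len(members) - 1)
            for j, m in enumerate(members)
        }
    else:
        fold_scores = {}
        for m in members:
            rest = [x for x in members if x != m]
            p0 = SeedSet.from_members(rest, network)
            fold_scores[m] = rwr_iterative(model, p0, tol=tol,
                                           max_iter=max_iter).scores

    per_seed: list[tuple[str, int, float]] = []
    for m in members:
        scores = fold_scores[m]
        pos = network.position(m)
        rank = _rank_among_nonseeds(scores, node_index, pos, seed_positions)
        per_seed.append((m, rank, float(scores[pos])))

    roc, auc = roc_from_ranks([rank for _, rank, _ in per_seed], n_negatives)
    return LoocvResult(per_seed=per_seed, n_negatives=n_negatives,
                       roc=roc, auc=auc)


def degree_matched_null(network: IntegratedNetwork, seeds: SeedSet,
                        n_bins: int = 10, rng_seed: int = 0) -> SeedSet:
    """Random non-seed set of equal size matching the seeds' degree profile.

    Node degrees are cut into ``n_bins`` quantile bins; for each bin the
    null draws (without replacement) as many non-seed nodes as the seed set
    has in that bin.  A bin short of candidates borrows from the nearest
    bins with a warning.  ``n_bins=1`` degenerates to a uniform random
    sample.  Deterministic given ``rng_seed``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    rng = np.random.default_rng(rng_seed)
    deg = network.degree
    members = seeds.members
    # inner quantile edges; searchsorted assigns bin indices 0..n_bins-1
    edges = np.quantile(deg, np.linspace(0, 1, n_bins + 1)[1:-1])
    bin_of = np.searchsorted(edges, deg, side="right")

    nonseed_by_bin: dict[int, list[str]] = {b: [] for b in range(n_bins)}
    seed_count_by_bin: dict[int, int] = {b: 0 for b in range(n_bins)}
    for i, nid in enumerate(network.node_index):
        if nid in members:
            seed_count_by_bin[bin_of[i]] += 1
        else:
            nonseed_by_bin[bin_of[i]].append(nid)

    chosen: list[str] = []
    for b in range(n_bins):
        need = seed_count_by_bin[b]
        if need == 0:
            continue
        pool = list(nonseed_by_bin[b])
        take = min(need, len(pool))
        if take:
            picked = rng.choice(len(pool), size=take, replace=False)
            picked_ids = [pool[i] for i in sorted(picked)]
            chosen.extend(picked_ids)
            taken = set(picked_ids)
            nonseed_by_bin[b] = [x for x in pool if x not in taken]
        short = need - take
        if short:
            logger.warning(
                "degree-matched null: bin %d short %d candidate(s); "
                "borrowing from nearest bins", b, short,
            )
            for dist in range(1, n_bins):
                for nb in (b - dist, b + dist):
                    if short == 0 or not (0 <= nb < n_bins):
                        continue
                    pool = nonseed_by_bin[nb]
                    take2 = min(short, len(pool))
                    if take2:
                        picked = rng.choice(len(pool), size=take2, replace=False)
                        picked_ids = [pool[i] for i in sorted(picked)]
                        chosen.extend(picked_ids)
                        taken = set(picked_ids)
                        nonseed_by_bin[nb] = [x for x in pool if x not in taken]
                        short -= take2
                if short == 0:
                    break
            if short:
                raise ValueError("not enough non-seed nodes to build a "
                                 "degree-matched null of equal size")
    return SeedSet.from_members(chosen, network)
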