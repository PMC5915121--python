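"""Turn RWR scores into a ranked candidate list with top-K selection.

Candidates are ordered by descending steady-state score; known seeds are
either dropped (the default — candidate discovery wants novel proteins) or
kept with a boolean flag for diagnostics.  Ties break by ascending node id,
so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .rwr import ScoreVector, SeedSet

logger = logging.getLogger(__name__)

__all__ = ["RankRecord", "RankedList", "rank_candidates", "top_k",
           "DEFAULT_TOP_K", "SEED_POLICIES"]

SEED_POLICIES = ("excluded", "flagged")

#: Default size of the short list carried forward for detailed study.
DEFAULT_TOP_K = 300


@dataclass(frozen=True)
class RankRecord:
    rank: int
    node_id: str
    score: float
    is_seed: bool = False


@dataclass
class RankedList:
    """Ordered candidate records with contiguous ranks 1..len."""

    records: list[RankRecord]
    seed_policy: str = "excluded"

    def __post_init__(self) -> None:
        if self.seed_policy not in SEED_POLICIES:
            raise ValueError(f"unknown seed_policy {self.seed_policy!r}")
        for i, rec in enumerate(self.records, start=1):
            if rec.rank != i:
                raise ValueError(f"ranks not contiguous: expected {i}, got {rec.rank}")
        for prev, cur in zip(self.records, self.records[1:]):
            if cur.score > prev.score + 1e-15:
                raise ValueError("scores must be non-increasing with rank")
            if cur.score == prev.score and cur.node_id < prev.node_id:
                raise ValueError("equal scores must be ordered by ascending node id")

    def __len__(self) -> int:
        return len(self.records)

    def node_ids(self) -> list[str]:
        return [rec.node_id for rec in self.records]


def rank_candidates(scores: ScoreVector, seeds: SeedSet | None = None,
                    seed_policy: str = "excluded") -> RankedList:
    """Rank nodes by descending score (ties by ascending node id).

    With ``seed_policy="excluded"`` (default) seed nodes are removed before
    ranking; with ``"flagged"`` they stay in place carrying ``is_seed=True``.
    A pure function of its inputs: repeated calls give identical output.
    """
    if seed_policy not in SEED_POLICIES:
        raise ValueError(f"unknown seed_policy {seed_policy!r}")
    members = seeds.members if seeds is not None else frozenset()
    pairs = [
        (nid, float(s)) for nid, s in zip(scores.node_index, scores.scores)
        if not (seed_policy == "excluded" and nid in members)
    ]
    pairs.sort(key=lambda item: (-item[1], item[0]))
    records = [
        RankRecord(rank=i, node_id=nid, score=s, is_seed=nid in members)
        for i, (nid, s) in enumerate(pairs, start=1)
    ]
    return RankedList(records=records, seed_policy=seed_policy)


def top_k(ranked: RankedList, k: int = DEFAULT_TOP_K) -> RankedList:
    """First min(k, len) records, ranks preserved."""
    if k < 1:
        raise ValueError(f"k must be at least 1, got {k}")
    if k > len(ranked.records):
        logger.warning("top_k: k=%d exceeds list length %d; returning all",
                       k, len(ranked.records))
    return RankedList(records=ranked.records[:k], seed_policy=ranked.seed_policy)
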