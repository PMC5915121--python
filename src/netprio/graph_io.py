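"""Reading, cleaning and integration of weighted interaction networks.

A protein–protein interaction (PPI) model is rarely a single dataset: evidence
comes from physical-interaction databases, domain co-occurrence, co-expression
and homology transfer, each delivered as a weighted edge list.  This module
reads one :class:`EvidenceNetwork` per source, cleans it (no self-loops, one
edge per unordered pair, weights in (0, 1]) and merges the sources into a
single :class:`IntegratedNetwork` — a node-indexed, symmetric, sparse weighted
graph on which propagation runs.

It also reads seed lists (identifiers of known members of the functional
system of interest, e.g. known angiogenesis proteins) and writes ranked
candidate lists as TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import scipy.sparse as sp

if TYPE_CHECKING:  # pragma: no cover
    from .prioritize import RankedList
    from .rwr import SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceNetwork",
    "IntegratedNetwork",
    "read_edge_list",
    "write_edge_list",
    "integrate",
    "read_seed_list",
    "write_ranked_list",
    "read_ranked_list",
]


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EvidenceNetwork:
    """One evidence source's cleaned weighted undirected edge set.

    Parameters
    ----------
    source_name:
        Short label for the source (e.g. ``"coexpression"``).
    edges:
        Mapping from canonical (sorted) unordered node pair to a weight in
        (0, 1].  Construction validates the invariants.
    id_namespace:
        Free-text tag naming the identifier scheme (gene symbol, Ensembl...).
    """

    source_name: str
    edges: Mapping[tuple[str, str], float]
    id_namespace: str = "unspecified"

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r} in source {self.source_name!r}")
            if (a, b) != _canonical_pair(a, b):
                raise ValueError(f"edge key {(a, b)!r} is not in canonical order")
            if not (0.0 < w <= 1.0):
                raise ValueError(
                    f"weight {w!r} for edge {(a, b)!r} outside (0, 1] "
                    f"in source {self.source_name!r}"
                )

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class IntegratedNetwork:
    """The unified node-indexed weighted graph ("one single PPI network").

    ``node_index`` is sorted and duplicate-free; position ``i`` in every
    vector/matrix refers to ``node_index[i]``.  ``adjacency`` is a symmetric
    scipy CSR matrix with zero diagonal, so storage scales with edge count.
    """

    node_index: list[str]
    adjacency: sp.csr_matrix
    _pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.node_index)
        if sorted(set(self.node_index)) != list(self.node_index):
            raise ValueError("node_index must be sorted and duplicate-free")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node_index length")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal (self-loops)")
        asym = abs(self.adjacency - self.adjacency.T)
        if asym.nnz and asym.max() > 1e-12:
            raise ValueError("adjacency is not symmetric")
        self._pos = {nid: i for i, nid in enumerate(self.node_index)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def degree(self) -> np.ndarray:
        """Per-node sum of incident edge weights (weighted degree)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def position(self, node_id: str) -> int:
        return self._pos[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._pos

    def edge_set(self) -> dict[tuple[str, str], float]:
        """Edges as a canonical-pair → weight mapping (for comparisons/IO)."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return {
            _canonical_pair(self.node_index[i], self.node_index[j]): float(w)
            for i, j, w in zip(coo.row, coo.col, coo.data)
        }


def read_edge_list(stream: Iterable[str], source_name: str = "edges",
                   id_namespace: str = "unspecified") -> EvidenceNetwork:
    """Parse a whitespace-separated edge list into a cleaned EvidenceNetwork.

    Each non-comment line is ``idA idB [weight]``; a missing weight defaults
    to 1.0 (curated database associations are treated as full confidence).
    Self-loops are dropped, duplicate unordered pairs merged keeping the
    maximum weight; dropped line numbers are logged.

    Raises
    ------
    EdgeListError
        On a malformed line (wrong field count, non-numeric weight, weight
        outside (0, 1]) — naming its line number — or when no edge survives.
    """
    edges: dict[tuple[str, str], float] = {}
    dropped_loops: list[int] = []
    n_merged = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) not in (2, 3):
            raise EdgeListError(
                f"{source_name}: line {lineno}: expected 2 or 3 fields, got {len(fields)}"
            )
        a, b = fields[0], fields[1]
        if len(fields) == 3:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise EdgeListError(
                    f"{source_name}: line {lineno}: non-numeric weight {fields[2]!r}"
                ) from exc
            if not (0.0 < w <= 1.0) or math.isnan(w):
                raise EdgeListError(
                    f"{source_name}: line {lineno}: weight {w} outside (0, 1]"
                )
        else:
            w = 1.0
        if a == b:
            dropped_loops.append(lineno)
            continue
        key = _canonical_pair(a, b)
        if key in edges:
            n_merged += 1
            edges[key] = max(edges[key], w)
        else:
            edges[key] = w
    if dropped_loops:
        logger.warning(
            "%s: dropped %d self-loop line(s): %s",
            source_name, len(dropped_loops), dropped_loops,
        )
    if n_merged:
        logger.info("%s: merged %d duplicate edge record(s) keeping max weight",
                    source_name, n_merged)
    if not edges:
        raise EdgeListError(f"{source_name}: no edges found in input")
    return EvidenceNetwork(source_name=source_name, edges=edges,
                           id_namespace=id_namespace)


def write_edge_list(network: EvidenceNetwork | IntegratedNetwork,
                    stream: IO[str]) -> None:
    """Write edges as TSV ``idA idB weight`` (canonical pair order, sorted)."""
    if isinstance(network, IntegratedNetwork):
        edges = network.edge_set()
    else:
        edges = dict(network.edges)
    stream.write("# idA\tidB\tweight\n")
    for (a, b), w in sorted(edges.items()):
        stream.write(f"{a}\t{b}\t{w:.12g}\n")


COMBINE_RULES = ("max", "sum-capped-at-1", "weighted-mean")


def integrate(networks: Sequence[EvidenceNetwork],
              combine_rule: str = "max",
              coefficients: Sequence[float] | None = None) -> IntegratedNetwork:
    """Merge evidence sources into one IntegratedNetwork.

    Parameters
    ----------
    networks:
        One or more cleaned evidence networks.
    combine_rule:
        ``"max"`` (default) links a pair at its strongest evidence across
        sources; ``"sum-capped-at-1"`` sums weights and caps at 1;
        ``"weighted-mean"`` takes a convex combination with per-source
        ``coefficients`` (absent edges contribute 0).
    coefficients:
        Required for ``weighted-mean``: one nonnegative coefficient per
        source, summing to 1.
    """
    if not networks:
        raise ValueError("integrate requires at least one EvidenceNetwork")
    if combine_rule not in COMBINE_RULES:
        raise ValueError(f"unknown combine_rule {combine_rule!r}; "
                         f"choose from {COMBINE_RULES}")
    if combine_rule == "weighted-mean":
        if coefficients is None or len(coefficients) != len(networks):
            raise ValueError("weighted-mean needs one coefficient per source")
        if any(c < 0 for c in coefficients):
            raise ValueError("weighted-mean coefficients must be nonnegative")
        if abs(sum(coefficients) - 1.0) > 1e-9:
            raise ValueError("weighted-mean coefficients must sum to 1")
    elif coefficients is not None:
        raise ValueError(f"coefficients only apply to weighted-mean, not {combine_rule!r}")

    combined: dict[tuple[str, str], float] = {}
    if combine_rule == "max":
        for net in networks:
            for key, w in net.edges.items():
                combined[key] = max(combined.get(key, 0.0), w)
    elif combine_rule == "sum-capped-at-1":
        for net in networks:
            for key, w in net.edges.items():
                combined[key] = min(1.0, combined.get(key, 0.0) + w)
    else:  # weighted-mean; order-invariant because addition order is summed per key
        for coef, net in zip(coefficients, networks):  # type: ignore[arg-type]
            for key, w in net.edges.items():
                combined[key] = combined.get(key, 0.0) + coef * w

    node_index = sorted(set().union(*(net.nodes for net in networks)))
    pos = {nid: i for i, nid in enumerate(node_index)}
    n = len(node_index)
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for (a, b), w in combined.items():
        i, j = pos[a], pos[b]
        rows.extend((i, j))
        cols.extend((j, i))
        data.extend((w, w))
    adjacency = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return IntegratedNetwork(node_index=node_index, adjacency=adjacency)


def read_seed_list(stream: Iterable[str], network: IntegratedNetwork) -> "SeedSet":
    """Read one identifier per line and restrict to nodes in the network.

    Blank lines and ``#`` comments are ignored; duplicates collapsed.
    Identifiers absent from ``network.node_index`` are reported with a warning
    (they can receive no propagation mass).  Raises ``ValueError`` if no seed
    maps into the network.
    """
    from .rwr import SeedSet

    seen: set[str] = set()
    mapped: list[str] = []
    missing: list[str] = []
    for raw in stream:
        token = raw.strip()
        if not token or token.startswith("#"):
            continue
        if token in seen:
            continue
        seen.add(token)
        if token in network:
            mapped.append(token)
        else:
            missing.append(token)
    if missing:
        logger.warning("%d seed id(s) absent from the network and dropped: %s",
                       len(missing), missing)
    if not mapped:
        raise ValueError("no seed identifier maps to a network node")
    return SeedSet.from_members(mapped, network)


def write_ranked_list(ranked: "RankedList", stream: IO[str]) -> None:
    """Write a ranked candidate list as TSV: header then rank, node_id, score.

    Scores are printed with 12 significant digits so a round-trip preserves
    them to better than 1e-9 relative.
    """
    if not ranked.records:
        raise ValueError("refusing to write an empty ranked list")
    stream.write("rank\tnode_id\tscore\n")
    for rec in ranked.records:
        stream.write(f"{rec.rank}\t{rec.node_id}\t{rec.score:.12g}\n")


def read_ranked_list(stream: Iterable[str]) -> "RankedList":
    """Inverse of :func:`write_ranked_list` (header required)."""
    from .prioritize import RankedList, RankRecord

    it = iter(stream)
    try:
        header = next(it).strip()
    except StopIteration:
        raise EdgeListError("empty ranked-list input") from None
    if header.split("\t") != ["rank", "node_id", "score"]:
        raise EdgeListError(f"unexpected ranked-list header {header!r}")
    records = []
    for lineno, raw in enumerate(it, start=2):
        line = raw.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise EdgeListError(f"line {lineno}: expected 3 tab-separated fields")
        records.append(RankRecord(rank=int(fields[0]), node_id=fields[1],
                                  score=float(fields[2])))
    return RankedList(records=records, seed_policy="excluded")
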