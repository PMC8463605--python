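"""Centrality measures and the eigenvector-centrality (EC) resection surrogate.

Running the stochastic propagation model inside a combinatorial optimizer is
computationally prohibitive, so the effect of a virtual resection is scored
by a spectral surrogate instead: the drop in mean eigenvector centrality of
the hypothesized epileptogenic-zone (EZ) nodes after the edges are removed.
EC measures participation in the dominant eigenmode of the adjacency matrix
and tracks how fast early spreading from a node proceeds, which is what
makes it a usable stand-in for the simulated propagation.

Conventions
-----------
* EC is the leading eigenvector of the (binary or weighted) adjacency
  matrix, Euclidean-normalized and oriented non-negative.  On disconnected
  graphs it is the *global* leading eigenvector: components that do not
  attain the top eigenvalue get centrality 0.
* Betweenness (node and edge) is the unnormalized unordered-pair count with
  fractional credit split equally among co-optimal shortest paths, computed
  on the binary graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .connectome import ConnectomeMatrix, SeedSet
from .errors import (
    DegenerateEffectError,
    DegenerateGraphError,
    MatrixDomainError,
    ParameterError,
)

__all__ = [
    "CentralityBundle",
    "ResectionEffect",
    "eigenvector_centrality",
    "centrality_suite",
    "write_centrality_tables",
    "seed_ec",
    "ec_difference",
    "epidemic_threshold",
    "full_disconnection_edges",
    "remove_edges",
]

Edge = tuple[int, int]

_DEGENERACY_GAP = 1e-10


@dataclass(frozen=True)
class CentralityBundle:
    """Per-node EC, degree and betweenness, plus per-edge betweenness."""

    ec: np.ndarray
    degree: np.ndarray
    node_bc: np.ndarray
    edge_bc: dict[Edge, float]


@dataclass(frozen=True)
class ResectionEffect:
    """EC drop of the seed caused by removing a set of edges.

    ``ec_diff_normalized`` is the fraction of the full-resection effect:
    1.0 when every seed-to-rest edge is removed, 0.0 for an empty removal.
    """

    ec_before: float
    ec_after: float
    ec_diff: float
    ec_diff_normalized: float


def _as_values(adjacency: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(adjacency, ConnectomeMatrix):
        return adjacency.values
    return np.asarray(adjacency, dtype=float)


def eigenvector_centrality(adjacency: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Leading adjacency eigenvector, unit Euclidean norm, non-negative.

    Computed by dense symmetric eigendecomposition (exact for the network
    sizes used here).  The sign is fixed by making the entry sum positive;
    negative round-off entries are clipped to zero and the vector is
    renormalized.  A near-degenerate top eigenvalue (gap < 1e-10), which
    can occur after disconnecting resections, triggers a warning and is
    resolved deterministically by the eigensolver's ordering.
    """
    a = _as_values(adjacency)
    if not np.any(a):
        raise DegenerateGraphError("eigenvector centrality of an all-zero matrix")
    eigvals, eigvecs = np.linalg.eigh(a)
    if a.shape[0] > 1 and eigvals[-1] - eigvals[-2] < _DEGENERACY_GAP:
        warnings.warn(
            f"top eigenvalue is (near-)degenerate "
            f"(gap {eigvals[-1] - eigvals[-2]:.2e}); eigenvector centrality "
            "resolved by eigensolver ordering",
            stacklevel=2,
        )
    v = eigvecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return v / np.linalg.norm(v)


def epidemic_threshold(adjacency: ConnectomeMatrix | np.ndarray) -> float:
    """Critical spreading rate ``lambda_c = 1 / lambda_max(adjacency)``.

    Spreading rates beta/gamma above this spectral threshold produce large
    outbreaks; below it, activity started at the seed dies out quickly.
    """
    a = _as_values(adjacency)
    if not np.any(a):
        raise DegenerateGraphError("epidemic threshold of an all-zero matrix")
    return float(1.0 / np.linalg.eigvalsh(a)[-1])


def centrality_suite(adjacency: ConnectomeMatrix | np.ndarray) -> CentralityBundle:
    """EC, degree, and node/edge betweenness of a binary network."""
    a = _as_values(adjacency)
    if not np.isin(a, (0.0, 1.0)).all():
        raise MatrixDomainError("centrality_suite requires a binary matrix")
    g = nx.from_numpy_array(a)
    node_bc_d = nx.betweenness_centrality(g, normalized=False)
    edge_bc_d = nx.edge_betweenness_centrality(g, normalized=False)
    edge_bc = {(min(i, j), max(i, j)): v for (i, j), v in edge_bc_d.items()}
    return CentralityBundle(
        ec=eigenvector_centrality(a),
        degree=np.count_nonzero(a, axis=1),
        node_bc=np.array([node_bc_d[i] for i in range(a.shape[0])]),
        edge_bc=edge_bc,
    )


def write_centrality_tables(
    bundle: CentralityBundle,
    labels: Sequence[str],
    node_path: str | Path,
    edge_path: str | Path,
) -> None:
    """Export node (id, label, ec, degree, node_bc) and edge (i, j, edge_bc)
    measures as TSV."""
    with open(node_path, "w") as fh:
        fh.write("node_id\tlabel\tec\tdegree\tnode_bc\n")
        for i, label in enumerate(labels):
            fh.write(
                f"{i}\t{label}\t{bundle.ec[i]:.10g}\t{bundle.degree[i]}"
                f"\t{bundle.node_bc[i]:.10g}\n"
            )
    with open(edge_path, "w") as fh:
        fh.write("node_i\tnode_j\tedge_bc\n")
        for (i, j), v in sorted(bundle.edge_bc.items()):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")


def seed_ec(
    adjacency: ConnectomeMatrix | np.ndarray, seed: SeedSet
) -> float:
    """Mean eigenvector centrality over the seed nodes (EC of the whole network)."""
    a = _as_values(adjacency)
    if isinstance(adjacency, ConnectomeMatrix):
        seed.validate_for(adjacency)
    ec = eigenvector_centrality(a)
    return float(ec[list(seed.node_indices)].mean())


def full_disconnection_edges(
    adjacency: ConnectomeMatrix | np.ndarray, seed: SeedSet
) -> list[Edge]:
    """All present edges from a seed node to a non-seed node (i in seed, j not)."""
    a = _as_values(adjacency)
    in_seed = seed.mask(a.shape[0])
    out: list[Edge] = []
    for i in seed.node_indices:
        for j in np.flatnonzero(a[i]):
            if not in_seed[j]:
                out.append((i, int(j)))
    return sorted(out)


def remove_edges(
    adjacency: ConnectomeMatrix | np.ndarray, edges: Iterable[Edge]
) -> np.ndarray:
    """Copy of the adjacency with the given undirected edges zeroed."""
    a = _as_values(adjacency).copy()
    for i, j in edges:
        if a[i, j] == 0:
            raise ParameterError(f"edge ({i}, {j}) is not present in the graph")
        a[i, j] = 0.0
        a[j, i] = 0.0
    return a


def ec_difference(
    adjacency: ConnectomeMatrix | np.ndarray,
    seed: SeedSet,
    removed_edges: Sequence[Edge],
) -> ResectionEffect:
    """Score a virtual resection by the EC drop of the seed.

    EC is recomputed on the edge-deleted graph; the normalization
    denominator is the EC drop of a *full* disconnection of the seed (all
    seed-to-rest edges removed), which in the regular case equals the seed
    EC of the intact network because the fully disconnected seed has
    centrality 0.
    """
    a = _as_values(adjacency)
    if isinstance(adjacency, ConnectomeMatrix):
        seed.validate_for(adjacency)
    def _seed_ec_or_zero(values: np.ndarray) -> float:
        # a removal can empty the graph entirely (tiny test networks);
        # every node then has centrality 0 by convention
        if not values.any():
            return 0.0
        ec = eigenvector_centrality(values)
        return float(ec[list(seed.node_indices)].mean())

    ec_before = seed_ec(a, seed)
    ec_after = (
        ec_before if len(removed_edges) == 0
        else _seed_ec_or_zero(remove_edges(a, removed_edges))
    )
    diff = ec_before - ec_after
    full = full_disconnection_edges(a, seed)
    if sorted(set(removed_edges)) == full:
        full_diff = diff  # this *is* the full resection; anchor exactly at 1
    else:
        full_after = _seed_ec_or_zero(remove_edges(a, full)) if full else ec_before
        full_diff = ec_before - full_after
    if abs(full_diff) < 1e-9:
        raise DegenerateEffectError(
            "full-resection EC difference is numerically zero; "
            "normalized effect undefined"
        )
    return ResectionEffect(
        ec_before=ec_before,
        ec_after=ec_after,
        ec_diff=diff,
        ec_diff_normalized=diff / full_diff,
    )
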