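"""Undirected protein-protein interaction (PPI) network container and I/O.

The statistic implemented in :mod:`surrogene.core` asks, for a gene *g* and a
tumor sample, whether the immediate network neighborhood of *g* carries more
somatically altered genes than expected by chance.  Everything it needs from
the network is the node set, per-gene adjacency, and per-gene degree, which
this module provides on top of a simple :class:`networkx.Graph`.

Networks are read from HPRD-style flat files: two or more whitespace- or
tab-delimited columns of gene symbols, one interaction per line.  Symbols are
uppercased and trimmed at ingest; self-loops and duplicate edges are dropped
(the enrichment null assumes a simple graph).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PPINetwork", "load_network", "write_network"]


class NetworkFormatError(ValueError):
    """Raised when an edge-list file yields no valid edges."""


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class PPINetwork:
    """Simple undirected gene-symbol graph.

    Invariants: no self-loops, no duplicate edges, symmetric adjacency.
    Isolated nodes are permitted (they can never be surrogate candidates with
    x_obs > 0 but still count toward the network size N used by the null).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "PPINetwork":
        g = nx.Graph()
        n_self = 0
        n_dup = 0
        for a, b in edges:
            a, b = _normalize(a), _normalize(b)
            if not a or not b:
                continue
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
        g.add_nodes_from(_normalize(n) for n in extra_nodes if _normalize(n))
        if n_self or n_dup:
            logger.info(
                "dropped %d self-loop(s) and %d duplicate edge(s)", n_self, n_dup
            )
        return cls(g)

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def neighbors(self, gene: str) -> set[str]:
        """Immediate interaction partners of *gene* (never includes *gene*)."""
        if gene not in self.graph:
            raise KeyError(f"gene not in network: {gene!r}")
        return set(self.graph[gene])

    def degree(self, gene: str) -> int:
        if gene not in self.graph:
            raise KeyError(f"gene not in network: {gene!r}")
        return self.graph.degree[gene]

    def degree_table(self) -> pd.DataFrame:
        """One row per node: (gene, degree).  Degrees sum to 2|E|."""
        rows = sorted((g, d) for g, d in self.graph.degree())
        return pd.DataFrame(rows, columns=["gene", "degree"])

    def node_order(self) -> list[str]:
        """Deterministic (sorted) node ordering used for matrix layouts."""
        return sorted(self.graph.nodes)


def load_network(path: str | Path, node_list: str | Path | None = None) -> PPINetwork:
    """Read an edge list (>= 2 whitespace/tab-delimited symbol columns).

    Extra columns are ignored; lines starting with ``#`` are skipped.
    Optionally a one-column *node_list* file adds isolated nodes.

    Raises
    ------
    OSError
        If the file cannot be read.
    NetworkFormatError
        If no valid edge is found; the message names the first offending line.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    first_bad: tuple[int, str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                if first_bad is None:
                    first_bad = (lineno, line.strip())
                continue
            edges.append((parts[0], parts[1]))
    if not edges:
        detail = (
            f"first offending line {first_bad[0]}: {first_bad[1]!r}"
            if first_bad
            else "file contains no edge records"
        )
        raise NetworkFormatError(f"no valid edges in {path} ({detail})")

    extra: list[str] = []
    if node_list is not None:
        with open(node_list) as fh:
            extra = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]

    net = PPINetwork.from_edges(edges, extra_nodes=extra)
    logger.info(
        "loaded network from %s: %d nodes, %d edges (%d input records)",
        path,
        net.n_nodes,
        net.n_edges,
        len(edges),
    )
    return net


def write_network(
    net: PPINetwork, path: str | Path, node_list: str | Path | None = None
) -> None:
    """Write a two-column tab-delimited edge list (round-trips with load).

    Isolated nodes cannot be expressed in an edge list; pass *node_list* to
    write them to a companion one-column file.
    """
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")
    if node_list is not None:
        isolated = sorted(g for g, d in net.graph.degree() if d == 0)
        with open(node_list, "w") as fh:
            fh.writelines(f"{g}\n" for g in isolated)
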