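"""Surrogate-oncogene detection: neighborhood alteration enrichment per sample.

A *surrogate oncogene* is a gene whose immediate PPI neighbors carry
significantly more somatic alterations in a given sample than expected if
the same number of alterations were placed on the network at random.  For a
gene of degree ``k`` in a network of ``N`` genes, and a sample with ``M``
distinct altered genes of which ``x_obs`` are neighbors of the gene, the
null places ``M`` distinct alterations uniformly on the network and asks how
often the neighborhood captures ``x_obs`` or more of them:

    p = P(X >= x_obs),   X = |random M-subset of nodes  ∩  neighbors(g)|

Drawing M distinct genes from N and counting hits among the k neighbors is
exactly a hypergeometric experiment, so the permutation p-value has the
closed form ``hypergeom.sf(x_obs - 1, N, k, M)``.  Both routes are exposed:

* ``mode="exact"`` (default) — the hypergeometric tail, fast and exact;
* ``mode="perm"`` — genuine Monte-Carlo permutations (the procedure the
  statistic is defined by), with null counts cached per (k, M).

The focal gene itself is part of the permutation pool (the whole network is
"mutated"), but its own alteration never counts toward ``x_obs`` — only
neighbors are counted; self-alteration is reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genomic import AlterationProfile
from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SurrogateGeneSet",
    "SurrogateCall",
    "SurrogateMatrix",
    "NullCache",
    "expand_seed_set",
    "count_altered_neighbors",
    "exact_tail_pvalue",
    "permutation_pvalue",
    "call_surrogates",
    "neighbor_frequency",
]

#: state codes used when the matrix is serialized
STATE_CODES = {"none": 0, "surrogate_only": 1, "altered_only": 2, "both": 3}


# ---------------------------------------------------------------------------
# seed-set expansion


@dataclass
class SurrogateGeneSet:
    """Seed oncogenes plus network neighbors with enough seed connections."""

    seeds: set[str]
    expanded: set[str]
    min_connections: int = 2

    def __post_init__(self) -> None:
        if not self.seeds <= self.expanded:
            raise ValueError("seeds must be a subset of the expanded set")


def expand_seed_set(
    net: PPINetwork, seeds: Iterable[str], min_connections: int = 2
) -> SurrogateGeneSet:
    """Expand a seed oncogene list over the network.

    A non-seed gene joins the surrogate set iff it has at least
    *min_connections* neighbors inside the seed set.  Seeds absent from the
    network are logged and dropped.
    """
    requested = {s.strip().upper() for s in seeds if s.strip()}
    kept = requested & net.nodes
    dropped = requested - kept
    if dropped:
        logger.warning(
            "%d seed gene(s) not in network, dropped: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:10]),
        )
    if not kept:
        raise ValueError("no seed genes present in the network")
    expanded = set(kept)
    for gene in net.nodes - kept:
        if len(net.neighbors(gene) & kept) >= min_connections:
            expanded.add(gene)
    return SurrogateGeneSet(seeds=kept, expanded=expanded, min_connections=min_connections)


# ---------------------------------------------------------------------------
# the statistic


@dataclass
class SurrogateCall:
    """One (sample, gene) neighborhood-enrichment test result."""

    sample_id: str
    gene: str
    k: int
    M: int
    x_obs: int
    n_perm: int  # 0 in exact mode
    p_value: float
    significant: bool
    contributing_neighbors: list[tuple[str, tuple[str, ...]]]
    self_altered: bool


def count_altered_neighbors(
    net: PPINetwork, gene: str, profile: AlterationProfile
) -> tuple[int, list[tuple[str, tuple[str, ...]]], bool]:
    """Observed altered-neighbor count for one (gene, sample).

    Returns ``(x_obs, contributing, self_altered)`` where *contributing*
    lists each altered neighbor with its alteration types.  The gene's own
    alteration is excluded from the count.
    """
    nbrs = net.neighbors(gene)
    hit = sorted(nbrs & profile.altered)
    contributing = [(g, profile.alteration_types(g)) for g in hit]
    return len(hit), contributing, gene in profile.altered


def exact_tail_pvalue(N: int, k: int, M: int, x_obs: int) -> float:
    """Upper-tail probability of the null: P(X >= x_obs), X ~ Hypergeom(N, k, M).

    This is the closed form of the permutation null (M distinct alterations
    drawn uniformly from N network genes, hits counted among k neighbors).
    """
    if not (0 <= k <= N and 0 <= M <= N):
        raise ValueError(f"infeasible parameters: N={N}, k={k}, M={M}")
    if x_obs < 0:
        raise ValueError(f"x_obs must be >= 0, got {x_obs}")
    if x_obs == 0:
        return 1.0
    if x_obs > min(k, M):
        return 0.0
    return float(min(1.0, max(0.0, hypergeom.sf(x_obs - 1, N, k, M))))


class NullCache:
    """Monte-Carlo null distributions keyed by (k, M), one seeded stream.

    Node labels are exchangeable under the uniform null, so a single null
    per (degree, alteration count) pair serves every gene of that degree:
    we draw M distinct indices from range(N) and count how many land in the
    first k.  Caching also makes p monotone in x_obs by construction, since
    every x is evaluated against the same realized null counts.
    """

    def __init__(self, N: int, n_perm: int = 10_000, rng: np.random.Generator | None = None):
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        self.N = int(N)
        self.n_perm = int(n_perm)
        self.rng = rng if rng is not None else np.random.default_rng()
        self._counts: dict[tuple[int, int], np.ndarray] = {}

    def null_counts(self, k: int, M: int) -> np.ndarray:
        """Realized neighbor-hit counts of n_perm random placements."""
        if M > self.N:
            raise ValueError(f"M={M} exceeds network size N={self.N}")
        key = (int(k), int(M))
        if key not in self._counts:
            self._counts[key] = self._simulate(k, M)
        return self._counts[key]

    def _simulate(self, k: int, M: int) -> np.ndarray:
        if M == 0 or k == 0:
            return np.zeros(self.n_perm, dtype=np.int64)
        counts = np.empty(self.n_perm, dtype=np.int64)
        # chunk to bound the (chunk x N) random-key matrix at ~32 MB
        chunk = max(1, min(self.n_perm, int(4e6) // self.N))
        done = 0
        while done < self.n_perm:
            size = min(chunk, self.n_perm - done)
            keys = self.rng.random((size, self.N))
            # indices of the M smallest keys per row = uniform M-subset
            idx = np.argpartition(keys, M - 1, axis=1)[:, :M]
            counts[done : done + size] = (idx < k).sum(axis=1)
            done += size
        return counts

    def pvalue(self, k: int, M: int, x_obs: int, correction: bool = False) -> float:
        """Proportion of permutations with count >= x_obs.

        With ``correction=True`` the add-one estimate (r+1)/(n_perm+1) is
        returned, which cannot be exactly zero.
        """
        r = int((self.null_counts(k, M) >= x_obs).sum())
        if correction:
            return (r + 1) / (self.n_perm + 1)
        return r / self.n_perm


def permutation_pvalue(
    net: PPINetwork,
    gene: str,
    x_obs: int,
    M: int,
    n_perm: int = 10_000,
    rng_seed: int | np.random.Generator | None = None,
    cache: NullCache | None = None,
    correction: bool = False,
) -> float:
    """Monte-Carlo permutation p-value for one observed neighbor count.

    Each permutation places M distinct alterations uniformly on the network
    and counts how many land in the neighborhood of *gene*; p is the
    proportion of permutations reaching x_obs or more.
    """
    k = net.degree(gene)
    if x_obs > min(k, M):
        raise ValueError(f"x_obs={x_obs} exceeds min(k={k}, M={M})")
    if cache is None:
        rng = (
            rng_seed
            if isinstance(rng_seed, np.random.Generator)
            else np.random.default_rng(rng_seed)
        )
        cache = NullCache(net.n_nodes, n_perm=n_perm, rng=rng)
    return cache.pvalue(k, M, x_obs, correction=correction)


# ---------------------------------------------------------------------------
# cohort-level calling


@dataclass
class SurrogateMatrix:
    """Samples x surrogate-set genes state matrix.

    States: ``none``, ``surrogate_only`` (significant neighborhood, gene not
    itself altered), ``altered_only``, ``both``.  The binary views feed the
    downstream classifiers and survival trees.
    """

    states: pd.DataFrame  # rows = samples, columns = genes, dtype str
    alpha: float

    @property
    def samples(self) -> list[str]:
        return list(self.states.index)

    @property
    def genes(self) -> list[str]:
        return list(self.states.columns)

    def significant(self) -> pd.DataFrame:
        """Binary matrix: 1 iff the gene is a significant surrogate."""
        return self.states.isin(["surrogate_only", "both"]).astype(int)

    def altered(self) -> pd.DataFrame:
        """Binary matrix: 1 iff the gene itself is altered in the sample."""
        return self.states.isin(["altered_only", "both"]).astype(int)

    def to_codes(self) -> pd.DataFrame:
        """Integer coding 0-3 (none / surrogate_only / altered_only / both)."""
        return self.states.apply(lambda col: col.map(STATE_CODES)).astype(int)

    def to_csv(self, path) -> None:
        self.to_codes().to_csv(path, index_label="sample")


def call_surrogates(
    net: PPINetwork,
    gene_set: SurrogateGeneSet,
    profiles: Sequence[AlterationProfile],
    alpha: float = 0.05,
    mode: Literal["exact", "perm"] = "exact",
    n_perm: int = 10_000,
    rng_seed: int | None = None,
    correction: bool = False,
) -> tuple[list[SurrogateCall], SurrogateMatrix]:
    """Test every (sample, surrogate-set gene) pair for neighborhood enrichment.

    A call is significant iff ``p < alpha`` (strict, so ``alpha=0`` yields
    none).  ``mode="exact"`` evaluates the hypergeometric closed form of the
    null; ``mode="perm"`` runs *n_perm* seeded Monte-Carlo permutations with
    null distributions shared across genes of equal degree within a sample.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if mode not in ("exact", "perm"):
        raise ValueError(f"unknown mode: {mode!r}")
    N = net.n_nodes
    genes = sorted(gene_set.expanded)
    cache = None
    if mode == "perm":
        cache = NullCache(N, n_perm=n_perm, rng=np.random.default_rng(rng_seed))

    calls: list[SurrogateCall] = []
    states = pd.DataFrame(
        "none", index=[p.sample_id for p in profiles], columns=genes, dtype=object
    )
    for prof in profiles:
        M = prof.M
        n_sig = 0
        for gene in genes:
            x_obs, contributing, self_altered = count_altered_neighbors(net, gene, prof)
            k = net.degree(gene)
            if mode == "exact":
                p = exact_tail_pvalue(N, k, M, x_obs)
                n_used = 0
            else:
                p = cache.pvalue(k, M, x_obs, correction=correction)
                n_used = n_perm
            sig = p < alpha
            n_sig += sig
            calls.append(
                SurrogateCall(
                    sample_id=prof.sample_id,
                    gene=gene,
                    k=k,
                    M=M,
                    x_obs=x_obs,
                    n_perm=n_used,
                    p_value=p,
                    significant=sig,
                    contributing_neighbors=contributing,
                    self_altered=self_altered,
                )
            )
            if sig and self_altered:
                state = "both"
            elif sig:
                state = "surrogate_only"
            elif self_altered:
                state = "altered_only"
            else:
                state = "none"
            states.loc[prof.sample_id, gene] = state
        logger.debug("sample %s: %d significant surrogate(s)", prof.sample_id, n_sig)
    return calls, SurrogateMatrix(states=states, alpha=alpha)


def calls_to_table(calls: Iterable[SurrogateCall]) -> pd.DataFrame:
    """Flat calls table (one row per sample x gene test)."""
    rows = [
        (
            c.sample_id,
            c.gene,
            c.k,
            c.M,
            c.x_obs,
            c.p_value,
            c.significant,
            c.self_altered,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "gene", "k", "M", "x_obs", "p_value", "significant", "self_altered"],
    )


def neighbor_frequency(
    calls: Sequence[SurrogateCall], gene: str, net: PPINetwork | None = None
) -> pd.DataFrame:
    """Cross-sample view of one gene's altered neighbors.

    For each neighbor that contributed to the gene's observed count in any
    sample: the number of samples in which it was altered and (if *net* is
    given) its degree within the gene-centered subnetwork (gene + its
    altered neighbors).
    """
    gene_calls = [c for c in calls if c.gene == gene]
    if not gene_calls:
        raise KeyError(f"gene never tested: {gene!r}")
    freq: dict[str, int] = {}
    for c in gene_calls:
        for nbr, _types in c.contributing_neighbors:
            freq[nbr] = freq.get(nbr, 0) + 1
    rows = []
    members = set(freq) | {gene}
    for nbr in sorted(freq):
        sub_deg = (
            len(net.neighbors(nbr) & members) if net is not None else pd.NA
        )
        rows.append((nbr, freq[nbr], sub_deg))
    return pd.DataFrame(
        rows, columns=["neighbor", "n_samples_altered", "subnetwork_degree"]
    )


def subnetwork_export(
    calls: Sequence[SurrogateCall], gene: str, net: PPINetwork
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of the gene-centered altered-neighbor subnetwork."""
    freq = neighbor_frequency(calls, gene, net=net)
    members = set(freq["neighbor"]) | {gene}
    nodes = pd.DataFrame(
        {
            "gene": sorted(members),
            "role": ["surrogate" if g == gene else "neighbor" for g in sorted(members)],
        }
    )
    edges = [
        (a, b)
        for a, b in net.graph.subgraph(members).edges
    ]
    edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in edges), columns=["gene_a", "gene_b"])
    return nodes, edges
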