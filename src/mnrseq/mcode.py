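"""Molecular-complex detection (MCODE) on a gene-interaction graph.

Implements the classic two-stage algorithm: every vertex is weighted by the
density of the highest k-core of its closed neighborhood times k, and
complexes are grown outward from high-weight seeds, admitting neighbors
whose weight is within a fraction (the vertex weight percentage, VWP) of
the seed's.  A complex is scored density x size.  Admission back to the
differential-expression results follows the pipeline's rules: score
strictly greater than 4, at least seven nodes ("more than six"), and at
least one member gene below the primary FDR threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import PipelineConfig

logger = logging.getLogger("mnrseq")


@dataclass
class Complex:
    """A candidate molecular complex (dense subgraph)."""

    members: tuple[str, ...]
    seed: str
    density: float
    score: float
    admitted: bool | None = None
    qualifying_gene: str | None = None
    flags: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mcode_vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """Weight of each vertex: k times the density of the highest k-core of
    the subgraph induced on the vertex and its neighbors.  Isolated
    vertices weigh 0."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        if not nbrs:
            weights[v] = 0.0
            continue
        sub = graph.subgraph([v, *nbrs])
        core_num = nx.core_number(sub)
        k = max(core_num.values())
        if k == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in core_num.items() if c >= k]
        weights[v] = k * _density(sub.subgraph(core_nodes))
    return weights


def mcode_find_complexes(
    graph: nx.Graph,
    weights: dict[str, float] | None = None,
    vwp: float = 0.2,
    haircut: bool = True,
) -> list[Complex]:
    """Grow complexes from high-weight seeds.

    Seeds are taken in decreasing weight (ties by node id).  From a seed,
    breadth-first expansion admits unassigned neighbors whose weight is at
    least ``seed_weight * (1 - vwp)``; each vertex joins at most one
    complex.  With ``haircut`` on, members left with fewer than two
    connections inside the complex are pruned (repeatedly, so dangling
    trees disappear).  Complexes need at least two nodes and one edge.
    Output is sorted by score descending, ties by seed id.
    """
    if weights is None:
        weights = mcode_vertex_weights(graph)
    if not 0 <= vwp < 1:
        raise ValueError("vwp must be in [0, 1)")
    unassigned = set(graph.nodes)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    complexes: list[Complex] = []
    for seed in order:
        if seed not in unassigned or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in sorted(graph.neighbors(node), key=str):
                    if nb in unassigned and nb not in members and weights[nb] >= threshold:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
        sub = graph.subgraph(members).copy()
        if haircut:
            while True:
                stray = [u for u in sub.nodes if sub.degree(u) < 2]
                if not stray or sub.number_of_nodes() - len(stray) < 2:
                    sub.remove_nodes_from(stray)
                    break
                sub.remove_nodes_from(stray)
        if sub.number_of_nodes() < 2 or sub.number_of_edges() < 1:
            # failed seed still leaves the pool so it cannot re-seed forever
            unassigned.discard(seed)
            continue
        final_members = tuple(sorted(sub.nodes, key=str))
        unassigned -= set(final_members)
        unassigned.discard(seed)
        d = _density(sub)
        complexes.append(
            Complex(members=final_members, seed=seed, density=d,
                    score=d * len(final_members))
        )
    complexes.sort(key=lambda c: (-c.score, str(c.seed)))
    logger.info("mcode_find_complexes: %d complexes from %d nodes",
                len(complexes), graph.number_of_nodes())
    return complexes


def admit_complexes(
    complexes: list[Complex],
    de_fdr: dict[str, float] | pd.DataFrame,
    config: PipelineConfig | None = None,
) -> list[Complex]:
    """Annotate complexes with the admission rules: score > mcode_min_score,
    at least ``mcode_min_nodes`` members, and at least one member gene with
    DE FDR below ``fdr_primary``.  Genes absent from the DE table count as
    non-qualifying."""
    config = config or PipelineConfig()
    if isinstance(de_fdr, pd.DataFrame):
        de_fdr = (
            de_fdr.groupby("gene_symbol")["fdr"].min().to_dict()
        )
    missing: set[str] = set()
    for c in complexes:
        score_ok = c.score > config.mcode_min_score
        size_ok = c.n >= config.mcode_min_nodes
        best_gene, best_fdr = None, np.inf
        for g in c.members:
            if g not in de_fdr:
                missing.add(g)
                continue
            if de_fdr[g] < best_fdr:
                best_gene, best_fdr = g, de_fdr[g]
        fdr_ok = best_fdr < config.fdr_primary
        c.flags = {"score_ok": score_ok, "size_ok": size_ok, "fdr_ok": bool(fdr_ok)}
        c.admitted = score_ok and size_ok and bool(fdr_ok)
        c.qualifying_gene = best_gene if fdr_ok else None
    if missing:
        logger.info("admit_complexes: %d member genes absent from DE table", len(missing))
    return complexes


def complexes_table(complexes: list[Complex]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(complexes, start=1):
        rows.append(
            {
                "complex_id": i,
                "seed": c.seed,
                "n": c.n,
                "density": c.density,
                "score": c.score,
                "admitted": c.admitted,
                "qualifying_gene": c.qualifying_gene or "",
                "score_ok": c.flags.get("score_ok"),
                "size_ok": c.flags.get("size_ok"),
                "fdr_ok": c.flags.get("fdr_ok"),
                "members": ";".join(c.members),
            }
        )
    return pd.DataFrame(rows)
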