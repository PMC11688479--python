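"""Gene-set intersection and PPI hub ranking by maximal clique centrality.

Compound target sets predicted upstream (by external target-prediction
services, consumed here as plain gene lists) are intersected with disease
gene sets to obtain Venn-style counts, and the induced protein-protein
interaction network is ranked for hub genes.

Hub score: cytoHubba-style Maximal Clique Centrality (MCC),

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!

with the special case MCC(v) = degree(v) when v's neighborhood contains
no edge (the node sits only in 2-cliques).  Note this "MCC" is unrelated
to the Matthews correlation coefficient of the ML benchmark; the two
acronyms collide in the literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

#: Clique enumeration is exponential worst-case; refuse beyond this size.
NODE_CEILING = 5000


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized (uppercase, trimmed) gene symbols."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        genes = frozenset(
            s.strip().upper() for s in symbols if s is not None and s.strip()
        )
        return cls(name, genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class IntersectionResult:
    genes: GeneSet
    n_a: int
    n_b: int
    n_common: int


@dataclass(frozen=True)
class HubRanking:
    """MCC scores per node plus the top-k list (score desc, then symbol)."""

    scores: dict[str, int]
    top: tuple[tuple[str, int], ...]


def intersect_sets(a: GeneSet, b: GeneSet) -> IntersectionResult:
    """Exact set intersection with Venn-style counts (|a|, |b|, |a∩b|)."""
    common = a.genes & b.genes
    return IntersectionResult(
        genes=GeneSet(f"{a.name}&{b.name}", common),
        n_a=len(a),
        n_b=len(b),
        n_common=len(common),
    )


def build_ppi_graph(
    edges: Iterable[tuple[str, str, float]],
    min_score: float = 0.4,
) -> nx.Graph:
    """Build an undirected PPI graph from (gene, gene, confidence) triples.

    Self-loops are dropped; duplicate edges keep the highest confidence;
    edges below ``min_score`` are excluded.  Confidence is in [0, 1].
    """
    g = nx.Graph()
    for u, v, w in edges:
        u, v = u.strip().upper(), v.strip().upper()
        if not u or not v or u == v:
            continue
        w = float(w)
        if w < min_score:
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    return g


def clique_centrality(g: nx.Graph, top_k: int = 10) -> HubRanking:
    """Rank nodes by Maximal Clique Centrality.

    score(v) = Σ_{maximal cliques C ∋ v} (|C|-1)!, except that a node whose
    neighborhood is edgeless scores its degree.  Ties in the top-k break
    lexicographically by symbol for determinism.
    """
    if g.number_of_nodes() > NODE_CEILING:
        raise ValueError(
            f"graph has {g.number_of_nodes()} nodes (> {NODE_CEILING}); "
            f"clique enumeration is infeasible — use a degree-based ranking instead"
        )
    scores: dict[str, int] = {v: 0 for v in g.nodes}
    edgeless_nbhd = {
        v: g.subgraph(g.neighbors(v)).number_of_edges() == 0 for v in g.nodes
    }
    for clique in nx.find_cliques(g):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            if not edgeless_nbhd[v]:
                scores[v] += contrib
    for v, edgeless in edgeless_nbhd.items():
        if edgeless:
            scores[v] = g.degree(v)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return HubRanking(scores=scores, top=tuple(ordered[:top_k]))


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set from a one-symbol-per-line text file."""
    path = Path(path)
    symbols = path.read_text(encoding="utf-8").splitlines()
    return GeneSet.from_symbols(name or path.stem, symbols)


def read_string_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a STRING-style TSV edge list: protein1 protein2 combined_score.

    Scores on the STRING 0–1000 integer scale are rescaled to [0, 1];
    scores already in [0, 1] pass through.  A header line naming the
    columns is skipped if present.
    """
    edges: list[tuple[str, str, float]] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.split()
        if len(parts) < 3:
            continue
        if parts[0].lower().startswith("protein"):
            continue  # header
        score = float(parts[2])
        if score > 1.0:
            score /= 1000.0
        edges.append((parts[0], parts[1], score))
    return edges


def write_hub_tsv(ranking: HubRanking, path: str | Path) -> None:
    lines = ["gene\tmcc_score"]
    lines += [f"{gene}\t{score}" for gene, score in ranking.top]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
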