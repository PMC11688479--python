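"""Hypergeometric over-representation analysis (ORA) with BH adjustment.

A query gene list is tested against each term of an annotation collection
(GO/KEGG-style GMT files).  For a universe of N genes, a term of size K,
a query of size n and an overlap of k, the enrichment p-value is the
hypergeometric upper tail

    p = P[X >= k],   X ~ Hypergeometric(N, K, n)

and q-values are Benjamini-Hochberg adjusted across all terms of the
collection.  Default cutoffs follow common practice for this kind of
screen: p <= 0.01 and q <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .targetnet import GeneSet

DEFAULT_P_CUT = 0.01
DEFAULT_Q_CUT = 0.05


@dataclass(frozen=True)
class AnnotationCollection:
    """Term id -> (term name, gene set), plus the gene universe.

    When no explicit universe is given, it is the union of all annotated
    genes — the usual ORA default.
    """

    sets: dict[str, tuple[str, GeneSet]]
    universe: GeneSet

    @classmethod
    def from_terms(
        cls,
        terms: dict[str, tuple[str, Iterable[str]]],
        universe: Iterable[str] | None = None,
    ) -> "AnnotationCollection":
        sets = {
            tid: (name, GeneSet.from_symbols(tid, genes))
            for tid, (name, genes) in terms.items()
        }
        if universe is None:
            all_genes: set[str] = set()
            for _, gs in sets.values():
                all_genes |= gs.genes
            uni = GeneSet("universe", frozenset(all_genes))
        else:
            uni = GeneSet.from_symbols("universe", universe)
        return cls(sets=sets, universe=uni)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int  # overlap
    K: int  # term size
    n: int  # query size (inside universe)
    N: int  # universe size
    p: float
    q: float


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n); exactly 1 when k == 0."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), clipped at 1.  Raises on any
    p outside (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def ora(
    query: GeneSet,
    ann: AnnotationCollection,
    p_cut: float = DEFAULT_P_CUT,
    q_cut: float = DEFAULT_Q_CUT,
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` in every term of ``ann``.

    Query genes outside the universe are dropped (with a warning via the
    return path of the restricted n).  All terms are tested, q-values are
    BH-adjusted over the whole collection, then rows are filtered to
    p <= p_cut and q <= q_cut and sorted by p ascending (ties by term id).
    """
    if len(ann.universe) == 0:
        raise ValueError("empty annotation universe")
    if len(query) == 0:
        raise ValueError("empty query gene set")
    inside = query.genes & ann.universe.genes
    if not inside:
        raise ValueError("no query gene lies in the annotation universe")
    if len(inside) < len(query):
        import warnings

        warnings.warn(
            f"{len(query) - len(inside)} query gene(s) outside the universe "
            f"were dropped",
            stacklevel=2,
        )
    N = len(ann.universe)
    n = len(inside)
    rows: list[tuple[str, str, int, int, float]] = []
    for tid, (name, gs) in ann.sets.items():
        term_genes = gs.genes & ann.universe.genes
        k = len(inside & term_genes)
        p = hypergeom_upper_tail(k, N, len(term_genes), n)
        rows.append((tid, name, k, len(term_genes), p))
    qvals = bh_adjust([r[4] for r in rows])
    out = [
        EnrichmentRow(tid, name, k, K, n, N, p, q)
        for (tid, name, k, K, p), q in zip(rows, qvals)
        if p <= p_cut and q <= q_cut
    ]
    out.sort(key=lambda r: (r.p, r.term_id))
    return out


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT annotation file: term <TAB> description <TAB> gene...  per line."""
    terms: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        terms[parts[0]] = (parts[1], parts[2:])
    return AnnotationCollection.from_terms(terms)


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    lines = ["term\tname\tk/K\tn/N\tp\tq"]
    for r in rows:
        lines.append(
            f"{r.term_id}\t{r.term_name}\t{r.k}/{r.K}\t{r.n}/{r.N}\t{r.p:.6g}\t{r.q:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
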