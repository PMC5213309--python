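"""Hypergeometric over-representation analysis of a study gene list against a
flat term -> gene annotation table, with BH-FDR and an enrichment-map term
network.

For a universe of N genes of which K carry a term, a study list of n genes
containing k of them is scored with the upper hypergeometric tail
P(X >= k).  The universe defaults to all presence-filtered genes — the study
list is already conditioned on network membership, and conditioning the
universe the same way would double-count that selection.

The enrichment map connects enriched terms whose annotated gene sets overlap
strongly, using the overlap coefficient |A & B| / min(|A|, |B|) (the
similarity family EnrichmentMap-style visualizations use), restricted to
universe genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import adjust_bh
from .io import TermAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "GoeaResult",
    "hypergeom_tail",
    "run_goea",
    "build_enrichment_map",
]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` study hits, ``K`` term size in the universe, ``n`` study size,
    ``N`` universe size.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class GoeaResult:
    """Per-term k/K/n/N, p and BH q, with the tested universe retained so the
    enrichment map can be built from the same gene background."""

    table: pd.DataFrame
    universe: set[str]
    q_max: float

    def enriched_terms(self) -> list[str]:
        return list(self.table.index[self.table["enriched"]])


def run_goea(
    study: list[str],
    annotations: TermAnnotation,
    universe: list[str],
    q_max: float = 0.05,
) -> GoeaResult:
    """One hypergeometric test per term with K >= 1 and k >= 1, BH across
    tested terms; a term is enriched when q <= ``q_max``.

    Study genes outside the universe are dropped with a warning; an empty
    study after intersection yields an empty (warned) result.
    """
    uni = set(universe)
    if len(uni) != len(universe):
        raise ValueError("universe contains duplicate genes")
    study_set = set(study)
    outside = study_set - uni
    if outside:
        logger.warning("%d study genes outside the universe dropped", len(outside))
        study_set &= uni
    N, n = len(uni), len(study_set)
    if n == 0:
        logger.warning("empty study list after universe intersection")
        return GoeaResult(
            pd.DataFrame(
                columns=["term_name", "k", "K", "n", "N", "p", "q", "enriched"]
            ),
            uni,
            q_max,
        )
    rows = []
    for tid in annotations:
        term_genes = annotations.genes_of(tid) & uni
        K = len(term_genes)
        k = len(term_genes & study_set)
        if K < 1 or k < 1:
            continue
        rows.append(
            {"term": tid, "term_name": annotations.name_of(tid),
             "k": k, "K": K, "n": n, "N": N,
             "p": hypergeom_tail(k, K, n, N)}
        )
    if not rows:
        return GoeaResult(
            pd.DataFrame(columns=["term_name", "k", "K", "n", "N", "p", "q", "enriched"]),
            uni,
            q_max,
        )
    table = pd.DataFrame(rows).set_index("term")
    table["q"] = adjust_bh(table["p"].to_numpy())
    table["enriched"] = table["q"] <= q_max
    return GoeaResult(table.sort_values(["p", "term_name"]), uni, q_max)


def build_enrichment_map(
    result: GoeaResult, annotations: TermAnnotation, overlap_min: float = 0.5
) -> nx.Graph:
    """Term network over enriched terms.

    Nodes carry q, k and K; an edge joins terms whose universe-restricted
    annotation sets have overlap coefficient |A & B| / min(|A|, |B|) at or
    above ``overlap_min`` (inclusive).
    """
    if not (0 <= overlap_min <= 1):
        raise ValueError("overlap_min must lie in [0, 1]")
    G = nx.Graph()
    enriched = result.enriched_terms()
    genes = {
        t: annotations.genes_of(t) & result.universe for t in enriched
    }
    for t in enriched:
        row = result.table.loc[t]
        G.add_node(
            t,
            term_name=str(row["term_name"]),
            q=float(row["q"]),
            k=int(row["k"]),
            K=int(row["K"]),
        )
    terms = sorted(enriched)
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            denom = min(len(genes[a]), len(genes[b]))
            if denom == 0:
                continue
            coef = len(genes[a] & genes[b]) / denom
            if coef >= overlap_min:
                G.add_edge(a, b, overlap=float(coef))
    return G
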