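"""Hypergeometric over-representation tests for gene-set collections.

Given a selected gene list (e.g. differentially expressed genes) and a
universe of testable genes, each set is scored by the upper-tail
hypergeometric probability P(X >= k) of its overlap with the selection,
with the sample odds ratio and expected overlap reported alongside
(columns mirror the conventional output: Pvalue, OddsRatio, ExpCount,
Count, Size, Term).

Conditional (DAG-decorrelated) testing for hierarchies such as the Gene
Ontology processes terms children-before-parents and removes the genes of
each significant child from its ancestors before those are tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeometric_test",
    "enrich_collection",
    "conditional_enrich",
    "default_universe",
]


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    term: str
    p_value: float
    odds_ratio: float
    expected_count: float
    observed_count: int
    set_size: int  # members within the universe
    universe_size: int
    selected_size: int


def default_universe(collection: GeneSetCollection, array_genes) -> set:
    """Genes on the array that carry at least one annotation in the collection."""
    annotated = set().union(*(gs.members for gs in collection)) if len(collection) else set()
    return annotated & set(array_genes)


def hypergeometric_test(selected, gene_set, universe, term: str = "", set_id: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric test of one set against the selection.

    With U = |universe|, m = |set ∩ universe|, s = |selected|,
    k = |selected ∩ set|: p = P(X >= k), X ~ Hypergeom(U, m, s);
    ExpCount = s m / U; OddsRatio = (k/(s-k)) / ((m-k)/(U-m-s+k)), infinite
    when a denominator cell is zero.
    """
    universe = set(universe)
    selected = set(selected)
    outside = selected - universe
    if outside:
        raise ValueError(f"selected gene(s) absent from the universe: {sorted(outside)[:5]}")
    members = (gene_set.members if hasattr(gene_set, "members") else set(gene_set)) & universe
    U, m, s = len(universe), len(members), len(selected)
    k = len(selected & members)
    p = float(stats.hypergeom.sf(k - 1, U, m, s))
    expected = s * m / U if U else 0.0
    denom_a, denom_b = s - k, m - k
    other = U - m - s + k
    if denom_a == 0 or denom_b == 0:
        odds = np.inf
    else:
        odds = (k * other) / (denom_a * denom_b)
    return EnrichmentResult(
        set_id=set_id or getattr(gene_set, "set_id", ""),
        term=term or getattr(gene_set, "description", ""),
        p_value=min(max(p, 0.0), 1.0),
        odds_ratio=float(odds),
        expected_count=float(expected),
        observed_count=k,
        set_size=m,
        universe_size=U,
        selected_size=s,
    )


def _to_frame(results: list[EnrichmentResult], p_threshold: float) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "Pvalue": r.p_value,
                "OddsRatio": r.odds_ratio,
                "ExpCount": r.expected_count,
                "Count": r.observed_count,
                "Size": r.set_size,
                "Term": r.term,
            }
            for r in results
        ]
    )
    if df.empty:
        return df
    # informative, never filtering: BH-adjusted p alongside the raw threshold
    df["Padj_BH"] = stats.false_discovery_control(df["Pvalue"], method="bh")
    df = df[df["Pvalue"] < p_threshold]
    return df.sort_values(["Pvalue", "set_id"], kind="mergesort").reset_index(drop=True)


def enrich_collection(selected, collection: GeneSetCollection, universe,
                      p_threshold: float = 0.01) -> pd.DataFrame:
    """Test every set; keep rows with p < threshold, sorted by (p, set_id)."""
    results = [
        hypergeometric_test(selected, gs, universe, term=gs.description, set_id=gs.set_id)
        for gs in collection
    ]
    return _to_frame(results, p_threshold)


def conditional_enrich(selected, collection: GeneSetCollection, universe,
                       p_threshold: float = 0.001) -> pd.DataFrame:
    """DAG-conditional testing, children before parents.

    Terms are processed in reverse topological order of the parent->child
    relation; when a term is significant (p < threshold) its member genes
    are removed from every ancestor's set before the ancestors are tested.
    A flat collection (no relations) reduces to :func:`enrich_collection`.
    """
    g = collection.relation_graph()
    order = list(reversed(list(nx.topological_sort(g))))
    effective = {gs.set_id: set(gs.members) for gs in collection}
    results = []
    for set_id in order:
        gs = collection[set_id]
        res = hypergeometric_test(
            selected, frozenset(effective[set_id]), universe, term=gs.description, set_id=set_id
        )
        results.append(res)
        if res.p_value < p_threshold:
            for anc in nx.ancestors(g, set_id):
                effective[anc] -= set(gs.members)
    return _to_frame(results, p_threshold)
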