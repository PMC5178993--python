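"""ICA-vs-PCA comparison, LD between hit SNPs, and trait-graph export.

``match_components`` pairs components of two decompositions by the
correlation of their score vectors; ``ld_r2`` is composite LD (squared
Pearson correlation of additive genotype codes); ``build_graph`` turns
one component into a complete trait graph with loading-colored nodes,
serializable to GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import PhenotypeMatrix
from .decomposition import Decomposition
from .errors import UndefinedStatisticError, ValidationError


@dataclass
class ComponentMatch:
    index_1: int
    index_2: int
    label_1: str
    label_2: str
    loading_r: float
    score_r: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise UndefinedStatisticError("correlation undefined for constant vector")
    return float((a * b).sum() / denom)


def match_components(d1: Decomposition, d2: Decomposition) -> list[ComponentMatch]:
    """Greedy 1-1 pairing of components by |score correlation|.

    For every candidate pair the Pearson correlations of loading vectors
    and of score vectors are computed; pairs are consumed greedily in
    decreasing |score_r|.
    """
    if list(d1.trait_names) != list(d2.trait_names):
        raise ValidationError("decompositions use different trait sets")
    if d1.scores.shape[0] != d2.scores.shape[0]:
        raise ValidationError("decompositions use different individuals")
    k1, k2 = d1.k, d2.k
    score_r = np.zeros((k1, k2))
    loading_r = np.zeros((k1, k2))
    for i in range(k1):
        for j in range(k2):
            score_r[i, j] = _pearson(d1.scores[:, i], d2.scores[:, j])
            loading_r[i, j] = _pearson(d1.weights[i], d2.weights[j])
    matches: list[ComponentMatch] = []
    used1: set[int] = set()
    used2: set[int] = set()
    order = np.dstack(
        np.unravel_index(np.argsort(-np.abs(score_r), axis=None), score_r.shape)
    )[0]
    for i, j in order:
        if i in used1 or j in used2:
            continue
        used1.add(int(i))
        used2.add(int(j))
        matches.append(
            ComponentMatch(
                index_1=int(i),
                index_2=int(j),
                label_1=d1.component_labels[i],
                label_2=d2.component_labels[j],
                loading_r=float(loading_r[i, j]),
                score_r=float(score_r[i, j]),
            )
        )
        if len(matches) == min(k1, k2):
            break
    return matches


def match_by_pvalue(
    d1: Decomposition,
    d2: Decomposition,
    assoc_1,
    assoc_2,
    snp_id: str,
) -> ComponentMatch:
    """Pair, for one SNP, the component of each decomposition with the
    lowest raw association p-value (the manual pairing rule)."""
    def best(assoc, labels) -> int:
        cands = [r for r in assoc if r.snp_id == snp_id and r.testable]
        if not cands:
            raise ValidationError(f"no testable results for SNP {snp_id!r}")
        best_r = min(cands, key=lambda r: r.p_raw)
        return labels.index(best_r.metaphenotype_label)

    i = best(assoc_1, d1.component_labels)
    j = best(assoc_2, d2.component_labels)
    return ComponentMatch(
        index_1=i,
        index_2=j,
        label_1=d1.component_labels[i],
        label_2=d2.component_labels[j],
        loading_r=_pearson(d1.weights[i], d2.weights[j]),
        score_r=_pearson(d1.scores[:, i], d2.scores[:, j]),
    )


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of additive genotype
    codes over jointly observed individuals."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    both = ~np.isnan(g1) & ~np.isnan(g2)
    if both.sum() < 2:
        raise ValidationError("need >= 2 jointly observed individuals")
    a, b = g1[both], g2[both]
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise UndefinedStatisticError("LD undefined for a monomorphic column")
    return _pearson(a, b) ** 2


def build_graph(
    d: Decomposition, component_label: str, X: PhenotypeMatrix
) -> nx.Graph:
    """Complete trait graph for one metaphenotype.

    Nodes carry the component's loadings and a color value normalized to
    [-1, 1] by the largest |loading|; edges carry pairwise Pearson trait
    correlations computed from ``X``.
    """
    if component_label not in d.component_labels:
        raise ValidationError(
            f"unknown component {component_label!r}; have {d.component_labels}"
        )
    if list(X.trait_names) != list(d.trait_names):
        raise ValidationError("phenotype traits do not match the decomposition")
    ci = d.component_labels.index(component_label)
    w = d.weights[ci]
    wmax = np.max(np.abs(w))
    graph = nx.Graph(component_label=component_label, method=d.method)
    for j, name in enumerate(d.trait_names):
        graph.add_node(
            name,
            trait_name=name,
            weight=float(w[j]),
            color_value=float(w[j] / wmax) if wmax > 0 else 0.0,
        )
    vals = np.asarray(X.values, dtype=float)
    m = len(d.trait_names)
    for a in range(m):
        for b in range(a + 1, m):
            both = ~np.isnan(vals[:, a]) & ~np.isnan(vals[:, b])
            r = _pearson(vals[both, a], vals[both, b])
            graph.add_edge(d.trait_names[a], d.trait_names[b], correlation=r)
    return graph


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_match_table(matches: list[ComponentMatch], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "component_1": [m.label_1 for m in matches],
            "component_2": [m.label_2 for m in matches],
            "loading_r": [m.loading_r for m in matches],
            "score_r": [m.score_r for m in matches],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
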