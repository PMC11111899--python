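"""Set, network and enrichment mathematics for target-gene analysis.

Operates on exported tables (scored gene lists, a PPI-style edge list,
annotation sets in GMT format) rather than on live databases:

* score-threshold filtering of candidate target tables (duplicate symbols
  resolved by maximum score);
* drug-set / disease-set intersection on case-normalised symbols;
* degree statistics of the undirected interaction network and selection of
  core (hub) genes with degree strictly greater than a cutoff;
* hypergeometric over-representation of a study set against annotation sets,
  with Benjamini–Hochberg adjustment (globally, or within each declared
  namespace as is common GO practice).

Edge lists with a ``combined_score`` column can be confidence-filtered while
loading (e.g. the conventional 0.7 high-confidence cutoff).
"""

from __future__ import annotations

import operator
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_symbol",
    "filter_targets",
    "intersect_sets",
    "load_scored_table",
    "load_edge_list",
    "read_gmt",
    "build_network",
    "degree_stats",
    "select_core",
    "ora_hypergeometric",
]

_COMPARATORS = {">=": operator.ge, ">": operator.gt,
                "<=": operator.le, "<": operator.lt}


def normalize_symbol(gene: str) -> str:
    return str(gene).strip().upper()


def load_scored_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    need = {"gene", "score"}
    if not need <= set(frame.columns):
        raise ValueError(f"{path}: scored table needs columns {sorted(need)}")
    return frame


def filter_targets(table: pd.DataFrame, cutoff: float,
                   comparator: str = ">=") -> set[str]:
    """Genes whose score passes ``comparator cutoff``; max score wins on ties.

    An empty table yields an empty set.
    """
    if comparator not in _COMPARATORS:
        raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
    if table.empty:
        return set()
    op = _COMPARATORS[comparator]
    scores = table.assign(gene=table["gene"].map(normalize_symbol))
    best = scores.groupby("gene")["score"].max()
    return set(best.index[op(best.to_numpy(), cutoff)])


def intersect_sets(drug_set: Iterable[str], disease_set: Iterable[str]) -> set[str]:
    """Exact intersection on normalised symbols."""
    return ({normalize_symbol(g) for g in drug_set}
            & {normalize_symbol(g) for g in disease_set})


def load_edge_list(path: str | Path, min_score: float | None = None) -> pd.DataFrame:
    """Edge TSV (gene_a, gene_b[, combined_score]); optional confidence filter."""
    frame = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b"} <= set(frame.columns):
        raise ValueError(f"{path}: edge list needs gene_a and gene_b columns")
    if min_score is not None:
        if "combined_score" not in frame.columns:
            raise ValueError(f"{path}: no combined_score column to filter on")
        frame = frame[frame["combined_score"] >= min_score]
    return frame.reset_index(drop=True)


def build_network(edges: pd.DataFrame, nodes: Iterable[str] | None = None) -> nx.Graph:
    """Simple undirected graph: self-loops dropped, duplicate edges collapsed."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(normalize_symbol(n) for n in nodes)
    for ga, gb in zip(edges["gene_a"], edges["gene_b"]):
        u, v = normalize_symbol(ga), normalize_symbol(gb)
        if u != v:
            g.add_edge(u, v)
    return g


def degree_stats(network: nx.Graph) -> tuple[pd.Series, float]:
    """Per-node degree and the average degree 2|E|/|V|."""
    deg = pd.Series(dict(network.degree()), dtype=int).sort_index()
    avg = 2.0 * network.number_of_edges() / network.number_of_nodes() if len(deg) else float("nan")
    return deg, avg


def select_core(network: nx.Graph, cutoff: int = 10) -> list[str]:
    """Hub genes with degree strictly greater than ``cutoff``.

    Sorted by degree descending, ties by symbol.
    """
    deg, _ = degree_stats(network) if network.number_of_nodes() else (pd.Series(dtype=int), 0.0)
    core = deg[deg > cutoff]
    return core.sort_values(ascending=False, kind="stable").index.tolist() if len(core) else []


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT file -> (sets, descriptions); members are normalised symbols."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs name, description, members")
        name, desc, *members = parts
        sets[name] = {normalize_symbol(m) for m in members if m}
        descriptions[name] = desc
    return sets, descriptions


def ora_hypergeometric(study_set: Iterable[str], universe: Iterable[str],
                       annotation_sets: Mapping[str, Iterable[str]],
                       namespaces: Mapping[str, str] | None = None,
                       per_namespace: bool = True) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH adjustment.

    For each annotation set of size K over a universe of size M, with a
    study set of size n overlapping in k genes, p = P(X >= k) for
    X ~ Hypergeometric(M, K, n).  BH runs within each namespace when
    ``namespaces`` labels the sets and ``per_namespace`` is true, else
    globally across all tested sets.  An empty study set yields p = 1
    everywhere.  Significance convention: adjusted p < 0.05.
    """
    uni = {normalize_symbol(g) for g in universe}
    study = {normalize_symbol(g) for g in study_set}
    if not study <= uni:
        raise ValueError("study set must be a subset of the universe")
    m_total = len(uni)
    n_study = len(study)
    rows = []
    for name, members in annotation_sets.items():
        mem = {normalize_symbol(g) for g in members}
        if not mem <= uni:
            raise ValueError(f"annotation set {name!r} not contained in the universe")
        k_overlap = len(study & mem)
        if n_study == 0:
            p = 1.0
        else:
            p = float(hypergeom.sf(k_overlap - 1, m_total, len(mem), n_study))
        rows.append({
            "set": name,
            "namespace": (namespaces or {}).get(name, ""),
            "size": len(mem),
            "overlap": k_overlap,
            "p": min(p, 1.0),
            "members": ";".join(sorted(study & mem)),
        })
    result = pd.DataFrame(rows)
    if result.empty:
        return result.assign(p_adj=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    result["p_adj"] = np.nan
    groups = (result.groupby("namespace").groups.items()
              if (per_namespace and namespaces) else [("", result.index)])
    for _, idx in groups:
        result.loc[idx, "p_adj"] = multipletests(result.loc[idx, "p"], method="fdr_bh")[1]
    result["significant"] = result["p_adj"] < 0.05
    return result.sort_values(["p_adj", "p", "set"], kind="stable").reset_index(drop=True)
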