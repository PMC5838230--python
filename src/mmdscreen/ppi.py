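"""Protein-protein interaction overlay for the phenotype network.

Consumes a local STRING-style edge list (geneA, geneB, combined score),
relabels phenotype-network nodes by their target gene symbols, and compares
phenotype closeness with known physical interaction: pairs close in
phenotype space but absent from the PPI network are the hypothesis-generating
candidates, while shared edges corroborate known complexes. Anchor queries
highlight the first neighbours of a gene or gene pair of primary interest.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import SchemaError
from .network import PhenotypeNetwork

PPI_COLUMNS = ("geneA", "geneB", "confidence")


@dataclasses.dataclass
class PPINetwork:
    """Undirected, score-filtered protein interaction network."""

    graph: nx.Graph
    min_confidence: float
    source: str = ""

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def load_ppi_edges(
    path: str | Path,
    min_confidence: float = 0.7,
    *,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Load a STRING-style edge list, filter by confidence, deduplicate.

    Scores on the STRING 0-1000 combined-score scale (detected when the
    maximum score exceeds 1) are rescaled to [0, 1]. Duplicate and reversed
    edges keep the maximum confidence; self-edges are dropped.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    rename = {v: k for k, v in (columns or {}).items()}
    df = df.rename(columns=rename)
    if "confidence" not in df.columns and "combined_score" in df.columns:
        df = df.rename(columns={"combined_score": "confidence"})
    missing = [c for c in PPI_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing PPI column(s) {missing}")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    if conf.isna().any():
        row = int(conf.isna().idxmax()) + 2
        raise SchemaError(f"{path.name}: non-numeric confidence at line {row}")
    if conf.max() > 1:
        conf = conf / 1000.0  # STRING combined scores are on 0-1000
    g = nx.Graph()
    for a, b, c in zip(df["geneA"].astype(str), df["geneB"].astype(str), conf):
        if a == b or c < min_confidence:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], float(c))
        else:
            g.add_edge(a, b, confidence=float(c))
    return PPINetwork(graph=g, min_confidence=min_confidence, source=str(path))


def write_ppi_edges(ppi: PPINetwork, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"geneA": a, "geneB": b, "confidence": d["confidence"]}
        for a, b, d in ppi.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=list(PPI_COLUMNS)).to_csv(path, sep="\t", index=False)
    return path


def map_constructs_to_genes(
    net: PhenotypeNetwork,
    mapping: Mapping[str, str],
    *,
    collapse: str = "min",
) -> PhenotypeNetwork:
    """Relabel phenotype-network nodes by gene symbol.

    ``mapping`` maps construct labels (either the bare population id or the
    set-qualified node label) to gene symbols. Multiple constructs targeting
    one gene collapse into a single node; parallel edges keep the minimum
    MMD (closest-construct semantics) or the mean, per ``collapse``.
    """
    if collapse not in ("min", "mean"):
        raise ValueError("collapse must be 'min' or 'mean'")

    def gene_of(node: str) -> str | None:
        if node in mapping:
            return mapping[node]
        pop = net.graph.nodes[node].get("population_id", node)
        return mapping.get(pop)

    unmapped = [n for n in net.graph.nodes if gene_of(n) is None]
    if unmapped:
        raise KeyError(f"unmapped construct(s): {sorted(unmapped)}")

    g = nx.Graph()
    for node in net.graph.nodes:
        gene = gene_of(node)
        if gene in g:
            g.nodes[gene]["constructs"].append(node)
        else:
            g.add_node(gene, constructs=[node])
    weights: dict[tuple[str, str], list[float]] = {}
    for u, v, d in net.graph.edges(data=True):
        gu, gv = gene_of(u), gene_of(v)
        if gu == gv:
            continue  # constructs of the same gene merge into one node
        key = tuple(sorted((gu, gv)))
        weights.setdefault(key, []).append(d["mmd"])
    for (gu, gv), ws in weights.items():
        w = min(ws) if collapse == "min" else sum(ws) / len(ws)
        g.add_edge(gu, gv, mmd=float(w))
    for node in g.nodes:
        g.nodes[node]["constructs"] = ";".join(sorted(g.nodes[node]["constructs"]))
    return PhenotypeNetwork(graph=g, threshold=net.threshold, condition=net.condition)


def anchor_neighborhood(
    graph: nx.Graph, anchor: str | Sequence[str]
) -> tuple[set[str], set[tuple[str, str]]]:
    """First neighbours of an anchor node or anchor edge (gene pair).

    For an anchor edge the neighbour set is the union of both endpoints'
    neighbours, excluding the endpoints themselves; the returned edge set
    contains every edge from an anchor gene to a highlighted neighbour (plus
    the anchor edge itself when present).
    """
    if isinstance(anchor, str):
        anchors = [anchor]
    else:
        anchors = list(anchor)
        if len(anchors) not in (1, 2):
            raise ValueError("anchor must be a single gene or a gene pair")
    missing = [a for a in anchors if a not in graph]
    if missing:
        raise KeyError(f"anchor gene(s) not in network: {missing}")
    neighbours: set[str] = set()
    for a in anchors:
        neighbours.update(graph.neighbors(a))
    neighbours -= set(anchors)
    edges = {
        tuple(sorted((a, n))) for a in anchors for n in graph.neighbors(a) if n in neighbours
    }
    if len(anchors) == 2 and graph.has_edge(*anchors):
        edges.add(tuple(sorted(anchors)))
    return neighbours, edges


@dataclasses.dataclass
class OverlayReport:
    """Partition of gene pairs by phenotype-network vs PPI-network support."""

    both: set[tuple[str, str]]
    phenotype_only: set[tuple[str, str]]
    ppi_only: set[tuple[str, str]]
    shared_genes: set[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, pairs in (
            ("both", self.both),
            ("phenotype_only", self.phenotype_only),
            ("ppi_only", self.ppi_only),
        ):
            for a, b in sorted(pairs):
                rows.append({"geneA": a, "geneB": b, "category": cat})
        return pd.DataFrame(rows, columns=["geneA", "geneB", "category"])


def overlay_networks(
    pheno: PhenotypeNetwork, ppi: PPINetwork, *, restrict_ppi_to_shared: bool = True
) -> OverlayReport:
    """Classify gene pairs as supported by both networks, phenotype closeness
    only, or physical interaction only.

    ``restrict_ppi_to_shared`` limits PPI-only pairs to genes present in the
    phenotype network, mirroring a screen-hits STRING query; set it False to
    keep every PPI edge.
    """
    pheno_edges = {tuple(sorted(e)) for e in pheno.graph.edges}
    ppi_graph = ppi.graph
    shared = set(pheno.graph.nodes) & set(ppi_graph.nodes)
    if restrict_ppi_to_shared:
        ppi_edges = {
            tuple(sorted((u, v)))
            for u, v in ppi_graph.edges
            if u in shared and v in shared
        }
    else:
        ppi_edges = {tuple(sorted(e)) for e in ppi_graph.edges}
    return OverlayReport(
        both=pheno_edges & ppi_edges,
        phenotype_only=pheno_edges - ppi_edges,
        ppi_only=ppi_edges - pheno_edges,
        shared_genes=shared,
    )
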