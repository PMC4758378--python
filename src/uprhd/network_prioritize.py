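"""Seed-centred interactome assembly and multi-evidence gene prioritization.

The interactome is built around seed proteins (by default the UPR sensor
and effector genes ATF6, ATF4, DDIT3, EIF2AK3, ERN1 and XBP1): it contains
the seeds plus their direct interaction partners, with edges among included
nodes retained (induced subgraph; a flag restricts to seed-neighbor edges
only). Annotation gene lists are overlaid to count, e.g., apoptosis
proteins inside the interactome and, among those, HTT interactors with
their direct/indirect interaction type. Finally, tri-set prioritization
intersects a differential consensus signature, an HD therapeutic-target
list and the HTT interactor list, and joins promoter motif flags and
CAG-correlation statistics into one record per candidate gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .consensus import ConsensusSignature
from .io_gene_sets import GeneSet
from .motif_scan import MotifHitTable

logger = logging.getLogger(__name__)

UPR_SEED_GENES = ("ATF6", "ATF4", "DDIT3", "EIF2AK3", "ERN1", "XBP1")


@dataclass
class InteractionNetwork:
    """Simple undirected graph with flagged seed nodes."""

    graph: nx.Graph
    seeds: frozenset[str]

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def _normalize_edges(edges: Iterable) -> list[tuple[str, str, dict]]:
    out = []
    if isinstance(edges, pd.DataFrame):
        cols = list(edges.columns)
        for row in edges.itertuples(index=False):
            a, b = str(row[0]).upper(), str(row[1]).upper()
            attrs = {cols[i]: row[i] for i in range(2, len(cols))}
            out.append((a, b, attrs))
    else:
        for e in edges:
            a, b = str(e[0]).upper(), str(e[1]).upper()
            attrs = {"source": e[2]} if len(e) > 2 else {}
            out.append((a, b, attrs))
    return out


def build_interactome(
    edges: Iterable,
    seeds: Sequence[str] = UPR_SEED_GENES,
    induced: bool = True,
) -> InteractionNetwork:
    """Seed nodes plus their 1-hop neighbors.

    Self-loops and duplicate edges are discarded. With ``induced=True``
    (default) all edges among included nodes are kept; otherwise only
    seed-neighbor edges. Raises if no seed occurs in the edge list.
    """
    if not seeds:
        raise ValueError("at least one seed node required")
    seed_set = frozenset(str(s).upper() for s in seeds)
    full = nx.Graph()
    for a, b, attrs in _normalize_edges(edges):
        if a == b:
            continue
        full.add_edge(a, b, **attrs)
    present = seed_set & set(full.nodes)
    if not present:
        raise ValueError("no seed gene present in the edge list")
    keep = set(present)
    for s in present:
        keep.update(full.neighbors(s))
    if induced:
        sub = full.subgraph(keep).copy()
    else:
        sub = nx.Graph()
        sub.add_nodes_from(keep)
        for s in present:
            for nbr in full.neighbors(s):
                sub.add_edge(s, nbr, **full.edges[s, nbr])
    return InteractionNetwork(graph=sub, seeds=seed_set)


def overlay_annotation(
    net: InteractionNetwork,
    annotation: GeneSet | Iterable[str],
) -> tuple[pd.DataFrame, int]:
    """Per-node membership flags for an annotation list plus the overlap count."""
    ann = annotation.members if isinstance(annotation, GeneSet) else frozenset(str(g).upper() for g in annotation)
    nodes = sorted(net.nodes)
    flags = [n in ann for n in nodes]
    table = pd.DataFrame({"node": nodes, "annotated": flags, "is_seed": [n in net.seeds for n in nodes]})
    return table, int(sum(flags))


def cross_annotation(
    net: InteractionNetwork,
    annot_a: GeneSet | Iterable[str],
    annot_b_with_type: Mapping[str, str] | pd.DataFrame,
) -> pd.DataFrame:
    """Nodes carrying both annotations, with the interaction type of the second.

    ``annot_b_with_type`` maps gene -> 'direct'/'indirect' (a two-column
    frame is accepted; conflicting duplicate types raise). Columns of the
    result: gene, interaction_type.
    """
    a = annot_a.members if isinstance(annot_a, GeneSet) else frozenset(str(g).upper() for g in annot_a)
    if isinstance(annot_b_with_type, pd.DataFrame):
        types: dict[str, str] = {}
        for gene, typ in annot_b_with_type.itertuples(index=False):
            g = str(gene).upper()
            t = str(typ).lower()
            if g in types and types[g] != t:
                raise ValueError(f"conflicting interaction types for {g}: {types[g]} vs {t}")
            types[g] = t
    else:
        types = {str(g).upper(): str(t).lower() for g, t in annot_b_with_type.items()}
    both = sorted(net.nodes & a & set(types))
    return pd.DataFrame({"gene": both, "interaction_type": [types[g] for g in both]})


def triset_prioritize(
    diff_upr: ConsensusSignature | Sequence[ConsensusSignature] | Iterable[str],
    hdtt: GeneSet | Iterable[str],
    htt_int_types: Mapping[str, str],
    motif_table: MotifHitTable | pd.DataFrame | None = None,
    corr_records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One record per gene common to the differential-UPR, HDTT and HTT-interactor lists.

    Motif flags (per pattern) and CAG-correlation rho / fdr_cor are joined
    where available, left undefined (NA) otherwise. Sorted by correlation
    significance (ascending fdr, unknowns last), then gene.
    """
    directions: dict[str, str] = {}
    if isinstance(diff_upr, ConsensusSignature):
        sigs = [diff_upr]
    else:
        items = list(diff_upr)
        if items and isinstance(items[0], ConsensusSignature):
            sigs = items
        else:
            sigs = [ConsensusSignature(direction="na", genes=frozenset(str(g).upper() for g in items))]
    diff_genes: set[str] = set()
    for sig in sigs:
        for g in sig.genes:
            diff_genes.add(g)
            directions[g] = sig.direction
    hdtt_set = hdtt.members if isinstance(hdtt, GeneSet) else frozenset(str(g).upper() for g in hdtt)
    types = {str(g).upper(): str(t).lower() for g, t in htt_int_types.items()}
    common = sorted(diff_genes & hdtt_set & set(types))

    presence = None
    if isinstance(motif_table, MotifHitTable):
        presence = motif_table.presence
    elif isinstance(motif_table, pd.DataFrame):
        presence = motif_table.astype(bool)

    corr = None
    if corr_records is not None:
        corr = corr_records.set_index(corr_records["gene"].astype(str).str.upper())

    rows = []
    for g in common:
        row: dict = {
            "gene": g,
            "direction": directions.get(g, "na"),
            "htt_interaction": types[g],
        }
        if presence is not None:
            for pattern in presence.columns:
                row[pattern] = bool(presence.loc[g, pattern]) if g in presence.index else pd.NA
        if corr is not None and g in corr.index:
            row["rho"] = float(corr.loc[g, "rho"])
            row["fdr_cor"] = float(corr.loc[g, "fdr_cor"])
        else:
            row["rho"] = np.nan
            row["fdr_cor"] = np.nan
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(
            ["fdr_cor", "gene"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> pd.DataFrame:
    """TSV edge list: geneA, geneB and optional extra columns (type, source)."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    frame.iloc[:, 0] = frame.iloc[:, 0].astype(str).str.upper()
    frame.iloc[:, 1] = frame.iloc[:, 1].astype(str).str.upper()
    return frame


def write_sif(net: InteractionNetwork, path: str | Path, relation: str = "pp") -> None:
    with Path(path).open("w") as fh:
        for a, b in net.edges():
            fh.write(f"{a}\t{relation}\t{b}\n")


def write_node_edge_tables(net: InteractionNetwork, nodes_path: str | Path, edges_path: str | Path) -> None:
    nodes = pd.DataFrame(
        {"node": sorted(net.nodes), "is_seed": [n in net.seeds for n in sorted(net.nodes)]}
    )
    nodes.to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(net.edges(), columns=["geneA", "geneB"]).to_csv(edges_path, sep="\t", index=False)
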