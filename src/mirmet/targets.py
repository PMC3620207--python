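"""Canonical seed-match target prediction and the miRNA–target network.

A target site is the reverse complement of the miRNA seed in a 3'UTR,
classified by the standard taxonomy: an 8mer is a perfect match to miRNA
nucleotides 2–8 followed by an A opposite nucleotide 1; a 7mer-m8 is the
nt 2–8 match alone; a 7mer-A1 is the nt 2–7 match plus the t1 A.  At one
UTR position only the highest tier is reported (8mer > 7mer-m8 > 7mer-A1).
Predicted (miRNA, gene) pairs form a bipartite regulatory network; genes
regulated by many miRNAs ("hubs") are reported by degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

_COMP = str.maketrans("ACGU", "UGCA")

SITE_TIERS = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class TargetSite:
    mir_name: str
    gene_id: str
    site_type: str   # 8mer | 7mer-m8 | 7mer-A1
    utr_position: int  # 0-based start of the matched site in the UTR


def _rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU(T) characters in sequence: {sorted(bad)}")
    return seq


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seed_patterns(mir_seq: str) -> dict[str, str]:
    """The three site patterns (UTR sense, 5'→3') for one mature miRNA."""
    m = _rna(mir_seq)
    if len(m) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    return {
        "8mer": _revcomp(m[1:8]) + "A",
        "7mer-m8": _revcomp(m[1:8]),
        "7mer-A1": _revcomp(m[1:7]) + "A",
    }


def find_sites(mir_seq: str, utr: str, mir_name: str = "", gene_id: str = "") -> list[TargetSite]:
    """All seed sites of one miRNA in one UTR (highest tier per position)."""
    u = _rna(utr)
    if len(u) < 7:
        raise ValueError("UTR must be at least 7 nt")
    pats = seed_patterns(mir_seq)
    sites: list[TargetSite] = []
    for i in range(len(u) - 6):
        if u[i:i + 8] == pats["8mer"]:
            tier = "8mer"
        elif u[i:i + 7] == pats["7mer-m8"]:
            tier = "7mer-m8"
        elif u[i:i + 7] == pats["7mer-A1"]:
            tier = "7mer-A1"
        else:
            continue
        sites.append(TargetSite(mir_name, gene_id, tier, i))
    return sites


def predict_targets(
    mirnas: dict[str, str], utrs: dict[str, str],
    extra_sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Site table for every (miRNA, UTR) combination.

    ``extra_sites`` merges an externally predicted site table (columns
    mir_name, gene_id, site_type, utr_position) as a union, with a
    ``source`` column recording provenance.
    """
    rows = [
        (s.mir_name, s.gene_id, s.site_type, s.utr_position, "seed-match")
        for name, mseq in mirnas.items()
        for gene, useq in utrs.items()
        for s in find_sites(mseq, useq, name, gene)
    ]
    table = pd.DataFrame(
        rows, columns=["mir_name", "gene_id", "site_type", "utr_position", "source"]
    )
    if extra_sites is not None and len(extra_sites):
        ext = extra_sites.copy()
        if "source" not in ext.columns:
            ext["source"] = "external"
        table = (
            pd.concat([table, ext[table.columns]], ignore_index=True)
            .drop_duplicates(["mir_name", "gene_id", "site_type", "utr_position"])
            .reset_index(drop=True)
        )
    return table


def build_network(sites: pd.DataFrame, min_sites_per_edge: int = 1) -> nx.Graph:
    """Bipartite miRNA–gene graph with one edge per supported pair."""
    g = nx.Graph()
    if len(sites) == 0:
        return g
    counts = sites.groupby(["mir_name", "gene_id"]).size()
    for (mir, gene), n_sites in counts.items():
        if n_sites < min_sites_per_edge:
            continue
        g.add_node(mir, kind="mirna")
        g.add_node(gene, kind="gene")
        g.add_edge(mir, gene, n_sites=int(n_sites))
    return g


def network_tables(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(nodes, edges) tables with per-node degree."""
    nodes = pd.DataFrame(
        [(n, d["kind"], g.degree(n)) for n, d in g.nodes(data=True)],
        columns=["node", "kind", "degree"],
    ).sort_values(["kind", "node"], kind="mergesort").reset_index(drop=True)
    edges = pd.DataFrame(
        [(u, v, d["n_sites"]) if g.nodes[u]["kind"] == "mirna" else (v, u, d["n_sites"])
         for u, v, d in g.edges(data=True)],
        columns=["mir_name", "gene_id", "n_sites"],
    ).sort_values(["mir_name", "gene_id"], kind="mergesort").reset_index(drop=True)
    return nodes, edges


def hub_report(g: nx.Graph, min_degree: int = 5) -> pd.DataFrame:
    """Genes regulated by at least ``min_degree`` miRNAs, by degree desc."""
    rows = [
        (n, g.degree(n)) for n, d in g.nodes(data=True)
        if d["kind"] == "gene" and g.degree(n) >= min_degree
    ]
    return (
        pd.DataFrame(rows, columns=["gene_id", "degree"])
        .sort_values(["degree", "gene_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """Simple-interaction-format export (mir <tab> targets <tab> gene)."""
    _, edges = network_tables(g)
    with open(path, "w") as fh:
        for r in edges.itertuples():
            fh.write(f"{r.mir_name}\ttargets\t{r.gene_id}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)
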