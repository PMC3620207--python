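"""Hypergeometric over-representation analysis of gene sets.

Given a query gene list (here: predicted miRNA targets), a GMT collection
of gene sets and a gene universe, each set with at least one overlapping
gene is scored by the upper-tail hypergeometric probability
P(X >= k) for X ~ Hypergeometric(N, K, n), then adjusted across sets
(Benjamini–Hochberg by default, Bonferroni by flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    k: int            # overlap size
    K: int            # set size within the universe
    n: int            # query size within the universe
    N: int            # universe size
    p_value: float
    adj_p: float = float("nan")
    overlap_ids: list[str] = field(default_factory=list)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) (log-space stable tail)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
        sets[parts[0]] = list(dict.fromkeys(parts[2:]))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def enrich(
    query: set[str],
    gene_sets: dict[str, list[str]],
    universe: set[str] | None = None,
    method: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` against every gene set.

    ``universe`` defaults to all genes annotated in ``gene_sets``.  Query
    IDs outside the universe are dropped with a warning.  Returns one row
    per set with k >= 1, BH- (or Bonferroni-) adjusted, sorted by adjusted
    p then set name, with Table-style columns (pathway, number of genes,
    gene IDs, p-values).
    """
    if universe is None:
        universe = set().union(*gene_sets.values()) if gene_sets else set()
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    dropped = query - universe
    if dropped:
        log.warning("%d query IDs outside the universe were dropped", len(dropped))
    q = set(query) & universe
    results: list[EnrichmentResult] = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        overlap = sorted(members & q)
        if not overlap:
            continue
        p = hypergeom_upper(len(overlap), len(members), len(q), len(universe))
        results.append(EnrichmentResult(
            set_name=name, k=len(overlap), K=len(members), n=len(q),
            N=len(universe), p_value=p, overlap_ids=overlap,
        ))
    if not results:
        return pd.DataFrame(columns=["pathway", "number_of_genes", "gene_ids",
                                     "p_value", "adj_p", "K", "n", "N"])
    pvals = [r.p_value for r in results]
    if method.upper() == "BH":
        adj = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
    elif method.lower() == "bonferroni":
        adj = multipletests(pvals, alpha=alpha, method="bonferroni")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    table = pd.DataFrame({
        "pathway": [r.set_name for r in results],
        "number_of_genes": [r.k for r in results],
        "gene_ids": [" ".join(r.overlap_ids) for r in results],
        "p_value": [r.p_value for r in results],
        "adj_p": [r.adj_p for r in results],
        "K": [r.K for r in results],
        "n": [r.n for r in results],
        "N": [r.N for r in results],
    })
    return table.sort_values(["adj_p", "pathway"], kind="mergesort").reset_index(drop=True)
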