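"""Hierarchical small-RNA annotation of clean tags.

Each uniquely mapped tag receives exactly one category by walking a fixed
priority order (default miRNA > rRNA > tRNA > snRNA > snoRNA > repeat >
exon > intron > unannotated).  The miRNA category is a sequence match to a
mature miRNA (exact, or a 3' length variant up to ±2 nt with the same 5'
end); every other category is an exact-locus overlap with a typed feature
interval.  Matching against the genome is exact on both strands; tags with
no locus or more than ``max_hits`` loci are excluded from category
assignment but kept in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .reference import ReferenceBundle, revcomp

DEFAULT_PRIORITY = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA",
                    "repeat", "exon", "intron")
CATEGORIES = DEFAULT_PRIORITY + ("unannotated",)


@dataclass
class AnnotateConfig:
    max_hits: int = 1
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    mirna_3p_tolerance: int = 2  # allowed 3' length difference vs the mature

    def __post_init__(self) -> None:
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


def _find_all(haystack: str, needle: str) -> list[int]:
    out, pos = [], haystack.find(needle)
    while pos >= 0:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def map_tags(tags: pd.DataFrame, bundle: ReferenceBundle,
             max_hits: int = 1) -> pd.DataFrame:
    """Exact genome loci (both strands) per tag.

    Adds columns ``loci`` (list of (contig, start, end, strand)),
    ``genome_hits`` and ``map_status`` in {unique..., unmapped,
    multi_mapped}; only tags with 1..max_hits loci keep status 'mapped'.
    """
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    loci_col, status_col = [], []
    contigs = sorted(bundle.genome)
    for seq in tags["sequence"]:
        loci = []
        for c in contigs:
            g = bundle.genome[c]
            for p in _find_all(g, seq):
                loci.append((c, p, p + len(seq), "+"))
            for p in _find_all(g, revcomp(seq)):
                loci.append((c, p, p + len(seq), "-"))
        loci_col.append(loci)
        if not loci:
            status_col.append("unmapped")
        elif len(loci) > max_hits:
            status_col.append("multi_mapped")
        else:
            status_col.append("mapped")
    out = tags.copy()
    out["loci"] = loci_col
    out["genome_hits"] = [len(l) for l in loci_col]
    out["map_status"] = status_col
    return out


def _mature_lookup(bundle: ReferenceBundle, tol: int) -> dict[str, str]:
    """Map every acceptable tag sequence (3' variants) to its miRNA name."""
    lut: dict[str, str] = {}
    for name, m in bundle.mature_mirnas.items():
        for d in range(0, tol + 1):
            if len(m) - d >= 1:
                lut.setdefault(m[: len(m) - d], name)
    return lut


def classify(mapped: pd.DataFrame, bundle: ReferenceBundle,
             config: AnnotateConfig | None = None) -> pd.DataFrame:
    """Assign one category per mapped tag (see module docstring)."""
    cfg = config or AnnotateConfig()
    trees: dict[str, IntervalTree] = {}
    for f in bundle.ncrna_features:
        trees.setdefault(f.contig, IntervalTree())[f.start:f.end] = f
    mat_lut = _mature_lookup(bundle, cfg.mirna_3p_tolerance)
    exact = {m: n for n, m in bundle.mature_mirnas.items()}

    def mirna_match(seq: str) -> str | None:
        if seq in mat_lut:
            return mat_lut[seq]
        for d in range(1, cfg.mirna_3p_tolerance + 1):  # tag longer than mature
            if len(seq) - d >= 1 and seq[: len(seq) - d] in exact:
                return exact[seq[: len(seq) - d]]
        return None

    cats, ids = [], []
    for row in mapped.itertuples():
        if row.map_status != "mapped":
            cats.append("excluded")
            ids.append("")
            continue
        category, matched = "unannotated", ""
        overlaps: dict[str, str] = {}
        for contig, start, end, _strand in row.loci:
            if contig in trees:
                for iv in sorted(trees[contig].overlap(start, end),
                                 key=lambda iv: iv.data.name):
                    overlaps.setdefault(iv.data.type, iv.data.name)
        for cat in cfg.priority:
            if cat == "miRNA":
                hit = mirna_match(row.sequence)
                if hit is not None:
                    category, matched = "miRNA", hit
                    break
            elif cat in overlaps:
                category, matched = cat, overlaps[cat]
                break
        cats.append(category)
        ids.append(matched)
    out = mapped.copy()
    out["category"] = cats
    out["matched_id"] = ids
    return out


def category_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-category read counts and fractions per library (retained tags)."""
    retained = annotated[annotated["map_status"] == "mapped"]
    rows = []
    for cat in CATEGORIES:
        sel = retained[retained["category"] == cat]
        rows.append((cat, int(sel["count_bm"].sum()), int(sel["count_nm"].sum())))
    out = pd.DataFrame(rows, columns=["category", "count_bm", "count_nm"])
    for lib in ("bm", "nm"):
        total = out[f"count_{lib}"].sum()
        out[f"frac_{lib}"] = out[f"count_{lib}"] / total if total else 0.0
    return out


def mirna_counts(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA counts aggregated over matching tags (columns for DE)."""
    sel = annotated[(annotated["map_status"] == "mapped")
                    & (annotated["category"] == "miRNA")]
    agg = (sel.groupby("matched_id")[["count_bm", "count_nm"]].sum()
           .reset_index().rename(columns={"matched_id": "mir_name"}))
    return agg.sort_values("mir_name").reset_index(drop=True)
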