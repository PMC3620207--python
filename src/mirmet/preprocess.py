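"""Raw FASTQ -> clean, collapsed sequence tags.

The cleaner locates the 3' adapter (first exact occurrence, falling back
to the longest adapter-prefix overlap at the read end, at least
``min_overlap`` nt), trims it, and discards reads that fail mean-quality,
contain N, lack the adapter, or whose trimmed insert falls outside the
clean-length window (default 12–30 nt).  Survivors are collapsed to unique
tags with per-library counts; every input read is accounted for in the run
report (clean + per-reason discards = input).
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

DISCARD_REASONS = ("low_quality", "contains_n", "no_adapter", "too_short", "too_long")


@dataclass
class CleanParams:
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 7        # shortest adapter-prefix overlap at read end
    min_quality: float = 20.0   # mean Phred threshold
    min_len: int = 12
    max_len: int = 30

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass
class CleanResult:
    tags: Counter = field(default_factory=Counter)   # insert sequence -> count
    n_input: int = 0
    n_clean: int = 0
    discards: Counter = field(default_factory=Counter)

    def report(self) -> dict:
        rep = {
            "input_reads": self.n_input,
            "clean_reads": self.n_clean,
            "unique_tags": len(self.tags),
            "discards": {r: int(self.discards.get(r, 0)) for r in DISCARD_REASONS},
        }
        assert self.n_input == self.n_clean + sum(self.discards.values()), \
            "read accounting identity violated"
        return rep


def trim_adapter(seq: str, adapter: str, min_overlap: int = 7) -> str | None:
    """Insert portion of a read, or None when no adapter is found.

    First exact occurrence of the full adapter wins; otherwise the longest
    suffix of the read equal to an adapter prefix of >= min_overlap nt.
    """
    pos = seq.find(adapter)
    if pos >= 0:
        return seq[:pos]
    for k in range(min(len(adapter) - 1, len(seq)), min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k]
    return None


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def clean_reads(fastq_path: str | Path, params: CleanParams | None = None) -> CleanResult:
    """Clean one FASTQ(.gz) library into collapsed tags plus a run report."""
    params = params or CleanParams()
    res = CleanResult()
    path = Path(fastq_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                res.n_input += 1
                seq = seq.upper()
                if _mean_phred(qual) < params.min_quality:
                    res.discards["low_quality"] += 1
                    continue
                if "N" in seq:
                    res.discards["contains_n"] += 1
                    continue
                insert = trim_adapter(seq, params.adapter, params.min_overlap)
                if insert is None:
                    res.discards["no_adapter"] += 1
                    continue
                if len(insert) < params.min_len:
                    res.discards["too_short"] += 1
                    continue
                if len(insert) > params.max_len:
                    res.discards["too_long"] += 1
                    continue
                res.tags[insert] += 1
                res.n_clean += 1
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record near read {res.n_input + 1} in {path}: {exc}"
            ) from exc
    if res.n_input == 0:
        log.warning("empty FASTQ input: %s", path)
    return res


def merge_libraries(bm: CleanResult, nm: CleanResult) -> pd.DataFrame:
    """Tag table with per-library counts (columns: sequence, count_bm, count_nm)."""
    seqs = sorted(set(bm.tags) | set(nm.tags))
    return pd.DataFrame({
        "sequence": seqs,
        "count_bm": [bm.tags.get(s, 0) for s in seqs],
        "count_nm": [nm.tags.get(s, 0) for s in seqs],
    })


def summarize_lengths(tags: pd.DataFrame, min_len: int = 1, max_len: int = 35) -> pd.DataFrame:
    """Per-length read counts and fractions per library, count-weighted.

    Fractions are 0 (not NaN) for an empty library.  The 20–24 nt mass is
    the conventional mature-miRNA window summary.
    """
    lengths = range(min_len, max_len + 1)
    out = pd.DataFrame({"length": list(lengths)})
    for lib in ("bm", "nm"):
        col = f"count_{lib}"
        per = {l: 0 for l in lengths}
        if len(tags):
            grouped = tags.assign(L=tags["sequence"].str.len()).groupby("L")[col].sum()
            for l, c in grouped.items():
                per[int(l)] = int(c)
        total = sum(per.values())
        out[col] = [per[l] for l in lengths]
        out[f"frac_{lib}"] = [c / total if total else 0.0 for c in out[col]]
    return out


def mass_20_24(dist: pd.DataFrame) -> dict[str, float]:
    """Fraction of reads with length 20–24 nt, per library."""
    sel = dist["length"].between(20, 24)
    return {lib: float(dist.loc[sel, f"frac_{lib}"].sum()) for lib in ("bm", "nm")}


def write_collapsed_fasta(tags: pd.DataFrame, lib: str, path: str | Path) -> None:
    """Collapsed-tag FASTA with `>tagK_xCOUNT` headers for one library."""
    col = f"count_{lib}"
    with open(path, "w") as fh:
        k = 0
        for r in tags.itertuples():
            count = getattr(r, col)
            if count > 0:
                k += 1
                fh.write(f">tag{k}_x{count}\n{r.sequence}\n")
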