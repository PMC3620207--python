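"""Novel miRNA discovery from unannotated, uniquely mapped tags.

Loci of unannotated tags are clustered; around each cluster's most
abundant tag a genomic window (default 100 nt flanks, both strands) is
folded, and the window is accepted as a hairpin candidate when the tag
behaves like a Dicer product: it lies fully on one arm, at least 16 of its
bases pair into the stem with all partners on the opposite arm, the loop
between the arms is 4–30 nt, and the folded precursor reaches the
free-energy threshold (default −18 kcal/mol).  Candidates overlapping on
the genome are deduplicated keeping the lowest energy; a second tag on the
opposite arm whose 3' end shows the 2-nt Dicer overhang marks star
support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fold import FoldBackend, pair_partners
from .fold import fold as _default_fold
from .reference import ReferenceBundle, revcomp

log = logging.getLogger(__name__)


@dataclass
class NovelConfig:
    flank: int = 100
    mfe_threshold: float = -18.0   # kcal/mol
    min_paired_mature: int = 16
    loop_range: tuple[int, int] = (4, 30)
    min_tag_count: int = 5         # mature read support to seed a cluster
    cluster_gap: int = 30
    mature_len_range: tuple[int, int] = (18, 26)


@dataclass
class HairpinCandidate:
    name: str
    contig: str
    start: int            # precursor genome interval, 0-based half-open
    end: int
    strand: str
    precursor_seq: str
    structure: str
    mfe: float
    mature_seq: str
    mature_offset: int    # 0-based start of the mature within the precursor
    mature_arm: str       # 5p | 3p
    star_support: bool
    first_nt: str
    count_bm: int
    count_nm: int

    def validate(self, mfe_threshold: float) -> None:
        assert len(self.structure) == len(self.precursor_seq)
        partner = pair_partners(self.structure)  # raises if unbalanced
        ms, me = self.mature_offset, self.mature_offset + len(self.mature_seq)
        assert self.precursor_seq[ms:me] == self.mature_seq
        pairs = [int(partner[i]) for i in range(ms, me) if partner[i] >= 0]
        assert pairs, "mature has no paired base"
        # fully within one arm: no partner inside the mature itself
        assert all(p >= me or p < ms for p in pairs), "mature overlaps the loop"
        assert self.mfe <= mfe_threshold
        assert self.first_nt == self.mature_seq[0]


def _clusters(loci: list[tuple], gap: int):
    """Greedy clustering of sorted (contig, start, end, strand, row) loci."""
    current: list[tuple] = []
    for loc in sorted(loci, key=lambda t: (t[0], t[1], t[2])):
        if current and (loc[0] != current[-1][0] or loc[1] > current[-1][2] + gap):
            yield current
            current = []
        current.append(loc)
    if current:
        yield current


def _arm_geometry(partner: np.ndarray, ms: int, me: int,
                  cfg: NovelConfig) -> tuple[str, int, int, int] | None:
    """Check Dicer-consistency of the mature at [ms, me) in a structure.

    Returns (arm, duplex_min, duplex_max, n_paired) or None when rejected.
    """
    pairs = [(i, int(partner[i])) for i in range(ms, me) if partner[i] >= 0]
    if len(pairs) < cfg.min_paired_mature:
        return None
    partners = [p for _, p in pairs]
    if all(p >= me for p in partners):
        arm = "5p"
        inner_i = max(i for i, _ in pairs)
        loop_len = min(partners) - inner_i - 1
    elif all(p < ms for p in partners):
        arm = "3p"
        inner_i = min(i for i, _ in pairs)
        loop_len = inner_i - max(partners) - 1
    else:
        return None
    if not cfg.loop_range[0] <= loop_len <= cfg.loop_range[1]:
        return None
    return arm, min(partners), max(partners), len(pairs)


def detect_candidates(annotated: pd.DataFrame, bundle: ReferenceBundle,
                      config: NovelConfig | None = None,
                      fold: FoldBackend = _default_fold) -> list[HairpinCandidate]:
    """Hairpin candidates from the annotated tag table (see module doc)."""
    cfg = config or NovelConfig()
    unann = annotated[(annotated["map_status"] == "mapped")
                      & (annotated["category"] == "unannotated")]
    prec_iv = [(p.contig, p.start, p.end) for p in bundle.precursors]

    loci = []
    for row in unann.itertuples():
        contig, start, end, strand = row.loci[0]
        if any(c == contig and start < e and end > s for c, s, e in prec_iv):
            continue  # annotated miRNA locus, not novel
        loci.append((contig, start, end, strand, row))

    raw: list[HairpinCandidate] = []
    for cluster in _clusters(loci, cfg.cluster_gap):
        rep = max(cluster, key=lambda t: t[4].count_bm + t[4].count_nm)
        contig, rstart, rend, rstrand, rrow = rep
        total = rrow.count_bm + rrow.count_nm
        if total < cfg.min_tag_count:
            continue
        if not cfg.mature_len_range[0] <= len(rrow.sequence) <= cfg.mature_len_range[1]:
            continue
        glen = len(bundle.genome[contig])
        ws, we = max(0, rstart - cfg.flank), min(glen, rend + cfg.flank)
        if ws > rstart - cfg.flank or we < rend + cfg.flank:
            log.info("flank truncated at contig edge for locus %s:%d", contig, rstart)
        gslice = bundle.genome[contig][ws:we]
        for strand, wseq in (("+", gslice), ("-", revcomp(gslice))):
            cand = _evaluate_window(wseq, rrow, cluster, contig, ws, we, strand,
                                    cfg, fold)
            if cand is not None:
                raw.append(cand)

    raw = _dedup(raw)
    raw.sort(key=lambda c: (c.contig, c.start))
    out = []
    for k, c in enumerate(raw, 1):
        c.name = f"novel_mir_{k}"
        c.validate(cfg.mfe_threshold)
        out.append(c)
    return out


def _evaluate_window(wseq: str, rrow, cluster, contig: str, ws: int, we: int,
                     strand: str, cfg: NovelConfig,
                     fold: FoldBackend) -> HairpinCandidate | None:
    off = wseq.find(rrow.sequence)
    if off < 0:
        return None
    mlen = len(rrow.sequence)
    structure, _ = fold(wseq)
    partner = pair_partners(structure)
    geom = _arm_geometry(partner, off, off + mlen, cfg)
    if geom is None:
        return None
    _, pmin, pmax, _ = geom
    # trim to the duplex span (+3 nt so a Dicer-offset star read fits), refold
    ps = max(0, min(off, pmin) - 3)
    pe = min(len(wseq), max(off + mlen - 1, pmax) + 1 + 3)
    pseq = wseq[ps:pe]
    pstruct, pmfe = fold(pseq)
    ppartner = pair_partners(pstruct)
    pgeom = _arm_geometry(ppartner, off - ps, off - ps + mlen, cfg)
    if pgeom is None or pmfe > cfg.mfe_threshold:
        return None
    arm = pgeom[0]
    if strand == "+":
        gstart, gend = ws + ps, ws + pe
    else:
        gstart, gend = we - pe, we - ps
    star = _has_star(ppartner, off - ps, mlen, arm, cluster, rrow, strand,
                     gstart, gend, ws, we)
    return HairpinCandidate(
        name="", contig=contig, start=gstart, end=gend, strand=strand,
        precursor_seq=pseq, structure=pstruct, mfe=pmfe,
        mature_seq=rrow.sequence, mature_offset=off - ps, mature_arm=arm,
        star_support=star, first_nt=rrow.sequence[0],
        count_bm=int(rrow.count_bm), count_nm=int(rrow.count_nm))


def _has_star(partner: np.ndarray, ms: int, mlen: int, arm: str, cluster,
              rrow, strand: str, gstart: int, gend: int, ws: int, we: int) -> bool:
    """2-nt 3' overhang check for any other cluster tag on the opposite arm.

    With the duplex written (left tag x, right tag y) in precursor
    coordinates, Dicer processing leaves y's 3' end exactly 2 nt past the
    partner of x's first paired base.
    """
    for contig, tstart, tend, tstrand, trow in cluster:
        if trow.sequence == rrow.sequence or tstrand != strand:
            continue
        if tstart < gstart or tend > gend:
            continue
        if strand == "+":
            s, e = tstart - gstart, tend - gstart
        else:
            s, e = gend - tend, gend - tstart
        left, right = ((ms, ms + mlen), (s, e)) if arm == "5p" else ((s, e), (ms, ms + mlen))
        a, d = left[0], right[1]
        paired = [i for i in range(left[0], left[1]) if 0 <= i < len(partner) and partner[i] >= 0]
        if not paired:
            continue
        i0 = min(paired)
        if d == int(partner[i0]) + (i0 - a) + 3:
            return True
    return False


def _dedup(cands: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Among genome-overlapping candidates keep the lowest energy."""
    kept: list[HairpinCandidate] = []
    for c in sorted(cands, key=lambda c: (c.mfe, c.contig, c.start)):
        if not any(k.contig == c.contig and c.start < k.end and c.end > k.start
                   for k in kept):
            kept.append(c)
    return kept


def candidate_stats(candidates: list[HairpinCandidate]) -> dict:
    """Summary statistics of a candidate set (no NaNs on empty input)."""
    if not candidates:
        return {"count": 0, "shared": 0, "mean_mfe": 0.0, "min_mfe": 0.0,
                "max_mfe": 0.0, "mature_length_mode": 0,
                "first_nt_fractions": {b: 0.0 for b in "ACGT"}}
    mfes = [c.mfe for c in candidates]
    lengths = [len(c.mature_seq) for c in candidates]
    firsts = [c.first_nt for c in candidates]
    mode = int(pd.Series(lengths).mode().iloc[0])
    return {
        "count": len(candidates),
        "shared": sum(1 for c in candidates if c.count_bm > 0 and c.count_nm > 0),
        "mean_mfe": float(np.mean(mfes)),
        "min_mfe": float(np.min(mfes)),
        "max_mfe": float(np.max(mfes)),
        "mature_length_mode": mode,
        "first_nt_fractions": {b: firsts.count(b) / len(firsts) for b in "ACGT"},
    }


def candidates_table(candidates: list[HairpinCandidate]) -> pd.DataFrame:
    cols = ["name", "contig", "start", "end", "strand", "mfe", "mature_seq",
            "mature_arm", "star_support", "first_nt", "count_bm", "count_nm",
            "precursor_seq", "structure"]
    return pd.DataFrame([[getattr(c, k) for k in cols] for c in candidates],
                        columns=cols)
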