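"""Synthetic reference bundle for the two-library small-RNA experiment.

The bundle plays the role of the genome + annotation databases a real run
would download: a toy genome with known miRNA precursors written into it,
typed ncRNA/genic features, planted novel hairpin loci (inverted repeats
outside any annotation), per-gene 3'UTRs and GMT gene sets.  Everything is
deterministic in the seed.

Coordinates are 0-based half-open internally; GFF3 I/O converts to the
1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

FEATURE_TYPES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron")


class PlacementError(RuntimeError):
    """Raised when a feature cannot be placed without overlap."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Feature:
    name: str
    type: str
    contig: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"


@dataclass(frozen=True)
class Precursor:
    name: str
    contig: str
    start: int
    end: int
    strand: str
    seq: str
    mature_name: str
    arm: str  # 5p | 3p


@dataclass(frozen=True)
class NovelHairpin:
    """A planted novel-miRNA locus: inverted repeat outside any annotation."""
    name: str
    contig: str
    start: int
    end: int
    strand: str
    mature_seq: str   # read emitted from the 5' arm
    star_seq: str     # Dicer-offset read from the 3' arm
    mature_start: int  # genome coordinate of the mature read


@dataclass
class ReferenceConfig:
    contig_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 200_000})
    gc: float = 0.42
    n_mirna: int = 50
    mature_len_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.10, 21: 0.20, 22: 0.45, 23: 0.15, 24: 0.10})
    n_novel: int = 5
    novel_arm_len: int = 24
    novel_loop_range: tuple[int, int] = (6, 10)
    novel_u5_bias: float = 0.8
    n_features: dict[str, int] = field(default_factory=lambda: {
        "rRNA": 6, "tRNA": 20, "snRNA": 10, "snoRNA": 10,
        "repeat": 8, "exon": 15, "intron": 10})
    feature_len_ranges: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "rRNA": (500, 2000), "tRNA": (70, 90), "snRNA": (80, 150),
        "snoRNA": (60, 200), "repeat": (150, 400), "exon": (100, 300),
        "intron": (300, 800)})
    n_genes: int = 200
    utr_len_range: tuple[int, int] = (400, 2000)
    n_gene_sets: int = 20
    gene_set_size_range: tuple[int, int] = (10, 40)
    max_place_tries: int = 500


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    mature_mirnas: dict[str, str]
    precursors: list[Precursor]
    ncrna_features: list[Feature]
    utr3: dict[str, str]
    gene_sets: dict[str, list[str]]
    novel_loci: list[NovelHairpin]

    def validate(self) -> None:
        """Structural invariants; raises AssertionError on violation."""
        prec_by_mature: dict[str, int] = {}
        for p in self.precursors:
            sub = self.genome[p.contig][p.start:p.end]
            if p.strand == "-":
                sub = revcomp(sub)
            assert sub == p.seq, f"precursor {p.name} disagrees with genome"
            mat = self.mature_mirnas[p.mature_name]
            assert mat in p.seq, f"mature {p.mature_name} not in its precursor"
            prec_by_mature[p.mature_name] = prec_by_mature.get(p.mature_name, 0) + 1
        for name, seq in self.mature_mirnas.items():
            n_hosts = sum(seq in p.seq for p in self.precursors)
            assert n_hosts == 1, f"mature {name} found in {n_hosts} precursors"
        for f in self.ncrna_features:
            assert 0 <= f.start < f.end <= len(self.genome[f.contig]), \
                f"feature {f.name} outside contig bounds"
        for h in self.novel_loci:
            assert 0 <= h.start < h.end <= len(self.genome[h.contig])


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


class _Placer:
    """Tracks occupied intervals per contig; rejects overlapping placements."""

    def __init__(self, contig_lengths: dict[str, int], rng: np.random.Generator,
                 max_tries: int):
        self.lengths = contig_lengths
        self.rng = rng
        self.max_tries = max_tries
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}

    def place(self, length: int, what: str, margin: int = 30) -> tuple[str, int]:
        contigs = list(self.lengths)
        for _ in range(self.max_tries):
            contig = contigs[self.rng.integers(len(contigs))]
            clen = self.lengths[contig]
            if clen < length + 2 * margin:
                continue
            start = int(self.rng.integers(margin, clen - length - margin))
            if all(e <= start - margin or s >= start + length + margin
                   for s, e in self.occupied[contig]):
                self.occupied[contig].append((start, start + length))
                return contig, start
        raise PlacementError(
            f"could not place {what} (length {length}) without overlap after "
            f"{self.max_tries} tries; enlarge the contig or reduce feature counts")


def build_reference(config: ReferenceConfig | None = None, seed: int = 0) -> ReferenceBundle:
    """Build a ReferenceBundle deterministically from ``seed``."""
    cfg = config or ReferenceConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    genome = {c: list(_rand_seq(rng, n, cfg.gc)) for c, n in cfg.contig_lengths.items()}
    placer = _Placer(cfg.contig_lengths, rng, cfg.max_place_tries)

    lens = np.array(sorted(cfg.mature_len_weights))
    lenw = np.array([cfg.mature_len_weights[int(l)] for l in lens], dtype=float)
    lenw /= lenw.sum()

    matures: dict[str, str] = {}
    precursors: list[Precursor] = []
    for k in range(cfg.n_mirna):
        name = f"mir-{k + 1:03d}"
        while True:
            mlen = int(rng.choice(lens, p=lenw))
            mature = _rand_seq(rng, mlen, 0.5)
            if mature not in matures.values():
                break
        # star arm: reverse complement with a few interior mutations so the
        # mature sequence maps uniquely (one genomic locus, one strand)
        star = list(revcomp(mature))
        for pos in rng.choice(np.arange(3, mlen - 3), size=3, replace=False):
            cur = star[pos]
            star[pos] = str(rng.choice([b for b in "ACGT" if b != cur]))
        star = "".join(star)
        loop = _rand_seq(rng, int(rng.integers(8, 16)), 0.3)
        f5 = _rand_seq(rng, int(rng.integers(5, 11)))
        f3 = _rand_seq(rng, int(rng.integers(5, 11)))
        arm = "5p" if rng.random() < 0.5 else "3p"
        if arm == "5p":
            prec = f5 + mature + loop + star + f3
        else:
            prec = f5 + star + loop + mature + f3
        contig, start = placer.place(len(prec), f"precursor {name}")
        genome[contig][start:start + len(prec)] = list(prec)
        matures[name] = mature
        precursors.append(Precursor(
            name=f"pre-{name}", contig=contig, start=start,
            end=start + len(prec), strand="+", seq=prec,
            mature_name=name, arm=arm))

    features: list[Feature] = []
    for ftype in FEATURE_TYPES:
        lo, hi = cfg.feature_len_ranges[ftype]
        for k in range(cfg.n_features.get(ftype, 0)):
            length = int(rng.integers(lo, hi + 1))
            contig, start = placer.place(length, f"{ftype} feature")
            features.append(Feature(
                name=f"{ftype}-{k + 1:03d}", type=ftype, contig=contig,
                start=start, end=start + length,
                strand="+" if rng.random() < 0.5 else "-"))

    novel: list[NovelHairpin] = []
    for k in range(cfg.n_novel):
        armA = list(_rand_seq(rng, cfg.novel_arm_len, 0.55))
        if rng.random() < cfg.novel_u5_bias:
            armA[0] = "T"
        armA = "".join(armA)
        armB = list(revcomp(armA))
        for pos in rng.choice(np.arange(3, cfg.novel_arm_len - 3), size=2, replace=False):
            cur = armB[pos]
            armB[pos] = str(rng.choice([b for b in "ACGT" if b != cur]))
        armB = "".join(armB)
        loop = _rand_seq(rng, int(rng.integers(cfg.novel_loop_range[0],
                                               cfg.novel_loop_range[1] + 1)), 0.3)
        block = armA + loop + armB
        contig, start = placer.place(len(block), f"novel hairpin {k + 1}")
        genome[contig][start:start + len(block)] = list(block)
        mature_seq = armA[:21]
        # Dicer duplex: star 3' end sits 2 nt past the partner of the mature
        # 5' base, i.e. 2 nt downstream of the hairpin block
        gseq = "".join(genome[contig])
        star_seq = gseq[start + len(block) + 2 - 21: start + len(block) + 2]
        novel.append(NovelHairpin(
            name=f"novel-locus-{k + 1}", contig=contig, start=start,
            end=start + len(block), strand="+",
            mature_seq=mature_seq, star_seq=star_seq, mature_start=start))

    utrs = {f"gene{k + 1:04d}": _rand_seq(
        rng, int(rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1)), 0.45)
        for k in range(cfg.n_genes)}
    gene_ids = sorted(utrs)
    gene_sets = {}
    for k in range(cfg.n_gene_sets):
        size = int(rng.integers(cfg.gene_set_size_range[0],
                                cfg.gene_set_size_range[1] + 1))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        gene_sets[f"pathway_{k + 1:02d}"] = sorted(str(g) for g in members)

    bundle = ReferenceBundle(
        genome={c: "".join(s) for c, s in genome.items()},
        mature_mirnas=matures, precursors=precursors, ncrna_features=features,
        utr3=utrs, gene_sets=gene_sets, novel_loci=novel)
    bundle.validate()
    return bundle
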