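"""Two-condition small-RNA read simulator.

``build_truth`` lays down the ground truth the analysis is later judged
against: a table of insert species (known matures, ncRNA degradation
fragments, planted novel-hairpin mature/star reads, random genomic
fragments) with expected sampling weights per condition, where the BM
(treatment) weights of selected miRNAs are scaled by planted log2 effects.
``simulate_reads`` then draws each library as one multinomial over the
species, appends the 3' adapter, truncates to the machine read length
(adapter read-through is what makes trimming meaningful), applies a
uniform per-base substitution error, and mixes in a configured fraction of
low-quality contaminant reads.  Everything is deterministic in the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import NovelHairpin, ReferenceBundle, revcomp

log = logging.getLogger(__name__)

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # Illumina small-RNA 3' adapter

#: insert-length distribution peaked at 22 nt (the mature-miRNA mode)
DEFAULT_LENGTH_PMF = {
    15: 0.01, 16: 0.01, 17: 0.02, 18: 0.04, 19: 0.06, 20: 0.10, 21: 0.14,
    22: 0.22, 23: 0.14, 24: 0.10, 25: 0.07, 26: 0.04, 27: 0.03, 28: 0.02,
}

#: category mixture: miRNA a few percent, unannotated the majority
DEFAULT_MIXTURE = {
    "mirna": 0.035, "rRNA": 0.18, "tRNA": 0.07, "snRNA": 0.025,
    "snoRNA": 0.025, "repeat": 0.02, "exon": 0.03, "intron": 0.02,
    "novel": 0.01, "unannotated": 0.585,
}


@dataclass
class SimConfig:
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {"nm": 200_000, "bm": 200_000})
    adapter: str = DEFAULT_ADAPTER
    read_len: int = 36
    error_rate: float = 0.001
    low_quality_fraction: float = 0.02
    mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    fragment_length_pmf: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PMF))
    n_effects: int = 10
    effect_magnitude: float = 3.0
    mirna_lognorm_sigma: float = 1.0
    ncrna_species: int = 400
    unann_species: int = 250
    novel_star_fraction: float = 0.2


@dataclass
class SimTruth:
    """Ground truth: species table + planted effects + run parameters."""

    species: pd.DataFrame  # columns: sequence, source, category, w_nm, w_bm
    planted_effects: dict[str, float]  # log2 effect per known miRNA (0 = null)
    planted_novel_loci: list[NovelHairpin]
    adapter: str
    library_sizes: dict[str, int]
    seed: int
    read_len: int = 36
    error_rate: float = 0.001
    low_quality_fraction: float = 0.02

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.species.to_csv(out / "truth_species.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.planted_effects.items()),
            columns=["mir_name", "log2_effect"],
        ).to_csv(out / "truth_effects.tsv", sep="\t", index=False)
        meta = {
            "adapter": self.adapter, "library_sizes": self.library_sizes,
            "seed": self.seed, "read_len": self.read_len,
            "error_rate": self.error_rate,
            "low_quality_fraction": self.low_quality_fraction,
        }
        (out / "truth_meta.json").write_text(json.dumps(meta, indent=2))


def _sample_lengths(rng: np.random.Generator, pmf: dict[int, float], n: int) -> np.ndarray:
    lens = np.array(sorted(pmf))
    w = np.array([pmf[int(l)] for l in lens], dtype=float)
    return rng.choice(lens, size=n, p=w / w.sum())


def build_truth(bundle: ReferenceBundle, config: SimConfig | None = None,
                seed: int = 0) -> SimTruth:
    """Assemble the species table and planted effects for one experiment."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    mix = dict(cfg.mixture)
    rows: list[tuple[str, str, str, float, float]] = []

    # known miRNAs: lognormal abundances; planted log2 effects scale BM
    mirs = sorted(bundle.mature_mirnas)
    base_w = rng.lognormal(0.0, cfg.mirna_lognorm_sigma, size=len(mirs))
    base_w /= base_w.sum()
    effects = {m: 0.0 for m in mirs}
    if cfg.n_effects > 0 and mirs:
        eligible = [m for m, w in zip(mirs, base_w) if w >= np.median(base_w)]
        chosen = rng.choice(eligible, size=min(cfg.n_effects, len(eligible)),
                            replace=False)
        for i, m in enumerate(sorted(str(x) for x in chosen)):
            effects[m] = cfg.effect_magnitude if i % 2 == 0 else -cfg.effect_magnitude
    for m, w in zip(mirs, base_w):
        w_nm = mix.get("mirna", 0.0) * w
        rows.append((bundle.mature_mirnas[m], m, "mirna",
                     w_nm, w_nm * 2.0 ** effects[m]))

    # ncRNA degradation fragments: species drawn from typed feature intervals
    frag_types = [t for t in ("rRNA", "tRNA", "snRNA", "snoRNA",
                              "repeat", "exon", "intron") if mix.get(t, 0) > 0]
    feats_by_type = {t: [f for f in bundle.ncrna_features if f.type == t]
                     for t in frag_types}
    type_w = np.array([mix[t] for t in frag_types], dtype=float)
    if frag_types and cfg.ncrna_species > 0 and type_w.sum() > 0:
        n_per = rng.multinomial(cfg.ncrna_species, type_w / type_w.sum())
        for t, n_sp in zip(frag_types, n_per):
            feats = feats_by_type[t]
            if not feats:
                continue
            sp_w = rng.lognormal(0.0, 1.0, size=n_sp)
            sp_w = mix[t] * sp_w / sp_w.sum()
            lens = _sample_lengths(rng, cfg.fragment_length_pmf, n_sp)
            for w, L in zip(sp_w, lens):
                f = feats[rng.integers(len(feats))]
                L = int(min(L, f.end - f.start))
                start = int(rng.integers(f.start, f.end - L + 1))
                frag = bundle.genome[f.contig][start:start + L]
                if f.strand == "-":
                    frag = revcomp(frag)
                rows.append((frag, f.name, t, w, w))

    # planted novel hairpins: mature + Dicer-offset star reads
    if bundle.novel_loci and mix.get("novel", 0) > 0:
        hp_w = rng.lognormal(0.0, 0.3, size=len(bundle.novel_loci))
        hp_w = mix["novel"] * hp_w / hp_w.sum()
        for h, w in zip(bundle.novel_loci, hp_w):
            rows.append((h.mature_seq, h.name, "novel",
                         w * (1 - cfg.novel_star_fraction),
                         w * (1 - cfg.novel_star_fraction)))
            rows.append((h.star_seq, h.name + "*", "novel",
                         w * cfg.novel_star_fraction,
                         w * cfg.novel_star_fraction))

    # unannotated: random genomic fragments (either strand)
    if cfg.unann_species > 0 and mix.get("unannotated", 0) > 0:
        contigs = sorted(bundle.genome)
        clens = np.array([len(bundle.genome[c]) for c in contigs], dtype=float)
        sp_w = rng.lognormal(0.0, 1.0, size=cfg.unann_species)
        sp_w = mix["unannotated"] * sp_w / sp_w.sum()
        lens = _sample_lengths(rng, cfg.fragment_length_pmf, cfg.unann_species)
        for k, (w, L) in enumerate(zip(sp_w, lens)):
            c = contigs[rng.choice(len(contigs), p=clens / clens.sum())]
            start = int(rng.integers(0, len(bundle.genome[c]) - int(L)))
            frag = bundle.genome[c][start:start + int(L)]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            rows.append((frag, f"unann-{k + 1:04d}", "unannotated", w, w))

    species = pd.DataFrame(rows, columns=["sequence", "source", "category",
                                          "w_nm", "w_bm"])
    # collapse accidental sequence collisions so truth marginals are per-tag
    species = (species.groupby("sequence", as_index=False)
               .agg({"source": "first", "category": "first",
                     "w_nm": "sum", "w_bm": "sum"}))
    for col in ("w_nm", "w_bm"):
        total = species[col].sum()
        if total > 0:
            species[col] = species[col] / total
    return SimTruth(
        species=species.sort_values("sequence").reset_index(drop=True),
        planted_effects=effects,
        planted_novel_loci=list(bundle.novel_loci),
        adapter=cfg.adapter, library_sizes=dict(cfg.library_sizes), seed=seed,
        read_len=cfg.read_len, error_rate=cfg.error_rate,
        low_quality_fraction=cfg.low_quality_fraction)


def simulate_reads(bundle: ReferenceBundle, truth: SimTruth,
                   out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write one FASTQ per library; returns {library: path}.

    ``seed`` defaults to the truth seed (byte-identical reruns); passing a
    different seed re-draws the sampling noise around the same truth.
    """
    if not truth.adapter:
        raise ValueError("adapter must be non-empty")
    if (truth.species[["w_nm", "w_bm"]] < 0).any().any():
        raise ValueError("species weights must be nonnegative")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 303]))
    paths: dict[str, Path] = {}
    bases = np.array(list("ACGT"))
    L = truth.read_len
    seqs = truth.species["sequence"].to_list()
    read_of = []
    for s in seqs:
        r = (s + truth.adapter)[:L]
        if len(r) < L:
            r = r + "".join(bases[rng.integers(0, 4, L - len(r))])
        read_of.append(r)
    for lib in sorted(truth.library_sizes):
        path = out / f"{lib}.fastq"
        n_total = int(truth.library_sizes[lib])
        if n_total == 0:
            log.warning("library %s has size 0; writing empty FASTQ", lib)
            path.write_text("")
            paths[lib] = path
            continue
        n_contam = int(round(n_total * truth.low_quality_fraction))
        n_real = n_total - n_contam
        w = truth.species[f"w_{lib}"].to_numpy(dtype=float)
        counts = rng.multinomial(n_real, w / w.sum())
        species_idx = np.repeat(np.arange(len(seqs)), counts)
        reads = [read_of[i] for i in species_idx]
        # uniform per-base substitution errors
        n_err = rng.binomial(n_real * L, truth.error_rate)
        for flat in rng.integers(0, n_real * L, size=n_err):
            i, pos = divmod(int(flat), L)
            r = reads[i]
            cur = r[pos]
            alt = str(bases[rng.integers(0, 4)])
            while alt == cur:
                alt = str(bases[rng.integers(0, 4)])
            reads[i] = r[:pos] + alt + r[pos + 1:]
        quals = ["I" * L] * n_real
        for _ in range(n_contam):
            reads.append("".join(bases[rng.integers(0, 4, L)]))
            quals.append("#" * L)
        order = rng.permutation(len(reads))
        with open(path, "w") as fh:
            for j, k in enumerate(order, 1):
                fh.write(f"@{lib}_{j:07d}\n{reads[k]}\n+\n{quals[k]}\n")
        paths[lib] = path
    return paths
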