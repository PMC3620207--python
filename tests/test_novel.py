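"""Hairpin candidate detection: planted recovery, rejection, star support."""

import dataclasses

import pandas as pd
import pytest

from mirmet.novel import (NovelConfig, candidate_stats, detect_candidates)
from mirmet.reference import ReferenceBundle, revcomp


def hairpin_bundle(arm="TGAGGTAGTAGGTTGTATAGTTCG", loop="TTCAAT", star_mut=2):
    # star_mut > 0 keeps the repeat imperfect, as real precursors are;
    # a perfect inverted repeat is its own reverse complement and yields a
    # mirror candidate on the minus strand
    """Genome with one planted inverted repeat in low-complexity flanks."""
    arm_b = list(revcomp(arm))
    for i in range(star_mut):
        pos = 5 + 3 * i
        arm_b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm_b[pos]]
    block = arm + loop + "".join(arm_b)
    flank_l = "ACACCA" * 20  # A/C alphabet: cannot pair with itself
    flank_r = "CAACCA" * 20
    genome = flank_l + block + flank_r
    bundle = ReferenceBundle(
        genome={"chr1": genome}, mature_mirnas={}, precursors=[],
        ncrna_features=[], utr3={}, gene_sets={}, novel_loci=[])
    return bundle, len(flank_l), block


def annotated_frame(rows):
    """rows: (sequence, count_bm, count_nm, (contig, start, end, strand))"""
    return pd.DataFrame({
        "sequence": [r[0] for r in rows],
        "count_bm": [r[1] for r in rows],
        "count_nm": [r[2] for r in rows],
        "loci": [[r[3]] for r in rows],
        "map_status": ["mapped"] * len(rows),
        "category": ["unannotated"] * len(rows),
    })


def test_planted_hairpin_recovered_with_valid_structure():
    bundle, off, block = hairpin_bundle()
    mature = block[:21]
    ann = annotated_frame([(mature, 10, 8, ("chr1", off, off + 21, "+"))])
    cands = detect_candidates(ann, bundle)
    assert len(cands) == 1
    c = cands[0]
    assert c.mature_seq == mature and c.mature_arm == "5p"
    assert c.start <= off and c.end >= off + len(block) - 3
    c.validate(NovelConfig().mfe_threshold)  # structural invariants hold
    assert c.first_nt == "T"


def test_tag_in_unstructured_flank_rejected():
    bundle, off, block = hairpin_bundle()
    tag = bundle.genome["chr1"][10:31]  # inside the A/C flank: no pairing
    ann = annotated_frame([(tag, 10, 0, ("chr1", 10, 31, "+"))])
    assert detect_candidates(ann, bundle) == []


def test_star_tag_with_dicer_overhang_sets_star_support():
    bundle, off, block = hairpin_bundle()
    g = bundle.genome["chr1"]
    mature = block[:21]
    star = g[off + len(block) + 2 - 21: off + len(block) + 2]
    ann = annotated_frame([
        (mature, 10, 8, ("chr1", off, off + 21, "+")),
        (star, 3, 1, ("chr1", off + len(block) + 2 - 21,
                      off + len(block) + 2, "+")),
    ])
    cands = detect_candidates(ann, bundle)
    assert len(cands) == 1 and cands[0].star_support


def test_star_without_overhang_not_supported():
    bundle, off, block = hairpin_bundle()
    g = bundle.genome["chr1"]
    mature = block[:21]
    aligned = g[off + len(block) - 21: off + len(block)]  # blunt end, no overhang
    ann = annotated_frame([
        (mature, 10, 8, ("chr1", off, off + 21, "+")),
        (aligned, 3, 1, ("chr1", off + len(block) - 21, off + len(block), "+")),
    ])
    cands = detect_candidates(ann, bundle)
    assert len(cands) == 1 and not cands[0].star_support


def test_low_count_tags_do_not_seed_candidates():
    bundle, off, block = hairpin_bundle()
    mature = block[:21]
    ann = annotated_frame([(mature, 2, 1, ("chr1", off, off + 21, "+"))])
    assert detect_candidates(ann, bundle, NovelConfig(min_tag_count=5)) == []


def test_relaxing_mfe_threshold_only_adds_candidates(small_run):
    run_dir, cfg = small_run
    from mirmet.bundle_io import load_bundle
    from mirmet.pipeline import _load_annotation
    bundle = load_bundle(run_dir / "reference")
    ann = _load_annotation(run_dir)
    strict = detect_candidates(ann, bundle, NovelConfig(mfe_threshold=-30.0))
    relaxed = detect_candidates(ann, bundle, NovelConfig(mfe_threshold=-18.0))
    strict_keys = {(c.contig, c.start, c.end, c.strand) for c in strict}
    relaxed_keys = {(c.contig, c.start, c.end, c.strand) for c in relaxed}
    assert strict_keys <= relaxed_keys


def test_candidate_stats_summary():
    bundle, off, block = hairpin_bundle()
    mature = block[:21]
    ann = annotated_frame([(mature, 10, 8, ("chr1", off, off + 21, "+"))])
    (c,) = detect_candidates(ann, bundle)
    a = dataclasses.replace(c, mfe=-20.0, count_bm=5, count_nm=0)
    b = dataclasses.replace(c, mfe=-40.0)
    stats = candidate_stats([a, b])
    assert stats["count"] == 2
    assert stats["shared"] == 1  # only b expressed in both libraries
    assert stats["mean_mfe"] == -30.0
    assert stats["min_mfe"] == -40.0 and stats["max_mfe"] == -20.0
    assert stats["mature_length_mode"] == 21
    assert stats["first_nt_fractions"]["T"] == 1.0


def test_empty_candidate_stats_have_no_nans():
    stats = candidate_stats([])
    assert stats["count"] == 0 and stats["mean_mfe"] == 0.0
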