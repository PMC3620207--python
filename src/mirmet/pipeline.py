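"""Pipeline orchestration: simulate → preprocess → annotate → novel → de →
targets → enrich, with per-stage caching on disk and a run manifest.

Every stage reads its inputs from the run directory and writes its outputs
back there, so any stage can be re-run from cached upstream outputs.  All
randomness flows from the single root seed via named substreams.  A stage
failure leaves a FAILED marker with the stage name; partial outputs are
retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as pkg_version
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import bundle_io, diffexpr, enrich as enrich_mod, preprocess as prep
from . import novel as novel_mod
from . import simulate as sim
from . import targets as tgt
from .annotate import AnnotateConfig
from .config import RunConfig
from .novel import NovelConfig
from .preprocess import CleanParams
from .reference import build_reference

log = logging.getLogger(__name__)

STAGES = ("reference", "simulate", "preprocess", "annotate", "novel",
          "de", "targets", "enrich")

LIBS = ("bm", "nm")  # bm = treatment, nm = control


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in dependency order; returns run dir."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    failed_marker = run_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    for stage in STAGES:
        if stage not in stages:
            continue
        fn = globals()[f"stage_{stage}"]
        log.info("running stage %s", stage)
        try:
            fn(config, run_dir)
        except Exception:
            failed_marker.write_text(stage + "\n")
            raise
    _write_manifest(config, run_dir)
    return run_dir


def _write_manifest(config: RunConfig, run_dir: Path) -> None:
    checksums = {
        str(p.relative_to(run_dir)): _sha256(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "mirmet",
        "version": pkg_version("mirmet"),
        "seed": config.seed,
        "config": config.model_dump(),
        "checksums": checksums,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def stage_reference(config: RunConfig, run_dir: Path) -> None:
    ref = config.reference
    if ref.mode == "load":
        bundle = bundle_io.load_bundle(ref.dir)
    else:
        bundle = build_reference(ref.generate.to_reference_config(), seed=config.seed)
    bundle_io.save_bundle(bundle, run_dir / "reference")


def stage_simulate(config: RunConfig, run_dir: Path) -> None:
    bundle = bundle_io.load_bundle(run_dir / "reference")
    truth = sim.build_truth(bundle, config.simulate.to_sim_config(), seed=config.seed)
    out = run_dir / "reads"
    truth.save(out)
    sim.simulate_reads(bundle, truth, out)


def stage_preprocess(config: RunConfig, run_dir: Path) -> None:
    p = config.preprocess
    params = CleanParams(adapter=config.simulate.adapter, min_overlap=p.min_overlap,
                         min_quality=p.min_quality, min_len=p.min_len,
                         max_len=p.max_len)
    out = run_dir / "preprocess"
    out.mkdir(exist_ok=True)
    results = {}
    report = {}
    for lib in LIBS:
        res = prep.clean_reads(run_dir / "reads" / f"{lib}.fastq", params)
        results[lib] = res
        report[lib] = res.report()
    tags = prep.merge_libraries(results["bm"], results["nm"])
    tags.to_csv(out / "tags.tsv", sep="\t", index=False)
    for lib in LIBS:
        prep.write_collapsed_fasta(tags, lib, out / f"collapsed_{lib}.fa")
    dist = prep.summarize_lengths(tags)
    dist.to_csv(out / "length_distribution.tsv", sep="\t", index=False)
    report["mass_20_24"] = prep.mass_20_24(dist)
    (out / "report.json").write_text(json.dumps(report, indent=2))


def _serialize_loci(loci: list[tuple]) -> str:
    return ";".join(f"{c}:{s}-{e}:{st}" for c, s, e, st in loci)


def _parse_loci(text: str) -> list[tuple]:
    if not isinstance(text, str) or not text:
        return []
    out = []
    for part in text.split(";"):
        c, span, st = part.rsplit(":", 2)
        s, e = span.split("-")
        out.append((c, int(s), int(e), st))
    return out


def stage_annotate(config: RunConfig, run_dir: Path) -> None:
    bundle = bundle_io.load_bundle(run_dir / "reference")
    tags = pd.read_csv(run_dir / "preprocess" / "tags.tsv", sep="\t")
    a = config.annotate
    mapped = ann.map_tags(tags, bundle, max_hits=a.max_hits)
    annotated = ann.classify(mapped, bundle, AnnotateConfig(
        max_hits=a.max_hits, priority=tuple(a.priority),
        mirna_3p_tolerance=a.mirna_3p_tolerance))
    out = run_dir / "annotate"
    out.mkdir(exist_ok=True)
    flat = annotated.copy()
    flat["loci"] = flat["loci"].map(_serialize_loci)
    flat.to_csv(out / "annotation.tsv", sep="\t", index=False)
    ann.category_summary(annotated).to_csv(out / "category_summary.tsv",
                                           sep="\t", index=False)
    ann.mirna_counts(annotated).to_csv(out / "mirna_counts.tsv",
                                       sep="\t", index=False)


def _load_annotation(run_dir: Path) -> pd.DataFrame:
    annotated = pd.read_csv(run_dir / "annotate" / "annotation.tsv", sep="\t",
                            keep_default_na=False)
    annotated["loci"] = annotated["loci"].map(_parse_loci)
    return annotated


def stage_novel(config: RunConfig, run_dir: Path) -> None:
    bundle = bundle_io.load_bundle(run_dir / "reference")
    annotated = _load_annotation(run_dir)
    n = config.novel
    cands = novel_mod.detect_candidates(annotated, bundle, NovelConfig(
        flank=n.flank, mfe_threshold=n.mfe_threshold,
        min_paired_mature=n.min_paired_mature,
        loop_range=(n.loop_min, n.loop_max), min_tag_count=n.min_tag_count))
    out = run_dir / "novel"
    out.mkdir(exist_ok=True)
    novel_mod.candidates_table(cands).to_csv(out / "candidates.tsv",
                                             sep="\t", index=False)
    (out / "stats.json").write_text(json.dumps(novel_mod.candidate_stats(cands),
                                               indent=2))


def stage_de(config: RunConfig, run_dir: Path) -> None:
    counts = pd.read_csv(run_dir / "annotate" / "mirna_counts.tsv", sep="\t")
    report = json.loads((run_dir / "preprocess" / "report.json").read_text())
    d = config.de
    table = diffexpr.call_de(
        counts.rename(columns={"count_nm": "count_control",
                               "count_bm": "count_treatment"}),
        total_control=report["nm"]["clean_reads"],
        total_treatment=report["bm"]["clean_reads"],
        fc_threshold=d.fc_threshold, alpha=d.alpha, filter_mode=d.filter_mode)
    out = run_dir / "de"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "de_full.tsv", sep="\t", index=False)
    sig = table[table["status"].isin([diffexpr.UP, diffexpr.DOWN])]
    sig = sig.rename(columns={"mir_name": "miR name", "fold_change": "fold-change",
                              "p_value": "p-value", "status": "Status"})
    sig[["miR name", "fold-change", "p-value", "Status"]].to_csv(
        out / "de_table.tsv", sep="\t", index=False)


def stage_targets(config: RunConfig, run_dir: Path) -> None:
    bundle = bundle_io.load_bundle(run_dir / "reference")
    table = pd.read_csv(run_dir / "de" / "de_full.tsv", sep="\t")
    de_mirs = table.loc[table["status"].isin([diffexpr.UP, diffexpr.DOWN]),
                        "mir_name"].tolist()
    mirnas = {m: bundle.mature_mirnas[m] for m in de_mirs
              if m in bundle.mature_mirnas}
    t = config.targets
    extra = (pd.read_csv(t.external_sites, sep="\t")
             if t.external_sites else None)
    sites = tgt.predict_targets(mirnas, bundle.utr3, extra_sites=extra)
    net = tgt.build_network(sites, min_sites_per_edge=t.min_sites_per_edge)
    out = run_dir / "targets"
    out.mkdir(exist_ok=True)
    sites.to_csv(out / "sites.tsv", sep="\t", index=False)
    nodes, edges = tgt.network_tables(net)
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    tgt.write_graphml(net, out / "network.graphml")
    tgt.write_sif(net, out / "network.sif")
    tgt.hub_report(net, min_degree=t.hub_min_degree).to_csv(
        out / "hubs.tsv", sep="\t", index=False)


def stage_enrich(config: RunConfig, run_dir: Path) -> None:
    bundle = bundle_io.load_bundle(run_dir / "reference")
    nodes = pd.read_csv(run_dir / "targets" / "nodes.tsv", sep="\t")
    query = set(nodes.loc[nodes["kind"] == "gene", "node"])
    e = config.enrich
    table = enrich_mod.enrich(query, bundle.gene_sets, method=e.method,
                              alpha=e.alpha)
    out = run_dir / "enrich"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)


def evaluate_against_truth(run_dir: str | Path) -> dict:
    """Compare a finished run with the generator's ground truth.

    Reports DE sensitivity and direction accuracy over planted non-zero
    effects, and recall of planted novel hairpin loci.
    """
    run_dir = Path(run_dir)
    effects = pd.read_csv(run_dir / "reads" / "truth_effects.tsv", sep="\t")
    de = pd.read_csv(run_dir / "de" / "de_full.tsv", sep="\t")
    status = dict(zip(de["mir_name"], de["status"]))
    planted = effects[effects["log2_effect"] != 0]
    n_called = n_correct = 0
    for r in planted.itertuples():
        st = status.get(r.mir_name, "absent")
        want = diffexpr.UP if r.log2_effect > 0 else diffexpr.DOWN
        if st in (diffexpr.UP, diffexpr.DOWN):
            n_called += 1
            if st == want:
                n_correct += 1
    truth_loci = pd.read_csv(run_dir / "reference" / "novel_loci.tsv", sep="\t")
    cands = pd.read_csv(run_dir / "novel" / "candidates.tsv", sep="\t")
    n_recovered = 0
    for h in truth_loci.itertuples():
        hit = ((cands["contig"] == h.contig) & (cands["start"] < h.end)
               & (cands["end"] > h.start))
        if hit.any():
            n_recovered += 1
    n_planted = int(len(planted))
    return {
        "n_planted_effects": n_planted,
        "n_called": n_called,
        "n_correct_direction": n_correct,
        "de_sensitivity": n_correct / n_planted if n_planted else float("nan"),
        "n_planted_hairpins": int(len(truth_loci)),
        "n_hairpins_recovered": n_recovered,
        "n_candidates": int(len(cands)),
    }
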