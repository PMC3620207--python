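"""On-disk form of the reference bundle (FASTA / GFF3 / GMT / TSV)."""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrich import read_gmt, write_gmt
from .reference import Feature, NovelHairpin, Precursor, ReferenceBundle


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        path, "fasta")


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def save_bundle(bundle: ReferenceBundle, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta(bundle.genome, out / "genome.fa")
    _write_fasta(bundle.mature_mirnas, out / "mature.fa")
    _write_fasta({p.name: p.seq for p in bundle.precursors}, out / "precursor.fa")
    _write_fasta(bundle.utr3, out / "utr3.fa")
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    with open(out / "features.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("# coordinates are 1-based inclusive\n")
        for f in bundle.ncrna_features:
            fh.write("\t".join([
                f.contig, "mirmet", f.type, str(f.start + 1), str(f.end),
                ".", f.strand, ".", f"ID={f.name}"]) + "\n")
        for p in bundle.precursors:
            fh.write("\t".join([
                p.contig, "mirmet", "miRNA_primary_transcript",
                str(p.start + 1), str(p.end), ".", p.strand, ".",
                f"ID={p.name};mature={p.mature_name};arm={p.arm}"]) + "\n")
    cols = ["name", "contig", "start", "end", "strand",
            "mature_seq", "star_seq", "mature_start"]
    pd.DataFrame(
        [[getattr(h, c) for c in cols] for h in bundle.novel_loci], columns=cols,
    ).to_csv(out / "novel_loci.tsv", sep="\t", index=False)
    return out


def load_bundle(in_dir: str | Path) -> ReferenceBundle:
    d = Path(in_dir)
    genome = _read_fasta(d / "genome.fa")
    matures = _read_fasta(d / "mature.fa")
    prec_seqs = _read_fasta(d / "precursor.fa")
    features: list[Feature] = []
    precursors: list[Precursor] = []
    db = gffutils.create_db(str(d / "features.gff3"), ":memory:",
                            merge_strategy="create_unique")
    for feat in db.all_features():
        start0, end0 = feat.start - 1, feat.end  # GFF3 1-based inclusive -> half-open
        if feat.featuretype == "miRNA_primary_transcript":
            name = feat.attributes["ID"][0]
            precursors.append(Precursor(
                name=name, contig=feat.seqid, start=start0, end=end0,
                strand=feat.strand, seq=prec_seqs[name],
                mature_name=feat.attributes["mature"][0],
                arm=feat.attributes["arm"][0]))
        else:
            features.append(Feature(
                name=feat.attributes["ID"][0], type=feat.featuretype,
                contig=feat.seqid, start=start0, end=end0, strand=feat.strand))
    novel: list[NovelHairpin] = []
    novel_path = d / "novel_loci.tsv"
    if novel_path.exists():
        tbl = pd.read_csv(novel_path, sep="\t")
        novel = [NovelHairpin(
            name=r.name, contig=r.contig, start=int(r.start), end=int(r.end),
            strand=r.strand, mature_seq=r.mature_seq, star_seq=r.star_seq,
            mature_start=int(r.mature_start)) for r in tbl.itertuples(index=False)]
    bundle = ReferenceBundle(
        genome=genome, mature_mirnas=matures, precursors=precursors,
        ncrna_features=features, utr3=_read_fasta(d / "utr3.fa"),
        gene_sets=read_gmt(d / "gene_sets.gmt"), novel_loci=novel)
    bundle.validate()
    return bundle
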