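"""On-disk cohort layout: FASTA, GFF3, metadata and truth tables.

Per genome: ``<id>.fna`` (contigs), ``<id>.gff`` (CDS features,
``##gff-version 3``, 1-based inclusive, forward strand), ``<id>.ffn``
(per-gene CDS) and ``<id>.faa`` (per-gene proteins).  Cohort-level:
``metadata.tsv`` and, for synthetic cohorts, truth tables plus the
scaled threshold YAML.  All files are written with fixed ordering and
``\\n`` line endings so identical configurations produce byte-identical
output.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import ThresholdConfig
from .records import CdsRecord, GenomeRecord
from .simulate import TruthLabels


def _write_fasta(path: Path, entries) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def write_cohort(records: list[GenomeRecord], outdir,
                 truth: TruthLabels | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for rec in records:
        _write_fasta(outdir / f"{rec.genome_id}.fna", sorted(rec.contigs.items()))
        _write_fasta(outdir / f"{rec.genome_id}.ffn",
                     [(c.gene_id, c.nucleotide_seq) for c in rec.cds_records])
        _write_fasta(outdir / f"{rec.genome_id}.faa",
                     [(c.gene_id, c.protein_seq) for c in rec.cds_records])
        with open(outdir / f"{rec.genome_id}.gff", "w", newline="\n") as fh:
            fh.write("##gff-version 3\n")
            for cid in sorted(rec.contigs):
                fh.write(f"##sequence-region {cid} 1 {len(rec.contigs[cid])}\n")
            for c in rec.cds_records:
                fh.write("\t".join([
                    c.contig_id, "pansubspec", "CDS", str(c.start), str(c.end),
                    ".", "+", "0", f"ID={c.gene_id}"]) + "\n")
        meta_rows.append({
            "genome_id": rec.genome_id,
            "subspecies_label": rec.subspecies_label or "",
            "size_bp": rec.size_bp, "n_cds": rec.n_cds,
            "n_contigs": rec.n_contigs,
            "coverage": "" if rec.coverage is None else rec.coverage})
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t",
                                   index=False, lineterminator="\n")
    if truth is not None:
        write_truth(truth, outdir, records)


def write_truth(truth: TruthLabels, outdir, records: list[GenomeRecord]) -> None:
    outdir = Path(outdir)
    gene_rows = [{"gene_id": g, "genome_id": g.split("|", 1)[0], "family_id": f,
                  "is_alien": int(g in truth.alien_genes)}
                 for g, f in sorted(truth.family_of_gene.items())]
    pd.DataFrame(gene_rows).to_csv(outdir / "truth_genes.tsv", sep="\t",
                                   index=False, lineterminator="\n")
    dup_of = {d: s for s, d in truth.duplicate_pairs}
    genome_rows = [{
        "genome_id": r.genome_id,
        "true_subspecies": truth.true_subspecies.get(r.genome_id, ""),
        "declared_label": r.subspecies_label or "",
        "qc_reasons": ";".join(truth.qc_violations.get(r.genome_id, [])),
        "duplicate_of": dup_of.get(r.genome_id, ""),
        "is_type_strain": int(r.genome_id in truth.type_strains.values())}
        for r in records]
    pd.DataFrame(genome_rows).to_csv(outdir / "truth_genomes.tsv", sep="\t",
                                     index=False, lineterminator="\n")
    marker_rows = [{"subspecies": s, "family_id": f}
                   for s in sorted(truth.marker_families)
                   for f in truth.marker_families[s]]
    pd.DataFrame(marker_rows, columns=["subspecies", "family_id"]).to_csv(
        outdir / "truth_markers.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame({"family_id": truth.core_families}).to_csv(
        outdir / "truth_core_families.tsv", sep="\t", index=False,
        lineterminator="\n")
    if truth.thresholds is not None:
        truth.thresholds.to_yaml(outdir / "thresholds.yaml")


def read_cohort(indir) -> list[GenomeRecord]:
    """Rebuild GenomeRecords from an on-disk cohort directory."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t")
    records = []
    for row in meta.itertuples():
        gid = row.genome_id
        contigs = {r.id: str(r.seq)
                   for r in SeqIO.parse(indir / f"{gid}.fna", "fasta")}
        prots = {r.id: str(r.seq)
                 for r in SeqIO.parse(indir / f"{gid}.faa", "fasta")}
        nucs = {r.id: str(r.seq)
                for r in SeqIO.parse(indir / f"{gid}.ffn", "fasta")}
        gff = pd.read_csv(indir / f"{gid}.gff", sep="\t", comment="#",
                          header=None,
                          names=["seqid", "source", "type", "start", "end",
                                 "score", "strand", "phase", "attributes"])
        cds = []
        for feat in gff.itertuples():
            if feat.type != "CDS":
                continue
            gene_id = dict(kv.split("=", 1)
                           for kv in feat.attributes.split(";"))["ID"]
            cds.append(CdsRecord(
                gene_id=gene_id, genome_id=gid, contig_id=feat.seqid,
                start=int(feat.start), end=int(feat.end),
                nucleotide_seq=nucs[gene_id], protein_seq=prots[gene_id]))
        label = row.subspecies_label if isinstance(row.subspecies_label, str) else None
        cov = None if pd.isna(row.coverage) else float(row.coverage)
        records.append(GenomeRecord(genome_id=gid, subspecies_label=label,
                                    contigs=contigs, coverage=cov,
                                    cds_records=cds))
    return records


def read_thresholds(path) -> ThresholdConfig:
    return ThresholdConfig.from_yaml(path)
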