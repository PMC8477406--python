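"""End-to-end cohort analysis: QC -> dedup -> clustering -> pan-genome ->
phylogeny -> HGT screen, with deterministic TSV/Newick outputs.

Every output file is written with fixed ordering and ``\\n`` line
endings, so a given cohort + seed produces byte-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ani import PairwiseAniTable, ani_matrix
from .cluster import GeneFamily, cluster_genes
from .config import ThresholdConfig
from .hgt import calls_to_dataframe, screen_genome
from .pangenome import (PresenceAbsenceMatrix, build_presence_matrix,
                        core_and_unique, rarefaction_curves, subspecies_core)
from .phylo import (bootstrap_supports, classify_by_type_strain,
                    core_distance_matrix, neighbor_joining)
from .qc import apply_quality_filters, deduplicate_by_ani
from .records import GenomeRecord


@dataclass
class PipelineResult:
    kept_ids: list[str]
    qc_report: object
    dropped_pairs: list[tuple[str, str]]
    ani: PairwiseAniTable
    families: list[GeneFamily]
    pa: PresenceAbsenceMatrix
    core_families: list[str]
    tug_counts: dict[str, int]
    subspecies_cores: dict[str, object]
    tree: object
    distance_matrix: object = None
    classification: list[dict] = field(default_factory=list)
    hgt_fractions: dict[str, float] = field(default_factory=dict)
    hgt_calls: pd.DataFrame | None = None
    pan_curve: object = None


def run_pipeline(records: list[GenomeRecord], thresholds: ThresholdConfig,
                 seed: int = 0, bootstrap: int | None = None,
                 type_strains: dict[str, str] | None = None,
                 n_permutations: int = 100) -> PipelineResult:
    """Run all analysis stages on an annotated cohort."""
    qc = apply_quality_filters(records, thresholds)
    passed = [r for r in records if r.genome_id in set(qc.kept)]
    ani = ani_matrix(passed, thresholds)
    kept_ids, dropped_pairs = deduplicate_by_ani(passed, ani,
                                                 thresholds.dedup_ani_pct)
    kept = [r for r in passed if r.genome_id in set(kept_ids)]

    # reassign subspecies by type-strain ANI before any per-subspecies
    # analysis, so declared mislabels cannot distort prevalence counts
    declared = {r.genome_id: r.subspecies_label for r in kept}
    classification = []
    labels = declared
    if type_strains:
        classification = classify_by_type_strain(ani, type_strains, declared)
        assigned = {c["genome_id"]: c["assigned_subspecies"]
                    for c in classification}
        labels = {g: assigned.get(g, declared[g]) for g in declared}

    families = cluster_genes(kept, thresholds)
    pa = build_presence_matrix(families, [r.genome_id for r in kept], labels)
    core, tugs = core_and_unique(pa)
    curve = rarefaction_curves(pa, n_permutations=n_permutations, seed=seed)
    sub_cores = subspecies_core(pa, thresholds)

    proteins = {c.gene_id: c.protein_seq for r in kept for c in r.cds_records}
    core_fams = [f for f in families if f.family_id in set(core)]
    D, per_family = core_distance_matrix(core_fams,
                                         [r.genome_id for r in kept], proteins)
    tree = neighbor_joining(D)
    B = thresholds.bootstrap_replicates if bootstrap is None else bootstrap
    if B > 0 and len(per_family) >= 2:
        tree = bootstrap_supports(per_family, D.ids, B=B, seed=seed, tree=tree)

    call_frames = []
    fractions = {}
    for r in kept:
        calls, frac = screen_genome(r, thresholds)
        fractions[r.genome_id] = frac
        call_frames.append(calls_to_dataframe(r.genome_id, calls))
    hgt_calls = (pd.concat(call_frames, ignore_index=True)
                 if call_frames else None)

    return PipelineResult(kept_ids=kept_ids, qc_report=qc,
                          dropped_pairs=dropped_pairs, ani=ani,
                          families=families, pa=pa, core_families=core,
                          tug_counts=tugs, subspecies_cores=sub_cores,
                          tree=tree, distance_matrix=D,
                          classification=classification,
                          hgt_fractions=fractions, hgt_calls=hgt_calls,
                          pan_curve=curve)


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_results(result: PipelineResult, outdir) -> None:
    """Write every pipeline product as TSV/Newick with stable ordering."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _tsv(pd.DataFrame(result.qc_report.to_rows()), outdir / "qc_report.tsv")
    _tsv(pd.DataFrame(result.dropped_pairs, columns=["kept", "dropped"]),
         outdir / "dedup.tsv")
    ani_df = result.ani.to_dataframe().round(4)
    ani_df.index.name = "genome_id"
    ani_df.to_csv(outdir / "ani_matrix.tsv", sep="\t", lineterminator="\n")
    _tsv(pd.DataFrame([(f.family_id, g, gene) for f in result.families
                       for g, gene in f.members],
                      columns=["family_id", "genome_id", "gene_id"]),
         outdir / "families.tsv")
    pa_df = result.pa.counts.copy()
    pa_df.index.name = "genome_id"
    pa_df.to_csv(outdir / "presence_absence.tsv", sep="\t",
                 lineterminator="\n")
    _tsv(result.pan_curve.table, outdir / "pan_curves.tsv")
    _tsv(pd.DataFrame({"family_id": result.core_families}),
         outdir / "core_families.tsv")
    _tsv(pd.DataFrame(sorted(result.tug_counts.items()),
                      columns=["genome_id", "n_tugs"]),
         outdir / "tug_counts.tsv")
    sub_rows = []
    for s in sorted(result.subspecies_cores):
        df = result.subspecies_cores[s].families
        for row in df.itertuples(index=False):
            sub_rows.append({"subspecies": s, "family_id": row.family_id,
                             "prevalence_pct": round(100 * row.prevalence, 2)})
    _tsv(pd.DataFrame(sub_rows,
                      columns=["subspecies", "family_id", "prevalence_pct"]),
         outdir / "subspecies_core.tsv")
    with open(outdir / "tree.nwk", "w", newline="\n") as fh:
        fh.write(result.tree.to_newick() + "\n")
    if result.distance_matrix is not None:
        with open(outdir / "core_distances.phy", "w", newline="\n") as fh:
            fh.write(result.distance_matrix.to_phylip())
        import pandas as _pd
        ddf = _pd.DataFrame(result.distance_matrix.matrix,
                            index=result.distance_matrix.ids,
                            columns=result.distance_matrix.ids).round(8)
        ddf.index.name = "genome_id"
        ddf.to_csv(outdir / "core_distances.tsv", sep="\t",
                   lineterminator="\n")
    if result.hgt_calls is not None:
        calls = result.hgt_calls.copy()
        calls["score"] = calls["score"].round(6)
        _tsv(calls, outdir / "hgt_calls.tsv")
    _tsv(pd.DataFrame(sorted(result.hgt_fractions.items()),
                      columns=["genome_id", "hgt_pct"]).round(3),
         outdir / "hgt_fractions.tsv")
    if result.classification:
        rows = [{k: v for k, v in c.items() if k != "ani_to_type_strains"}
                for c in result.classification]
        _tsv(pd.DataFrame(rows), outdir / "classification.tsv")
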