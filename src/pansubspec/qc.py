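"""Genome quality selection and ANI-based deduplication.

Quality rules (all strict, exactly as phrased for the cohort study):
a genome is discarded iff its size is *less than* the minimum, its CDS
count is *less than* the minimum, it has *more than* the contig maximum,
or its coverage (when known) is *lower than* the minimum fold coverage.
Duplicated genomes are pairs with symmetric ANI strictly above 99.99 %;
one representative per connected duplicate group is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ani import PairwiseAniTable
from .config import ThresholdConfig
from .records import GenomeRecord


@dataclass
class QcReport:
    kept: list[str] = field(default_factory=list)
    discarded: dict[str, list[str]] = field(default_factory=dict)
    coverage_unknown: list[str] = field(default_factory=list)

    def to_rows(self):
        rows = [{"genome_id": g, "status": "kept", "reasons": ""}
                for g in self.kept]
        rows += [{"genome_id": g, "status": "discarded",
                  "reasons": ";".join(r)} for g, r in self.discarded.items()]
        return rows


def apply_quality_filters(records: list[GenomeRecord],
                          thresholds: ThresholdConfig) -> QcReport:
    """Apply the four genome-selection rules; list every violated rule."""
    report = QcReport()
    for rec in records:
        reasons = []
        if rec.size_bp < thresholds.min_genome_size_bp:
            reasons.append("size")
        if rec.n_cds < thresholds.min_cds:
            reasons.append("cds")
        if rec.n_contigs > thresholds.max_contigs:
            reasons.append("contigs")
        if rec.coverage is None:
            report.coverage_unknown.append(rec.genome_id)
        elif rec.coverage < thresholds.min_coverage:
            reasons.append("coverage")
        if reasons:
            report.discarded[rec.genome_id] = reasons
        else:
            report.kept.append(rec.genome_id)
    return report


def deduplicate_by_ani(records: list[GenomeRecord], ani: PairwiseAniTable,
                       threshold_pct: float = 99.99
                       ) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop all but one representative of each >threshold ANI duplicate group.

    The representative of a connected duplicate component is the genome
    with the largest size, ties broken by lexicographically smallest id.
    Returns (kept ids in input order, list of (kept, dropped) pairs).
    """
    ids = [r.genome_id for r in records]
    by_id = {r.genome_id: r for r in records}
    # union-find over genomes joined by >threshold symmetric ANI
    parent = {g: g for g in ids}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if ani.symmetric(a, b) > threshold_pct:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    components: dict[str, list[str]] = {}
    for g in ids:
        components.setdefault(find(g), []).append(g)

    kept_set = set()
    dropped_pairs: list[tuple[str, str]] = []
    for members in components.values():
        rep = min(members, key=lambda g: (-by_id[g].size_bp, g))
        kept_set.add(rep)
        for g in members:
            if g != rep:
                dropped_pairs.append((rep, g))
    kept = [g for g in ids if g in kept_set]
    return kept, sorted(dropped_pairs)
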