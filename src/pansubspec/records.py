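"""Core in-memory records for annotated genome assemblies.

A cohort is a list of :class:`GenomeRecord`, each carrying its contigs,
its CDS complement (:class:`CdsRecord`) and the assembly metadata the
quality filters act on (size, CDS count, contig count, fold coverage,
declared subspecies label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq


@dataclass
class CdsRecord:
    """A single protein-coding gene on a contig (1-based inclusive coords)."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    nucleotide_seq: str
    protein_seq: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if len(self.nucleotide_seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    def validate_translation(self) -> None:
        """Assert the stored protein is the standard-code translation of the CDS."""
        expected = str(Seq(self.nucleotide_seq).translate())
        if expected != self.protein_seq:
            raise ValueError(f"{self.gene_id}: protein != translation(CDS)")


@dataclass
class GenomeRecord:
    """One annotated assembly: contigs, CDS set, metadata, subspecies label."""

    genome_id: str
    subspecies_label: str | None
    contigs: dict[str, str]
    coverage: float | None = None
    cds_records: list[CdsRecord] = field(default_factory=list)

    @property
    def size_bp(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_cds(self) -> int:
        return len(self.cds_records)

    def whole_sequence(self) -> str:
        """Concatenation of all contigs in insertion order (for fragment ANI)."""
        return "".join(self.contigs.values())
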