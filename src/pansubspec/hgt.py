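"""Codon-usage-deviation screen for putatively horizontally acquired genes.

Each gene is summarized by its relative synonymous codon usage (RSCU)
over the 59 informative codons.  A genome-level profile (per-codon mean
and standard deviation of RSCU across genes) defines the expected
native usage; a gene's alienness score is the mean absolute
standardized deviation of its RSCU from the profile, with the SD
floored at 0.1 so invariant codons cannot blow up the score.  Genes at
or above the score threshold are called alien; short genes (< 100
codons) face a length-adjusted (stricter) threshold because their RSCU
estimates are noisy.  The per-genome HGT fraction is the percentage of
CDS called alien.  Downstream statistics are detector-agnostic and also
accept externally produced call tables in the same schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import INFORMATIVE_CODONS, rscu_vector
from .config import ThresholdConfig
from .records import CdsRecord, GenomeRecord

_SD_FLOOR = 0.1
_SHORT_GENE_CODONS = 100


@dataclass
class UsageProfile:
    """Genome-level RSCU mean/SD over informative codons."""

    mean: np.ndarray
    sd: np.ndarray
    n_genes: int


@dataclass
class AlienCall:
    gene_id: str
    score: float
    is_alien: bool


def codon_usage_profile(cds: list[CdsRecord]) -> UsageProfile:
    """Elementwise mean and SD of per-gene RSCU vectors."""
    if len(cds) < 20:
        warnings.warn(f"codon-usage profile from only {len(cds)} genes",
                      stacklevel=2)
    if not cds:
        k = len(INFORMATIVE_CODONS)
        return UsageProfile(mean=np.ones(k), sd=np.zeros(k), n_genes=0)
    vectors = np.stack([rscu_vector(c.nucleotide_seq) for c in cds])
    return UsageProfile(mean=vectors.mean(axis=0), sd=vectors.std(axis=0),
                        n_genes=len(cds))


def alienness_scores(genome: GenomeRecord, profile: UsageProfile,
                     thresholds: ThresholdConfig | None = None
                     ) -> list[AlienCall]:
    """Score every CDS of a genome against the genome's usage profile."""
    thresholds = thresholds or ThresholdConfig()
    sd = np.maximum(profile.sd, _SD_FLOOR)
    calls = []
    for c in genome.cds_records:
        z = np.mean(np.abs(rscu_vector(c.nucleotide_seq) - profile.mean) / sd)
        n_codons = len(c.nucleotide_seq) // 3
        cutoff = thresholds.alien_score_threshold
        if n_codons < _SHORT_GENE_CODONS:
            cutoff *= 1 + 50 / n_codons
        calls.append(AlienCall(gene_id=c.gene_id, score=float(z),
                               is_alien=bool(z >= cutoff)))
    return calls


def hgt_fraction(calls: list[AlienCall], n_cds: int) -> float:
    """Percentage of CDS called alien."""
    if n_cds < 1:
        raise ValueError("n_cds must be >= 1")
    return 100.0 * sum(c.is_alien for c in calls) / n_cds


def screen_genome(genome: GenomeRecord,
                  thresholds: ThresholdConfig | None = None
                  ) -> tuple[list[AlienCall], float]:
    """Profile, score and summarize one genome."""
    profile = codon_usage_profile(genome.cds_records)
    calls = alienness_scores(genome, profile, thresholds)
    frac = hgt_fraction(calls, genome.n_cds) if genome.n_cds else 0.0
    return calls, frac


def calls_to_dataframe(genome_id: str, calls: list[AlienCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "genome_id": genome_id,
        "gene_id": [c.gene_id for c in calls],
        "score": [c.score for c in calls],
        "is_alien": [int(c.is_alien) for c in calls]})


def read_calls(path) -> pd.DataFrame:
    """Read an alien-call table (own output or an external tool's)."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "gene_id", "score", "is_alien"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    return df
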