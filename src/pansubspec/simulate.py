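"""Synthetic three-subspecies pan-genome cohorts with planted truth.

The generator emits annotated genome assemblies (contig FASTA, GFF3 CDS
annotations, per-gene protein and nucleotide FASTA, a metadata table)
whose pan-genome structure is known exactly: core families carried by
every genome, subspecies marker families at a fixed prevalence,
shell/cloud families by Bernoulli draws, alien genes sampled from a
deviant codon-usage profile, verbatim duplicate genomes, genomes that
each breach exactly one quality rule, and mislabelled strains.  The
planted truth (family membership per gene, alien flags, true subspecies,
violation reasons, duplicate pairs) is returned alongside so every
downstream stage can be scored against it.

Divergence model: each gene family has one ancestral CDS; each
subspecies derives a variant by substituting sites at half the
configured inter-subspecies rate, and each genome derives its gene copy
from the subspecies variant at half the intra-subspecies rate, so
expected pairwise distances match the configured rates.  Substitutions
that would create an internal stop codon are reverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .codons import (AMINO_ACIDS, STOP_CODONS, SYNONYMOUS_FAMILIES,
                     background_and_alien_profiles, profile_separation)
from .config import CohortConfig, ConfigurationError, ThresholdConfig
from .records import CdsRecord, GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class FamilyUniverse:
    """One gene family of the planted universe."""

    family_id: str
    tier: str                       # core | subspecies_marker | shell | cloud
    marker_subspecies: str | None
    target_prevalence: float
    ancestral_protein: str
    ancestral_cds: str
    is_alien: bool = False
    length_codons: int = 0

    def __post_init__(self) -> None:
        if self.tier not in ("core", "subspecies_marker", "shell", "cloud"):
            raise ConfigurationError(f"unknown tier {self.tier!r}")
        self.length_codons = len(self.ancestral_cds) // 3


@dataclass
class TruthLabels:
    """Machine-readable ground truth of a generated cohort."""

    family_of_gene: dict[str, str] = field(default_factory=dict)
    alien_genes: set[str] = field(default_factory=set)
    true_subspecies: dict[str, str] = field(default_factory=dict)
    qc_violations: dict[str, list[str]] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    core_families: list[str] = field(default_factory=list)
    marker_families: dict[str, list[str]] = field(default_factory=dict)
    type_strains: dict[str, str] = field(default_factory=dict)
    thresholds: ThresholdConfig | None = None


def mutate_sequence(seq: str, rate: float, seed) -> str:
    """Substitute each site independently with probability ``rate``.

    A substituted site always changes to one of the three other bases.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    idx = _BASE_INDEX[arr]
    if (idx < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate == 0 or len(seq) == 0:
        return seq.upper()
    hit = rng.random(arr.size) < rate
    shift = rng.integers(1, 4, size=arr.size)
    new_idx = np.where(hit, (idx + shift) % 4, idx)
    return _BASES[new_idx].tobytes().decode("ascii")


def _repair_stops(mutated: str, parent: str) -> str:
    """Revert any codon that mutation turned into a stop."""
    out = []
    changed = False
    for i in range(0, len(mutated), 3):
        codon = mutated[i:i + 3]
        if codon in STOP_CODONS:
            codon = parent[i:i + 3]
            changed = True
        out.append(codon)
    return "".join(out) if changed else mutated


def _sample_cds(length_codons: int, profile: dict[str, float],
                rng: np.random.Generator) -> str:
    """Sample a CDS codon-by-codon: uniform amino acids, profiled synonyms.

    The first residue is fixed to methionine (ATG start); no stop codon is
    appended (annotation-style CDS, protein length == length_codons).
    """
    aas = rng.choice(len(AMINO_ACIDS), size=length_codons)
    codons = []
    for j, ai in enumerate(aas):
        aa = "M" if j == 0 else AMINO_ACIDS[ai]
        fam = SYNONYMOUS_FAMILIES[aa]
        probs = np.array([profile[c] for c in fam])
        codons.append(fam[rng.choice(len(fam), p=probs / probs.sum())])
    return "".join(codons)


def sample_family_universe(config: CohortConfig,
                           background_profile: dict[str, float] | None = None,
                           alien_profile: dict[str, float] | None = None,
                           ) -> list[FamilyUniverse]:
    """Sample the planted gene-family universe for a cohort.

    Families come in four groups: species core, per-subspecies markers
    (of which ``n_alien_markers_per_subspecies`` are horizontally
    acquired, emulating foreign subspecies-core genes), shell and cloud
    accessory families, and per-subspecies pools of alien accessory
    families with deviant codon usage.
    """
    if background_profile is None or alien_profile is None:
        bg, al = background_and_alien_profiles(config.alien_bias)
        background_profile = background_profile or bg
        alien_profile = alien_profile or al
    has_aliens = (config.n_alien_markers_per_subspecies > 0
                  or config.n_alien_pool_per_subspecies > 0)
    if has_aliens:
        sep = profile_separation(alien_profile, background_profile)
        if sep < config.alien_min_kl:
            raise ConfigurationError(
                f"alien/background codon-usage separation {sep:.3f} below "
                f"required {config.alien_min_kl}")

    ss = np.random.SeedSequence(config.seed)
    rng_len, rng_bg, rng_alien, rng_prev = (np.random.default_rng(s)
                                            for s in ss.spawn(4))
    lo = max(100, config.mean_cds_length_codons - 30)
    hi = config.mean_cds_length_codons + 31

    families: list[FamilyUniverse] = []

    def add(fid, tier, marker, prev, alien):
        length = int(rng_len.integers(lo, hi))
        profile = alien_profile if alien else background_profile
        rng = rng_alien if alien else rng_bg
        cds = _sample_cds(length, profile, rng)
        families.append(FamilyUniverse(
            family_id=fid, tier=tier, marker_subspecies=marker,
            target_prevalence=prev, ancestral_protein=str(Seq(cds).translate()),
            ancestral_cds=cds, is_alien=alien))

    for i in range(config.n_core):
        add(f"core_{i:04d}", "core", None, 1.0, False)
    for s in config.subspecies_names:
        for i in range(config.n_marker):
            alien = i < config.n_alien_markers_per_subspecies
            add(f"marker_{s}_{i:03d}", "subspecies_marker", s,
                config.marker_prevalence, alien)
    for i in range(config.n_shell):
        add(f"shell_{i:04d}", "shell", None,
            float(np.round(rng_prev.uniform(0.3, 0.7), 4)), False)
    for i in range(config.n_cloud):
        add(f"cloud_{i:04d}", "cloud", None,
            float(np.round(rng_prev.uniform(0.02, 0.15), 4)), False)
    for s in config.subspecies_names:
        for i in range(config.n_alien_pool_per_subspecies):
            add(f"alienpool_{s}_{i:03d}", "cloud", s, 0.5, True)
    return families


def _random_spacer(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _assemble(genome_id: str, label: str, genes: list[tuple[str, str]],
              spacers: list[str], coverage: float,
              n_contigs: int = 1) -> GenomeRecord:
    """Lay genes onto ``n_contigs`` contigs with the given spacers.

    ``spacers`` has one entry per gene (preceding it) plus a trailing one.
    """
    assert len(spacers) == len(genes) + 1
    groups: list[list[int]] = [[] for _ in range(n_contigs)]
    per = max(1, -(-len(genes) // n_contigs))
    for i in range(len(genes)):
        groups[min(i // per, n_contigs - 1)].append(i)
    contigs: dict[str, str] = {}
    cds_records: list[CdsRecord] = []
    for ci, group in enumerate(groups):
        cid = f"{genome_id}_contig{ci:03d}"
        parts = [spacers[group[0]]] if group else []
        pos = len(parts[0]) if group else 0
        for i in group:
            fam_id, cds = genes[i]
            start = pos + 1
            end = pos + len(cds)
            cds_records.append(CdsRecord(
                gene_id=f"{genome_id}|{fam_id}", genome_id=genome_id,
                contig_id=cid, start=start, end=end, nucleotide_seq=cds,
                protein_seq=str(Seq(cds).translate())))
            parts.append(cds)
            parts.append(spacers[i + 1])
            pos = end + len(spacers[i + 1])
        contigs[cid] = "".join(parts)
    return GenomeRecord(genome_id=genome_id, subspecies_label=label,
                        contigs=contigs, coverage=coverage,
                        cds_records=cds_records)


def _carried_families(universe, config, subspecies, genome_index,
                      rng_shell: np.random.Generator) -> list[FamilyUniverse]:
    """Deterministic family carriage for one genome (excluding alien pool)."""
    carried = []
    n_sub = dict(zip(config.subspecies_names, config.n_genomes_per_subspecies))
    for fam in universe:
        if fam.tier == "core":
            carried.append(fam)
        elif fam.tier == "subspecies_marker":
            if fam.marker_subspecies != subspecies:
                continue
            n_carriers = int(round(fam.target_prevalence * n_sub[subspecies]))
            if genome_index < n_carriers:
                carried.append(fam)
        elif fam.tier in ("shell", "cloud") and not fam.is_alien:
            if rng_shell.random() < fam.target_prevalence:
                carried.append(fam)
    return carried


def _alien_block(universe, config, subspecies, genome_index, n_native) -> list:
    """Rotating block of the subspecies alien pool sized to the alien fraction."""
    frac = dict(zip(config.subspecies_names,
                    config.alien_fraction_per_subspecies))[subspecies]
    pool = [f for f in universe
            if f.is_alien and f.tier == "cloud" and f.marker_subspecies == subspecies]
    if frac == 0 or not pool:
        return []
    # alternate strict half-blocks of the pool so every alien family stays
    # near 50% in-group prevalence, safely below the subspecies-core rule
    half = max(1, len(pool) // 2)
    want = min(int(round(frac / (1 - frac) * n_native)), half)
    start = (genome_index % 2) * half
    block = pool[start:start + half] if start else pool[:half]
    return block[:want]


def generate_cohort(universe: list[FamilyUniverse], config: CohortConfig
                    ) -> tuple[list[GenomeRecord], TruthLabels]:
    """Emit the annotated genome cohort and its truth labels.

    Genome order: clean genomes per subspecies, then QC violators, then
    duplicates.  Type strains are the first clean genome of each
    subspecies; mislabelled genomes are chosen among clean genomes with
    index >= 2 so they never collide with type strains or duplicates.
    """
    ss = np.random.SeedSequence([config.seed, 1])
    rng_variant, rng_gene, rng_spacer, rng_shell, rng_cov, rng_viol = (
        np.random.default_rng(s) for s in ss.spawn(6))

    truth = TruthLabels()
    truth.core_families = [f.family_id for f in universe if f.tier == "core"]
    truth.marker_families = {
        s: [f.family_id for f in universe
            if f.tier == "subspecies_marker" and f.marker_subspecies == s]
        for s in config.subspecies_names}

    # per-family, per-subspecies ancestral variants (half the inter rate each)
    variants: dict[tuple[str, str], str] = {}
    for fam in universe:
        for s in config.subspecies_names:
            v = mutate_sequence(fam.ancestral_cds,
                                config.inter_subspecies_divergence / 2, rng_variant)
            variants[(fam.family_id, s)] = _repair_stops(v, fam.ancestral_cds)

    # spacers are inherited DNA too: one ancestral spacer per family slot
    # (plus the contig start), mutated down the same subspecies/genome
    # cascade, so whole-genome identity reflects the configured divergences
    spacer_variants: dict[tuple[str, str], str] = {}
    for key in ["^start"] + [f.family_id for f in universe]:
        anc = _random_spacer(config.spacer_len_bp, rng_spacer)
        for s in config.subspecies_names:
            spacer_variants[(key, s)] = mutate_sequence(
                anc, config.inter_subspecies_divergence / 2, rng_spacer)

    def make_genes(subspecies, genome_index):
        carried = _carried_families(universe, config, subspecies, genome_index,
                                    rng_shell)
        carried += _alien_block(universe, config, subspecies, genome_index,
                                len(carried))
        genes = []
        intra = config.intra_subspecies_divergence / 2
        spacers = [mutate_sequence(spacer_variants[("^start", subspecies)],
                                   intra, rng_gene)]
        for fam in carried:
            parent = variants[(fam.family_id, subspecies)]
            g = mutate_sequence(parent, intra, rng_gene)
            genes.append((fam.family_id, _repair_stops(g, parent)))
            spacers.append(mutate_sequence(
                spacer_variants[(fam.family_id, subspecies)], intra, rng_gene))
        return genes, spacers

    records: list[GenomeRecord] = []

    def register(rec: GenomeRecord, true_ss: str,
                 genes: list[tuple[str, str]], alien_ids: set[str]) -> None:
        records.append(rec)
        truth.true_subspecies[rec.genome_id] = true_ss
        for fam_id, _ in genes:
            truth.family_of_gene[f"{rec.genome_id}|{fam_id}"] = fam_id
        truth.alien_genes.update(f"{rec.genome_id}|{fid}" for fid in alien_ids)

    alien_family_ids = {f.family_id for f in universe if f.is_alien}

    # clean genomes
    for s, n in zip(config.subspecies_names, config.n_genomes_per_subspecies):
        for j in range(n):
            gid = f"G_{s}_{j:03d}"
            genes, spacers = make_genes(s, j)
            cov = float(np.round(rng_cov.uniform(50, 100), 1))
            rec = _assemble(gid, s, genes, spacers, cov)
            register(rec, s, genes,
                     {fid for fid, _ in genes if fid in alien_family_ids})
            if j == 0:
                truth.type_strains[s] = gid

    clean = list(records)
    if clean:
        thresholds = ThresholdConfig(
            min_genome_size_bp=int(0.85 * min(r.size_bp for r in clean)),
            min_cds=int(0.85 * min(r.n_cds for r in clean)),
            max_contigs=10, min_coverage=30.0)
    else:
        thresholds = ThresholdConfig(min_genome_size_bp=1, min_cds=1,
                                     max_contigs=10, min_coverage=30.0)
    truth.thresholds = thresholds

    # QC violators: each breaches exactly one rule of the scaled thresholds
    modes = ["size", "cds", "contigs", "coverage"]
    n_ss = len(config.subspecies_names)
    for v in range(config.n_qc_violators):
        s = config.subspecies_names[v % n_ss]
        mode = modes[v % len(modes)]
        gid = f"G_{s}_viol{v:02d}"
        genes, spacers = make_genes(s, 0)
        cov = float(np.round(rng_cov.uniform(50, 100), 1))
        n_contigs = 1
        if mode == "size":
            short = []
            for fid, cds in genes:
                keep = max(30, (len(cds) // 3) * 3 * 6 // 10 // 3 * 3)
                short.append((fid, cds[:keep]))
            genes = short
        elif mode == "cds":
            keep_n = max(1, thresholds.min_cds - 5)
            dropped = sum(len(c) for _, c in genes[keep_n:])
            genes = genes[:keep_n]
            spacers = spacers[:keep_n + 1]
            # filler spacer keeps the size rule satisfied despite fewer genes
            genes_filler = dropped
        elif mode == "contigs":
            n_contigs = thresholds.max_contigs + 5
        elif mode == "coverage":
            cov = float(np.round(thresholds.min_coverage / 3, 1))
        rec = _assemble(gid, s, genes, spacers, cov, n_contigs=n_contigs)
        if mode == "cds":
            cid = next(iter(rec.contigs))
            rec.contigs[cid] = rec.contigs[cid] + _random_spacer(genes_filler,
                                                                 rng_viol)
        register(rec, s, genes,
                 {fid for fid, _ in genes if fid in alien_family_ids})
        truth.qc_violations[gid] = [mode]

    # verbatim duplicates of clean genomes (index 1 of each subspecies if any)
    for d in range(config.n_duplicates):
        s = config.subspecies_names[d % n_ss]
        n = dict(zip(config.subspecies_names,
                     config.n_genomes_per_subspecies))[s]
        if n == 0:
            continue
        src_idx = 1 if n > 1 else 0
        src = next(r for r in clean if r.genome_id == f"G_{s}_{src_idx:03d}")
        gid = f"{src.genome_id}_dup{d:02d}"
        contigs = {k.replace(src.genome_id, gid): v for k, v in src.contigs.items()}
        cds = [CdsRecord(gene_id=c.gene_id.replace(src.genome_id, gid, 1),
                         genome_id=gid,
                         contig_id=c.contig_id.replace(src.genome_id, gid),
                         start=c.start, end=c.end,
                         nucleotide_seq=c.nucleotide_seq,
                         protein_seq=c.protein_seq)
               for c in src.cds_records]
        rec = GenomeRecord(genome_id=gid, subspecies_label=s, contigs=contigs,
                           coverage=src.coverage, cds_records=cds)
        src_genes = [(truth.family_of_gene[c.gene_id], c.nucleotide_seq)
                     for c in src.cds_records]
        register(rec, s, [(f, None) for f, _ in src_genes],
                 {f for f, _ in src_genes if f in alien_family_ids})
        truth.duplicate_pairs.append((src.genome_id, gid))

    # mislabel clean genomes (index >= 2), wrong label = next subspecies
    mislabelled = 0
    for j, s in enumerate(config.subspecies_names * config.n_mislabelled):
        if mislabelled >= config.n_mislabelled:
            break
        n = dict(zip(config.subspecies_names,
                     config.n_genomes_per_subspecies))[s]
        idx = 2 + j // n_ss
        if idx >= n:
            continue
        gid = f"G_{s}_{idx:03d}"
        rec = next(r for r in records if r.genome_id == gid)
        wrong = config.subspecies_names[(config.subspecies_names.index(s) + 1)
                                        % n_ss]
        rec.subspecies_label = wrong
        mislabelled += 1

    return records, truth
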