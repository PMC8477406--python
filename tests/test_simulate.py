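"""Synthetic cohort generator: determinism, planted structure, sequence laws."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from pansubspec.codons import (SYNONYMOUS_FAMILIES, codon_profile,
                               background_and_alien_profiles,
                               profile_separation)
from pansubspec.config import CohortConfig, ConfigurationError
from pansubspec.simulate import (generate_cohort, mutate_sequence,
                                 sample_family_universe)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestMutateSequence:
    def test_zero_rate_identity(self):
        assert mutate_sequence("ACGTACGT", 0.0, 1) == "ACGTACGT"

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGN", 0.1, 1)

    def test_rate_recovered_within_binomial_interval(self):
        # 99% interval for Bin(10000, 0.02)/10000
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10000))
        out = mutate_sequence(seq, 0.02, 5)
        ham = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert 0.014 <= ham <= 0.026

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seq=DNA, rate=st.floats(0, 1), seed=st.integers(0, 2**31 - 1))
    def test_determinism_and_length(self, seq, rate, seed):
        a = mutate_sequence(seq, rate, seed)
        b = mutate_sequence(seq, rate, seed)
        assert a == b and len(a) == len(seq)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seq=DNA, seed=st.integers(0, 2**31 - 1))
    def test_rate_one_changes_every_site(self, seq, seed):
        out = mutate_sequence(seq, 1.0, seed)
        assert all(a != b for a, b in zip(seq, out))


class TestFamilyUniverse:
    def test_empty_universe(self):
        cfg = CohortConfig(n_core=0, n_marker=0, n_shell=0, n_cloud=0,
                           alien_fraction_per_subspecies=(0, 0, 0),
                           n_alien_markers_per_subspecies=0)
        assert sample_family_universe(cfg) == []

    def test_same_seed_identical(self):
        cfg = CohortConfig(n_core=5, n_marker=2, n_shell=3, n_cloud=3, seed=9)
        a = sample_family_universe(cfg)
        b = sample_family_universe(cfg)
        assert [(f.family_id, f.ancestral_cds) for f in a] == \
               [(f.family_id, f.ancestral_cds) for f in b]

    def test_translation_consistency(self):
        cfg = CohortConfig(n_core=10, n_marker=1, n_shell=2, n_cloud=2, seed=1)
        for fam in sample_family_universe(cfg):
            assert str(Seq(fam.ancestral_cds).translate()) == \
                fam.ancestral_protein
            assert "*" not in fam.ancestral_protein

    def test_uniform_profile_gives_uniform_synonymous_usage(self):
        # multinomial oracle: each codon's within-family frequency should sit
        # within 3 SD of 1/family-size when sampled from a uniform profile
        cfg = CohortConfig(n_core=50, n_marker=0, n_shell=0, n_cloud=0,
                           alien_fraction_per_subspecies=(0, 0, 0),
                           n_alien_markers_per_subspecies=0, seed=2)
        uniform = codon_profile(1.0)
        fams = sample_family_universe(cfg, background_profile=uniform,
                                      alien_profile=uniform)
        counts: dict[str, int] = {}
        for f in fams:
            for i in range(0, len(f.ancestral_cds), 3):
                c = f.ancestral_cds[i:i + 3]
                counts[c] = counts.get(c, 0) + 1
        for codons in SYNONYMOUS_FAMILIES.values():
            if len(codons) < 2:
                continue
            n = sum(counts.get(c, 0) for c in codons)
            p = 1 / len(codons)
            sd = (n * p * (1 - p)) ** 0.5
            for c in codons:
                assert abs(counts.get(c, 0) - n * p) <= 3 * sd + 1

    def test_alien_separability(self):
        cfg = CohortConfig()
        bg, al = background_and_alien_profiles(cfg.alien_bias)
        assert profile_separation(al, bg) >= cfg.alien_min_kl

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_core=-1)
        with pytest.raises(ConfigurationError):
            CohortConfig(intra_subspecies_divergence=0.1,
                         inter_subspecies_divergence=0.05)


class TestGenerateCohort:
    def test_duplicate_is_verbatim_copy(self, small_cohort):
        _, _, records, truth = small_cohort
        assert truth.duplicate_pairs
        by_id = {r.genome_id: r for r in records}
        for src, dup in truth.duplicate_pairs:
            assert (sorted(by_id[src].contigs.values())
                    == sorted(by_id[dup].contigs.values()))

    def test_marker_prevalence_exact(self, default_cohort):
        # realized prevalence = round(p * n) / n, lowest genome indices carry
        cfg, _, records, truth = default_cohort
        clean = {r.genome_id for r in records
                 if r.genome_id not in truth.qc_violations
                 and all(r.genome_id != d for _, d in truth.duplicate_pairs)}
        for s, n in zip(cfg.subspecies_names, cfg.n_genomes_per_subspecies):
            members = [f"G_{s}_{j:03d}" for j in range(n)]
            expected = round(cfg.marker_prevalence * n)
            for fam in truth.marker_families[s]:
                carriers = [g for g in members
                            if f"{g}|{fam}" in truth.family_of_gene]
                assert carriers == members[:expected]

    def test_within_subspecies_identity_exceeds_between(self, small_cohort):
        # gapless comparison of orthologous core CDS, the planted ordering
        cfg, _, records, truth = small_cohort
        fam = truth.core_families[0]
        seqs = {}
        for r in records:
            if r.genome_id in truth.qc_violations:
                continue
            for c in r.cds_records:
                if truth.family_of_gene.get(c.gene_id) == fam:
                    seqs[r.genome_id] = c.nucleotide_seq
        def ident(a, b):
            return np.mean([x == y for x, y in zip(a, b)])
        within, between = [], []
        gids = sorted(seqs)
        for i, a in enumerate(gids):
            for b in gids[i + 1:]:
                same = truth.true_subspecies[a] == truth.true_subspecies[b]
                (within if same else between).append(ident(seqs[a], seqs[b]))
        assert min(within) > max(between)

    def test_translation_consistency_of_emitted_genes(self, small_cohort):
        _, _, records, _ = small_cohort
        for r in records[:3]:
            for c in r.cds_records:
                c.validate_translation()

    def test_reproducibility_byte_identical(self, tmp_path, small_config):
        import hashlib
        from pansubspec.io import write_cohort
        from pansubspec.simulate import generate_cohort, sample_family_universe

        def run(sub):
            out = tmp_path / sub
            uni = sample_family_universe(small_config)
            records, truth = generate_cohort(uni, small_config)
            write_cohort(records, out, truth)
            return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(out.iterdir())}

        assert run("a") == run("b")

    def test_qc_violators_breach_exactly_one_rule(self, default_cohort):
        _, _, records, truth = default_cohort
        thr = truth.thresholds
        by_id = {r.genome_id: r for r in records}
        for gid, reasons in truth.qc_violations.items():
            r = by_id[gid]
            breached = []
            if r.size_bp < thr.min_genome_size_bp:
                breached.append("size")
            if r.n_cds < thr.min_cds:
                breached.append("cds")
            if r.n_contigs > thr.max_contigs:
                breached.append("contigs")
            if r.coverage is not None and r.coverage < thr.min_coverage:
                breached.append("coverage")
            assert breached == reasons
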