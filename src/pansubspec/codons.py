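"""Codon bookkeeping shared by the simulator and the HGT screen.

Uses the standard bacterial/standard genetic code.  "Informative"
codons are the 59 sense codons whose amino acid has more than one
synonym (i.e. excluding ATG and TGG); relative synonymous codon usage
(RSCU) is only meaningful for those.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: amino acid -> sorted tuple of its synonymous codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(CODON_TO_AA[_codon], ())
for _codon in SENSE_CODONS:
    aa = CODON_TO_AA[_codon]
    SYNONYMOUS_FAMILIES[aa] = tuple(sorted(SYNONYMOUS_FAMILIES[aa] + (_codon,)))

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(SYNONYMOUS_FAMILIES))

#: the 59 codons with at least one synonym (ATG and TGG excluded)
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if len(SYNONYMOUS_FAMILIES[CODON_TO_AA[c]]) > 1
)
INFORMATIVE_INDEX: dict[str, int] = {c: i for i, c in enumerate(INFORMATIVE_CODONS)}


def codon_profile(bias: float, favour: str = "GC") -> dict[str, float]:
    """Within-family codon preference weights, normalized per synonymous family.

    ``bias`` is the odds ratio favouring codons whose third position is in
    ``favour`` (default G/C, the typical preference of a high-GC organism
    such as *Bifidobacterium*).  ``bias=1`` gives uniform synonymous usage.
    """
    if bias <= 0:
        raise ValueError("bias must be positive")
    prefs: dict[str, float] = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        weights = np.array([bias if c[2] in favour else 1.0 for c in codons])
        weights /= weights.sum()
        for c, w in zip(codons, weights):
            prefs[c] = float(w)
    return prefs


def background_and_alien_profiles(bias: float) -> tuple[dict[str, float], dict[str, float]]:
    """Host (GC3-favouring) and alien (AT3-favouring) synonymous preferences."""
    return codon_profile(bias, "GC"), codon_profile(bias, "AT")


def profile_separation(p: dict[str, float], q: dict[str, float]) -> float:
    """Mean per-synonymous-family KL divergence KL(p || q), in nats.

    Families with a single codon contribute 0 and are skipped.
    """
    kls = []
    for codons in SYNONYMOUS_FAMILIES.values():
        if len(codons) < 2:
            continue
        pv = np.array([p[c] for c in codons])
        qv = np.array([q[c] for c in codons])
        kls.append(float(np.sum(pv * np.log(pv / qv))))
    return float(np.mean(kls))


def rscu_vector(seq: str) -> np.ndarray:
    """RSCU over the 59 informative codons for one CDS.

    RSCU of codon c = observed count / (family count / family size).
    Codons of amino acids unobserved in the gene get RSCU 1 by convention.
    """
    if len(seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3].upper()
        counts[codon] = counts.get(codon, 0) + 1
    out = np.ones(len(INFORMATIVE_CODONS))
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        if len(codons) < 2:
            continue
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        expected = total / len(codons)
        for c in codons:
            out[INFORMATIVE_INDEX[c]] = counts.get(c, 0) / expected
    return out
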