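"""Presence/absence matrix, pan/core/TUG statistics, rarefaction and
subspecies-specific core genomes.

Presence means count >= 1 (paralogs collapse to "present").  The
species core is the set of families present in 100 % of genomes; a
truly unique gene (TUG) family is present in exactly one genome.  The
subspecies-specific core of subspecies *s* consists of families present
in at least ``prevalence_min`` (default 85 %) of the genomes of *s* and
in at most ``other_prevalence_max`` (default 0 = strict absence) of
each other subspecies.  Rarefaction adds genomes in random order and
tracks pan and core sizes; pan-genome openness is assessed by the mean
number of new families over the last few steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import GeneFamily
from .config import ThresholdConfig


class PangenomeInputError(ValueError):
    pass


@dataclass
class PresenceAbsenceMatrix:
    """Genomes x families count matrix with per-genome subspecies labels."""

    counts: pd.DataFrame                 # index: genome ids, columns: family ids
    subspecies: dict[str, str | None]

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.columns)


def build_presence_matrix(families: list[GeneFamily], genomes: list[str],
                          subspecies: dict[str, str | None] | None = None
                          ) -> PresenceAbsenceMatrix:
    """Counts of family members per genome (paralogs counted, capped later)."""
    known = set(genomes)
    counts = pd.DataFrame(0, index=list(genomes),
                          columns=[f.family_id for f in families], dtype=int)
    for fam in families:
        for genome_id, _ in fam.members:
            if genome_id not in known:
                raise PangenomeInputError(
                    f"family {fam.family_id} references unknown genome "
                    f"{genome_id}")
            counts.loc[genome_id, fam.family_id] += 1
    return PresenceAbsenceMatrix(counts=counts,
                                 subspecies=dict(subspecies or
                                                 {g: None for g in genomes}))


def core_and_unique(pa: PresenceAbsenceMatrix
                    ) -> tuple[list[str], dict[str, int]]:
    """Species core family ids and TUG count per genome."""
    if pa.counts.empty:
        raise PangenomeInputError("empty presence/absence matrix")
    pres = pa.presence
    core = list(pres.columns[pres.all(axis=0)])
    single = pres.columns[pres.sum(axis=0) == 1]
    tugs = pres[single].sum(axis=1).astype(int).to_dict()
    return core, tugs


@dataclass
class PanCurve:
    """Per-permutation pan/core trajectories and the openness tail statistic."""

    table: pd.DataFrame   # columns: permutation, step, pan, core, new
    tail_statistic: float
    n_permutations: int
    seed: int


def rarefaction_curves(pa: PresenceAbsenceMatrix, n_permutations: int = 100,
                       seed: int = 0, tail_k: int = 3) -> PanCurve:
    """Pan/core rarefaction over random genome orderings.

    The tail statistic is the mean number of newly added families over
    the last ``tail_k`` steps, across permutations — the quantity used
    to judge whether the pan-genome is still open.
    """
    pres = pa.presence.to_numpy()
    n = pres.shape[0]
    if n < 2:
        raise PangenomeInputError("rarefaction requires >= 2 genomes")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_permutations):
        order = rng.permutation(n)
        m = pres[order]
        pan = np.logical_or.accumulate(m, axis=0).sum(axis=1)
        core = np.logical_and.accumulate(m, axis=0).sum(axis=1)
        new = np.diff(pan, prepend=0)
        for step in range(n):
            rows.append((p, step + 1, int(pan[step]), int(core[step]),
                         int(new[step])))
    table = pd.DataFrame(rows, columns=["permutation", "step", "pan", "core",
                                        "new"])
    tail = table[table["step"] > n - tail_k]["new"].mean() if n > 1 else 0.0
    return PanCurve(table=table, tail_statistic=float(tail),
                    n_permutations=n_permutations, seed=seed)


@dataclass
class SubspeciesCoreSet:
    subspecies: str
    families: pd.DataFrame  # family_id, prevalence, out-group prevalences

    @property
    def family_ids(self) -> list[str]:
        return list(self.families["family_id"])


def subspecies_core(pa: PresenceAbsenceMatrix,
                    thresholds: ThresholdConfig | None = None
                    ) -> dict[str, SubspeciesCoreSet]:
    """Subspecies-specific core families under the prevalence/absence rule."""
    thresholds = thresholds or ThresholdConfig()
    unlabelled = [g for g in pa.genome_ids if not pa.subspecies.get(g)]
    if unlabelled:
        raise PangenomeInputError(f"unlabelled genomes: {unlabelled[:5]}")
    labels = pd.Series({g: pa.subspecies[g] for g in pa.genome_ids})
    pres = pa.presence
    prevalence = pres.groupby(labels).mean()  # subspecies x families
    out: dict[str, SubspeciesCoreSet] = {}
    for s in prevalence.index:
        others = prevalence.drop(index=s)
        keep = ((prevalence.loc[s] >= thresholds.prevalence_min)
                & (others <= thresholds.other_prevalence_max).all(axis=0))
        fams = prevalence.columns[keep]
        df = pd.DataFrame({
            "family_id": fams,
            "prevalence": prevalence.loc[s, fams].to_numpy(),
        })
        for o in others.index:
            df[f"prevalence_{o}"] = others.loc[o, fams].to_numpy()
        out[s] = SubspeciesCoreSet(subspecies=s,
                                   families=df.reset_index(drop=True))
    return out
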