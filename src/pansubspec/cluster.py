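"""Gene-family (COG) clustering.

Candidate protein pairs are found by an exact shared-k-mer prefilter,
scored by global Needleman-Wunsch alignment (BLOSUM62, affine gaps,
BLAST-like 11/1 gap costs via Bio.Align.PairwiseAligner), filtered by
the identity/coverage rules (>= 50 % identity over >= 80 % of both
sequences by default), and the resulting similarity graph is clustered
with the Markov Cluster algorithm (MCL).

Identity is computed over aligned columns excluding terminal-gap
columns, so genuinely homologous fragments are not penalized for length;
coverage counts each sequence's residues inside the non-terminal-gap
core, which is what makes fragments fail the 80 % coverage rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .config import ThresholdConfig
from .records import CdsRecord

_PRUNE = 1e-6
_TOL = 1e-8
_MAX_ITER = 200


@dataclass
class AlignmentStats:
    protein_a: str
    protein_b: str
    identity_pct: float
    coverage_a: float
    coverage_b: float
    score: float
    n_columns: int = 0   # aligned columns excluding terminal gaps


@dataclass
class SimilarityGraph:
    nodes: list[str]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def add_edge(self, i: int, j: int, weight: float) -> None:
        if i == j or weight <= 0:
            return
        self.edges[(min(i, j), max(i, j))] = weight


@dataclass
class GeneFamily:
    family_id: str
    members: list[tuple[str, str]]  # (genome_id, gene_id)

    @property
    def n_genomes(self) -> int:
        return len({g for g, _ in self.members})


def kmer_prefilter(proteins: list[CdsRecord], k: int = 5,
                   min_shared: int = 2) -> list[tuple[int, int]]:
    """Unordered index pairs sharing at least ``min_shared`` distinct aa k-mers.

    Exact (no sampling), so any pair that can pass the downstream
    identity/coverage rules at realistic divergence is returned.
    ``min_shared=0`` disables filtering and returns all pairs.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    n = len(proteins)
    if min_shared == 0:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    kmer_sets = [frozenset(p.protein_seq[i:i + k]
                           for i in range(len(p.protein_seq) - k + 1))
                 for p in proteins]
    index: dict[str, list[int]] = {}
    for gi, ks in enumerate(kmer_sets):
        for km in ks:
            index.setdefault(km, []).append(gi)
    # count shared k-mers per pair with chunked numpy unique
    counts: dict[int, int] = {}
    chunk: list[np.ndarray] = []
    chunk_size = 0

    def flush():
        nonlocal chunk, chunk_size
        if not chunk:
            return
        codes, c = np.unique(np.concatenate(chunk), return_counts=True)
        for code, cnt in zip(codes.tolist(), c.tolist()):
            counts[code] = counts.get(code, 0) + cnt
        chunk, chunk_size = [], 0

    for members in index.values():
        m = len(members)
        if m < 2:
            continue
        arr = np.asarray(members, dtype=np.int64)
        ii, jj = np.triu_indices(m, k=1)
        chunk.append(arr[ii] * n + arr[jj])
        chunk_size += ii.size
        if chunk_size > 5_000_000:
            flush()
    flush()
    return sorted((code // n, code % n)
                  for code, c in counts.items() if c >= min_shared)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST convention: gap of length L costs 11 + L
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def align_pair_global(a: str, b: str,
                      aligner: Align.PairwiseAligner | None = None
                      ) -> AlignmentStats:
    """Global alignment statistics under the terminal-gap conventions above."""
    if not a or not b:
        raise ValueError("empty protein sequence")
    if a == b:
        return AlignmentStats("", "", 100.0, 1.0, 1.0, 0.0, len(a))
    aligner = aligner or _ALIGNER
    alignment = aligner.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    arr_a = np.frombuffer(ga.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(gb.encode(), dtype=np.uint8)
    gap = ord("-")
    res_a = arr_a != gap
    res_b = arr_b != gap
    both = res_a & res_b
    idx = np.nonzero(both)[0]
    if idx.size == 0:
        return AlignmentStats("", "", 0.0, 0.0, 0.0, float(alignment.score), 0)
    lo, hi = idx[0], idx[-1] + 1  # core: first..last column with both residues
    core_cols = hi - lo
    matches = int(np.count_nonzero((arr_a[lo:hi] == arr_b[lo:hi]) & both[lo:hi]))
    identity = 100.0 * matches / core_cols
    cov_a = float(np.count_nonzero(res_a[lo:hi])) / len(a)
    cov_b = float(np.count_nonzero(res_b[lo:hi])) / len(b)
    return AlignmentStats("", "", identity, cov_a, cov_b,
                          float(alignment.score), int(core_cols))


def build_similarity_graph(proteins: list[CdsRecord],
                           pairs: list[tuple[int, int]],
                           thresholds: ThresholdConfig) -> SimilarityGraph:
    """Align candidate pairs and keep edges passing identity/coverage rules.

    Edge weight = identity_pct x min(coverage_a, coverage_b).
    """
    graph = SimilarityGraph(nodes=[p.gene_id for p in proteins])
    for i, j in pairs:
        stats = align_pair_global(proteins[i].protein_seq, proteins[j].protein_seq)
        if (stats.identity_pct >= thresholds.family_min_identity_pct
                and stats.coverage_a >= thresholds.family_min_coverage
                and stats.coverage_b >= thresholds.family_min_coverage):
            graph.add_edge(i, j, stats.identity_pct
                           * min(stats.coverage_a, stats.coverage_b))
    return graph


def _mcl_component(weights: np.ndarray, inflation: float) -> list[list[int]]:
    """Run MCL on one dense component matrix; return clusters of local indices."""
    n = weights.shape[0]
    m = weights.copy()
    incident_max = m.max(axis=0)
    np.fill_diagonal(m, np.where(incident_max > 0, incident_max, 1.0))
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(_MAX_ITER):
        prev = m
        m = m @ m
        m = m ** inflation
        m[m < _PRUNE] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.max(np.abs(m - prev)) < _TOL:
            break
    else:
        warnings.warn("MCL did not converge in 200 iterations; "
                      "using last iterate", stacklevel=2)
    # attractor interpretation: rows with nonzero diagonal seed clusters;
    # overlapping attractor rows merge; stragglers follow their strongest column
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    attractors = [i for i in range(n) if m[i, i] > _PRUNE]
    for i in attractors:
        for j in np.nonzero(m[i] > _PRUNE)[0]:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[rj] = ri
    covered = set()
    for i in attractors:
        covered.update(int(j) for j in np.nonzero(m[i] > _PRUNE)[0])
        covered.add(i)
    for j in range(n):
        if j not in covered:
            target = int(np.argmax(m[:, j]))
            ri, rj = find(target), find(j)
            if ri != rj:
                parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for x in range(n):
        clusters.setdefault(find(x), []).append(x)
    return sorted(clusters.values())


def mcl_cluster(graph: SimilarityGraph, proteins: list[CdsRecord],
                inflation: float = 2.0) -> list[GeneFamily]:
    """Markov clustering of the similarity graph into gene families.

    MCL is run independently per connected component (MCL never merges
    components, so this is exact and keeps the dense matrices small).
    Singleton nodes become singleton families.  Families are numbered
    deterministically by their lexicographically smallest member.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    n = len(graph.nodes)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j) in graph.edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    comps: dict[int, list[int]] = {}
    for x in range(n):
        comps.setdefault(find(x), []).append(x)

    member_lists: list[list[int]] = []
    for comp in comps.values():
        if len(comp) == 1:
            member_lists.append(comp)
            continue
        local = {g: li for li, g in enumerate(comp)}
        w = np.zeros((len(comp), len(comp)))
        for (i, j), wt in graph.edges.items():
            if i in local:
                w[local[i], local[j]] = wt
                w[local[j], local[i]] = wt
        for cluster in _mcl_component(w, inflation):
            member_lists.append([comp[li] for li in cluster])

    member_lists.sort(key=lambda ml: min(graph.nodes[i] for i in ml))
    families = []
    for fi, ml in enumerate(member_lists):
        members = sorted((proteins[i].genome_id, proteins[i].gene_id)
                         for i in ml)
        families.append(GeneFamily(family_id=f"fam_{fi:05d}", members=members))
    return families


def cluster_genes(records, thresholds: ThresholdConfig | None = None,
                  k: int = 5, min_shared: int = 2) -> list[GeneFamily]:
    """End-to-end clustering of all CDS of a genome collection."""
    thresholds = thresholds or ThresholdConfig()
    proteins = [c for r in records for c in r.cds_records]
    pairs = kmer_prefilter(proteins, k=k, min_shared=min_shared)
    graph = build_similarity_graph(proteins, pairs, thresholds)
    return mcl_cluster(graph, proteins, thresholds.mcl_inflation)
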