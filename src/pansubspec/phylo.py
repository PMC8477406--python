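"""Core-genome distances, neighbour-joining tree, gene-wise bootstrap and
type-strain classification.

The distance between two genomes is the alignment-length-weighted mean
of per-core-family pairwise p-distances (one representative member per
genome per family, the longest protein).  This is the one intentional
methodological substitution in the tree stage: instead of aligning a
concatenated super-sequence with a progressive MSA and reading distances
off the alignment, distances are averaged over per-family pairwise
global alignments — equivalent input to NJ up to MSA quality.
Bootstrap resamples core families with replacement (gene-wise
bootstrap); supports are the percentage of replicate trees containing
the same leaf bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ani import PairwiseAniTable
from .cluster import GeneFamily, align_pair_global


class PhyloInputError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise PhyloInputError("distance matrix shape mismatch")
        if not np.allclose(m, m.T) or (np.diag(m) != 0).any() or (m < 0).any():
            raise PhyloInputError("distance matrix must be symmetric, "
                                  "non-negative, zero-diagonal")
        self.matrix = m

    def to_phylip(self) -> str:
        """Square PHYLIP format (names truncated/padded to 10 chars)."""
        lines = [f"{len(self.ids):5d}"]
        for name, row in zip(self.ids, self.matrix):
            cells = " ".join(f"{v:.8f}" for v in row)
            lines.append(f"{name[:10]:<10} {cells}")
        return "\n".join(lines) + "\n"


@dataclass
class TreeNode:
    """Node of an unrooted NJ tree (rooted at the final trifurcation)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick() for c in self.children)
        label = "" if self.support is None else str(int(round(self.support)))
        return f"({inner}){label}:{self.length:.10g}"


def leaf_path_lengths(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """All-pairs path lengths between leaves (additivity oracle)."""
    names = sorted(tree.leaf_names())
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    dist = np.zeros((n, n))

    def walk(node) -> dict[int, float]:
        if node.is_leaf:
            return {idx[node.name]: 0.0}
        below: list[dict[int, float]] = []
        for c in node.children:
            d = walk(c)
            below.append({k: v + c.length for k, v in d.items()})
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for i, di in below[a].items():
                    for j, dj in below[b].items():
                        dist[i, j] = dist[j, i] = di + dj
        merged: dict[int, float] = {}
        for d in below:
            merged.update(d)
        return merged

    walk(tree)
    return names, dist


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge leaf bipartitions, canonicalized to the smaller side."""
    all_leaves = frozenset(tree.leaf_names())
    parts: set[frozenset[str]] = set()

    def walk(node, at_root):
        for c in node.children:
            if not c.is_leaf:
                side = frozenset(c.leaf_names())
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    canon = min(side, other,
                                key=lambda s: (len(s), tuple(sorted(s))))
                    parts.add(canon)
                walk(c, False)

    walk(tree, True)
    return parts


def core_distance_matrix(core_families: list[GeneFamily], genomes: list[str],
                         proteins: dict[str, str]
                         ) -> tuple[DistanceMatrix, list[tuple[np.ndarray,
                                                               np.ndarray]]]:
    """Weighted-mean p-distance matrix over core families.

    ``proteins`` maps gene_id -> protein sequence.  Returns the distance
    matrix and, per family, its (p-distance, alignment-column) matrices
    so the gene-wise bootstrap can reweight without re-aligning.
    """
    n = len(genomes)
    gi = {g: i for i, g in enumerate(genomes)}
    per_family: list[tuple[np.ndarray, np.ndarray]] = []
    for fam in core_families:
        rep: dict[str, str] = {}
        for genome_id, gene_id in fam.members:
            if genome_id not in gi:
                continue
            prot = proteins[gene_id]
            cur = rep.get(genome_id)
            # longest protein wins; ties broken by smaller gene_id
            if (cur is None or len(prot) > len(cur[1])
                    or (len(prot) == len(cur[1]) and gene_id < cur[0])):
                rep[genome_id] = (gene_id, prot)
        missing = [g for g in genomes if g not in rep]
        if missing:
            raise PhyloInputError(
                f"core family {fam.family_id} missing genomes {missing[:5]}")
        p = np.zeros((n, n))
        cols = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                stats = align_pair_global(rep[genomes[a]][1],
                                          rep[genomes[b]][1])
                p[a, b] = p[b, a] = 1.0 - stats.identity_pct / 100.0
                cols[a, b] = cols[b, a] = stats.n_columns
        per_family.append((p, cols))
    total_cols = sum(c for _, c in per_family)
    weighted = sum(p * c for p, c in per_family)
    with np.errstate(invalid="ignore"):
        d = np.where(total_cols > 0, weighted / np.maximum(total_cols, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(genomes), matrix=d), per_family


def distance_from_family_resample(per_family, indices, genomes
                                  ) -> DistanceMatrix:
    """Weighted-mean distance over a (bootstrap) multiset of family indices."""
    total_cols = sum(per_family[i][1] for i in indices)
    weighted = sum(per_family[i][0] * per_family[i][1] for i in indices)
    d = np.where(total_cols > 0, weighted / np.maximum(total_cols, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(genomes), matrix=d)


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Canonical neighbour joining; exact on additive matrices.

    Negative branch-length estimates are clamped to zero with the
    deficit moved to the sibling edge.
    """
    n = len(D.ids)
    if n < 3:
        raise PhyloInputError("NJ requires >= 3 leaves")
    d = D.matrix.copy()
    nodes = [TreeNode(name=g) for g in D.ids]

    def clamp(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # first min: deterministic
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        du = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [new]
        d = d_new

    a, b, c = d[0, 1], d[0, 2], d[1, 2]
    l0 = max((a + b - c) / 2, 0.0)
    l1 = max((a + c - b) / 2, 0.0)
    l2 = max((b + c - a) / 2, 0.0)
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = length
    return TreeNode(children=list(nodes))


def bootstrap_supports(per_family, genomes: list[str], B: int = 100,
                       seed: int = 0, tree: TreeNode | None = None
                       ) -> TreeNode:
    """Gene-wise bootstrap: support = % of replicate trees with the same
    bipartition.  Annotates (a copy of) the main-tree internal nodes."""
    if B < 1:
        raise PhyloInputError("bootstrap replicates must be >= 1")
    if len(per_family) < 2:
        raise PhyloInputError("bootstrap requires >= 2 core families")
    if tree is None:
        tree = neighbor_joining(
            distance_from_family_resample(per_family,
                                          range(len(per_family)), genomes))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    nf = len(per_family)
    for _ in range(B):
        idx = rng.integers(0, nf, size=nf)
        rep_tree = neighbor_joining(
            distance_from_family_resample(per_family, idx, genomes))
        for part in bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1

    all_leaves = frozenset(tree.leaf_names())

    def annotate(node):
        for c in node.children:
            if not c.is_leaf:
                side = frozenset(c.leaf_names())
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    canon = min(side, other,
                                key=lambda s: (len(s), tuple(sorted(s))))
                    c.support = 100.0 * counts.get(canon, 0) / B
                annotate(c)

    annotate(tree)
    return tree


def random_additive_instance(n_leaves: int, rng: np.random.Generator
                             ) -> tuple[DistanceMatrix, set[frozenset[str]],
                                        TreeNode]:
    """Random unrooted binary tree with positive branch lengths.

    Returns its exact leaf path-length matrix (an additive metric), its
    bipartition set, and the tree — the standard oracle for NJ: on an
    additive matrix NJ must recover topology and path lengths exactly.
    """
    if n_leaves < 4:
        raise PhyloInputError("need >= 4 leaves for an informative instance")
    nodes = [TreeNode(name=f"L{i:02d}", length=float(rng.uniform(0.1, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)),
                          children=[nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes))
                 if k not in (i, j)] + [parent]
    tree = TreeNode(children=nodes)
    names, mat = leaf_path_lengths(tree)
    return DistanceMatrix(names, mat), bipartitions(tree), tree


def classify_by_type_strain(ani: PairwiseAniTable,
                            type_strains: dict[str, str],
                            labels: dict[str, str | None],
                            tol: float = 1e-9):
    """Assign each genome to the subspecies of its highest-ANI type strain.

    Returns a list of dicts with assignment, the declared label, and
    flags: ``misclassified`` when assignment differs from the declared
    label, ``ambiguous`` on an ANI tie (assigned to the lexicographically
    first subspecies).
    """
    missing = [s for s, g in type_strains.items() if g not in ani.genome_ids]
    if missing:
        raise PhyloInputError(f"type strains absent from ANI table: {missing}")
    out = []
    for g in ani.genome_ids:
        scores = {s: ani.symmetric(g, ts) for s, ts in type_strains.items()}
        best = max(scores.values())
        tied = sorted(s for s, v in scores.items() if best - v <= tol)
        assigned = tied[0]
        declared = labels.get(g)
        out.append({
            "genome_id": g,
            "assigned_subspecies": assigned,
            "declared_label": declared,
            "ambiguous": len(tied) > 1,
            "misclassified": declared is not None and assigned != declared,
            "ani_to_type_strains": scores,
        })
    return out
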