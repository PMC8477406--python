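"""Fragment-based average nucleotide identity (ANI).

The query genome is cut into non-overlapping fragments (default 1 kb;
a trailing short fragment is discarded).  Each fragment is located in
the reference by exact 16-mer seeding: seed hits vote for an alignment
diagonal, the best diagonal wins (ties to the leftmost reference
position), and the fragment is scored by ungapped comparison against
the reference window on that diagonal.  Fragments reaching the minimum
identity count as mapped; ANI is the mean identity of mapped fragments.
A pair whose mapped fraction falls below the configured minimum is
flagged unreliable.  Only the forward strand is searched (sufficient
for same-strand assemblies such as the synthetic cohorts; a
reverse-strand search would be required for arbitrary real data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ThresholdConfig
from .records import GenomeRecord

_K = 16
_SEED_STRIDE = 8
_MAX_HITS_PER_SEED = 16

_BASE_INDEX = np.zeros(256, dtype=np.uint8)  # non-ACGT maps to A
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_POWERS = (4 ** np.arange(_K - 1, -1, -1)).astype(np.uint64)


class AniInputError(ValueError):
    pass


def _encode(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray) -> np.ndarray:
    if arr.size < _K:
        return np.empty(0, dtype=np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, _K).astype(np.uint64)
    return windows @ _POWERS


class _ReferenceIndex:
    """Sorted 16-mer code index of one reference sequence."""

    def __init__(self, seq: str):
        self.arr = _encode(seq)
        codes = _kmer_codes(self.arr)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.positions = order.astype(np.int64)

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query offsets, reference positions) of all seed hits."""
        left = np.searchsorted(self.sorted_codes, codes, "left")
        right = np.searchsorted(self.sorted_codes, codes, "right")
        counts = np.minimum(right - left, _MAX_HITS_PER_SEED)
        qoff, rpos = [], []
        for i in np.nonzero(counts)[0]:
            hits = self.positions[left[i]:left[i] + counts[i]]
            qoff.append(np.full(hits.size, i))
            rpos.append(hits)
        if not qoff:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(qoff), np.concatenate(rpos)


@dataclass
class AniResult:
    query_id: str
    reference_id: str
    ani_pct: float
    n_fragments_total: int
    n_fragments_mapped: int
    unreliable: bool = False

    @property
    def mapped_fraction(self) -> float:
        if self.n_fragments_total == 0:
            return 0.0
        return self.n_fragments_mapped / self.n_fragments_total


def _score_fragment(frag: np.ndarray, index: _ReferenceIndex,
                    stride: int = _SEED_STRIDE) -> float | None:
    """Best-diagonal ungapped identity (%) of one fragment, or None if unseeded."""
    seed_starts = np.arange(0, frag.size - _K + 1, stride)
    codes = _kmer_codes(frag)[seed_starts]
    qoff, rpos = index.lookup(codes)
    if qoff.size == 0:
        return None
    diagonals = rpos - seed_starts[qoff]
    diags, votes = np.unique(diagonals, return_counts=True)
    best = diags[votes == votes.max()].min()  # tie -> leftmost reference position
    ref = index.arr
    q_lo = max(0, -best)
    q_hi = min(frag.size, ref.size - best)
    if q_hi <= q_lo:
        return 0.0
    matches = int(np.count_nonzero(frag[q_lo:q_hi] == ref[best + q_lo:best + q_hi]))
    return 100.0 * matches / frag.size


def compute_ani(query: GenomeRecord, reference: GenomeRecord,
                thresholds: ThresholdConfig | None = None,
                _index: _ReferenceIndex | None = None) -> AniResult:
    """One-directional fragment ANI of ``query`` against ``reference``."""
    thresholds = thresholds or ThresholdConfig()
    qseq = query.whole_sequence()
    rseq = reference.whole_sequence()
    if not qseq or not rseq:
        raise AniInputError("empty genome")
    index = _index if _index is not None else _ReferenceIndex(rseq)
    qarr = _encode(qseq)
    flen = thresholds.fragment_len_bp
    n_frag = qarr.size // flen
    identities = []
    for i in range(n_frag):
        ident = _score_fragment(qarr[i * flen:(i + 1) * flen], index)
        if ident is not None and ident >= thresholds.min_fragment_identity_pct:
            identities.append(ident)
    n_mapped = len(identities)
    ani = float(np.mean(identities)) if identities else 0.0
    unreliable = (n_frag == 0
                  or n_mapped / n_frag < thresholds.min_mapped_fraction)
    return AniResult(query_id=query.genome_id, reference_id=reference.genome_id,
                     ani_pct=ani, n_fragments_total=n_frag,
                     n_fragments_mapped=n_mapped, unreliable=unreliable)


class PairwiseAniTable:
    """Symmetric ANI accessor over directional results (diagonal = 100)."""

    def __init__(self, genome_ids: list[str]):
        self.genome_ids = list(genome_ids)
        self.directional: dict[tuple[str, str], AniResult] = {}

    def add(self, result: AniResult) -> None:
        self.directional[(result.query_id, result.reference_id)] = result

    def symmetric(self, a: str, b: str) -> float:
        if a == b:
            return 100.0
        try:
            fwd = self.directional[(a, b)].ani_pct
            rev = self.directional[(b, a)].ani_pct
        except KeyError as exc:
            raise AniInputError(f"missing ANI pair {a}/{b}") from exc
        return (fwd + rev) / 2.0

    def is_unreliable(self, a: str, b: str) -> bool:
        if a == b:
            return False
        return (self.directional[(a, b)].unreliable
                or self.directional[(b, a)].unreliable)

    def to_dataframe(self):
        import pandas as pd
        ids = self.genome_ids
        mat = [[self.symmetric(a, b) for b in ids] for a in ids]
        return pd.DataFrame(mat, index=ids, columns=ids)


def ani_matrix(records: list[GenomeRecord],
               thresholds: ThresholdConfig | None = None) -> PairwiseAniTable:
    """All-vs-all directional ANI; symmetric value = mean of both directions."""
    if len(records) < 2:
        raise AniInputError("ANI matrix requires at least 2 genomes")
    thresholds = thresholds or ThresholdConfig()
    table = PairwiseAniTable([r.genome_id for r in records])
    indexes = {r.genome_id: _ReferenceIndex(r.whole_sequence()) for r in records}
    for ref in records:
        for qry in records:
            if qry.genome_id == ref.genome_id:
                continue
            table.add(compute_ani(qry, ref, thresholds,
                                  _index=indexes[ref.genome_id]))
    return table


def ani_subgroups(table: PairwiseAniTable, cut_pct: float) -> list[set[str]]:
    """Single-linkage components of the graph with edges where ANI >= cut."""
    ids = table.genome_ids
    parent = {g: g for g in ids}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if table.symmetric(a, b) >= cut_pct:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[str, set[str]] = {}
    for g in ids:
        groups.setdefault(find(g), set()).add(g)
    return sorted(groups.values(), key=lambda s: sorted(s)[0])
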