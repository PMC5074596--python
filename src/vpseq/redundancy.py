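"""Contig-redundancy analysis.

The pairwise distance is 1 - M / min(len a, len b), where M is the number of
matched positions in the best end-gap-free (overlap) alignment of a against b
and against revcomp(b) (match +1, mismatch -1, gap -2; IUPAC-compatible pairs
count as matches).  Identical sequences and contained fragments score 0;
sequences with no overlapping region score 1 (overlaps below a small score
floor are chance hits and are discarded).  "Asymmetric fragments" are
pairs that are distant before extension (disjoint 5' and 3' pieces of one
transcript) but redundant after it.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from vpseq.seqio import IUPAC_SETS, Contig, revcomp

_ALPHABET = "ACGTRYKMSWN"

_matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
for _a in _ALPHABET:
    for _b in _ALPHABET:
        _matrix[_a, _b] = 1.0 if IUPAC_SETS[_a] & IUPAC_SETS[_b] else -1.0

def _make_aligner(**end_scores) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _matrix
    al.open_gap_score = -2.0
    al.extend_gap_score = -2.0
    for attr, v in end_scores.items():
        setattr(al, attr, v)
    return al


# End-gap-free overlap: at each edge exactly one sequence's overhang is free
# (dovetail both ways, and either containment).  Freeing both sequences at
# both edges would degenerate into local alignment, whose spurious cores make
# unrelated sequences look similar.
_ALIGNERS = (
    _make_aligner(left_deletion_score=0.0, right_insertion_score=0.0),  # a-suffix/b-prefix
    _make_aligner(left_insertion_score=0.0, right_deletion_score=0.0),  # b-suffix/a-prefix
    _make_aligner(left_deletion_score=0.0, right_deletion_score=0.0),   # b inside a
    _make_aligner(left_insertion_score=0.0, right_insertion_score=0.0),  # a inside b
)


@dataclass
class ContigPair:
    id_a: str
    id_b: str
    distance: float
    relation: str   # identical | contained | overlapping | asymmetric_fragments | unrelated


def _canonical(a: str, b: str) -> tuple[str, str]:
    """Orbit representative under swapping and joint reverse complement.

    The optimal score is invariant under both operations, but the traceback
    reported for co-optimal alignments is not; aligning a canonical pair makes
    the distance exactly symmetric and strand-invariant.
    """
    return min((a, b), (b, a), (revcomp(a), revcomp(b)), (revcomp(b), revcomp(a)))


#: Overlaps scoring below this are chance dovetail hits, not real overlaps.
MIN_OVERLAP_SCORE = 20


def _matched_positions(a: str, b: str) -> tuple[int, int]:
    """(score, matched positions) of the best overlap alignment (one strand)."""
    a, b = _canonical(a, b)
    best = (None, 0)
    for al in _ALIGNERS:
        aln = al.align(a, b)[0]
        m = 0
        for (ta, tb), (qa, qb) in zip(*aln.aligned):
            for i in range(tb - ta):
                if IUPAC_SETS[a[ta + i]] & IUPAC_SETS[b[qa + i]]:
                    m += 1
        key = (int(round(aln.score)), m)
        if best[0] is None or key > best:
            best = key
    return best


def pair_distance(a: Contig | str, b: Contig | str) -> float:
    """Symmetric, strand-invariant distance in [0, 1]."""
    sa = a.bases if isinstance(a, Contig) else a
    sb = b.bases if isinstance(b, Contig) else b
    if not sa or not sb:
        raise ValueError("pair_distance requires non-empty sequences")
    score, m = max(_matched_positions(sa, sb), _matched_positions(sa, revcomp(sb)))
    # chance dovetail windows between unrelated sequences score in the single
    # digits; demanding a net 20 matched bases makes "no overlap" exactly 1
    if score < min(MIN_OVERLAP_SCORE, len(sa), len(sb)):
        m = 0
    d = 1.0 - m / min(len(sa), len(sb))
    return min(1.0, max(0.0, d))


def _classify_pair(a: Contig, b: Contig, d: float, d_max: float) -> str:
    if d == 0.0:
        return "identical" if len(a) == len(b) else "contained"
    if d <= d_max:
        return "overlapping"
    return "unrelated"


def _candidate_pairs(contigs: list[Contig], k: int = 20) -> set[tuple[int, int]]:
    """Pairs sharing at least one exact k-mer on either strand."""
    kmers: dict[str, set[int]] = {}
    for idx, c in enumerate(contigs):
        seqs = (c.bases, revcomp(c.bases))
        seen: set[str] = set()
        for s in seqs:
            for i in range(len(s) - k + 1):
                seen.add(s[i: i + k])
        for km in seen:
            kmers.setdefault(km, set()).add(idx)
    pairs: set[tuple[int, int]] = set()
    for members in kmers.values():
        if len(members) > 1:
            mm = sorted(members)
            for i in range(len(mm)):
                for j in range(i + 1, len(mm)):
                    pairs.add((mm[i], mm[j]))
    return pairs


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def find_redundant(contigs, d_max: float = 0.05,
                   post_contigs=None) -> dict:
    """Single-linkage clusters of redundant contigs, longest member as representative.

    When ``post_contigs`` (the same ids after extension) is supplied, pairs
    whose distance exceeds ``d_max`` before extension but not after are
    reported as asymmetric_fragments — disjoint 5'/3' pieces of one transcript
    joined up by elongation.
    """
    contigs = list(contigs)
    n = len(contigs)
    uf = _UnionFind(n)
    pairs: list[ContigPair] = []
    for i, j in sorted(_candidate_pairs(contigs)):
        d = pair_distance(contigs[i], contigs[j])
        if d <= d_max:
            uf.union(i, j)
            pairs.append(ContigPair(contigs[i].id, contigs[j].id, d,
                                    _classify_pair(contigs[i], contigs[j], d, d_max)))

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)
    cluster_list = []
    representatives = []
    for root in sorted(clusters):
        members = clusters[root]
        rep = max(members, key=lambda idx: (len(contigs[idx]), contigs[idx].id))
        cluster_list.append([contigs[i].id for i in members])
        representatives.append(contigs[rep].id)

    asymmetric: list[ContigPair] = []
    if post_contigs is not None:
        post = {c.id: c for c in post_contigs}
        by_id = {c.id: c for c in contigs}
        post_list = [post[c.id] for c in contigs if c.id in post]
        for i, j in sorted(_candidate_pairs(post_list)):
            a, b = post_list[i], post_list[j]
            d_post = pair_distance(a, b)
            if d_post > d_max:
                continue
            d_pre = pair_distance(by_id[a.id], by_id[b.id])
            if d_pre > d_max:
                asymmetric.append(ContigPair(a.id, b.id, d_pre, "asymmetric_fragments"))

    return {
        "clusters": cluster_list,
        "representatives": representatives,
        "pairs": pairs,
        "asymmetric_fragments": asymmetric,
    }
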