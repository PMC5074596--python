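"""The elongation engine: pileup posteriors, ambiguity-aware base calling,
per-round extension from virtual primers, and the fixpoint iteration.

At each candidate position beyond a contig terminus the pileup of recruited
read overhangs gives nucleotide counts N(nt|i) with depth N(i).  The posterior
of a base is

    Pr(nt, i) = (N(nt|i) + n/4) / (N(i) + n),        n = 20 (pseudo-count)

and of a two-base ambiguity code the sum of its two component posteriors.  A
base is called when its posterior reaches 0.8; failing that, a two-base code
is called when *its* posterior reaches 0.8 and the previous call was an
unambiguous base (successive ambiguity codes are forbidden — they signal low
complexity or contamination).  Otherwise elongation stops.  With unanimous
pileups the inclusive 0.8 threshold sets a minimum calling depth of 55 reads:
(N + 5)/(N + 20) >= 0.8  <=>  N >= 55.

Each round recruits reads whose 20-base terminal virtual primer occurrence
anchors them at the contig end (one mismatch allowed in round 1 only; later
rounds instead gain IUPAC-code primers), calls bases outward, then redesigns
the primers from the new termini; the process repeats until a full pass adds
nothing to either end.  The engine is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from vpseq.read_index import PRIMER_LEN, ReadStore, find_primer_hits
from vpseq.seqio import AMBIGUITY_CODES, IUPAC_SETS, Contig, revcomp

NO_CALL = None

_BASES = "ACGT"


@dataclass
class ExtendParams:
    pseudo_n: int = 20
    p_threshold: float = 0.8     # inclusive >=
    round1_mismatch: int = 1
    later_round_mismatch: int = 0
    max_rounds: int = 100
    primer_len: int = PRIMER_LEN


@dataclass
class ProfileColumn:
    """Nucleotide counts at one candidate extension position (1 = first new base)."""

    position: int
    counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in _BASES})
    pseudo_n: int = 20

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class CallRule:
    p_threshold: float = 0.8
    previous_base: str = "A"

    def __post_init__(self) -> None:
        if not (0.5 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0.5, 1]")


def _posterior_frac(col: ProfileColumn, nt: str) -> Fraction:
    n = col.pseudo_n
    denom = 4 * (col.depth + n)
    if nt in _BASES:
        return Fraction(4 * col.counts[nt] + n, denom)
    comps = IUPAC_SETS.get(nt)
    if comps is None or len(comps) != 2:
        raise ValueError(f"posterior defined for bases and two-base codes, got {nt!r}")
    return Fraction(4 * sum(col.counts[b] for b in comps) + 2 * n, denom)


def posterior(col: ProfileColumn, nt: str, exact: bool = False):
    """Posterior probability of a base (or two-base code) at a pileup column.

    An empty column returns the uniform prior 0.25 per base.
    """
    f = _posterior_frac(col, nt)
    return f if exact else float(f)


def call_base(col: ProfileColumn, rule: CallRule) -> str | None:
    """Apply the three-branch calling rule; returns a base, a code, or NO_CALL.

    Comparisons use exact rational arithmetic; argmax ties break
    lexicographically (A<C<G<T, then R<Y<K<M<S<W).
    """
    thr = Fraction(str(rule.p_threshold))
    best_base = max(_BASES, key=lambda b: (_posterior_frac(col, b), -_BASES.index(b)))
    # max() with a tie on the Fraction picks the first in iteration order via
    # the negated index; equivalent to lexicographic preference.
    if _posterior_frac(col, best_base) >= thr:
        return best_base
    if rule.previous_base in _BASES:
        # a code stands for two *observed* alleles: both components need support,
        # otherwise pseudo-counts alone could promote a unanimous pileup to a code
        eligible = [c for c in AMBIGUITY_CODES
                    if all(col.counts[b] > 0 for b in IUPAC_SETS[c])]
        if eligible:
            best_code = max(
                eligible, key=lambda c: (_posterior_frac(col, c), -AMBIGUITY_CODES.index(c))
            )
            if _posterior_frac(col, best_code) >= thr:
                return best_code
    return NO_CALL


@dataclass
class RoundLog:
    round: int
    end: str                 # 'five_prime' | 'three_prime'
    primer: str
    hits: int
    bases_added: int
    posteriors: list[float] = field(default_factory=list)
    depths: list[int] = field(default_factory=list)


@dataclass
class ExtensionReport:
    contig_id: str
    rounds: int = 0
    added5: int = 0
    added3: int = 0
    ambiguity_count: int = 0
    log: list[RoundLog] = field(default_factory=list)


def _extend_3prime(bases: str, store: ReadStore, params: ExtendParams, mismatch: int) -> tuple[str, RoundLog]:
    """One recruitment + outward calling pass at the 3' end; returns new bases."""
    plen = params.primer_len
    primer = bases[-plen:]
    rlog = RoundLog(round=0, end="three_prime", primer=primer, hits=0, bases_added=0)
    hits = find_primer_hits(store, primer, max_mismatch=mismatch)
    rlog.hits = len(hits)
    if not hits:
        return "", rlog

    # Overhangs: read bases 3' of the anchored primer occurrence.
    overhangs: list[str] = []
    for h in hits:
        oriented = h.oriented_read(store)
        tail = oriented[h.offset + plen:]
        if tail:
            overhangs.append(tail)
    if not overhangs:
        return "", rlog

    new: list[str] = []
    prev = bases[-1]
    max_overhang = max(len(t) for t in overhangs)
    for i in range(max_overhang):
        col = ProfileColumn(position=i + 1, pseudo_n=params.pseudo_n)
        for t in overhangs:
            if i < len(t) and t[i] in col.counts:
                col.counts[t[i]] += 1
        if col.depth == 0:
            break
        call = call_base(col, CallRule(p_threshold=params.p_threshold, previous_base=prev))
        if call is NO_CALL:
            break
        rlog.posteriors.append(posterior(col, call))
        rlog.depths.append(col.depth)
        new.append(call)
        prev = call
    rlog.bases_added = len(new)
    return "".join(new), rlog


def extend_once(contig: Contig, end: str, store: ReadStore, params: ExtendParams | None = None,
                mismatch: int | None = None) -> tuple[str, RoundLog]:
    """One extension round at one end; 5' extension runs on the reverse complement.

    Returns the appended bases in contig orientation (for the 5' end the
    string is what gets *prepended*).
    """
    params = params or ExtendParams()
    if mismatch is None:
        mismatch = params.round1_mismatch
    if len(contig.bases) < params.primer_len:
        return "", RoundLog(round=0, end=end, primer="", hits=0, bases_added=0)
    if end == "three_prime":
        return _extend_3prime(contig.bases, store, params, mismatch)
    if end == "five_prime":
        new_rc, rlog = _extend_3prime(revcomp(contig.bases), store, params, mismatch)
        rlog.end = "five_prime"
        return revcomp(new_rc) if new_rc else "", rlog
    raise ValueError(f"unknown end {end!r}")


def vpseq_extend(contig: Contig, store: ReadStore, params: ExtendParams | None = None) -> tuple[Contig, ExtensionReport]:
    """Iterate extension of both ends until a full pass adds zero bases.

    The input contig remains a verbatim contiguous substring of the output;
    ``core_span`` records where.
    """
    params = params or ExtendParams()
    report = ExtensionReport(contig_id=contig.id)
    bases = contig.bases
    added5 = added3 = 0
    for rnd in range(1, params.max_rounds + 1):
        report.rounds = rnd
        mismatch = params.round1_mismatch if rnd == 1 else params.later_round_mismatch
        cur = Contig(id=contig.id, bases=bases)
        gained = 0
        for end in ("five_prime", "three_prime"):
            new, rlog = extend_once(cur, end, store, params, mismatch=mismatch)
            rlog.round = rnd
            report.log.append(rlog)
            if new:
                if end == "five_prime":
                    bases = new + bases
                    added5 += len(new)
                else:
                    bases = bases + new
                    added3 += len(new)
                gained += len(new)
                cur = Contig(id=contig.id, bases=bases)
        if gained == 0:
            break
    report.added5 = added5
    report.added3 = added3
    report.ambiguity_count = sum(
        1 for i, ch in enumerate(bases)
        if ch in AMBIGUITY_CODES and not (added5 <= i < added5 + len(contig.bases))
    )
    out = Contig(id=contig.id, bases=bases, core_span=(added5, added5 + len(contig.bases)))
    return out, report


def batch_extend(contigs, store: ReadStore, params: ExtendParams | None = None):
    """Extend contigs independently, in input order; per-contig failures are logged."""
    import logging

    params = params or ExtendParams()
    for c in contigs:
        try:
            yield vpseq_extend(c, store, params)
        except Exception:  # pragma: no cover - defensive
            logging.getLogger(__name__).exception("extension failed for contig %s", c.id)
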