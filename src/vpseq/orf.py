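"""ORF-completeness classification of assembled contigs.

Each contig is classed as full_length, five_prime_partial, three_prime_partial
or internal.  When a protein alignment (blastx-style tabular hit) is supplied
the classification works in the hit's frame: the 3' side is complete when an
in-frame stop codon occurs at or after the aligned region, and the 5' side
when an in-frame ATG occurs at or before it *and* the start is corroborated
either by an in-frame stop upstream of that ATG or by the subject alignment
beginning near the protein's N-terminus.  Without a hit, the longest candidate
ORF over all six frames is used: a candidate is a between-stops segment
carrying an ATG and/or a terminating stop, measured from its first ATG when it
has one.  Start evidence is an upstream in-frame stop or enough 5' UTR.  The
two heuristic knobs (N-terminal proximity in amino acids, minimum 5' UTR in
nucleotides) are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from vpseq.seqio import Contig, revcomp

STOPS = {"TAA", "TAG", "TGA"}

#: Ordering used by "extension never demotes": internal < partial < full.
CLASS_ORDER = {"internal": 0, "five_prime_partial": 1, "three_prime_partial": 1, "full_length": 2}


@dataclass
class ProteinHit:
    """A blastx-style hit; query span is 1-based on the forward strand of the frame."""

    query_id: str
    frame: int                 # -3..-1, +1..+3
    q_start: int
    q_end: int
    s_start: int               # 1-based, amino acids
    s_end: int
    s_len: int
    evalue: float
    bitscore: float = 0.0


@dataclass
class OrfCall:
    contig_id: str
    orf_class: str             # full_length | five_prime_partial | three_prime_partial | internal
    frame: int
    start: Optional[int]       # 0-based ATG offset in the oriented sequence
    stop: Optional[int]        # 0-based offset of the stop codon
    evidence: str              # alignment_guided | longest_orf


@dataclass
class OrfParams:
    nterm_aa: int = 15         # subject N-terminus proximity accepted as start evidence
    min_utr: int = 30          # nt of 5' UTR accepted as start evidence


def _inframe_codons(seq: str, frame_off: int):
    for i in range(frame_off, len(seq) - 2, 3):
        yield i, seq[i: i + 3]


def _classify_guided(contig: Contig, hit: ProteinHit, p: OrfParams) -> OrfCall:
    seq = contig.bases if hit.frame > 0 else revcomp(contig.bases)
    a_start, a_end = hit.q_start - 1, hit.q_end - 1
    frame_off = a_start % 3

    # 3' side: first in-frame stop whose codon starts at/after the aligned end.
    stop_at = None
    for i, c in _inframe_codons(seq, frame_off):
        if i >= a_end - 2 and c in STOPS:
            stop_at = i
            break

    # 5' side: last in-frame stop before the alignment, then the first ATG
    # after it (or from the sequence start) at/before the alignment start.
    last_stop = None
    for i, c in _inframe_codons(seq, frame_off):
        if i >= a_start:
            break
        if c in STOPS:
            last_stop = i
    atg_at = None
    search_from = frame_off if last_stop is None else last_stop + 3
    for i in range(search_from, a_start + 1, 3):
        if seq[i: i + 3] == "ATG":
            atg_at = i
            break
    five_complete = atg_at is not None and (last_stop is not None or hit.s_start <= p.nterm_aa)
    three_complete = stop_at is not None

    if five_complete and three_complete:
        cls = "full_length"
    elif five_complete:
        cls = "three_prime_partial"
    elif three_complete:
        cls = "five_prime_partial"
    else:
        cls = "internal"
    return OrfCall(contig.id, cls, hit.frame, atg_at if five_complete else None,
                   stop_at, "alignment_guided")


def _candidates(seq: str):
    """Per frame: between-stops segments as (seg_start, atg, stop, preceded_by_stop, off)."""
    for off in range(3):
        seg_start = off
        atg = None
        preceded = False
        for i, c in _inframe_codons(seq, off):
            if c == "ATG" and atg is None:
                atg = i
            if c in STOPS:
                yield (seg_start, atg, i, preceded, off)
                seg_start = i + 3
                atg = None
                preceded = True
        yield (seg_start, atg, None, preceded, off)


def _classify_fallback(contig: Contig, p: OrfParams) -> OrfCall:
    best = None
    for strand, seq in ((1, contig.bases), (-1, revcomp(contig.bases))):
        for seg_start, atg, stop, preceded, off in _candidates(seq):
            if atg is None and stop is None:
                continue  # carries no ORF evidence at all
            begin = atg if atg is not None else seg_start
            end = stop if stop is not None else len(seq)
            length = end - begin
            if best is None or length > best[0]:
                best = (length, strand, off, atg, stop, preceded)
    if best is None:
        return OrfCall(contig.id, "internal", 1, None, None, "longest_orf")
    _, strand, off, atg, stop, preceded = best
    frame = (off + 1) * strand
    has_start, has_stop = atg is not None, stop is not None
    start_ok = has_start and (preceded or atg >= p.min_utr)
    if start_ok and has_stop:
        cls = "full_length"
    elif has_start and not has_stop:
        cls = "three_prime_partial"
    elif has_stop and not start_ok and has_start:
        cls = "five_prime_partial"   # ATG present but unsupported start
    elif has_stop:
        cls = "five_prime_partial"
    else:  # pragma: no cover - unreachable given the candidate filter
        cls = "internal"
    return OrfCall(contig.id, cls, frame, atg, stop, "longest_orf")


def classify_orf(contig: Contig, hit: ProteinHit | None = None,
                 params: OrfParams | None = None) -> OrfCall:
    if len(contig.bases) < 3:
        raise ValueError(f"contig {contig.id} shorter than one codon")
    params = params or OrfParams()
    if hit is not None:
        return _classify_guided(contig, hit, params)
    return _classify_fallback(contig, params)


def read_blast_hits(path, contig_lengths: dict[str, int] | None = None) -> dict[str, ProteinHit]:
    """Best hit per query from 12/13-column BLAST tabular output (outfmt 6 [+ slen]).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore [slen].  A hit with qstart > qend is on the minus
    strand; its span is mapped onto the reverse complement, which requires the
    contig length.  Best hit = lowest e-value, then highest bitscore.
    """
    names = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
             "qstart", "qend", "sstart", "send", "evalue", "bitscore", "slen"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = names[: df.shape[1]]
    if "slen" not in df.columns:
        df["slen"] = 10**9  # unknown protein length; N-terminal evidence unavailable
    best: dict[str, ProteinHit] = {}
    df = df.sort_values(["qseqid", "evalue", "bitscore"], ascending=[True, True, False])
    for _, row in df.drop_duplicates("qseqid", keep="first").iterrows():
        qid = str(row.qseqid)
        qs, qe = int(row.qstart), int(row.qend)
        minus = qs > qe
        if minus:
            if not contig_lengths or qid not in contig_lengths:
                raise ValueError(f"minus-strand hit for {qid} requires contig length")
            n = contig_lengths[qid]
            qs, qe = n - qs + 1, n - qe + 1
        frame_off = (qs - 1) % 3
        frame = -(frame_off + 1) if minus else frame_off + 1
        best[qid] = ProteinHit(
            query_id=qid, frame=frame, q_start=qs, q_end=qe,
            s_start=int(row.sstart), s_end=int(row.send), s_len=int(row.slen),
            evalue=float(row.evalue), bitscore=float(row.bitscore),
        )
    return best


def completeness_table(calls: Iterable[OrfCall]) -> pd.Series:
    """Counts per class plus the full-length fraction."""
    counts = {"full_length": 0, "five_prime_partial": 0, "three_prime_partial": 0, "internal": 0}
    total = 0
    for c in calls:
        counts[c.orf_class] += 1
        total += 1
    out = dict(counts)
    out["total"] = total
    out["fraction_full_length"] = counts["full_length"] / total if total else 0.0
    return pd.Series(out)
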