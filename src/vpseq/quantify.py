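"""Expression quantification and GO-term enrichment scoring.

Reads are assigned to contigs by exact 20-mer seeding plus full verification,
allowing a single penalized mismatch per read; mismatches at read positions
with Phred < 20 carry no penalty.  A read matching k contigs equally well
contributes 1/k of a fragment to each.  FPKM is the usual
10^9 * count / (length * total_assigned).  Differential classes use an FPKM
floor of 0.1 and a log2-ratio cut of +/-2.  GO enrichment between two gene
sets A and B is

    Enrich(GO) = log2( ((N_A(GO)+0.05)/N_total(A)) / ((N_B(GO)+0.05)/N_total(B)) )

with the 0.05 pseudo-count rescuing zero numerators.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Iterable

import pandas as pd

from vpseq.seqio import Contig, Read, revcomp

SEED_LEN = 20


@dataclass
class QuantParams:
    lowq: int = 20            # mismatches below this Phred are unpenalized
    max_penalized: int = 1
    seed_step: int = 10
    min_fpkm: float = 0.1
    log_cut: float = 2.0
    eps: float = 0.01         # pseudo-FPKM in the log ratio


@dataclass
class GoTermCounts:
    term: str
    n_a: int
    n_b: int
    total_a: int
    total_b: int
    pseudo: float = 0.05


def _contig_seed_index(contigs: list[Contig]) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, c in enumerate(contigs):
        s = c.bases
        for i in range(len(s) - SEED_LEN + 1):
            index.setdefault(s[i: i + SEED_LEN], []).append((ci, i))
    return index


def _penalized_mismatches(read: str, quals: list[int], contig: str, start: int, lowq: int,
                          budget: int) -> int | None:
    """Penalized mismatch count of the read aligned at contig[start:]; None if over budget."""
    if start < 0 or start + len(read) > len(contig):
        return None
    mm = 0
    for i, ch in enumerate(read):
        if contig[start + i] != ch:
            if quals[i] >= lowq:
                mm += 1
                if mm > budget:
                    return None
    return mm


def assign_reads(reads: Iterable[Read], contigs: Iterable[Contig],
                 params: QuantParams | None = None) -> tuple[dict[str, float], int]:
    """Fractional fragment counts per contig and the number of assigned reads."""
    params = params or QuantParams()
    contigs = list(contigs)
    index = _contig_seed_index(contigs)
    counts: dict[str, float] = {c.id: 0.0 for c in contigs}
    n_assigned = 0
    for r in reads:
        if len(r) < SEED_LEN:
            continue
        best: dict[int, int] = {}
        for strand in ("+", "-"):
            seq = r.bases if strand == "+" else revcomp(r.bases)
            quals = r.quals if strand == "+" else r.quals[::-1]
            offsets = list(range(0, len(seq) - SEED_LEN + 1, params.seed_step))
            if offsets[-1] != len(seq) - SEED_LEN:
                offsets.append(len(seq) - SEED_LEN)
            cand: set[tuple[int, int]] = set()
            for off in offsets:
                for ci, cpos in index.get(seq[off: off + SEED_LEN], ()):
                    cand.add((ci, cpos - off))
            for ci, start in cand:
                mm = _penalized_mismatches(seq, quals, contigs[ci].bases, start,
                                           params.lowq, params.max_penalized)
                if mm is not None and (ci not in best or mm < best[ci]):
                    best[ci] = mm
        if not best:
            continue
        mmin = min(best.values())
        winners = [ci for ci, mm in best.items() if mm == mmin]
        for ci in winners:
            counts[contigs[ci].id] += 1.0 / len(winners)
        n_assigned += 1
    return counts, n_assigned


def fpkm(count: float, contig_len: int, total_assigned: float) -> float:
    if total_assigned <= 0:
        raise ValueError("total_assigned must be positive")
    if contig_len <= 0:
        raise ValueError("contig_len must be positive")
    return 1e9 * count / (contig_len * total_assigned)


def fpkm_table(reads_by_sample: dict[str, Iterable[Read]], contigs: Iterable[Contig],
               params: QuantParams | None = None) -> pd.DataFrame:
    """Per-contig fragment counts and FPKM for each sample."""
    contigs = list(contigs)
    rows = {c.id: {"length": len(c)} for c in contigs}
    for sample, reads in reads_by_sample.items():
        counts, total = assign_reads(reads, contigs, params)
        for cid, cnt in counts.items():
            rows[cid][f"count_{sample}"] = cnt
            rows[cid][f"fpkm_{sample}"] = fpkm(cnt, rows[cid]["length"], total) if total else 0.0
    return pd.DataFrame.from_dict(rows, orient="index")


def de_classify(fpkm_a: float, fpkm_b: float, min_fpkm: float = 0.1,
                log_cut: float = 2.0, eps: float = 0.01) -> str:
    """One of up_in_A / up_in_B / not_DE / not_expressed."""
    if fpkm_a <= min_fpkm and fpkm_b <= min_fpkm:
        return "not_expressed"
    ratio = log2((fpkm_a + eps) / (fpkm_b + eps))
    if ratio > log_cut:
        return "up_in_A"
    if ratio < -log_cut:
        return "up_in_B"
    return "not_DE"


def enrich_score(c: GoTermCounts) -> float:
    """Log2 enrichment of a GO term in set A relative to set B."""
    if c.total_a <= 0 or c.total_b <= 0:
        raise ValueError("gene-set totals must be positive")
    return log2(((c.n_a + c.pseudo) / c.total_a) / ((c.n_b + c.pseudo) / c.total_b))


def enrichment_table(annot: pd.DataFrame, set_a: set[str], set_b: set[str],
                     pseudo: float = 0.05) -> pd.DataFrame:
    """Enrichment scores for every GO term, both orientations.

    ``annot`` has two columns: contig id, GO term (one term per row).
    """
    annot = annot.rename(columns=dict(zip(annot.columns[:2], ["contig", "term"])))
    in_a = annot[annot["contig"].isin(set_a)]
    in_b = annot[annot["contig"].isin(set_b)]
    total_a = in_a["contig"].nunique()
    total_b = in_b["contig"].nunique()
    rows = []
    for term in sorted(set(annot["term"])):
        na = in_a[in_a["term"] == term]["contig"].nunique()
        nb = in_b[in_b["term"] == term]["contig"].nunique()
        if total_a and total_b:
            s = enrich_score(GoTermCounts(term, na, nb, total_a, total_b, pseudo))
            rows.append({"term": term, "n_a": na, "n_b": nb,
                         "score_a_vs_b": s, "score_b_vs_a": -s})
    return pd.DataFrame(rows)
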