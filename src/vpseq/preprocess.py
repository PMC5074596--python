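"""Read cleaning: PCR-duplicate removal and quality-driven base-call trimming.

Two reads are PCR duplicates when their first 10 bases are identical and
positional identity over the shorter read strictly exceeds 90%.  Base calling
runs 5'->3': it starts at the first window of five consecutive Phred scores
strictly above 30 and stops once the cumulative fraction of accurately called
bases (Phred >= 30) drops to 0.5 or below.  Reads with no start window, or
shorter than the 10-base duplicate key after trimming, are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

from vpseq.seqio import Read

log = logging.getLogger(__name__)


@dataclass
class CleanParams:
    dup_prefix_len: int = 10
    dup_similarity: float = 0.90   # strict >
    start_run_len: int = 5
    start_q: int = 30              # strict >
    accurate_q: int = 30           # inclusive >=
    stop_fraction: float = 0.5
    min_len: int = 10              # must at least carry the duplicate-prefix key


def is_pcr_duplicate(a: Read, b: Read, p: CleanParams | None = None) -> bool:
    p = p or CleanParams()
    k = p.dup_prefix_len
    if len(a) < k or len(b) < k:
        return False
    if a.bases[:k] != b.bases[:k]:
        return False
    m = min(len(a), len(b))
    ident = sum(1 for x, y in zip(a.bases[:m], b.bases[:m]) if x == y)
    return ident / m > p.dup_similarity


def dedupe(reads: Iterable[Read], p: CleanParams | None = None) -> Iterator[Read]:
    """Drop PCR duplicates, keeping the first occurrence.

    Reads are bucketed by their 10-base prefix; within a bucket a read is
    dropped iff it duplicates an earlier *retained* read.
    """
    p = p or CleanParams()
    buckets: dict[str, list[Read]] = {}
    dropped = 0
    for r in reads:
        key = r.bases[: p.dup_prefix_len]
        kept = buckets.setdefault(key, [])
        if any(is_pcr_duplicate(r, other, p) for other in kept):
            dropped += 1
            continue
        kept.append(r)
        yield r
    if dropped:
        log.info("dedupe: dropped %d PCR duplicates", dropped)


def trim_read(r: Read, p: CleanParams | None = None) -> Read | None:
    """Quality-trim a read; return None if it is dropped."""
    p = p or CleanParams()
    q = r.quals
    n = len(q)
    run = p.start_run_len
    s = None
    for i in range(n - run + 1):
        if all(q[i + j] > p.start_q for j in range(run)):
            s = i
            break
    if s is None:
        return None
    acc = 0
    e = n
    for j in range(s, n):
        if q[j] >= p.accurate_q:
            acc += 1
        if acc / (j - s + 1) <= p.stop_fraction:
            e = j
            break
    if e - s < p.min_len:
        return None
    return Read(id=r.id, bases=r.bases[s:e], quals=q[s:e])


def clean_reads(reads: Iterable[Read], p: CleanParams | None = None) -> Iterator[Read]:
    """Full cleaning pass: trim, drop low-quality reads, then de-duplicate."""
    p = p or CleanParams()
    n_in = n_lowq = 0

    def trimmed() -> Iterator[Read]:
        nonlocal n_in, n_lowq
        for r in reads:
            n_in += 1
            t = trim_read(r, p)
            if t is None:
                n_lowq += 1
                continue
            yield t

    yield from dedupe(trimmed(), p)
    log.info("clean: %d reads in, %d dropped low-quality", n_in, n_lowq)
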