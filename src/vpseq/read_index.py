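"""Hash-table read store and virtual-primer search.

Reads are held without pairing information, concatenated into a single byte
buffer, and every 10-mer (half the 20-base primer) is indexed by its exact
2-bit code.  A primer occurrence with at most one mismatch must contain at
least one exact 10-mer half (pigeonhole), so lookups of the two halves
followed by full verification find every hit.  Only the forward strand is
indexed; the reverse strand is searched by looking up the reverse-complement
primer, which is equivalent and halves the index.

Later-round primers may carry IUPAC ambiguity codes.  Ambiguous positions are
expanded into concrete keys per 10-mer half, capped at 16 expansions (a half
with more than two ambiguous positions contributes no keys; the other half
still guarantees candidates for exact-matching reads).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from vpseq.seqio import IUPAC_SETS, Read, iupac_match, revcomp

log = logging.getLogger(__name__)

KMER = 10
PRIMER_LEN = 2 * KMER

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


@dataclass
class VirtualPrimer:
    """A 20-base terminal search key; round-1 primers contain no ambiguity codes."""

    seq: str
    end: str = "three_prime"  # or "five_prime"
    round: int = 1

    def __post_init__(self) -> None:
        if len(self.seq) != PRIMER_LEN:
            raise ValueError(f"virtual primer must be {PRIMER_LEN} bp, got {len(self.seq)}")


@dataclass(frozen=True)
class PrimerHit:
    read_id: str
    strand: str            # '+' or '-'
    offset: int            # 0-based primer start within the *oriented* read
    mismatches: int

    def oriented_read(self, store: "ReadStore") -> str:
        seq = store.read_by_id(self.read_id).bases
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class ReadStore:
    reads: list[Read] = field(default_factory=list)
    # CSR index over the forward-strand concatenation:
    _concat: str = ""
    _starts: np.ndarray = None        # read start offsets in _concat
    _sorted_codes: np.ndarray = None  # 10-mer codes, sorted
    _sorted_pos: np.ndarray = None    # concat positions, same order

    def __len__(self) -> int:
        return len(self.reads)

    def read_by_id(self, read_id: str) -> Read:
        return self.reads[self._id_to_idx[read_id]]

    def lookup_kmer(self, code: int) -> np.ndarray:
        """Concat positions of an exact 10-mer code."""
        lo = np.searchsorted(self._sorted_codes, code, side="left")
        hi = np.searchsorted(self._sorted_codes, code, side="right")
        return self._sorted_pos[lo:hi]

    def locate(self, concat_pos: int) -> tuple[int, int]:
        """Map a concat position to (read index, offset within the read)."""
        ridx = int(np.searchsorted(self._starts, concat_pos, side="right")) - 1
        return ridx, concat_pos - int(self._starts[ridx])


def encode_kmer(seq: str) -> int | None:
    """2-bit code of an unambiguous 10-mer, or None if it contains non-ACGT."""
    code = 0
    for ch in seq:
        v = _ENC[ord(ch)]
        if v < 0:
            return None
        code = (code << 2) | int(v)
    return code


def build_store(reads, exclude_ids: set[str] | None = None) -> ReadStore:
    """Index cleaned reads; reads shorter than 20 bp are skipped with a warning."""
    kept: list[Read] = []
    n_short = 0
    for r in reads:
        if exclude_ids and r.id in exclude_ids:
            continue
        if len(r) < PRIMER_LEN:
            n_short += 1
            continue
        kept.append(r)
    if n_short:
        log.warning("build_store: skipped %d reads shorter than %d bp", n_short, PRIMER_LEN)

    store = ReadStore(reads=kept)
    store._id_to_idx = {r.id: i for i, r in enumerate(kept)}
    if not kept:
        store._concat = ""
        store._starts = np.zeros(0, dtype=np.int64)
        store._sorted_codes = np.zeros(0, dtype=np.int64)
        store._sorted_pos = np.zeros(0, dtype=np.int64)
        return store

    # '#' separators keep windows from spanning two reads (they encode as -1).
    concat = "#".join(r.bases for r in kept)
    starts = np.cumsum([0] + [len(r) + 1 for r in kept[:-1]], dtype=np.int64)
    arr = _ENC[np.frombuffer(concat.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    t = arr.size
    if t < KMER:
        valid = np.zeros(0, dtype=bool)
        codes = np.zeros(0, dtype=np.int64)
    else:
        codes = np.zeros(t - KMER + 1, dtype=np.int64)
        ok = np.ones(t - KMER + 1, dtype=bool)
        for k in range(KMER):
            window = arr[k: t - KMER + 1 + k]
            ok &= window >= 0
            codes = (codes << 2) | np.where(window >= 0, window, 0)
        valid = ok
    pos = np.nonzero(valid)[0]
    codes = codes[pos]
    order = np.argsort(codes, kind="stable")
    store._concat = concat
    store._starts = starts
    store._sorted_codes = codes[order]
    store._sorted_pos = pos[order]
    return store


def _half_keys(half: str, max_expansions: int = 16) -> list[int]:
    """Concrete 2-bit codes for one 10-mer half of a (possibly IUPAC) primer."""
    ambiguous = [i for i, ch in enumerate(half) if ch not in "ACGT"]
    if len(ambiguous) > 2:
        return []
    choices = [sorted(IUPAC_SETS.get(ch, set())) if ch not in "ACGT" else [ch] for ch in half]
    keys = []
    for combo in itertools.islice(itertools.product(*choices), max_expansions):
        code = encode_kmer("".join(combo))
        if code is not None:
            keys.append(code)
    return keys


def _verify(store: ReadStore, primer_seq: str, concat_pos: int) -> int | None:
    """Mismatch count of the primer at a concat position, None if out of a read."""
    ridx, off = store.locate(concat_pos)
    read = store.reads[ridx]
    if off + PRIMER_LEN > len(read):
        return None
    window = store._concat[concat_pos: concat_pos + PRIMER_LEN]
    mm = 0
    for p_ch, r_ch in zip(primer_seq, window):
        if not iupac_match(p_ch, r_ch):
            mm += 1
            if mm > 1:
                return mm
    return mm


def find_primer_hits(store: ReadStore, primer: VirtualPrimer | str, max_mismatch: int = 0) -> list[PrimerHit]:
    """All reads (either strand) containing the primer with <= max_mismatch mismatches.

    Matching is per :func:`iupac_match`: an ambiguity code in the primer
    accepts any of its component bases; an 'N' in a read matches nothing.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    seq = primer.seq if isinstance(primer, VirtualPrimer) else primer
    if len(seq) != PRIMER_LEN:
        raise ValueError(f"virtual primer must be {PRIMER_LEN} bp, got {len(seq)}")

    hits: list[PrimerHit] = []
    seen: set[tuple[int, str, int]] = set()
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        candidates: set[int] = set()
        for half_start in (0, KMER):
            for code in _half_keys(query[half_start: half_start + KMER]):
                for p in store.lookup_kmer(code):
                    candidates.add(int(p) - half_start)
        for cpos in sorted(candidates):
            if cpos < 0:
                continue
            mm = _verify(store, query, cpos)
            if mm is None or mm > max_mismatch:
                continue
            ridx, off = store.locate(cpos)
            read = store.reads[ridx]
            # report the offset in the orientation that matches the primer
            offset = off if strand == "+" else len(read) - PRIMER_LEN - off
            key = (ridx, strand, offset)
            if key in seen:
                continue
            seen.add(key)
            hits.append(PrimerHit(read_id=read.id, strand=strand, offset=offset, mismatches=mm))
    return hits
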