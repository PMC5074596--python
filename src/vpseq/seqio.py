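"""FASTA/FASTQ I/O, the IUPAC nucleotide alphabet, and elementary sequence ops.

File parsing and writing are delegated to Biopython's :mod:`Bio.SeqIO`; this
module adds the light domain records (:class:`Read`, :class:`Contig`) the rest
of the package operates on, plus IUPAC-aware reverse complement and matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

# Base sets denoted by each IUPAC nucleotide code.  Only the six two-base
# codes (R,Y,K,M,S,W) are ever *written* by this package; three/four-base
# codes are accepted on input.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: The two-base ambiguity codes the caller may emit, in tie-break order.
AMBIGUITY_CODES: tuple[str, ...] = ("R", "Y", "K", "M", "S", "W")

#: Reverse mapping from a frozen pair of bases to its two-base code.
PAIR_TO_CODE: dict[frozenset, str] = {IUPAC_SETS[c]: c for c in AMBIGUITY_CODES}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "K": "M", "M": "K", "S": "S", "W": "W",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_REVCOMP_TABLE = str.maketrans(
    "".join(_COMPLEMENT) + "".join(_COMPLEMENT).lower(),
    "".join(_COMPLEMENT.values()) + "".join(_COMPLEMENT.values()),
)


class FormatError(ValueError):
    """Raised for malformed sequence records."""


@dataclass
class Read:
    """A cleaned sequencing read.  Pairing information is deliberately absent."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("read with empty id")
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Contig:
    """An assembled transcript over the IUPAC alphabet.

    ``core_span`` is the half-open interval of the original (pre-extension)
    sequence inside ``bases``; elongated spans lie outside it.
    """

    id: str
    bases: str
    core_span: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.core_span is None:
            self.core_span = (0, len(self.bases))
        s, e = self.core_span
        if not (0 <= s < e <= len(self.bases)):
            raise ValueError(f"contig {self.id!r}: invalid core_span {self.core_span}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def core(self) -> str:
        return self.bases[self.core_span[0]: self.core_span[1]]


def revcomp(seq: str) -> str:
    """IUPAC-correct reverse complement (R<->Y, K<->M, S/W self-complementary)."""
    out = seq.translate(_REVCOMP_TABLE)[::-1]
    bad = set(out) - set(_COMPLEMENT) - {c.lower() for c in _COMPLEMENT}
    if bad:
        raise ValueError(f"non-IUPAC character(s) in sequence: {sorted(bad)}")
    return out


def iupac_match(pattern_char: str, read_char: str) -> bool:
    """True iff ``read_char`` lies in the base set denoted by ``pattern_char``.

    An 'N' in a read matches nothing: pileup counts are taken over {A,C,G,T}
    only, and letting N match would inflate the consensus.
    """
    if read_char == "N":
        return False
    s = IUPAC_SETS.get(pattern_char)
    if s is None:
        return False
    return read_char in s


def read_fastq(path) -> Iterator[Read]:
    """Stream Phred+33 FASTQ records as :class:`Read`, uppercased."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield Read(
                id=rec.id,
                bases=str(rec.seq).upper(),
                quals=list(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # Biopython reports the offending record
        raise FormatError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = r.quals
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def read_fasta(path) -> Iterator[Contig]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield Contig(id=rec.id, bases=str(rec.seq).upper())


def write_fasta(contigs: Iterable[Contig], path, with_spans: bool = False) -> int:
    """Write contigs wrapped at 70 columns; optionally annotate extension spans."""
    n = 0
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=70)
        for c in contigs:
            desc = ""
            if with_spans:
                s, e = c.core_span
                desc = f"core={s}-{e} added5={s} added3={len(c.bases) - e}"
            writer.write_record(SeqRecord(Seq(c.bases), id=c.id, description=desc))
            n += 1
    return n
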