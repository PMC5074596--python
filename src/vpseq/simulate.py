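"""Synthetic transcriptome generator and gold-standard evaluation.

Generates transcripts with a planted ORF (ATG .. in-frame stop, flanked by
UTRs, with an in-frame stop just upstream of the ATG), optional heterozygous
50/50 biallelic sites, error-bearing fixed-rate substitution reads with
realistic Phred strings (high-quality core, decaying 3' tail), and contigs
truncated at both ends — the shape of the data the elongation method assumes.

Read start positions are sampled past the transcript boundaries and clipped,
so fragment edges pile up at the transcript termini exactly as random
fragmentation of full-length molecules produces terminal fragments abutting
the ends.  Without this pile-up the pileup depth would ramp down linearly over
the last read-length of the transcript and terminal bases could never reach
the consensus-calling depth, which no real library exhibits.  Clipped reads
shorter than 20 bp (the primer length) are discarded at indexing time anyway.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vpseq.orf import classify_orf
from vpseq.seqio import IUPAC_SETS, PAIR_TO_CODE, Contig, Read, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    n_transcripts: int = 50
    len_min: int = 900
    len_max: int = 3000
    gc: float = 0.45
    coverage: float | list[float] = 200.0
    read_len: int = 101
    err: float = 0.001
    het: float = 0.0005          # per-bp probability of a 50/50 biallelic site
    trunc5: int = 150
    trunc3: int = 150
    utr5: int = 100
    utr3: int = 100
    min_read_len: int = 20
    seed: int = 7

    def __post_init__(self) -> None:
        for r in (self.gc, self.err, self.het):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.read_len > self.len_min:
            raise ValueError("read length exceeds the shortest transcript")


@dataclass
class GoldRecord:
    transcript_id: str
    allele_a: str
    allele_b: str
    trunc5: int
    trunc3: int
    orf_start: int               # template offset of the planted ATG
    orf_stop: int                # template offset of the planted stop codon
    het_sites: list[tuple[int, str, str]]
    n_reads: int


@dataclass
class SimulatedDataset:
    config: SimConfig
    templates: list[Contig]      # allele A, full length
    contigs: list[Contig]        # truncated, the assembler stand-ins
    reads: list[Read]
    gold: dict[str, GoldRecord] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _plant_orf(seq: np.ndarray, cfg: SimConfig) -> tuple[int, int]:
    """Overwrite the template with ATG..stop and clean in-frame stops; return ORF span."""
    L = seq.size
    cds_start = cfg.utr5
    cds_len = ((L - cfg.utr5 - cfg.utr3 - 6) // 3) * 3
    stop_at = cds_start + 3 + cds_len
    seq[cds_start: cds_start + 3] = np.frombuffer(b"ATG", dtype="S1")
    seq[stop_at: stop_at + 3] = np.frombuffer(b"TAA", dtype="S1")
    # upstream in-frame stop immediately before the ATG (start evidence)
    seq[cds_start - 3: cds_start] = np.frombuffer(b"TGA", dtype="S1")
    # remove in-frame stops inside the CDS
    for i in range(cds_start + 3, stop_at, 3):
        if seq[i: i + 3].tobytes().decode() in STOP_CODONS:
            seq[i + 1] = b"C"
    return cds_start, stop_at


def _qual_string(n: int) -> list[int]:
    """High-quality core decaying over the final 15 cycles (40 -> 31)."""
    tail = min(15, n)
    quals = [40] * n
    for k in range(tail):
        quals[n - tail + k] = max(31, 40 - int(9 * (k + 1) / tail))
    return quals


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    rng = np.random.default_rng(cfg.seed)
    covs = cfg.coverage if isinstance(cfg.coverage, (list, tuple, np.ndarray)) \
        else [cfg.coverage] * cfg.n_transcripts
    if len(covs) != cfg.n_transcripts:
        raise ValueError("per-transcript coverage list has wrong length")

    templates: list[Contig] = []
    contigs: list[Contig] = []
    reads: list[Read] = []
    gold: dict[str, GoldRecord] = {}
    pad = cfg.read_len - cfg.min_read_len

    for t in range(cfg.n_transcripts):
        tid = f"t{t + 1:03d}"
        L = int(rng.integers(cfg.len_min, cfg.len_max + 1))
        arr_a = _random_seq(rng, L, cfg.gc)
        orf_start, orf_stop = _plant_orf(arr_a, cfg)
        arr_b = arr_a.copy()
        het_mask = rng.random(L) < cfg.het
        het_sites: list[tuple[int, str, str]] = []
        for pos in np.nonzero(het_mask)[0]:
            a = arr_a[pos].tobytes().decode()
            alt = rng.choice([b for b in "ACGT" if b != a])
            arr_b[pos] = alt.encode()
            het_sites.append((int(pos), a, alt))
        allele_a = arr_a.tobytes().decode()
        allele_b = arr_b.tobytes().decode()
        templates.append(Contig(id=tid, bases=allele_a))

        t5 = min(cfg.trunc5, max(0, L - cfg.trunc3 - cfg.read_len))
        t3 = min(cfg.trunc3, max(0, L - t5 - cfg.read_len))
        contigs.append(Contig(id=tid, bases=allele_a[t5: L - t3]))

        cov = float(covs[t])
        n_reads = int(round(cov * L / cfg.read_len))
        if n_reads > 0:
            starts = rng.integers(-pad, L - cfg.read_len + pad + 1, size=n_reads)
            use_b = rng.random(n_reads) < 0.5
            minus = rng.random(n_reads) < 0.5
            for ri in range(n_reads):
                s0 = max(0, int(starts[ri]))
                e0 = min(L, int(starts[ri]) + cfg.read_len)
                frag = (arr_b if use_b[ri] else arr_a)[s0:e0].copy()
                if cfg.err > 0:
                    errs = np.nonzero(rng.random(frag.size) < cfg.err)[0]
                    for pos in errs:
                        cur = frag[pos].tobytes().decode()
                        frag[pos] = rng.choice([b for b in "ACGT" if b != cur]).encode()
                seq = frag.tobytes().decode()
                if minus[ri]:
                    seq = revcomp(seq)
                reads.append(Read(
                    id=f"{tid}_r{ri + 1}",
                    bases=seq,
                    quals=_qual_string(len(seq)),
                ))
        gold[tid] = GoldRecord(tid, allele_a, allele_b, t5, t3,
                               orf_start, orf_stop, het_sites, n_reads)

    return SimulatedDataset(config=cfg, templates=templates, contigs=contigs,
                            reads=reads, gold=gold)


def _true_alleles(g: GoldRecord, pos: int) -> set[str]:
    for p, a, b in g.het_sites:
        if p == pos:
            return {a, b}
    return {g.allele_a[pos]}


def evaluate_extension(extended, gold: dict[str, GoldRecord]) -> dict:
    """Score elongated contigs against the known templates.

    Per contig: fraction of truncated bases recovered, per-base identity of
    the elongated spans (an ambiguity code is correct iff its base set covers
    the true allele(s)), het-site code accuracy, and ORF completeness before
    and after extension.  Aggregates are pooled over all contigs.
    """
    tot_trunc = tot_recovered = 0
    tot_added = tot_correct = 0
    het_covered = het_correct = 0
    n_full_before = n_full_after = n = 0
    per_contig = []
    for c in extended:
        if c.id not in gold:
            raise KeyError(f"no gold record for contig {c.id}")
        g = gold[c.id]
        L = len(g.allele_a)
        s, e = c.core_span
        added5, added3 = s, len(c.bases) - e
        trunc = g.trunc5 + g.trunc3
        recovered = min(added5, g.trunc5) + min(added3, g.trunc3)
        tot_trunc += trunc
        tot_recovered += recovered

        correct = evaluated = 0
        for i in list(range(added5)) + list(range(e, len(c.bases))):
            tpos = g.trunc5 - s + i
            evaluated += 1
            if 0 <= tpos < L:
                truth = _true_alleles(g, tpos)
                called = IUPAC_SETS.get(c.bases[i], set())
                if truth <= called:
                    correct += 1
                if len(truth) == 2:
                    het_covered += 1
                    if c.bases[i] == PAIR_TO_CODE[frozenset(truth)]:
                        het_correct += 1
        tot_added += evaluated
        tot_correct += correct

        before = classify_orf(Contig(id=c.id, bases=c.core))
        after = classify_orf(c)
        n += 1
        n_full_before += before.orf_class == "full_length"
        n_full_after += after.orf_class == "full_length"
        per_contig.append({
            "contig": c.id,
            "recovered": recovered, "truncated": trunc,
            "added": evaluated, "correct": correct,
            "class_before": before.orf_class, "class_after": after.orf_class,
        })

    return {
        "per_contig": per_contig,
        "recovered_fraction": tot_recovered / tot_trunc if tot_trunc else 1.0,
        "identity": tot_correct / tot_added if tot_added else 1.0,
        "het_covered": het_covered,
        "het_correct": het_correct,
        "het_code_fraction": het_correct / het_covered if het_covered else 1.0,
        "full_length_fraction_before": n_full_before / n if n else 0.0,
        "full_length_fraction_after": n_full_after / n if n else 0.0,
        "n_contigs": n,
    }
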