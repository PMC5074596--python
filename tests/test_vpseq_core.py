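import math
from fractions import Fraction

import numpy as np
import pytest

from vpseq.read_index import build_store
from vpseq.seqio import AMBIGUITY_CODES, IUPAC_SETS, Contig, Read
from vpseq.simulate import SimConfig, simulate_dataset
from vpseq.vpseq_core import (
    NO_CALL,
    CallRule,
    ExtendParams,
    ProfileColumn,
    batch_extend,
    call_base,
    extend_once,
    posterior,
    vpseq_extend,
)


def col(**counts):
    c = {b: 0 for b in "ACGT"}
    c.update(counts)
    return ProfileColumn(position=1, counts=c)


class TestPosterior:
    def test_empty_column_uniform_prior(self):
        for b in "ACGT":
            assert posterior(col(), b) == 0.25

    def test_unanimous_hundred(self):
        assert posterior(col(A=100), "A") == pytest.approx(105 / 120)

    def test_code_is_component_sum(self):
        c = col(A=30, G=30)
        assert posterior(c, "A") == pytest.approx(35 / 80)
        assert posterior(c, "R") == pytest.approx(0.875)
        assert posterior(c, "R", exact=True) == posterior(c, "A", exact=True) + posterior(c, "G", exact=True)

    def test_normalization_random_columns(self, rng):
        for _ in range(2000):
            c = col(**{b: int(x) for b, x in zip("ACGT", rng.integers(0, 500, 4))})
            total = sum(posterior(c, b, exact=True) for b in "ACGT")
            assert total == 1


def brute_call(counts, prev, p=Fraction(4, 5), n=20):
    """Direct evaluation of the three-branch rule, written independently."""
    depth = sum(counts.values())
    post = {b: Fraction(counts[b] * 4 + n, 4 * (depth + n)) for b in "ACGT"}
    best_b = max("ACGT", key=lambda b: post[b])  # max() keeps first on ties: A<C<G<T
    if post[best_b] >= p:
        return best_b
    if prev in "ACGT":
        cp = {}
        for code in AMBIGUITY_CODES:
            x, y = sorted(IUPAC_SETS[code])
            if counts[x] > 0 and counts[y] > 0:
                cp[code] = post[x] + post[y]
        if cp:
            best_c = max(AMBIGUITY_CODES, key=lambda c: cp.get(c, Fraction(-1)))
            if cp[best_c] >= p:
                return best_c
    return NO_CALL


class TestCallBase:
    def test_strong_single_base(self):
        assert call_base(col(A=100), CallRule(previous_base="T")) == "A"

    def test_heterozygous_code_and_successive_ban(self):
        c = col(A=30, G=30)
        assert call_base(c, CallRule(previous_base="T")) == "R"
        assert call_base(c, CallRule(previous_base="R")) is NO_CALL

    def test_unanimous_depth_boundary(self):
        # (N+5)/(N+20) >= 0.8  <=>  N >= 55
        assert call_base(col(A=54), CallRule(previous_base="T")) is NO_CALL
        assert call_base(col(A=55), CallRule(previous_base="T")) == "A"

    def test_threshold_depth_relation_parametric(self):
        # unanimous calling depth: N >= (p*n - n/4) / (1 - p), n = 20
        for p in (0.6, 0.7, 0.8, 0.9):
            frac = Fraction(str(p))
            n_min = math.ceil((frac * 20 - 5) / (1 - frac))
            rule = CallRule(p_threshold=p, previous_base="T")
            assert call_base(col(A=n_min), rule) == "A"
            if n_min > 0:
                assert call_base(col(A=n_min - 1), rule) is NO_CALL

    def test_exhaustive_grid_matches_bruteforce(self):
        values = [0, 1, 3, 27, 28, 54, 55, 56, 100]
        rule_t = CallRule(previous_base="T")
        rule_r = CallRule(previous_base="R")
        for a in values:
            for cc in values:
                for g in values:
                    for t in values:
                        c = col(A=a, C=cc, G=g, T=t)
                        assert call_base(c, rule_t) == brute_call(c.counts, "T")
                        assert call_base(c, rule_r) == brute_call(c.counts, "R")

    def test_lexicographic_tie_breaks(self):
        assert call_base(col(A=100, C=100), CallRule(previous_base="T")) == "M"
        # four-way tie below threshold
        assert call_base(col(A=1, C=1, G=1, T=1), CallRule(previous_base="T")) is NO_CALL


def reads_from(template, read_len, step, rid_prefix="r"):
    reads = []
    i = 0
    for s in range(0, len(template) - read_len + 1, step):
        reads.append(Read(f"{rid_prefix}{i}", template[s:s + read_len], [40] * read_len))
        i += 1
    return reads


class TestExtension:
    def test_no_hits_no_change(self, rng, small_store):
        foreign = "".join(rng.choice(list("ACGT"), size=120))
        c = Contig(id="x", bases=foreign)
        out, report = vpseq_extend(c, small_store)
        assert out.bases == foreign
        assert report.rounds == 1
        assert out.core_span == (0, 120)

    def test_extend_once_recovers_terminal_bases(self, small_sim, small_store):
        gold = small_sim.gold["t001"]
        c = small_sim.contigs[0]
        new, rlog = extend_once(c, "three_prime", small_store)
        assert 0 < len(new) <= 81  # one round is capped by read overhang (101-20)
        truth_from = gold.trunc5 + len(c.bases)
        assert gold.allele_a[truth_from: truth_from + len(new)] == new

    def test_full_template_recovery_multi_round(self, small_sim, small_store):
        for c in small_sim.contigs:
            g = small_sim.gold[c.id]
            out, report = vpseq_extend(c, small_store)
            assert out.bases == g.allele_a
            assert out.core == c.bases  # input contig verbatim inside output
            assert report.added5 == g.trunc5 and report.added3 == g.trunc3
            ends_5 = [l for l in report.log if l.end == "five_prime" and l.bases_added]
            assert len(ends_5) >= 2  # 150 bp needs at least two rounds per end

    def test_fixpoint(self, small_sim, small_store):
        c = small_sim.contigs[0]
        once, _ = vpseq_extend(c, small_store)
        twice, rep = vpseq_extend(Contig(id=c.id, bases=once.bases), small_store)
        assert twice.bases == once.bases

    def test_heterozygous_site_called_as_code(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=260))
        pos = 230  # inside the region to be recovered
        allele_a = base
        allele_b = base[:pos] + ("G" if base[pos] != "G" else "C") + base[pos + 1:]
        reads = reads_from(allele_a, 101, 1, "a") + reads_from(allele_b, 101, 1, "b")
        store = build_store(reads)
        contig = Contig(id="c", bases=base[:200])
        out, _ = vpseq_extend(contig, store)
        code = out.bases[pos]
        assert code in AMBIGUITY_CODES
        assert IUPAC_SETS[code] == {allele_a[pos], allele_b[pos]}
        # neighbors stay unambiguous
        assert out.bases[pos - 1] == base[pos - 1]
        assert out.bases[pos + 1] == base[pos + 1]

    def test_batch_is_order_independent(self, small_sim, small_store):
        fwd = [c.bases for c, _ in batch_extend(small_sim.contigs, small_store)]
        rev = [c.bases for c, _ in batch_extend(small_sim.contigs[::-1], small_store)]
        assert fwd == rev[::-1]

    def test_batch_monotone_lengths(self, small_sim, small_store):
        for c, _ in batch_extend(small_sim.contigs, small_store):
            pass
        outs = list(batch_extend(small_sim.contigs, small_store))
        assert len(outs) == len(small_sim.contigs)
        for (out, _), inp in zip(outs, small_sim.contigs):
            assert len(out) >= len(inp)

    def test_rounds_capped(self, small_sim, small_store):
        params = ExtendParams(max_rounds=2)
        _, report = vpseq_extend(small_sim.contigs[0], small_store, params)
        assert report.rounds <= 2

    def test_low_complexity_template_terminates(self):
        # adversarial: tandem repeat keeps recruiting the same primer
        unit = "ACGTTGCA"
        template = unit * 40
        reads = reads_from(template, 64, 1)
        store = build_store(reads)
        contig = Contig(id="rep", bases=template[100:220])
        out, report = vpseq_extend(contig, store)
        assert report.rounds <= ExtendParams().max_rounds
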