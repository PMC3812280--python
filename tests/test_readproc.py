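"""Adapter trimming, pair collapsing and length filtering.

The trimming and collapsing implementations are checked against
brute-force all-offset oracles written independently here.
"""

from __future__ import annotations

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st

from ligbias._seq import revcomp
from ligbias.libprep import ADAPTER_INPE, PrepConfig, ReadRecord, prepare_library, sequence_paired_end
from ligbias.readproc import (
    ProcessedRead,
    collapse_pair,
    filter_length,
    process_pairs,
    trim_adapter,
)
from ligbias.simgenome import fragment_genome

Q37 = chr(37 + 33)


def rec(seq: str, qual: str | None = None, name: str = "r") -> ReadRecord:
    return ReadRecord(name, seq, qual if qual is not None else Q37 * len(seq))


# ---------------------------------------------------------------- oracles

def oracle_trim(seq: str, adapter: str, rate: float = 1 / 3) -> str:
    """Repeatedly remove the longest suffix matching an adapter prefix at
    mismatch rate <= ``rate`` (all offsets, brute force) until stable."""
    while True:
        n = len(seq)
        cut = n
        for i in range(n):
            o = min(n - i, len(adapter))
            mm = sum(a != b for a, b in zip(seq[i : i + o], adapter[:o]))
            if mm <= rate * o + 1e-9:
                cut = i
                break
        if cut == n:
            return seq
        seq = seq[:cut]


def oracle_collapse_overlap(s1: str, s2rc: str, min_o: int = 11) -> int | None:
    """Best suffix/prefix overlap by (rate, then longest); None if no overlap
    of at least ``min_o`` bases has mismatch rate <= 1/3."""
    best = None
    for o in range(min(len(s1), len(s2rc)), min_o - 1, -1):
        mm = sum(a != b for a, b in zip(s1[len(s1) - o :], s2rc[:o]))
        if mm * 3 <= o + 1e-9:
            cand = (mm / o, -o)
            if best is None or cand < best:
                best = cand
    return None if best is None else -best[1]


# ---------------------------------------------------------------- trimming

class TestTrimAdapter:
    def test_clean_read_unchanged(self):
        # suffix engineered to disagree with every adapter prefix
        seq = "ACCACCACCACCACCACCACCACCACCACC"
        assert oracle_trim(seq, ADAPTER_INPE) == seq
        out = trim_adapter(rec(seq), ADAPTER_INPE)
        assert out.seq == seq

    def test_exact_read_through_removed(self):
        insert = "ACCACCACCACCACCACCACCACCACCACCACCACCACCACCACCACCACCACCACCACC"[:60]
        read = insert + ADAPTER_INPE + "ACCA" * 5
        out = trim_adapter(rec(read), ADAPTER_INPE)
        assert out.seq == insert

    def test_mismatch_rate_boundary_inclusive(self):
        # 12-base adapter overlap: 4 mismatches (rate 1/3) trims, 5 does not
        adapter = ADAPTER_INPE
        prefix = "ACCACCACCACCACCACCACCACCACCACCACCACCACCACCACCACC"[:48]
        core = list(adapter[:12])
        for k in range(4):
            core[3 * k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[core[k * 3]]
        read4 = prefix + "".join(core)
        assert trim_adapter(rec(read4), adapter).seq == prefix
        core[1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[core[1]]
        read5 = prefix + "".join(core)
        out5 = trim_adapter(rec(read5), adapter)
        assert len(out5.seq) > len(prefix)  # 5/12 > 1/3: not trimmed there

    def test_terminal_quality_and_n_trimming(self):
        seq = "NACGTACGTACGTACGTACGTACGTACCA"
        quals = "#" + Q37 * 26 + "##"  # Phred 2 at both termini
        out = trim_adapter(rec(seq, quals), ADAPTER_INPE)
        assert out.seq == seq[1:-2]
        assert out.qual == Q37 * 26

    def test_randomized_against_oracle(self):
        rng = np.random.default_rng(71)
        for _ in range(300):
            n = int(rng.integers(5, 70))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            # sometimes plant adapter with noise
            if rng.random() < 0.5:
                cut = int(rng.integers(0, n))
                planted = list(ADAPTER_INPE[: n - cut])
                for j in range(len(planted)):
                    if rng.random() < 0.2:
                        planted[j] = "ACGT"[rng.integers(0, 4)]
                seq = seq[:cut] + "".join(planted)
            out = trim_adapter(rec(seq), ADAPTER_INPE)
            assert out.seq == oracle_trim(seq, ADAPTER_INPE)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_never_longer(self, seq):
        once = trim_adapter(rec(seq), ADAPTER_INPE)
        twice = trim_adapter(ReadRecord("r", once.seq, once.qual), ADAPTER_INPE)
        assert twice.seq == once.seq
        assert len(once.seq) <= len(seq)


# ---------------------------------------------------------------- collapsing

class TestCollapsePair:
    def _pair_from_insert(self, insert: str, read_len: int = 100):
        r1 = rec(insert[:read_len], name="p/1")
        r2 = rec(revcomp(insert)[:read_len], name="p/2")
        return r1, r2

    def test_150bp_insert_collapses_to_exact_length(self):
        rng = np.random.default_rng(72)
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        out = collapse_pair(*self._pair_from_insert(insert))
        assert isinstance(out, ProcessedRead)
        assert out.seq == insert and len(out) == 150  # 100 + 100 - 50

    def test_190bp_insert_overlap_below_threshold_not_collapsed(self):
        rng = np.random.default_rng(73)
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 190))
        out = collapse_pair(*self._pair_from_insert(insert))
        assert isinstance(out, tuple)  # overlap 10 < 11
        assert out[0].origin == "pair_read1" and out[1].origin == "pair_read2"

    def test_consensus_prefers_higher_quality_base(self):
        insert = "ACGTACGTACGTACGTACGTACGT"  # 24 bp, full-length overlap
        r1 = rec(insert, name="p/1")
        wrong = "T" + insert[1:]
        r2 = ReadRecord("p/2", revcomp(wrong), chr(20 + 33) * 24)
        out = collapse_pair(r1, r2)
        assert isinstance(out, ProcessedRead)
        assert out.seq == insert  # Q37 beats Q20 at the disagreement

    def test_agreeing_qualities_sum_with_cap(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        out = collapse_pair(*self._pair_from_insert(insert))
        assert isinstance(out, ProcessedRead)
        assert set(out.quals) == {chr(41 + 33)}  # 37+37 capped at 41

    def test_truth_mode_reconstruction(self, equal_genome):
        # error-free 2x100 pairs from 120-180 bp inserts: whenever the true
        # mate overlap is >= 11 the collapse reconstructs the insert exactly
        frags = fragment_genome(equal_genome, 2_000, size_range=(120, 180), seed=74)
        cfg = PrepConfig(read_length=100)
        mols = prepare_library(frags, cfg, seed=75)
        pairs = sequence_paired_end(mols, cfg, seed=76)
        n_collapsible = 0
        for (r1, r2), mol in zip(pairs, mols):
            out = collapse_pair(r1, r2)
            true_overlap = 200 - mol.insert_len
            if true_overlap >= 11:
                n_collapsible += 1
                assert isinstance(out, ProcessedRead)
                assert out.seq == mol.insert_top
        assert n_collapsible > 1_500

    def test_randomized_overlap_against_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n1 = int(rng.integers(15, 60))
            n2 = int(rng.integers(15, 60))
            s1 = "".join("ACGT"[i] for i in rng.integers(0, 4, n1))
            if rng.random() < 0.6:  # plant a true overlap with noise
                o = int(rng.integers(5, min(n1, n2)))
                s2rc = list(s1[n1 - o :] + "".join("ACGT"[i] for i in rng.integers(0, 4, n2 - o)))
                for j in range(o):
                    if rng.random() < 0.1:
                        s2rc[j] = "ACGT"[rng.integers(0, 4)]
                s2rc = "".join(s2rc)
            else:
                s2rc = "".join("ACGT"[i] for i in rng.integers(0, 4, n2))
            out = collapse_pair(rec(s1, name="x/1"), rec(revcomp(s2rc), name="x/2"))
            expected = oracle_collapse_overlap(s1, s2rc)
            if expected is None:
                assert isinstance(out, tuple)
            else:
                assert isinstance(out, ProcessedRead)
                assert len(out) == n1 + n2 - expected


# ---------------------------------------------------------------- filtering

class TestFilterLength:
    def test_boundary_inclusive_at_25(self):
        reads = [ProcessedRead("a", "A" * n, Q37 * n) for n in (10, 24, 25, 30)]
        kept = filter_length(reads)
        assert [len(r) for r in kept] == [25, 30]

    def test_empty_input(self):
        assert filter_length([]) == []

    def test_stable_order(self):
        reads = [ProcessedRead(str(n), "A" * n, Q37 * n) for n in (30, 25, 40)]
        assert [r.name for r in filter_length(reads)] == ["30", "25", "40"]


def test_process_pairs_counts_are_consistent(equal_genome):
    frags = fragment_genome(equal_genome, 1_000, seed=78)
    cfg = PrepConfig()
    mols = prepare_library(frags, cfg, seed=79)
    pairs = sequence_paired_end(mols, cfg, seed=80)
    reads, counts = process_pairs(pairs)
    assert counts["raw_pairs"] == 1_000
    assert counts["collapsed"] + counts["uncollapsed_pairs"] == 1_000
    assert counts["passed"] == len(reads) <= counts["collapsed"]
    assert all(r.origin == "collapsed" and len(r) >= 25 for r in reads)
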