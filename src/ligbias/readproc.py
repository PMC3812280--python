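"""Read processing: adapter trimming, quality trimming, pair collapsing.

Mirrors the standard pre-alignment treatment of short-insert paired-end
data from degraded samples: remove known adapter read-through allowing a
mismatch rate of 1/3, trim terminal low-quality (Phred <= 2) or N bases,
collapse mates whose sequenced ends overlap by at least 11 bp into a
single full-insert read, and discard processed reads shorter than 25 bp.

Mismatch-rate comparisons are inclusive (<= 1/3), evaluated in exact
integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._seq import revcomp
from .libprep import ADAPTER_INPE, ReadRecord

__all__ = [
    "ProcessingConfig",
    "ProcessedRead",
    "trim_adapter",
    "collapse_pair",
    "filter_length",
    "process_pairs",
    "read_fastq",
    "stage_counts_tsv",
]


@dataclass(frozen=True)
class ProcessingConfig:
    adapter1: str = ADAPTER_INPE
    adapter2: str = ADAPTER_INPE
    max_adapter_mismatch_rate: float = 1.0 / 3.0
    min_overlap_collapse: int = 11
    min_length: int = 25
    min_qual_terminal: int = 2
    qual_cap: int = 41  # consensus quality ceiling

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_adapter_mismatch_rate < 1.0):
            raise ValueError("max_adapter_mismatch_rate must be in [0, 1)")
        if self.min_overlap_collapse < 1:
            raise ValueError("min_overlap_collapse must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class ProcessedRead:
    name: str
    seq: str
    quals: str
    origin: str = "single"  # {collapsed, pair_read1, pair_read2, single}

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("seq and quals must have equal length")

    def __len__(self) -> int:
        return len(self.seq)


def trim_adapter(read: ReadRecord, adapter: str, cfg: ProcessingConfig | None = None) -> ReadRecord:
    """Remove 3' adapter read-through, then trim low-quality/N termini.

    The longest read suffix that aligns ungapped to a prefix of the
    adapter with a mismatch rate <= ``max_adapter_mismatch_rate`` is
    removed (ties broken toward the longer trim, i.e. the earliest
    qualifying offset wins).  Terminal bases with Phred quality
    <= ``min_qual_terminal`` or called N are then trimmed from both ends.
    Both steps repeat until a fixed point so trimming is idempotent (a
    shortened read can expose a new, shorter qualifying suffix).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    cfg = cfg or ProcessingConfig()
    seq, quals = read.seq, read.qual
    while True:
        before = seq
        n = len(seq)
        m = len(adapter)
        cut = n
        if n:
            # pad with a sentinel so every offset has a full-length adapter
            # window; sentinel positions always mismatch and are subtracted
            arr = np.frombuffer((seq + "\x00" * m).encode("ascii"), dtype=np.uint8)
            ad = np.frombuffer(adapter.encode("ascii"), dtype=np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(arr, m)[:n]
            mm_padded = (win != ad).sum(axis=1)
            overlap = np.minimum(n - np.arange(n), m)
            mm = mm_padded - (m - overlap)
            ok = mm <= cfg.max_adapter_mismatch_rate * overlap + 1e-9
            hits = np.flatnonzero(ok)
            if hits.size:
                cut = int(hits[0])
        seq, quals = seq[:cut], quals[:cut]

        lo, hi = 0, len(seq)
        while lo < hi and (ord(quals[lo]) - 33 <= cfg.min_qual_terminal or seq[lo] == "N"):
            lo += 1
        while hi > lo and (ord(quals[hi - 1]) - 33 <= cfg.min_qual_terminal or seq[hi - 1] == "N"):
            hi -= 1
        seq, quals = seq[lo:hi], quals[lo:hi]
        if seq == before:
            break
    return ReadRecord(read.name, seq, quals)


def collapse_pair(
    read1: ReadRecord,
    read2: ReadRecord,
    cfg: ProcessingConfig | None = None,
) -> ProcessedRead | tuple[ProcessedRead, ProcessedRead]:
    """Collapse a trimmed mate pair into one full-insert read if possible.

    Read 2 is reverse-complemented; the best ungapped suffix(read1)/
    prefix(rc read2) overlap of at least ``min_overlap_collapse`` bases
    and mismatch rate <= 1/3 is chosen by maximal identity (ties toward
    the longer overlap).  The consensus takes the higher-quality base at
    disagreements and sums qualities (capped) at agreements.  Without a
    qualifying overlap the pair is returned unchanged.
    """
    cfg = cfg or ProcessingConfig()
    s1, q1 = read1.seq, read1.qual
    s2 = revcomp(read2.seq)
    q2 = read2.qual[::-1]
    n1, n2 = len(s1), len(s2)

    best: tuple[float, int] | None = None  # (mismatch rate, -overlap)
    if min(n1, n2) >= cfg.min_overlap_collapse:
        # one padded comparison matrix: row for overlap o compares
        # s1[n1-o:] with s2[:o]; sentinel padding never matches
        a1 = np.frombuffer((s1 + "\x00" * n2).encode("ascii"), dtype=np.uint8)
        a2 = np.frombuffer(s2.encode("ascii"), dtype=np.uint8)
        overlaps = np.arange(cfg.min_overlap_collapse, min(n1, n2) + 1)
        win = np.lib.stride_tricks.sliding_window_view(a1, n2)[n1 - overlaps]
        mm = (win != a2).cumsum(axis=1)[np.arange(overlaps.size), overlaps - 1]
        ok = mm * 3 <= overlaps + 1e-9  # inclusive 1/3 mismatch rate
        if ok.any():
            rates = mm[ok] / overlaps[ok]
            cand = np.lexsort((-overlaps[ok], rates))[0]
            best = (float(rates[cand]), -int(overlaps[ok][cand]))
    if best is None:
        name = read1.name
        return (
            ProcessedRead(read1.name, s1, q1, origin="pair_read1"),
            ProcessedRead(read2.name, read2.seq, read2.qual, origin="pair_read2"),
        )

    o = -best[1]
    cons_seq: list[str] = []
    cons_qual: list[str] = []
    for j in range(o):
        b1, b2 = s1[n1 - o + j], s2[j]
        p1, p2 = ord(q1[n1 - o + j]) - 33, ord(q2[j]) - 33
        if b1 == b2:
            cons_seq.append(b1)
            cons_qual.append(chr(min(p1 + p2, cfg.qual_cap) + 33))
        elif p1 >= p2:
            cons_seq.append(b1)
            cons_qual.append(chr(p1 + 33))
        else:
            cons_seq.append(b2)
            cons_qual.append(chr(p2 + 33))
    seq = s1[: n1 - o] + "".join(cons_seq) + s2[o:]
    quals = q1[: n1 - o] + "".join(cons_qual) + q2[o:]
    name = read1.name[:-2] if read1.name.endswith("/1") else read1.name
    return ProcessedRead(name, seq, quals, origin="collapsed")


def filter_length(reads: Sequence[ProcessedRead], cfg: ProcessingConfig | None = None) -> list[ProcessedRead]:
    """Keep reads of length >= ``min_length`` (stable order)."""
    cfg = cfg or ProcessingConfig()
    return [r for r in reads if len(r) >= cfg.min_length]


def process_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    cfg: ProcessingConfig | None = None,
    collapsed_only: bool = True,
) -> tuple[list[ProcessedRead], dict[str, int]]:
    """Trim, collapse and length-filter a stream of read pairs.

    Returns the surviving reads and per-stage counts (raw pairs, trimmed
    pairs, collapsed reads, length-filtered reads).  With
    ``collapsed_only`` (the treatment given to degraded samples), pairs
    that fail to collapse are dropped rather than kept as mates.
    """
    cfg = cfg or ProcessingConfig()
    counts = {"raw_pairs": 0, "collapsed": 0, "uncollapsed_pairs": 0, "passed": 0}
    out: list[ProcessedRead] = []
    candidates: list[ProcessedRead] = []
    for r1, r2 in pairs:
        counts["raw_pairs"] += 1
        t1 = trim_adapter(r1, cfg.adapter1, cfg)
        t2 = trim_adapter(r2, cfg.adapter2, cfg)
        res = collapse_pair(t1, t2, cfg)
        if isinstance(res, ProcessedRead):
            counts["collapsed"] += 1
            candidates.append(res)
        else:
            counts["uncollapsed_pairs"] += 1
            if not collapsed_only:
                candidates.extend(res)
    out = filter_length(candidates, cfg)
    counts["passed"] = len(out)
    return out, counts


def read_fastq(path: str | Path) -> list[ReadRecord]:
    recs = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        recs.append(ReadRecord(rec.description or rec.id, str(rec.seq), quals))
    return recs


def stage_counts_tsv(counts: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tcount\n")
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")
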