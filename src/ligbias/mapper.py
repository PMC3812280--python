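"""Desk-scale unique-hit read mapping and PCR-duplicate removal.

A k-mer hash over the reference seeds candidate loci (exact seed at the
read start, read end as fallback), which are extended ungapped.  A read is
reported only when it has a single best locus with at most
``max_mismatches`` mismatches and every other locus carries at least two
more — a uniqueness margin standing in for a mapping-quality cutoff
(discard multi-mappers) without reimplementing an aligner's MAPQ formula.
Simulated reads contain no indels, so alignment is ungapped; real data
should be mapped with an external aligner whose SAM the profiler also
accepts.

``AlignedRead.read_seq`` is stored in molecule orientation (the strand as
sequenced); for '-' alignments the reverse complement matches the
reference at [start, end].  SAM emission follows the SAM convention of
storing the reference-forward sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from ._seq import encode, revcomp
from .readproc import ProcessedRead
from .simgenome import ReferenceGenome

__all__ = ["AlignedRead", "align", "remove_duplicates", "write_sam", "read_sam"]


@dataclass
class AlignedRead:
    name: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    read_seq: str  # molecule orientation (5'->3' as sequenced)
    quals: str
    n_mismatches: int = 0
    sum_qual: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.read_seq):
            raise ValueError("alignment span must equal read length")


def _build_index(codes: np.ndarray, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    data = codes.tobytes()
    for i in range(len(data) - k + 1):
        index.setdefault(data[i : i + k], []).append(i)
    return index


def _cached_index(ref: ReferenceGenome, k: int) -> dict[bytes, list[int]]:
    # the index is pure function of (seq, k); memoize per reference object
    cache = getattr(ref, "_kmer_index_cache", None)
    if cache is None:
        cache = {}
        ref._kmer_index_cache = cache
    if k not in cache:
        cache[k] = _build_index(ref.codes, k)
    return cache[k]


def align(
    reads: Sequence[ProcessedRead],
    ref: ReferenceGenome,
    k_seed: int = 20,
    max_mismatches: int = 3,
) -> list[AlignedRead]:
    """Map reads to the reference, keeping unique high-confidence hits only."""
    if len(ref) < k_seed:
        raise ValueError("reference shorter than k_seed")
    codes = ref.codes
    L = len(codes)
    index = _cached_index(ref, k_seed)

    out: list[AlignedRead] = []
    for read in reads:
        n = len(read.seq)
        if n < k_seed:
            continue
        fwd = encode(read.seq)
        rev = encode(revcomp(read.seq))
        # candidate alignment starts per strand, from start-seed then end-seed
        cands: set[tuple[int, str]] = set()
        for arr, strand in ((fwd, "+"), (rev, "-")):
            data = arr.tobytes()
            for pos in index.get(data[:k_seed], ()):
                cands.add((pos, strand))
            for pos in index.get(data[-k_seed:], ()):
                cands.add((pos - (n - k_seed), strand))
        best: tuple[int, int, str, np.ndarray] | None = None  # (mm, start, strand, arr)
        second_mm = None
        for pos, strand in cands:
            if pos < 0 or pos + n > L:
                continue
            arr = fwd if strand == "+" else rev
            mm = int((codes[pos : pos + n] != arr).sum())
            if best is None or mm < best[0]:
                if best is not None:
                    second_mm = best[0]
                best = (mm, pos, strand, arr)
            elif second_mm is None or mm < second_mm:
                second_mm = mm
        if best is None or best[0] > max_mismatches:
            continue
        if second_mm is not None and second_mm - best[0] < 2:
            continue  # ambiguous locus
        mm, pos, strand, _ = best
        out.append(
            AlignedRead(
                name=read.name,
                contig=ref.name,
                start=pos + 1,
                end=pos + n,
                strand=strand,
                read_seq=read.seq,
                quals=read.quals,
                n_mismatches=mm,
                sum_qual=sum(read.quals.encode("ascii")) - 33 * len(read.quals),
            )
        )
    return out


def remove_duplicates(alignments: Sequence[AlignedRead]) -> tuple[list[AlignedRead], float]:
    """Collapse PCR duplicates on (contig, strand, start, end).

    The retained representative is the alignment with the highest summed
    base quality.  Returns the unique alignments (input order) and the
    clonality, 1 - #unique/#total (0.0 for empty input).
    """
    if not alignments:
        return [], 0.0
    best_by_key: dict[tuple, int] = {}
    for i, aln in enumerate(alignments):
        key = (aln.contig, aln.strand, aln.start, aln.end)
        j = best_by_key.get(key)
        if j is None or aln.sum_qual > alignments[j].sum_qual:
            best_by_key[key] = i
    keep = sorted(best_by_key.values())
    unique = [alignments[i] for i in keep]
    clonality = 1.0 - len(unique) / len(alignments)
    return unique, clonality


def write_sam(alignments: Sequence[AlignedRead], ref: ReferenceGenome, path: str | Path) -> None:
    """Emit minimal valid SAM (ungapped alignments, CIGAR '<len>M')."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.name, "LN": len(ref)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aln.name
            a.flag = 16 if aln.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = aln.start - 1
            a.mapping_quality = 37
            a.cigarstring = f"{len(aln.read_seq)}M"
            if aln.strand == "-":
                a.query_sequence = revcomp(aln.read_seq)
                a.query_qualities = pysam.qualitystring_to_array(aln.quals[::-1])
            else:
                a.query_sequence = aln.read_seq
                a.query_qualities = pysam.qualitystring_to_array(aln.quals)
            a.set_tag("NM", aln.n_mismatches)
            fh.write(a)


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Read (possibly externally produced) SAM into AlignedRead records.

    Only mapped, ungapped primary alignments are loaded; '-' strand
    sequences are flipped back into molecule orientation.
    """
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            seq = a.query_sequence or ""
            quals = pysam.qualities_to_qualitystring(a.query_qualities) if a.query_qualities is not None else "I" * len(seq)
            strand = "-" if a.is_reverse else "+"
            if strand == "-":
                seq = revcomp(seq)
                quals = quals[::-1]
            out.append(
                AlignedRead(
                    name=a.query_name,
                    contig=a.reference_name,
                    start=a.reference_start + 1,
                    end=a.reference_start + len(seq),
                    strand=strand,
                    read_seq=seq,
                    quals=quals,
                    n_mismatches=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                    sum_qual=sum(ord(c) - 33 for c in quals),
                )
            )
    return out
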