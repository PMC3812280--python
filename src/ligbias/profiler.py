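"""Positional base-composition and misincorporation profiling.

Computes the diagnostics used to authenticate degraded-DNA libraries:

* base composition at the first and last W read positions plus the W
  genomic bases flanking each alignment (upstream -W..-1, downstream
  N+1..N+W), all in molecule orientation — reads aligned to the '-'
  strand are flipped so "position 1" is always the molecule's 5'
  terminus and its flanks are mirrored and complemented;
* C->T and G->A mismatch rates per position from the 5' and 3' read ends,
  with denominators counting reference C (resp. G) at each position —
  zero-denominator positions are undefined (NaN), never 0;
* endogenous content (unique quality hits / collapsed reads) and
  percentage-point deficits against genomic composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import comp_codes, encode
from .mapper import AlignedRead
from .simgenome import ReferenceGenome

__all__ = [
    "PositionalProfile",
    "MisincorporationProfile",
    "composition_profile",
    "misincorporation_profile",
    "endogenous_content",
    "deficit",
]


@dataclass
class PositionalProfile:
    """Per-position base composition around read termini.

    Rows of each (W, 4) array are fractions of A, C, G, T; ``*_n`` are the
    per-position denominators.  ``read_start`` covers read positions
    1..W, ``flank_start`` genomic -W..-1 (both ordered -W -> -1 and
    1 -> W); ``read_end`` covers N-W+1..N and ``flank_end`` N+1..N+W.
    """

    W: int
    n_reads: int
    read_start: np.ndarray
    flank_start: np.ndarray
    read_end: np.ndarray
    flank_end: np.ndarray
    read_start_n: np.ndarray
    flank_start_n: np.ndarray
    read_end_n: np.ndarray
    flank_end_n: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pos in range(-self.W, 0):
            rows.append(("start", pos, *self.flank_start[pos + self.W], self.flank_start_n[pos + self.W]))
        for j in range(self.W):
            rows.append(("start", j + 1, *self.read_start[j], self.read_start_n[j]))
        for j in range(self.W):
            rows.append(("end", -(self.W - j), *self.read_end[j], self.read_end_n[j]))
        for j in range(self.W):
            rows.append(("end", j + 1, *self.flank_end[j], self.flank_end_n[j]))
        return pd.DataFrame(rows, columns=["terminus", "position", "A", "C", "G", "T", "n"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class MisincorporationProfile:
    """C->T / G->A rates per position from the 5' and 3' read ends.

    ``ct5``/``ga5`` index positions 1..W5 from the 5' end; ``ct3``/``ga3``
    index positions -1..-W5 from the 3' end (element 0 is the terminal
    base).  Rates are NaN where the denominator is zero.
    """

    W5: int
    n_reads: int
    ct5: np.ndarray
    ga5: np.ndarray
    ct3: np.ndarray
    ga3: np.ndarray
    ct5_den: np.ndarray
    ga5_den: np.ndarray
    ct3_den: np.ndarray
    ga3_den: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for j in range(self.W5):
            rows.append(("5p", j + 1, "C", "T", self.ct5_den[j], self.ct5[j]))
            rows.append(("5p", j + 1, "G", "A", self.ga5_den[j], self.ga5[j]))
            rows.append(("3p", -(j + 1), "C", "T", self.ct3_den[j], self.ct3[j]))
            rows.append(("3p", -(j + 1), "G", "A", self.ga3_den[j], self.ga3[j]))
        return pd.DataFrame(rows, columns=["end", "position", "ref", "read", "n_ref", "rate"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


def _gather_arrays(alignments: Sequence[AlignedRead]):
    starts = np.array([a.start - 1 for a in alignments], dtype=np.int64)
    ends = np.array([a.end - 1 for a in alignments], dtype=np.int64)
    minus = np.array([a.strand == "-" for a in alignments], dtype=bool)
    return starts, ends, minus


def _window_codes(alignments: Sequence[AlignedRead], W: int, from_end: bool) -> np.ndarray:
    """(n, W) read base codes from the 5' (or 3') terminus in molecule
    orientation; positions past the read length are padded with 5 (N)."""
    n = len(alignments)
    out = np.full((n, W), 5, dtype=np.uint8)
    for i, a in enumerate(alignments):
        seq = a.read_seq
        if from_end:
            chunk = seq[-W:] if len(seq) >= W else seq
            out[i, W - len(chunk) :] = encode(chunk)
        else:
            chunk = seq[:W]
            out[i, : len(chunk)] = encode(chunk)
    return out


def _comp_counts(codes: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise A/C/G/T fractions and denominators of a code matrix."""
    W = codes.shape[1]
    frac = np.full((W, 4), np.nan)
    den = np.zeros(W, dtype=np.int64)
    for j in range(W):
        col = codes[valid[:, j], j]
        col = col[col < 4]
        den[j] = col.size
        if col.size:
            frac[j] = np.bincount(col, minlength=4)[:4] / col.size
    return frac, den


def composition_profile(
    alignments: Sequence[AlignedRead],
    ref: ReferenceGenome,
    W: int = 10,
) -> PositionalProfile:
    """Base composition at read termini and their genomic flanks.

    Expects unique, deduplicated alignments.  Reads shorter than 2W
    contribute only to the positions they cover; flank positions clipped
    at contig edges are excluded position-wise.
    """
    if not alignments:
        raise ValueError("no data: empty alignment set")
    n = len(alignments)
    codes = ref.codes
    L = len(codes)
    starts, ends, minus = _gather_arrays(alignments)
    lengths = ends - starts + 1

    # read windows (molecule orientation; AlignedRead already stores it)
    rs = _window_codes(alignments, W, from_end=False)
    re_ = _window_codes(alignments, W, from_end=True)
    offs = np.arange(W)
    rs_valid = offs[None, :] < lengths[:, None]
    re_valid = offs[::-1][None, :] < lengths[:, None]

    # genomic flanks, molecule orientation:
    # '+': upstream = ref[start-W .. start-1], downstream = ref[end+1 .. end+W]
    # '-': upstream = comp(ref[end+W .. end+1]), downstream = comp(ref[start-1 .. start-W])
    up_idx = np.where(minus[:, None], ends[:, None] + W - offs[None, :], starts[:, None] - W + offs[None, :])
    dn_idx = np.where(minus[:, None], starts[:, None] - 1 - offs[None, :], ends[:, None] + 1 + offs[None, :])
    up_valid = (up_idx >= 0) & (up_idx < L)
    dn_valid = (dn_idx >= 0) & (dn_idx < L)
    up = codes[np.clip(up_idx, 0, L - 1)]
    dn = codes[np.clip(dn_idx, 0, L - 1)]
    up = np.where(minus[:, None], comp_codes(up), up)
    dn = np.where(minus[:, None], comp_codes(dn), dn)

    read_start, read_start_n = _comp_counts(rs, rs_valid)
    read_end, read_end_n = _comp_counts(re_, re_valid)
    flank_start, flank_start_n = _comp_counts(up, up_valid)
    flank_end, flank_end_n = _comp_counts(dn, dn_valid)
    return PositionalProfile(
        W=W,
        n_reads=n,
        read_start=read_start,
        flank_start=flank_start,
        read_end=read_end,
        flank_end=flank_end,
        read_start_n=read_start_n,
        flank_start_n=flank_start_n,
        read_end_n=read_end_n,
        flank_end_n=flank_end_n,
    )


def misincorporation_profile(
    alignments: Sequence[AlignedRead],
    ref: ReferenceGenome,
    W5: int = 25,
) -> MisincorporationProfile:
    """Per-position C->T and G->A mismatch rates against the reference.

    rate[p] = #(ref C, read T at p) / #(ref C at p), and symmetrically
    for G->A; computed from both the 5' and the 3' terminus in molecule
    orientation.
    """
    if not alignments:
        raise ValueError("no data: empty alignment set")
    codes = ref.codes
    L = len(codes)
    starts, ends, minus = _gather_arrays(alignments)
    lengths = ends - starts + 1
    offs = np.arange(W5)

    read5 = _window_codes(alignments, W5, from_end=False)
    read3 = _window_codes(alignments, W5, from_end=True)
    valid5 = offs[None, :] < lengths[:, None]
    valid3 = offs[::-1][None, :] < lengths[:, None]

    # reference base under molecule position j (5' window) and N-1-j (3')
    idx5 = np.where(minus[:, None], ends[:, None] - offs[None, :], starts[:, None] + offs[None, :])
    ref5 = codes[np.clip(idx5, 0, L - 1)]
    ref5 = np.where(minus[:, None], comp_codes(ref5), ref5)
    # 3' window, ordered like read3 (position N-W5+1 .. N)
    roffs = offs[::-1]
    idx3 = np.where(minus[:, None], starts[:, None] + roffs[None, :], ends[:, None] - roffs[None, :])
    ref3 = codes[np.clip(idx3, 0, L - 1)]
    ref3 = np.where(minus[:, None], comp_codes(ref3), ref3)

    def rates(readm, refm, validm):
        ct_den = ((refm == 1) & validm).sum(axis=0)
        ct_num = ((refm == 1) & (readm == 3) & validm).sum(axis=0)
        ga_den = ((refm == 2) & validm).sum(axis=0)
        ga_num = ((refm == 2) & (readm == 0) & validm).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ct = np.where(ct_den > 0, ct_num / np.maximum(ct_den, 1), np.nan)
            ga = np.where(ga_den > 0, ga_num / np.maximum(ga_den, 1), np.nan)
        return ct, ga, ct_den, ga_den

    ct5, ga5, ct5_den, ga5_den = rates(read5, ref5, valid5)
    ct3r, ga3r, ct3_denr, ga3_denr = rates(read3, ref3, valid3)
    # flip the 3' window so index 0 is the terminal base (position -1)
    return MisincorporationProfile(
        W5=W5,
        n_reads=len(alignments),
        ct5=ct5,
        ga5=ga5,
        ct3=ct3r[::-1].copy(),
        ga3=ga3r[::-1].copy(),
        ct5_den=ct5_den,
        ga5_den=ga5_den,
        ct3_den=ct3_denr[::-1].copy(),
        ga3_den=ga3_denr[::-1].copy(),
    )


def endogenous_content(n_unique_hits: int, n_collapsed: int) -> float:
    """Unique quality-passing hits over collapsed reads, to 5 decimals."""
    if n_collapsed == 0:
        raise ValueError("n_collapsed must be > 0")
    if n_unique_hits > n_collapsed:
        warnings.warn("more unique hits than collapsed reads: possible accounting bug")
    return round(n_unique_hits / n_collapsed, 5)


def deficit(observed_fraction: float, genomic_fraction: float) -> float:
    """Percentage-point deficit of an observed base fraction vs genomic.

    Positive when the observed fraction falls below the genomic one;
    reported to 6 decimals (e.g. observed 0.134 vs genomic 0.246 -> 11.2).
    """
    for v in (observed_fraction, genomic_fraction):
        if not (0.0 <= v <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
    return round(100.0 * (genomic_fraction - observed_fraction), 6)
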