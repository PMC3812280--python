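"""Library preparation chemistry: end repair, ligation, PCR, sequencing.

Two chemistries are modelled.  Blunt-end (BE) preparation end-repairs every
fragment and ligates adapters unconditionally.  AT-overhang preparation
end-repairs, 3'-A-tails, and ligates 5'-T-overhang adapters — a junction
whose efficiency depends on the insert's 5' terminal bases.  Because
deaminated overhang cytosines present as 5' uracil (a thymine analogue) to
the ligase, the AT chemistry selects against exactly the damaged termini
that carry the C->T signal used to authenticate degraded DNA.

End repair fills recessed 3' termini by copying the 5'-overhang template
(a template U is copied as A, so the overhang U later reads as T and the
filled complement carries A).  An alternative "chew" repair mode that
trims overhangs instead of filling them is available for exploring
repair-enzymology assumptions; filling is the default because it is what
T4-polymerase-based end repair does and what couples overhang deamination
to ligation rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import revcomp
from .simgenome import DamagedFragment

__all__ = [
    "LigationBias",
    "PrepConfig",
    "LibraryMolecule",
    "ReadRecord",
    "QualityProfile",
    "prepare_blunt_end",
    "prepare_at_overhang",
    "prepare_library",
    "amplify",
    "size_select",
    "sequence_paired_end",
    "write_fastq",
    "LIGATION_PRESETS",
    "ADAPTER_INPE",
    "ADAPTER_BE_P5",
    "ADAPTER_BE_P7",
    "ADAPTER_BE_SHORT",
    "PRIMER_INPE1",
    "PRIMER_INPE2",
]

# Illumina inPE adapter (ligated strand) and BE multiplex adapter strands;
# read-through appends the adapter as written.
ADAPTER_INPE = "GATCGGAAGAGCACACGTCT"
ADAPTER_BE_P5 = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"
ADAPTER_BE_P7 = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
ADAPTER_BE_SHORT = "AGATCGGAAGAGC"
PRIMER_INPE1 = "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT"
PRIMER_INPE2 = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"


@dataclass(frozen=True)
class LigationBias:
    """Relative ligation-success weight keyed by a strand's 5' terminal base.

    Uracil is the molecular analogue of thymine at the ligation junction,
    so its weight always equals the thymine weight.  The all-ones map is
    unbiased.
    """

    weight_A: float = 1.0
    weight_C: float = 1.0
    weight_G: float = 1.0
    weight_T: float = 1.0

    def __post_init__(self) -> None:
        for w in (self.weight_A, self.weight_C, self.weight_G, self.weight_T):
            if not (0.0 < w <= 1.0):
                raise ValueError("ligation weights must lie in (0, 1]")

    def weight(self, base: str) -> float:
        return {
            "A": self.weight_A,
            "C": self.weight_C,
            "G": self.weight_G,
            "T": self.weight_T,
            "U": self.weight_T,  # U behaves as T at the junction
        }[base]


#: Adapter-concentration presets for the AT chemistry.  Lower adapter
#: concentration magnifies the bias against 5'-T termini; the weights are
#: illustrative (calibration to real chemistry is out of scope) and chosen
#: so the simulated position-1 T fractions bracket the magnitudes seen at
#: standard (0.6 uM) vs low (0.012 uM) adapter concentrations.
LIGATION_PRESETS: dict[str, LigationBias] = {
    "unbiased": LigationBias(),
    "standard": LigationBias(weight_T=0.55),
    "low": LigationBias(weight_T=0.35),
}


@dataclass(frozen=True)
class QualityProfile:
    """Per-base substitution error rate and Phred quality of simulated reads."""

    error_rate: float = 0.0
    base_quality: int = 37

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class PrepConfig:
    """Configuration of one library build + amplification + sequencing run."""

    chemistry: str = "BE"  # {"BE", "AT"}
    ligation_bias: LigationBias = field(default_factory=LigationBias)
    adapter_p5: str = ADAPTER_INPE
    adapter_p7: str = ADAPTER_INPE
    pcr_cycles: int = 0
    uracil_bypass: bool = True
    amplification_efficiency: float = 1.0
    read_length: int = 100
    size_select: tuple[int, int] | None = None
    at_repair: str = "fill"  # {"fill", "chew"}
    retain_u: bool = False  # keep template U unresolved through repair
    quality: QualityProfile = field(default_factory=QualityProfile)

    def __post_init__(self) -> None:
        if self.chemistry not in ("BE", "AT"):
            raise ValueError("chemistry must be 'BE' or 'AT'")
        if self.pcr_cycles < 0:
            raise ValueError("pcr_cycles must be >= 0")
        if not (0.0 < self.amplification_efficiency <= 1.0):
            raise ValueError("amplification_efficiency must be in (0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.at_repair not in ("fill", "chew"):
            raise ValueError("at_repair must be 'fill' or 'chew'")
        for ad in (self.adapter_p5, self.adapter_p7):
            if not ad or set(ad) - set("ACGT"):
                raise ValueError("adapters must be non-empty ACGT strings")


@dataclass
class LibraryMolecule:
    """An adapter-flanked double-stranded insert after one prep chemistry.

    ``insert_top``/``insert_bottom`` are exact reverse complements after
    repair (U resolved unless ``retain_u``).  ``lineage_id`` is shared by
    all PCR duplicates of the molecule.
    """

    insert_top: str
    insert_bottom: str
    source: DamagedFragment
    lineage_id: int = -1
    accepted: bool = True
    reason: str = ""
    has_uracil: bool = False

    @property
    def insert_len(self) -> int:
        return len(self.insert_top)


@dataclass(frozen=True)
class ReadRecord:
    name: str
    seq: str
    qual: str


def _fill_in_repair(frag: DamagedFragment, retain_u: bool) -> tuple[str, str, bool]:
    """End-repair by filling recessed 3' termini from the overhang template.

    Returns (insert_top, insert_bottom, had_uracil).  With ``retain_u``
    False, every remaining template U resolves to T on its own strand and
    A on the complement (what PCR over uracil produces); strands come out
    exact reverse complements.
    """
    L = frag.footprint_len
    o5, o3 = frag.overhang5_len, frag.overhang3_len
    top = frag.top_seq + revcomp(frag.bottom_seq[:o3])  # fill across bottom 5'-overhang
    bottom = frag.bottom_seq + revcomp(frag.top_seq[:o5])  # fill across top 5'-overhang
    assert len(top) == len(bottom) == L
    had_u = "U" in top or "U" in bottom
    if had_u and not retain_u:
        top_l = list(top)
        bot_l = list(bottom)
        for m, b in enumerate(top_l):
            if b == "U":
                top_l[m] = "T"
                bot_l[L - 1 - m] = "A"
        for k, b in enumerate(bot_l):
            if b == "U":
                bot_l[k] = "T"
                top_l[L - 1 - k] = "A"
        top = "".join(top_l)
        bottom = "".join(bot_l)
    return top, bottom, had_u


def _chew_repair(frag: DamagedFragment, retain_u: bool) -> tuple[str, str, bool]:
    """End-repair by exonucleolytic removal of 5'-overhangs (blunting inward)."""
    o5, o3 = frag.overhang5_len, frag.overhang3_len
    top = frag.top_seq[o5:]  # drop the top 5'-overhang
    bottom = frag.bottom_seq[o3:]  # drop the bottom 5'-overhang
    had_u = "U" in top or "U" in bottom
    if had_u and not retain_u:
        L = len(top)
        top_l = list(top)
        bot_l = list(bottom)
        for m, b in enumerate(top_l):
            if b == "U":
                top_l[m] = "T"
                bot_l[L - 1 - m] = "A"
        for k, b in enumerate(bot_l):
            if b == "U":
                bot_l[k] = "T"
                top_l[L - 1 - k] = "A"
        top = "".join(top_l)
        bottom = "".join(bot_l)
    return top, bottom, had_u


def prepare_blunt_end(frag: DamagedFragment, retain_u: bool = False) -> LibraryMolecule:
    """Blunt-end chemistry: fill-in repair, unconditional adapter ligation."""
    if frag.footprint_len < 2:
        return LibraryMolecule("", "", frag, accepted=False, reason="degenerate")
    top, bottom, had_u = _fill_in_repair(frag, retain_u)
    return LibraryMolecule(top, bottom, frag, has_uracil=had_u and retain_u)


def prepare_at_overhang(
    frag: DamagedFragment,
    bias: LigationBias,
    seed: int = 0,
    repair: str = "fill",
    retain_u: bool = False,
    _rng: np.random.Generator | None = None,
) -> LibraryMolecule:
    """AT-overhang chemistry: repair, 3'-A-tail, biased 5'-T adapter ligation.

    The molecule is accepted with probability
    ``weight(5' base of top strand) * weight(5' base of bottom strand)``;
    a rejected molecule carries ``accepted=False`` with reason "ligation".
    A deaminated 5' terminus (U, read as T) is weighted as T, which is the
    mechanism depleting damage at read position 1.
    """
    if frag.footprint_len < 2:
        return LibraryMolecule("", "", frag, accepted=False, reason="degenerate")
    repair_fn = _fill_in_repair if repair == "fill" else _chew_repair
    top, bottom, had_u = repair_fn(frag, retain_u)
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    p = bias.weight(top[0]) * bias.weight(bottom[0])
    mol = LibraryMolecule(top, bottom, frag, has_uracil=had_u and retain_u)
    if rng.random() >= p:
        mol.accepted = False
        mol.reason = "ligation"
    return mol


def prepare_library(
    frags: Sequence[DamagedFragment],
    cfg: PrepConfig,
    seed: int = 0,
) -> list[LibraryMolecule]:
    """Run one chemistry over a batch of fragments, assigning lineage ids.

    Returns every molecule (accepted or not); downstream stages consume
    only the accepted ones.
    """
    rng = np.random.default_rng(seed)
    out: list[LibraryMolecule] = []
    for i, frag in enumerate(frags):
        if cfg.chemistry == "BE":
            mol = prepare_blunt_end(frag, retain_u=cfg.retain_u)
        else:
            mol = prepare_at_overhang(
                frag, cfg.ligation_bias, repair=cfg.at_repair, retain_u=cfg.retain_u, _rng=rng
            )
        mol.lineage_id = i
        out.append(mol)
    return out


def size_select(molecules: Iterable[LibraryMolecule], bounds: tuple[int, int]) -> list[LibraryMolecule]:
    """Keep exactly the inserts whose length lies within bounds (inclusive)."""
    lo, hi = bounds
    return [m for m in molecules if lo <= m.insert_len <= hi]


def amplify(
    molecules: Sequence[LibraryMolecule],
    cfg: PrepConfig,
    seed: int = 0,
) -> list[LibraryMolecule]:
    """PCR as a Galton-Watson branching process.

    Each molecule's copy count doubles per cycle with per-copy success
    probability ``amplification_efficiency``.  If ``uracil_bypass`` is
    false, a molecule whose repaired strands still encode template uracil
    yields no sequenceable copies (uracil-blocking polymerases stall);
    with default repair U is resolved before amplification, so this
    matters only when ``retain_u`` is configured.  Duplicates share their
    parent's ``lineage_id``.
    """
    if cfg.pcr_cycles < 0:
        raise ValueError("pcr_cycles must be >= 0")
    rng = np.random.default_rng(seed)
    mols = [m for m in molecules if m.accepted]
    if not mols:
        return []
    copies = np.ones(len(mols), dtype=np.int64)
    for _ in range(cfg.pcr_cycles):
        copies += rng.binomial(copies, cfg.amplification_efficiency)
    out: list[LibraryMolecule] = []
    for mol, k in zip(mols, copies):
        if mol.has_uracil and not cfg.uracil_bypass:
            continue  # blocked template: no sequenceable product
        out.extend([mol] * int(k))
    return out


_MUT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _read_through(template: str, read_length: int, adapter: str, rng: np.random.Generator) -> str:
    """First ``read_length`` bases seen by the sequencer from one strand:
    insert, then the opposite adapter, then random bases."""
    if len(template) >= read_length:
        return template[:read_length]
    s = template + adapter
    if len(s) >= read_length:
        return s[:read_length]
    tail = "".join("ACGT"[i] for i in rng.integers(0, 4, size=read_length - len(s)))
    return s + tail


def sequence_paired_end(
    molecules: Sequence[LibraryMolecule],
    cfg: PrepConfig,
    quality_profile: QualityProfile | None = None,
    seed: int = 0,
) -> list[tuple[ReadRecord, ReadRecord]]:
    """Sequence accepted molecules as 2 x ``read_length`` paired-end reads.

    Read 1 is the first bases of the top strand 5'->3', read 2 the first
    bases of the bottom strand 5'->3'; short inserts read through into the
    opposite adapter.  Record names encode lineage id and true coordinates
    (``lineage|contig|start|end|strand|copy``) for truth-mode evaluation.
    """
    qp = quality_profile or cfg.quality
    rng = np.random.default_rng(seed)
    qual_char = chr(qp.base_quality + 33)
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    copy_counter: dict[int, int] = {}
    for mol in molecules:
        if not mol.accepted:
            continue
        copy = copy_counter.get(mol.lineage_id, 0)
        copy_counter[mol.lineage_id] = copy + 1
        r1 = _read_through(mol.insert_top, cfg.read_length, cfg.adapter_p7, rng)
        r2 = _read_through(mol.insert_bottom, cfg.read_length, cfg.adapter_p5, rng)
        if qp.error_rate > 0.0:
            r1 = _add_errors(r1, qp.error_rate, rng)
            r2 = _add_errors(r2, qp.error_rate, rng)
        f = mol.source
        name = f"{mol.lineage_id}|{f.contig}|{f.start}|{f.end}|{f.strand}|{copy}"
        q1 = qual_char * len(r1)
        pairs.append((ReadRecord(name + "/1", r1, q1), ReadRecord(name + "/2", r2, q1)))
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits.tolist():
        chars[i] = _MUT[chars[i]][rng.integers(0, 3)]
    return "".join(chars)


def write_fastq(
    reads: Iterable[ReadRecord] | Iterable[tuple[ReadRecord, ReadRecord]],
    path1: str | Path,
    path2: str | Path | None = None,
) -> None:
    """Write reads (or read pairs, when ``path2`` is given) as Phred+33 FASTQ."""
    reads = list(reads)
    if path2 is None:
        with open(path1, "w") as fh:
            for r in reads:
                fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")
    else:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for r1, r2 in reads:
                f1.write(f"@{r1.name}\n{r1.seq}\n+\n{r1.qual}\n")
                f2.write(f"@{r2.name}\n{r2.seq}\n+\n{r2.qual}\n")
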