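"""End-to-end scenario runs and comparative signature reports.

A scenario couples a synthetic genome, a fragmentation regime (uniform,
mechanical shearing, or depurination-driven "ancient" breakage), a damage
preset (fresh / museum / pleistocene), and one library chemistry, then
runs the full pipeline — fragmentation, damage, library build, PCR,
paired-end sequencing, trimming/collapsing, mapping, duplicate removal,
profiling — and evaluates the qualitative signatures that distinguish the
chemistries:

* start-T / end-A composition deficits (AT-overhang ligation bias),
* purine excess at genomic position -1 (depurination),
* the position of the C->T misincorporation peak (1 for blunt-end
  libraries, 2 when the AT chemistry selects against 5'-deaminated
  termini) and the monotone decay of C->T away from the 5' terminus.

Flags are computed from stated thresholds (5 binomial SDs under the
null), never hand-set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import libprep, mapper, profiler, readproc, simgenome
from .libprep import PrepConfig
from .mapper import AlignedRead
from .profiler import MisincorporationProfile, PositionalProfile
from .readproc import ProcessedRead, ProcessingConfig
from .simgenome import CLEAVAGE_PRESETS, DAMAGE_PRESETS, CleavageBias, DamageModelParams, ReferenceGenome

__all__ = [
    "ScenarioConfig",
    "SignatureReport",
    "run_scenario",
    "compare_scenarios",
    "truth_alignments",
    "insert_alignments",
    "stage_seeds",
    "STANDARD_SCENARIOS",
]


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from one run seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass
class ScenarioConfig:
    name: str = "scenario"
    genome_length: int = 200_000
    gc: float = 0.508  # gives the ~24.6% genomic T of a GC~0.5 bacterial genome
    cleavage: str | CleavageBias = "uniform"
    damage: str | DamageModelParams = "fresh"
    prep: PrepConfig = field(default_factory=PrepConfig)
    n_fragments: int = 100_000
    size_range: tuple[int, int] = (125, 175)
    seed: int = 0
    mapping: str = "kmer"  # {"kmer", "truth"}

    def resolved_cleavage(self) -> CleavageBias:
        return CLEAVAGE_PRESETS[self.cleavage] if isinstance(self.cleavage, str) else self.cleavage

    def resolved_damage(self) -> DamageModelParams:
        return DAMAGE_PRESETS[self.damage] if isinstance(self.damage, str) else self.damage


@dataclass
class SignatureReport:
    name: str
    config: ScenarioConfig
    genomic_freqs: np.ndarray
    composition: PositionalProfile
    misincorporation: MisincorporationProfile
    counts: dict[str, float]
    start_T_deficit: bool
    end_A_deficit: bool
    purine_excess_at_minus1: bool
    ct_peak_position: int | None
    monotone_ct_decay: bool

    @property
    def t1_fraction(self) -> float:
        return float(self.composition.read_start[0, 3])

    @property
    def t1_deficit_pp(self) -> float:
        return profiler.deficit(self.t1_fraction, float(self.genomic_freqs[3]))

    def summary_row(self) -> dict:
        ct = self.misincorporation.ct5
        return {
            "scenario": self.name,
            "chemistry": self.config.prep.chemistry,
            "n_raw_pairs": self.counts["n_raw_pairs"],
            "n_collapsed": self.counts["n_collapsed"],
            "n_unique_hits": self.counts["n_unique_hits"],
            "clonality": self.counts["clonality"],
            "endogenous": self.counts["endogenous"],
            "T1_fraction": self.t1_fraction,
            "T1_deficit_pp": self.t1_deficit_pp,
            "purine_minus1": float(self.composition.flank_start[-1, 0] + self.composition.flank_start[-1, 2]),
            "ct_pos1": float(ct[0]),
            "ct_pos2": float(ct[1]),
            "start_T_deficit": self.start_T_deficit,
            "end_A_deficit": self.end_A_deficit,
            "purine_excess_at_minus1": self.purine_excess_at_minus1,
            "ct_peak_position": self.ct_peak_position,
            "monotone_ct_decay": self.monotone_ct_decay,
        }


def truth_alignments(reads: Sequence[ProcessedRead], ref: ReferenceGenome) -> list[AlignedRead]:
    """Build alignments from the true coordinates encoded in read names.

    Usable only on synthetic reads (names ``lineage|contig|start|end|
    strand|copy``); reads whose processed length no longer matches the
    true footprint (incomplete collapse) are dropped.  This bypasses the
    k-mer mapper for large-scale property checks where mapping itself is
    not under study.
    """
    out: list[AlignedRead] = []
    for r in reads:
        try:
            lineage, contig, start, end, strand, copy = r.name.split("|")
            start_i, end_i = int(start), int(end)
        except ValueError:
            continue
        if end_i - start_i + 1 != len(r.seq):
            continue
        out.append(
            AlignedRead(
                name=r.name,
                contig=contig,
                start=start_i,
                end=end_i,
                strand=strand,
                read_seq=r.seq,
                quals=r.quals,
                sum_qual=sum(r.quals.encode("ascii")) - 33 * len(r.quals),
            )
        )
    return out


def insert_alignments(molecules, base_quality: int = 37) -> list[AlignedRead]:
    """Alignments of accepted library inserts at their true coordinates.

    Skips the sequencing + trimming + collapsing round trip, which for
    error-free 2x100 reads of size-selected inserts reconstructs the
    insert exactly (a property the read-processing tests verify), so
    large-scale signature checks can profile the library pool directly.
    """
    q = chr(base_quality + 33)
    out: list[AlignedRead] = []
    for m in molecules:
        if not m.accepted or m.insert_len < 1:
            continue
        f = m.source
        if m.insert_len != f.footprint_len:
            continue  # chew-mode repair shifts coordinates; skip
        out.append(
            AlignedRead(
                name=str(m.lineage_id),
                contig=f.contig,
                start=f.start,
                end=f.end,
                strand=f.strand,
                read_seq=m.insert_top,
                quals=q * m.insert_len,
                sum_qual=base_quality * m.insert_len,
            )
        )
    return out


def _five_sd_excess(obs: float, null: float, n: int) -> bool:
    if n == 0 or math.isnan(obs):
        return False
    sd = math.sqrt(max(null * (1.0 - null), 1e-12) / n)
    return (obs - null) > 5.0 * sd


def run_scenario(cfg: ScenarioConfig, outdir: str | Path | None = None) -> SignatureReport:
    """Run one full scenario; deterministic for a fixed config seed.

    When ``outdir`` is given, intermediate artifacts (reference FASTA,
    paired FASTQ, SAM, profile TSVs, counts) are written there.
    """
    s = stage_seeds(cfg.seed)
    ref = simgenome.generate_reference(cfg.genome_length, cfg.gc, s[0], name="ref")
    frags = simgenome.fragment_genome(
        ref, cfg.n_fragments, cfg.size_range, cfg.resolved_cleavage(), seed=s[1]
    )
    dmg = cfg.resolved_damage()
    if dmg.overhang_geom_p < 1.0 or dmg.delta_ss > 0.0 or dmg.delta_ds > 0.0:
        frags = simgenome.damage_fragments(frags, dmg, seed=s[2])
    mols = libprep.prepare_library(frags, cfg.prep, seed=s[3])
    accepted = [m for m in mols if m.accepted]
    if cfg.prep.size_select is not None:
        accepted = libprep.size_select(accepted, cfg.prep.size_select)
    pool = libprep.amplify(accepted, cfg.prep, seed=s[4])
    pairs = libprep.sequence_paired_end(pool, cfg.prep, seed=s[5])

    pcfg = ProcessingConfig(adapter1=cfg.prep.adapter_p7, adapter2=cfg.prep.adapter_p5)
    processed, pcounts = readproc.process_pairs(pairs, pcfg)

    if cfg.mapping == "truth":
        alns = truth_alignments(processed, ref)
    else:
        alns = mapper.align(processed, ref)
    unique, clonality = mapper.remove_duplicates(alns)

    n_collapsed = pcounts["passed"]
    counts = {
        "n_fragments": cfg.n_fragments,
        "n_accepted_molecules": len(accepted),
        "n_raw_pairs": pcounts["raw_pairs"],
        "n_collapsed": n_collapsed,
        "n_quality_hits": len(alns),
        "n_unique_hits": len(unique),
        "clonality": round(clonality, 5),
        "endogenous": profiler.endogenous_content(len(unique), n_collapsed) if n_collapsed else float("nan"),
    }

    comp = profiler.composition_profile(unique, ref)
    mis = profiler.misincorporation_profile(unique, ref)
    gf = ref.base_freqs

    t1 = comp.read_start[0]
    aN = comp.read_end[-1]
    m1 = comp.flank_start[-1]  # genomic position -1
    # a deficit is an excess of (genomic - observed) over 0, tested at 5 SDs
    start_T = _five_sd_excess(2 * float(gf[3]) - float(t1[3]), float(gf[3]), int(comp.read_start_n[0]))
    end_A = _five_sd_excess(2 * float(gf[0]) - float(aN[0]), float(gf[0]), int(comp.read_end_n[-1]))
    pur = _five_sd_excess(float(m1[0] + m1[2]), float(gf[0] + gf[2]), int(comp.flank_start_n[-1]))

    ct = mis.ct5
    head = ct[:3]
    if np.all(np.isnan(head)) or np.nanmax(head) <= 0.0:
        peak = None
    else:
        peak = int(np.nanargmax(head)) + 1
    first5 = ct[:5]
    monotone = bool(
        not np.any(np.isnan(first5))
        and np.all(np.diff(first5) <= 1e-12)
        and first5[0] > 0.0
    )

    report = SignatureReport(
        name=cfg.name,
        config=cfg,
        genomic_freqs=gf,
        composition=comp,
        misincorporation=mis,
        counts=counts,
        start_T_deficit=start_T,
        end_A_deficit=end_A,
        purine_excess_at_minus1=pur,
        ct_peak_position=peak,
        monotone_ct_decay=monotone,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        simgenome.write_fasta(ref, outdir / "reference.fasta")
        libprep.write_fastq(pairs, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
        mapper.write_sam(unique, ref, outdir / "unique.sam")
        comp.to_tsv(outdir / "dnacomp.tsv")
        mis.to_tsv(outdir / "misincorporation.tsv")
        readproc.stage_counts_tsv({k: int(v) if v == int(v) else v for k, v in counts.items()}, outdir / "counts.tsv")
        (outdir / "report.md").write_text(_report_markdown([report]))
    return report


def _report_markdown(reports: Sequence[SignatureReport]) -> str:
    df = pd.DataFrame([r.summary_row() for r in reports])
    lines = ["# Scenario signature report", ""]
    lines.append(df.to_string(index=False))
    lines.append("")
    return "\n".join(lines)


def compare_scenarios(reports: Sequence[SignatureReport]) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Comparison table and verdicts over scenarios sharing one genome.

    Verdicts: for adapter-concentration pairs (same chemistry AT,
    different weight_T) the lower-weight run must show the larger
    position-1 T deficit; for BE vs AT pairs at equal damage the BE run
    must show the higher C->T rate at read position 1.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    g0 = reports[0].config
    for r in reports[1:]:
        if (r.config.genome_length, r.config.gc) != (g0.genome_length, g0.gc):
            raise ValueError("invalid comparison: scenarios use different genomes")
    df = pd.DataFrame([r.summary_row() for r in reports])

    verdicts: dict[str, bool] = {}
    at = [r for r in reports if r.config.prep.chemistry == "AT"]
    for i, a in enumerate(at):
        for b in at[i + 1 :]:
            wa, wb = a.config.prep.ligation_bias.weight_T, b.config.prep.ligation_bias.weight_T
            if wa == wb:
                continue
            low, std = (a, b) if wa < wb else (b, a)
            verdicts[f"lower_weight_T_increases_T1_deficit[{low.name} vs {std.name}]"] = (
                low.t1_deficit_pp > std.t1_deficit_pp
            )
    be = [r for r in reports if r.config.prep.chemistry == "BE"]
    for b in be:
        for a in at:
            if b.config.damage == a.config.damage and b.config.damage != "fresh":
                verdicts[f"be_ct1_exceeds_at_ct1[{b.name} vs {a.name}]"] = (
                    float(b.misincorporation.ct5[0]) > float(a.misincorporation.ct5[0])
                )
    return df, verdicts


def _std_prep(chem: str, weight_T: float | None = None) -> PrepConfig:
    bias = libprep.LigationBias() if weight_T is None else libprep.LigationBias(weight_T=weight_T)
    return PrepConfig(chemistry=chem, ligation_bias=bias, pcr_cycles=2, amplification_efficiency=0.5)


#: The five standard study conditions: fresh extracts under both
#: chemistries (AT at standard and low adapter concentration) and
#: degraded extracts under both chemistries.
STANDARD_SCENARIOS: dict[str, ScenarioConfig] = {
    "fresh-BE": ScenarioConfig(
        name="fresh-BE", cleavage="shearing", damage="fresh", prep=_std_prep("BE")
    ),
    "fresh-AT-standard": ScenarioConfig(
        name="fresh-AT-standard", cleavage="shearing", damage="fresh", prep=_std_prep("AT", 0.55)
    ),
    "fresh-AT-low": ScenarioConfig(
        name="fresh-AT-low", cleavage="shearing", damage="fresh", prep=_std_prep("AT", 0.35)
    ),
    "ancient-BE": ScenarioConfig(
        name="ancient-BE", cleavage="ancient", damage="pleistocene", prep=_std_prep("BE")
    ),
    "ancient-AT": ScenarioConfig(
        name="ancient-AT", cleavage="ancient", damage="pleistocene", prep=_std_prep("AT", 0.4)
    ),
}
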