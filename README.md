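# ligbias

Simulation and profiling of **adapter-ligation bias** in Illumina sequencing
libraries, and of how that bias reshapes the **post-mortem damage signatures**
used to authenticate degraded (ancient, museum, forensic) DNA.

## The problem

Degraded DNA carries two chemical hallmarks that double as authentication
criteria:

* **Depurination-driven fragmentation** — strand breaks occur preferentially
  3′ of purines, so the genomic base just upstream of a read start
  ("position −1") is enriched in A/G.
* **Cytosine deamination** — C→U conversion, strongly elevated in the
  single-stranded 5′-overhangs of degraded fragments. A uracil templates as
  thymine, so reads show C→T mismatches that are maximal at the 5′ terminus
  and decay inward (with the complementary G→A rise at 3′ ends).

Library chemistry interferes with these signals. **Blunt-end (BE)** ligation
accepts every end-repaired insert. **AT-overhang (AT)** ligation 3′-A-tails
inserts and ligates adapters bearing 5′-T overhangs; that junction is
inefficient for inserts whose 5′ terminal base is T — and a deaminated
terminal cytosine presents to the ligase as a 5′ U, a thymine analogue.
The consequences:

* a deficit of T at read position 1 and of A at the last position
  (magnified at low adapter concentration),
* depletion of 5′-deaminated templates, moving the C→T misincorporation
  peak from read position 1 to position **2**, and
* a systematic under-estimate of deamination levels from AT libraries.

`ligbias` builds every stage of this story as testable code: a mechanistic
read simulator (biased fragmentation, geometric overhangs, two-rate
deamination, both chemistries, Galton–Watson PCR, 2×100 paired-end reads
with adapter read-through), the standard read processing (adapter trimming
at mismatch rate ≤ 1/3, ≥11 bp pair collapsing, ≥25 bp length filter), a
desk-scale unique-hit mapper with PCR-duplicate removal, and positional
composition / misincorporation profilers.

## The model in brief

Fragment 5′ cut sites are drawn with probability ∝ *w*(base at −1); a
uniform *w* is unbiased shearing, purine-weighted *w* is depurination.
Overhang lengths are geometric(*p*) − 1 per end; each overhang cytosine
deaminates with probability δ_ss, interior cytosines with δ_ds ≤ δ_ss.
End repair fills recessed 3′ termini (template U copies as A). AT ligation
accepts a molecule with probability *w*(5′ base of top strand) ×
*w*(5′ base of bottom strand), with *w*(U) = *w*(T). For an equal-composition
genome and weight *w* on T this gives the closed forms

    acceptance rate      = ((3 + w)/4)²
    accepted 5′-T share  = w/4 / (w/4 + 3/4)      (w = 0.5 → 1/7 ≈ 0.1429)

which the pipeline reproduces end to end.

## Worked example

```python
import dataclasses
import numpy as np
from ligbias.experiment import STANDARD_SCENARIOS, compare_scenarios, run_scenario

reports = []
for preset in ("ancient-BE", "ancient-AT"):
    cfg = dataclasses.replace(STANDARD_SCENARIOS[preset], n_fragments=20_000, seed=7, mapping="truth")
    reports.append(run_scenario(cfg))

for r in reports:
    ct = np.round(r.misincorporation.ct5[:5], 3)
    print(f"{r.name:10s}  C->T by position 1-5: {ct}  peak at {r.ct_peak_position}")
    print(f"{'':10s}  start-T deficit: {r.t1_deficit_pp:.1f} pp   purine at -1: "
          f"{r.composition.flank_start[-1,0] + r.composition.flank_start[-1,2]:.3f}")

_, verdicts = compare_scenarios(reports)
for k, v in verdicts.items():
    print(k, "->", "PASS" if v else "FAIL")
```

prints

```
ancient-BE  C->T by position 1-5: [0.219 0.181 0.133 0.099 0.071]  peak at 1
            start-T deficit: -5.5 pp   purine at -1: 0.796
ancient-AT  C->T by position 1-5: [0.101 0.179 0.133 0.095 0.069]  peak at 2
            start-T deficit: 9.9 pp   purine at -1: 0.796
be_ct1_exceeds_at_ct1[ancient-BE vs ancient-AT] -> PASS
```

Both chemistries see the same damaged fragment pool (purine fraction ≈ 0.8
at −1, from the depurination preset). The BE library shows the canonical
C→T decay from position 1; the AT library suppresses position 1 (0.101 vs
0.219) and peaks at position 2, while also showing a ~10 percentage-point
start-T deficit that the BE library lacks.

## Command line

```
ligbias simulate --length 200000 --gc 0.508 --seed 1 --out ref.fasta
ligbias prep --reference ref.fasta --chemistry AT --ligation low --damage museum --outdir prep/
ligbias process --fastq1 prep/reads_R1.fastq --fastq2 prep/reads_R2.fastq --out collapsed.fastq
ligbias map --reads collapsed.fastq --reference ref.fasta --out unique.sam
ligbias profile --sam unique.sam --reference ref.fasta --outdir profiles/
ligbias run-all --preset ancient-AT --seed 1 --outdir run/
ligbias report --preset ancient-BE --preset ancient-AT --outdir cmp/
```

The five standard presets are `fresh-BE`, `fresh-AT-standard`,
`fresh-AT-low`, `ancient-BE`, `ancient-AT`.

### Output schemas

`dnacomp.tsv`: `terminus position A C G T n` — base fractions at read
positions 1..10 / N−9..N and genomic flanks −10..−1 / N+1..N+10, all in
molecule orientation. `misincorporation.tsv`: `end position ref read n_ref
rate` — per-position C→T and G→A rates from each terminus; positions with
zero denominator are `NA`, never 0.

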