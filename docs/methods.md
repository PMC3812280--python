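# Methods

This note documents the models implemented in `ligbias`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical/design decisions that were genuinely open.

## Fragmentation model

A reference genome is generated with i.i.d. bases at a configurable GC
content (G/C and A/T equiprobable within each class). The default scenario
genome is 200 kb at GC = 0.508, which puts the genomic T fraction at
~24.6% — the value typical of a GC-balanced bacterial genome and the
baseline against which start-T deficits are measured.

Fragments are sampled by drawing a strand (equiprobable), a length
(uniform on `size_range`, default 125–175 bp, matching gel size selection
of short-insert libraries), and a 5′ cut site with probability
proportional to `CleavageBias.weights[b]`, where *b* is the base
immediately 5′ of the cut **in molecule orientation** (for a − strand
molecule this is the complement of the reference base just 3′ of the
footprint). Over many fragments the composition at genomic −1 converges to
the closed-form reweighting

    f'_b = w_b f_b / Σ_c w_c f_c ,

which the tests verify at n = 50,000 within 3 binomial SDs.

Presets:

* `uniform` — (1, 1, 1, 1): unbiased fragmentation.
* `shearing` — weight 1.55 on C: mechanical shearing's mild preference for
  cutting 3′ of cytosine. The value was derived once from the closed form
  so that the expected C enrichment at −1 on a GC≈0.5 genome is ~9
  percentage points, the magnitude seen in fresh sonicated extracts.
* `ancient` — weight 4 on A and G: depurination-driven breakage. On an
  equal-composition genome the purine fraction at −1 is exactly
  (4·0.5)/(4·0.5 + 0.5) = 0.8.

Circular genomes are not modelled; fragments never wrap. Abasic-site
chemistry is not modelled — depurination enters only through the cut-site
weights. The physics of sonication/nebulization is out of scope; only its
terminal-base statistics are reproduced.

## Damage model

Both fragment ends carry **5′-overhangs** whose lengths are drawn i.i.d.
as geometric(p) − 1 (support includes 0; mean (1−p)/p). `p = 1` forces
blunt ends. The geometric-minus-one choice is the standard minimal
single-parameter model for overhang lengths. 3′-overhangs are not
modelled: two 5′-overhangs are sufficient to produce the complementary
C→T (5′) / G→A (3′) pattern of double-stranded library preparations.
Overhangs are truncated so the double-stranded interior stays non-empty.

Each cytosine deaminates to uracil with probability `delta_ss` inside
single-stranded overhangs and `delta_ds` in the interior
(0 ≤ delta_ds ≤ delta_ss ≤ 1, reflecting the orders-of-magnitude faster
single-stranded kinetics). Lesions are recorded per strand and offset;
A/G/T bases are never altered.

Damage presets (illustrative, deliberately not calibrated to any specific
specimen): `fresh` (no damage), `museum` (mean overhang 2, δ_ss = 0.10,
δ_ds = 0.01), `pleistocene` (mean overhang 3, δ_ss = 0.30, δ_ds = 0.01).
The δ_ss values are chosen to make terminal C→T rates land in the
0.1–0.3 range typical of degraded specimens so that signature shapes are
measurable with ~10⁵ fragments.

### Fragment bookkeeping

`start`/`end` are the 1-based duplex footprint. The physical strands are
stored 5′→3′; after overhang creation the recessed 3′ termini are
shortened, so `end − start + 1 == len(top_seq) + overhang3_len` (for blunt
fragments this is the usual `end − start + 1 == len(top_seq)`). This
resolves an otherwise contradictory pair of requirements (full-footprint
strings vs physically shortened recessed strands) in favour of storing
exactly the bases that exist.

## Library chemistry

**End repair** fills recessed 3′ termini by copying the 5′-overhang
template; a template U is copied as A, so after repair the overhang U
reads as T and its filled complement carries A. The repaired insert spans
the full footprint, and the two insert strands are exact reverse
complements.

An alternative `chew` repair mode (exonucleolytic blunting that removes
the overhangs) is exposed as a configuration flag because real-world
repair enzymology varies; **fill is the default** because T4-polymerase
based end repair fills 5′-overhangs, and because filling is what places
deaminated overhang cytosines at the 5′ terminus where the AT ligase sees
them — the mechanism that couples deamination to ligation rejection and
moves the C→T peak to position 2. Under `chew` that coupling disappears
(the overhang bases are discarded), so `chew` is an exploratory mode, not
a default.

Interior (double-stranded) deamination leaves a G:U mispair. Because a
`LibraryMolecule` commits to one sequence per strand, each U site is
resolved deterministically (U→T on its strand, A on the complement). This
counts both strands of an interior lesion toward the mismatch signal,
roughly doubling the effective interior rate relative to strand-split
sequencing of a mispaired duplex; δ_ds is an illustrative free parameter,
so this simplification is documented rather than corrected for.
Setting `retain_u` keeps uracils through repair, in which case
`amplify(..., uracil_bypass=False)` models uracil-blocking polymerases by
yielding no sequenceable copies from such templates.

**Blunt-end ligation** accepts every repaired molecule (fragments shorter
than 2 bp are rejected as degenerate). **AT-overhang ligation** accepts a
molecule with probability w(top 5′ base) × w(bottom 5′ base) — the bias
acts only through the two terminal bases, multiplicatively across the two
junctions. This single-parameter form simultaneously produces the start-T
and end-A deficits (the bottom strand's 5′ base is the complement of the
insert's 3′ base). w(U) = w(T) always, since uracil is a thymine analogue
at the junction.

Adapter concentration is not modelled chemically. The presets map
standard (0.6 µM) → w_T = 0.55 and low (0.012 µM) → w_T = 0.35, chosen
once so that simulated position-1 T fractions on a 24.6%-T genome
(≈ 15.2% and ≈ 10.2% by the closed form) bracket the observed magnitudes
for the two concentrations; the weights are fully user-configurable since
calibration to real chemistry is out of scope.

**PCR** is a Galton–Watson process: per cycle, each copy duplicates with
probability `amplification_efficiency`, so the expected copy number after
c cycles is (1 + e)^c. Emulsion vs regular PCR is not distinguished
(shown experimentally not to matter for these signatures). Default
scenario settings (2 cycles at e = 0.5) keep the duplicate load modest.

**Sequencing** emits 2×100 paired-end reads: read 1 is the top strand
5′→3′, read 2 the bottom strand 5′→3′; inserts shorter than the read
length read through into the opposite adapter (the printed inPE adapter
sequence by default, appended as written) and then into random bases.
Substitution errors are applied at a configurable rate with a flat Q37
quality profile; base-calling artifacts are out of scope. Read names
carry lineage id and true coordinates for truth-mode evaluation. The
3′-A added during A-tailing is not inserted into the read-through
sequence; at the default error-free, >read-length insert settings this
has no effect on any profiled quantity.

## Read processing

Adapter trimming removes the longest read suffix that aligns ungapped to
a prefix of the adapter with mismatch rate ≤ 1/3 (inclusive, exact
integer arithmetic; ties toward the longer trim), then trims terminal
bases with Phred ≤ 2 or N calls. Both steps iterate to a fixed point so
trimming is idempotent — a shortened read can expose a new, shorter
qualifying suffix, and a single pass would not be idempotent on such
inputs.

Collapsing reverse-complements read 2 and scans all suffix/prefix
overlaps ≥ 11 bp; among overlaps with mismatch rate ≤ 1/3 the one with
maximal identity wins, ties toward the longer overlap. The consensus
takes the higher-quality base at disagreements and sums qualities at
agreements, capped at Q41 (an arbitrary but logged ceiling). The overlap
mismatch tolerance and consensus rule are not externally specified for
this processing style; these choices are recorded here as the package's
own. Processed reads shorter than 25 bp are discarded (inclusive
boundary: a 25 bp read survives).

A consequence of the ≤ 1/3 rule worth knowing: random insert tails can
occasionally mimic an adapter prefix well enough to be trimmed (the
probability grows as the threshold admits floor(o/3) mismatches over an
overlap of o). Such spurious trims shorten the usable overlap and very
occasionally prevent a pair from collapsing. This is faithful to the
rule, not a defect; the collapse-reconstruction guarantee is therefore
stated for collapsing itself (error-free pairs with true overlap ≥ 11
always reconstruct the insert exactly).

## Mapping and duplicate removal

The mapper is a desk-scale unique-hit aligner for simulated data: a k-mer
hash (k = 20) over the reference seeds candidate loci from the read start
(read end as fallback), extended ungapped on both strands. A read is
reported only if its best locus has ≤ 3 mismatches and every other
candidate has at least 2 more — a uniqueness margin standing in for a
mapping-quality cutoff without reimplementing an aligner's MAPQ formula.
Simulated reads contain no indels; real data should be mapped externally,
and the profiler accepts any ungapped SAM.

Duplicates are collapsed on (contig, strand, start, end) — both
coordinates, the convention for collapsed single reads — keeping the
highest-summed-quality representative. Clonality is
1 − #unique/#total-including-duplicates, and endogenous content is
round(#unique hits / #collapsed reads, 5), both reported at 5 decimals to
match the print precision of the tabulated metrics.

## Profiling

All tabulation is in **molecule orientation**: reads aligned to the −
strand are flipped and their genomic flanks mirrored and complemented, so
"position 1" is always the molecule's 5′ terminus — the convention of the
damage-profiling literature, stated here explicitly because tools differ.
Composition is reported at read positions 1..W and N−W+1..N plus genomic
flanks −W..−1 and N+1..N+W (W = 10); flank positions clipped at contig
edges are excluded position-wise, and no exclusion is applied when a
flank window overlaps another read's footprint. Misincorporation rates
are per-position quotients #(ref C, read T)/#(ref C) (and G→A
symmetrically from the 3′ end); zero-denominator positions are NaN/`NA`,
never 0.

## Scenario signatures

Signature flags are computed from thresholds, never hand-set: a
composition deficit/excess flag fires when the deviation from genomic
composition exceeds 5 binomial SDs under the null at that position's
denominator; the C→T peak position is the argmax over read positions 1–3
(undefined when there is no C→T signal at all); monotone decay requires
non-increasing rates over positions 1–5 with a positive rate at
position 1. The 5-SD rule is scale-free and seedable and avoids magic
percentage cutoffs.

`compare_scenarios` checks the two directional claims across runs sharing
a genome: lower ligation weight on T strictly increases the position-1 T
deficit, and blunt-end chemistry shows the higher position-1 C→T rate at
equal damage.

## Problem sizes and verification

Closed-form checks (cut-site reweighting, AT acceptance fractions) are
verified by simulation at n = 50,000–100,000 fragments within 3 binomial
SDs. Signature-shape properties use n = 100,000 fragments per run; the
adapter-concentration dominance check uses 20 seed-replicated pairs at
n = 100,000. Large-scale property runs profile the library pool at its
true coordinates directly (`insert_alignments`), which is exact for
error-free size-selected inserts because collapsing reconstructs them
perfectly — a property the processing tests verify independently; full
pipeline runs (sequencing, trimming, collapsing, k-mer mapping,
deduplication) are exercised end to end at n = 20,000 and in the
byte-identical determinism test. The null composition calibration
(unbiased, undamaged) checks the maximum z-score over 40 positions × 4
bases against 4 SDs, the appropriate bound for a max over ~160 weakly
dependent binomial comparisons.

## What the synthetic data do not emulate

Real base-calling error structure (quality decay, context-dependent
miscalls), indels, adapter dimers, index hopping, single-stranded library
preparation, GC-dependent PCR efficiency, mappability variation, and
metagenomic mixtures of endogenous and contaminant templates. Passing
tests therefore demonstrate the internal consistency of the mechanistic
model and pipeline — that the chemistry-dependent signatures emerge from
the stated assumptions — not that any particular real specimen will show
a given rate. The real-data percentages quoted in the literature depend
on specimen-specific damage levels and are reproduced here only as
qualitative shapes (peak positions, deficits, orderings).

## Known limitations

* The slight guanine enrichment observed at blunt-end read starts in real
  fresh libraries has no established mechanism and is deliberately not
  reproduced.
* Occasionally reported one-position-further-shifted C→T peaks in AT
  libraries have no stated mechanism and are not modelled.
* The interior-deamination strand resolution (above) doubles the
  effective δ_ds contribution.
* The mapper's uniqueness margin is a surrogate for, not a clone of, any
  specific aligner's mapping-quality filter.
* A two-source (endogenous + microbial) mixture simulation — which would
  let one study endogenous-content flips between chemistries for AT-rich
  contaminants — is a documented extension, not implemented.
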