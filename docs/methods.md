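# Methods

This note records the conventions, defaults and open design choices behind
`sirnawalk`, in the spirit of a model-description document: what the code
assumes, what its parameters mean, and what its synthetic data can and cannot
tell you about real experiments.

## Coordinate and strand conventions

All transcript coordinates are 1-based, inclusive, on the sense strand; guide
(antisense) positions are numbered 5′→3′ with P1 the 5′-most nucleotide.
Because guide and target are antiparallel, guide position *q* pairs sense
position `t(q) = window_end − q + 1`. These conventions are echoed in every
TSV header the CLI writes. Input sequences are case-insensitive; output is
uppercase; IUPAC ambiguity codes are rejected outright, since every design
rule here is defined only on concrete bases.

## Guide design model

A design of length *L* against a locus with SNV at position `snv` targets the
window `[snv − (L − p), snv + (p − 1)]` and is the RNA reverse complement of
the **mutant** window, so the primary mismatch to wild type falls at guide
position *p*. *L* defaults to 19 nt — the classical synthetic-siRNA core, and
the arm length assumed for shRNA stems — and is configurable from 19 to 23
because hairpin arms in the literature are not always exactly 19 nt.

Mismatch classification is a total function over the 16 ordered RNA
target:guide pairs: 4 Watson-Crick, 2 G:U wobbles, 4 purine:purine,
4 pyrimidine:pyrimidine (non-WC), 2 purine/pyrimidine mismatches (A:C, C:A).
Labels are written `target:guide`, so a G→A variant targeted on the mutant
allele shows a "G:U" wobble against wild type, and a G→C variant a "G:G"
purine:purine clash.

### Mismatch-strength table

Ranking candidate secondary mismatches as "weak" or "strong" requires an
ordinal scale over mismatch pairs. The packaged default
(`data/strength_table.yaml`) encodes the ordering most consistent with the
allele-specific-silencing literature: Watson-Crick 0 < G:U/U:G wobble 1 <
A:C/C:A/U:C/C:U 2 < U:U 3 < C:C and purine:purine 4–5, G:G highest. The
exact integers are an editorial choice — published mismatch-tolerance data do
not pin down a unique total order — so the table is a documented, swappable
input rather than a constant, and rank selection breaks ties deterministically
in base order A<C<G<U. Variant naming follows wet-lab conventions:
`p13` (single mismatch at P13), `p1314` (adjacent-3′ double with an explicit
substitution), `p11_9C` (secondary C at P9 on a P11 design), with
`:weak`/`:strong` suffixes for rank-selected substitutions.

## Construct assembly

**siRNA duplexes** render the guide and its full reverse complement as
passenger, each with a 3′ `dTdT` deoxy overhang (core *L*, total *L*+2). The
passenger pairs the guide everywhere — secondary mismatches are against the
*target*, not within the duplex.

**U6 hairpin primers.** The reverse-primer template is
`AAAAAA .. slotA .. TGGGTCAGG .. slotS .. GGTGTTTCGTCCTTTCCACAA`. Taken
label-literally ("slotA holds the antisense DNA"), reverse-primer geometry
would place the guide in the hairpin's *5′* arm — contradicting the intended
architecture in which the antisense species occupies the 3′ arm. The default
`slot_mode="architecture"` therefore derives slot contents from the intended
transcript (`sense_arm + loop + guide + UUUUUU`): slotA receives the reverse
complement of the guide DNA and slotS the guide DNA itself. The literal
reading remains available (`slot_mode="literal"`) because oligo sheets written
that way exist. Likewise the loop defaults to `CCUGACCCA` (the template
segment read through reverse-primer geometry) with `UGGGUCAGG` selectable.
The transcript is rendered with the six template-encoded U's; Pol-III
termination typically leaves a shorter 3′ U overhang on the physical RNA
(recorded as metadata, default 2), which does not affect any downstream
computation here.

**Reporter inserts** default to 52 nt. With an even width the SNV cannot sit
exactly centrally; the package puts `width // 2` nt 5′ of the SNV (52 → SNV at
window position 27) and documents the offset in its output, since the true
offset used in historical constructs is not recoverable from publications.
Oligos carry XhoI (`C^TCGAG`) and NotI (`GC^GGCCGC`) sticky ends for
directional ligation; vector context beyond the overhangs is out of scope.

## 5′RACE model

The cleavage convention is a single parameter `g_star`: the guide position
paired with the 3′ fragment's 5′-most nucleotide, i.e. the fragment starts at
sense position `t(g_star)`. The default is 11, matching the empirical
junction observation that degradation-product 5′ ends align to the 11th guide
nucleotide. Note the tension with the classical biochemical statement that
slicing occurs "between the target bases paired to guide positions 10 and
11", which under this module's mapping would start the fragment opposite
guide position 10; because the literature states both forms, `g_star` is
exposed rather than hard-coded, and simulator and mapper stay self-consistent
for any value.

Junction mapping requires the adapter as an exact read prefix (a configurable
substitution allowance, default 0) and then an exact, unique match of the
next `min_anchor` nucleotides (default 12) against the transcript; ambiguous
or absent anchors are no-calls rather than guesses. No indel or
quality model is applied: the reads this targets are Sanger-quality products
of band-isolated PCR, not high-throughput data. T/U differences are ignored
so cDNA-sequenced reads map directly against mRNA.

## Screen statistics

Normalization follows the two reporter-assay conventions. Dual-luciferase:
per-well Renilla:firefly ratio, divided by the mean control ratio for the
same target allele (controls therefore self-normalize to mean 1). Dual-
fluorescence: per-channel background subtraction (mean of target-alone wells,
negative values floored at 0 with the floor documented, since instrument
noise can push readings below background), then division by the mean
background-subtracted nonspecific-control signal; eGFP and mCherry channels
are processed independently. Both normalizations are scale-invariant.

Per construct the package reports normalized wild-type and mutant expression,
percent silencing `100·(1 − rel)`, fold discrimination `wt_rel / mut_rel`
(> 1 = mutant-selective; reported as infinite, with a flag, when the mutant
signal is fully silenced), the silencing difference in percentage points, and
a two-tailed unpaired Student's *t* p-value (Welch optional). Percentages are
reported to 0 decimals and folds to 2, the field's usual style. No
multiple-testing correction is applied by default: screens of this size
conventionally report raw p-values, and a Bonferroni-style correction is a
one-line post-hoc on the returned table.

**Calibration caveat.** The p-value returned by `screen_discrimination`
compares the control-normalized replicate groups. When the control mean is
itself estimated from few wells (n = 6), every value in a group shares that
estimate's noise, which correlates replicates within a group and makes this
test anticonservative — with 10% CV noise the marginal rejection rate under
equal true expression is roughly 0.14 at α = 0.05, not 0.05 (the shared
divisor inflates the variance of the group-mean difference by ~2× relative to
what the pooled within-group variance estimates). The *t*-test itself is
calibrated: applied to equal-mean replicate groups — e.g. the raw per-well
ratios of the two targets under a true null — its type-I error is ≈ 0.05,
which is how the package's calibration test measures it. Users wanting
calibrated inference from normalized data should test on raw (or log) ratios,
or include control variance explicitly.

### Synthetic plates

`simulate_screen` emulates a six-replicate reporter screen: *n* = 6
experimental wells per target allele, *n* nonspecific-control wells per
target and (fluorescence mode) *n* background wells, every reading carrying
independent mean-one multiplicative log-normal noise at a given CV (default
10%, a typical plate-reader well-to-well spread; baselines: Renilla 5×10⁴,
firefly 10⁵, fluorescence background 100, control signal 1000 arbitrary
units). At CV = 0 the full pipeline recovers the true relative expressions
exactly; at CV = 10% the mean recovered fold across 200 simulated plates is
within ~1% of truth. What the simulator deliberately omits: transfection-
efficiency correlation between wells, plate-position (edge) effects,
channel cross-talk and bleed-through, saturation and detector nonlinearity,
and any sequence-dependent silencing efficacy — so passing recovery tests
demonstrates the correctness of the normalization and statistics arithmetic,
not that a real screen with these settings would behave this well.

Similarly, the RACE simulator produces perfectly ligated, error-free reads
from a single cleavage position; it validates coordinate bookkeeping
(simulate → ligate → map round trips recover `g_star` with 100% accuracy over
random loci and all alignments P1–P16), not the biochemistry of ligation
efficiency, partial degradation or mispriming.

## Problem sizes and determinism

Tests and the acceptance script run on synthetic loci of 120–500 nt (default
300 nt, SNV centred) — ample flank for every P1–P16 design while keeping the
junction anchor (12 nt) essentially always unique; the acceptance script
draws a fresh locus if an anchor collision ever produces a no-call. Fold-
recovery and calibration checks use 200 and 1000 simulated plates
respectively. All stochastic components take a NumPy `Generator` or integer
seed, and every pipeline is a pure function of (inputs, config, seed).

## Known limitations

- No efficacy prediction: thermodynamic asymmetry scores, seed-region
  off-target searches and target secondary-structure accessibility are out of
  scope; the toolkit designs and scores constructs, it does not rank their
  expected potency.
- Single-SNV model: one variant per locus; haplotypes with multiple linked
  variants are not represented.
- Dicer processing of shRNAs is assumed faithful — the predicted hairpin's 3′
  arm is taken as the loaded guide; verifying that (the point of the RACE
  workflow) is an experimental question.
- The mismatch-strength table is ordinal and editorial; do not interpret
  score differences quantitatively.
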