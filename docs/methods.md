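# Methods

## Model and scope

`deepsoma` operates on count-level pileups: for each (sample, site), the
number of reads supporting each allele, split by strand, optionally with
per-supporting-read attributes (mismatch count, distance to read end,
distance to the nearest indel, base and mapping quality, strand).  It does
not ingest alignments; converting BAM/CRAM to counts (and applying the
standard Phred ≥ 20 base / ≥ 30 mapping quality masks at pileup time) is
upstream of the package, though `apply_quality_mask` re-applies those masks
when read evidence is attached, and a converter from `samtools mpileup`
text output is provided for convenience.  The canonical interchange format
is a tab-separated counts table; calls are emitted as VCF v4.2 with custom
INFO keys (SS, SPV, VAFC, VAFN, DPC, DPN, ADF, ADR).

## Paired calling

Genotyping uses fixed thresholds rather than a likelihood model: a variant
is *present* when it has at least `min_reads2 = 2` supporting reads on at
least `min_strands2 = 1` strand and at least `min_var_freq = 1%` of depth;
*homozygous* at ≥ 75%; a sample below 50× is uncallable and the site is
skipped.  The somatic significance test is the one-sided Fisher exact test
on the 2×2 table of (ref, alt) counts in control vs case, evaluated as the
upper hypergeometric tail P(X ≥ case_alt) with margins fixed.  One-sided
because the screen asks specifically for enrichment in the case tissue; for
LOH candidates (variant in the control only) the test is applied in the
opposite direction, which makes SOMATIC and LOH exactly symmetric under
case/control exchange.  The implementation delegates the tail to
`scipy.stats.hypergeom.sf`; the test suite verifies agreement with an
independent exact-integer enumeration to 10⁻¹² on every table with row
margins ≤ 60.

With two controls, a SOMATIC call must be consistent against both (variant
absent from each, each contrast significant; the reported p is the maximum),
while presence in any control makes the site germline.  Purity parameters
are accepted but fixed at 1.0, where the purity correction is the identity.
No genome-wide multiple-testing correction is applied: the screen's error
control comes from the per-variant p ≤ 0.05 *plus* the hard filter cascade,
and the technical-replicate null quantifies the resulting false-positive
rate directly.

Unpaired screening constructs the expected (ref, alt) split at the
configured per-base error rate (default 1%, rounded to whole reads at the
observed depth) and applies the same one-sided test against it.  This is an
explicit design choice for a screen with no matched control: it asks "is
this allele fraction inconsistent with the background error process", not
"is it different from a paired tissue".

## Filter cascade

Order: status gate → depth → strand → control absence (paired) / frequency
window (unpaired) → recurrence → read evidence.  All filters are evaluated
for every input call, so the audit table is complete even for calls that
fail early.  Depth minima are inclusive (`≥`), reading "a minimum of N"
literally; the unpaired depth rule is strict (`> 300`).  The purely
per-call filters commute — the surviving set is order-independent — but the
read-evidence filter can reduce strand support, so it deliberately runs
last and the audit records both strand checks.

Choices where the design was genuinely open:

* **Control absence** defaults to literally zero alternate reads in every
  control.  At 1000× with a 10⁻³ error rate a control shows ≥ 1 matching
  error read at a given non-ref base with probability ≈ 28%, so this
  default is deliberately harsh — it trades sensitivity for specificity,
  which is the package's stance throughout.  The knob
  `control_absence_max_alt_reads` relaxes it.
* **Recurrence** flags any (site, allele) at ≤ 10% VAF in ≥ 3 distinct
  samples.  Independent recurrence of the same low-fraction point change
  across samples is overwhelmingly a cross-mapping artifact of paralogous
  genes; both thresholds are config-exposed.
* **Read evidence** quantifies the qualitative "questionable reads" rules:
  discard supporting reads with > 3 mismatches, within 5 bp of a read end,
  or within 10 bp of an indel, then require the surviving support to still
  meet the 4-per-strand rule.  Calls without attached evidence pass with a
  `NO_EVIDENCE` flag rather than failing, since counts-only inputs carry
  nothing to inspect.
* **Frequency windows**: the unpaired screen uses a < 40% gate; a stricter
  25% reporting window exists as a separate knob because both figures are
  defensible readings of the screening protocol, and conflating them would
  hide the difference.

## Synthetic data

The generator emulates targeted-capture deep sequencing at the study's
conditions: mean depth 1000× (negative-binomial, Poisson at dispersion 0 —
capture depth is overdispersed in practice), per-base substitution error
10⁻³ distributed uniformly over the three non-reference bases, germline
heterozygous/homozygous SNPs at 50%/100% expected fraction shared by all
samples of one individual (rates 10⁻³ / 5×10⁻⁴ per site, giving a
realistic SNP yield over a sub-megabase target), somatic clones planted at
stated fractions in stated samples, and recurrent artifact alleles
affecting a stated fraction of samples.  Reads split between strands
binomially (default balanced; an asymmetric-error mode exercises the strand
filter).  Engineered plant/artifact sites are excluded from the germline
draw so each site's truth fractions stay well-defined.  Read evidence, when
requested, is drawn clean (≤ 2 mismatches, mid-read, no indels, qualities
above the masks).

What it does **not** emulate: read sequences and alignment (so no
realignment artifacts beyond the recurrence model), capture efficiency and
duplication statistics, indel realignment, or error-rate heterogeneity
along reads.  Passing tests therefore demonstrate the pipeline's logic and
statistics under the stated error model, not robustness to every failure
mode of real libraries.

ddPCR droplets: wild-type and variant occupancies are independent Poisson
with mean cn·V; occupied droplets emit N(8000, 500²) in the matching
channel, empty droplets N(500, 200²), clipped at zero — clusters well
separated by the 4000/3000 gates.  Droplet volume defaults to 0.85 nL (the
common nominal droplet volume of commercial systems).  Double-positive
droplets count toward both channels' positive fractions, the standard
duplex treatment.

## Clone-size arithmetic

`cell_fraction = min(1, 2v)` for heterozygous variants (v for homozygous),
`clone_cells = round(fraction × cells_total × sampled_area_fraction)`,
`clone_area = clone_cells / density`.  Defaults: 0.5 × 10⁶ cells total,
density 5500 cells mm⁻².  The sample is parameterised by the *area
fraction* it covers, with a uniform density mapping area to cells.  The
companion "approximately" area field rounds to the nearest whole mm²
(falling back to one significant digit below 0.5 mm²), matching how such
patch sizes are quoted; 0.909 mm² reads as ≈ 1 mm², and exact values like
2.0 are preserved.

## Numerical and testing notes

* All randomness flows from a single integer seed per run
  (`numpy.random.default_rng`); reruns are byte-identical.
* The hypergeometric tail from scipy agrees with exact integer arithmetic
  to ~10⁻¹⁵ at the margins used here; the all-zero table is degenerate and
  returns p = 1 with a warning.
* A fully positive ddPCR channel is a saturation error (λ unbounded), and
  a fully empty reaction has undefined VAF; both raise typed exceptions
  rather than returning sentinel values.
* Problem sizes in the test suite are chosen to keep the full run around a
  minute while preserving the statistics being checked: the
  technical-replicate null uses 50,000 sites × 2 aliquots at 1000×; power
  is estimated from 200 seeded replicates of 50-site pairs (only the
  planted site informs the statistic); Poisson recovery uses 500 seeds ×
  15,000 droplets; the detection-power replicates run at error rate 0 —
  the "clean plants" condition — because the strict zero-read control
  absence filter intentionally rejects a quarter of true variants once
  background error reads appear in the control (see above).
* The binomial-recovery check on the generator uses 400 replicate seeds,
  a pooled-mean z within 3 standard errors.

## Known limitations

* Genotyping is threshold-based, not likelihood-based; near the 1% floor,
  sampling noise moves borderline variants across the gates (the analysis
  scripts show plants at 1.0–1.1% being lost while 2.7%/3.9% survive —
  the intended conservative behaviour, matching a screen whose nominal
  sensitivity floor is 1%).
* Indels are opaque allele tokens; no realignment or left-normalisation.
* No copy-number awareness: VAF→cell-fraction assumes diploidy and a
  single variant allele per cell.
* ddPCR thresholds are fixed inputs; no automatic cluster gating ("rain"
  handling).
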