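# Methods

## Amplicon reference and coordinates

An amplicon reference stores the **mutant-allele** sequence together with the
single-base sites that distinguish it from the wild-type allele (one
`marker`, one `pathogenic` site in the canonical case). The wild-type
sequence is always derived by substituting the annotated wild-type bases,
never stored, so the two alleles cannot drift apart. All coordinates are
1-based and inclusive on the top strand. Cut sites are between-base positions
reported as the offset of the base on the 5′ (left) side of the cut; this
round-trips unambiguously to alignment columns. Degenerate bases (N, IUPAC
codes) are rejected: amplicon references are fully resolved sequences.

The canonical fixture is the published 101-nt single-stranded donor used to
create the *Kcnq4* p.W276S knock-in mouse: marker c.810C>A at offset 41,
pathogenic c.830G>C at offset 61 (mutant codon TCG, wild type TGG), exactly
20 nt apart. On the derived wild-type sequence the knock-in protospacer
`CCTCCTATGCCGACTCGCTC` occupies 37–56 with PAM `TGG` at 57–59 and cut 53|54.

## Guide enumeration

Every NGG occurrence whose 20-nt protospacer window fits on the sequence
yields one candidate; both strands are scanned by default and candidates can
be filtered to those whose protospacer covers the pathogenic site. The
"bottom strand" scan looks for CCN on the top strand. SpCas9's blunt cut is
placed between protospacer positions 17|18 (3 nt 5′ of the PAM), mirrored on
the minus strand. Guides are sorted by top-strand span start, so enumeration
is deterministic. Allele discrimination re-reads each protospacer from the
derived wild-type sequence: a variant-overlapping guide differs from its
wild-type counterpart at exactly one base, the basis of allele-selective
cutting; the variant's distance from the PAM-proximal end is annotated
because PAM-proximal mismatches discriminate most strongly.

Strand handling is deliberately permissive (both strands scanned, overlap as
a filter flag) since candidate guides in this design space place the variant
at varying protospacer positions. On-target efficiency scoring and
genome-wide off-target search are out of scope (external predictors exist
for both); off-target amplicons can be quantified by pointing the same
quantification at their reference and cut site.

## Read alignment

Reads are fragments of the amplicon, so alignment is the standard *fitting*
alignment: the read aligns end to end, the reference flanks outside the read
are free, and internal gaps carry affine penalties (a gap of length k costs
`gap_open + (k−1)·gap_extend`; defaults match +2, mismatch −3, open 6,
extend 1). The engine is Biopython's `PairwiseAligner` (optimal Gotoh DP);
the test suite checks its scores against an independently written DP oracle
on random instances. Two exact-substring fast paths (mutant sequence;
derived wild-type sequence, which against the mutant reference is all
matches except the annotated sites) bypass the aligner for the bulk of
error-free reads. Traceback indels are **left-normalized** — shifted as far
5′ as sequence identity allows — so gap placement is deterministic and
independent of the engine's internal tie-breaking. Alignment identity is
matches over aligned columns (internal gaps included, free end gaps not);
reads under the identity floor (default 0.75) are discarded.

Alignment is always to the mutant reference; allele identity comes solely
from the marker column, never from alignment-score competition between two
references. This mirrors the marker logic of the assay and avoids reference
bias at the pathogenic base, where an edited read matches neither allele.

## Read classification and efficacy

Marker call: the base aligned to the marker offset (mutant base → `mutant`,
wild-type base → `wt`, any other base or a deletion spanning the column →
`other`). Reads whose alignment does not cover both the marker and the full
cut-site window are discarded; `other`-marker reads are likewise discarded
rather than counted as wild type, since their allele of origin is unknowable.
No base-quality filtering is applied at the marker column (the assay
describes none); qualities are carried but unused.

Indels are attributed to the nuclease when their reference footprint
intersects `[cut − w, cut + w]` with half-width `w = 5` nt by default — the
assay specifies only "around the cleavage site", so the window is a
config-exposed choice echoed in every output. The net indel length L is the
sum of signed lengths in the window (multiple indels sum before the frame
test, reading "any out-of-frame indel pattern" as net frame disruption).
Mutant-marker reads with `1 ≤ |L| ≤ 8` and `L mod 3 ≠ 0` are
`mutant_edited`; indels failing that test (in-frame net length, |L| > 8, or
a net-zero combination) are `mutant_excluded`; no window indel is
`mutant_unedited`. Substitutions can never produce an edited call.

Efficacy is `100 · edited / (edited + unedited + excluded)` — the
mutant-allele denominator, consistent with reporting "x% of mutant alleles
disrupted". The assay never states its denominator explicitly, so the
alternative (all classified reads) is available as `QuantConfig(denominator=
"all")`. Zero marker-positive reads leave efficacy undefined and flagged,
never silently 0. Background correction is `max(0, injected − control)` with
both raw values retained and a flag when flooring occurred; it requires
identical cut site and configuration on both sides.

## Synthetic reads

The read simulator emulates merged single-end amplicon reads from a
heterozygous locus: each read draws its allele (mutant fraction 0.5 by
default), is edited with the per-allele editing rate, and an edited read
carries **exactly one** indel whose left breakpoint is the cut site, length
drawn from a configurable spectrum (insertions filled with random bases).
Compound edits are not modelled — the classification rule addresses single
1–8 bp patterns and single indels keep the truth table unambiguous. The
default length spectrum is a generic NHEJ-like mix dominated by ±1 with a
deletion-heavy tail; it deliberately includes in-frame (−3, +3, −6) and
>8 bp lengths (17% of weight) so the exclusion rules are exercised: measured
out-of-frame efficacy is then ~0.83× the raw editing rate, and recovery tests
compare against the truth table rather than the nominal rate. Substitution
errors are applied uniformly per base after editing (default rate 0; 0.001
in the recovery experiments, a typical merged-amplicon error scale);
sequencer indel errors are not modelled by default. Qualities are constant
Q37. Read start positions are uniform among windows that cover the marker
and the cut-site neighbourhood, so classification is never coverage-limited.
Read length, depth and pairing of the original instrument runs are not
published; 150 nt single-end is a convention, not a reproduction.

Truth-agreement accounting: a substitution error that hits the marker column
makes the read's allele unknowable; two thirds of such errors produce an
`other` base and the read is *discarded* — an abstention, not a wrong call.
Per-read agreement is therefore measured over called (non-discarded) reads.
Including abstentions would pin expected agreement at exactly one minus the
substitution rate by construction, which measures the error model, not the
classifier.

## T7E1 conversion

`fraction cleaved` = total cleavage-band density / (cleavage + uncut), from
numeric densitometry only (gel image quantification is upstream, e.g.
ImageJ). `variant frequency (%) = 100 · (1 − √(1 − f))`, the inverse of the
random re-annealing model `f = 1 − (1 − p)²`. Fractions within 1e−12 of the
bounds are treated as float noise and clipped; anything further out is an
error, not a silent clip. The simulator is the forward model plus Gaussian
density noise clipped at zero; the noiseless round trip is exact to 1e−9
over the full 0–100% range.

## ABR phenotype statistics

Hearing improvement per animal is the mean of (contralateral − injected)
thresholds over 6, 12, 18, 24 and 30 kHz, in dB SPL; positive = improvement.
Thresholds must lie in the instrument range [10, 95] dB SPL (95 encodes "no
response"). Categories use half-open intervals: marked [15, ∞), moderate
[10, 15), mild [5, 10), minimal (−∞, 5). The stated "mild 5–9" and "minimal
≤5" ranges overlap at exactly 5 dB; the convention here sends 5.0 → mild,
taking the explicit 5–9 range as inclusive of its endpoints, and the
convention string is exposed in output metadata. Non-integer shifts use the
same intervals without rounding. Pearson r with the two-sided t-test p-value
comes from scipy; degenerate inputs (n < 3, missing efficacy, zero variance)
raise rather than returning NaN. Group-comparison tests beyond the
correlation (ANOVA etc.) are convenience output via standard scipy routines.

The cohort simulator is a linear dose-response: efficacy ~ Normal(mean, sd)
truncated at 0 (scipy truncnorm); injected threshold per frequency =
baseline − slope·efficacy + Gaussian noise; contralateral = baseline +
independent noise; thresholds clipped to [10, 95]. Defaults — baselines
55–75 dB rising with frequency (a hearing-impaired heterozygote), slope
1 dB per efficacy %, noise 3 dB, efficacy 5 ± 2% — are this package's
choices of realistic scales; none are published values. The population
correlation of (efficacy, mean shift) has the closed form
`r = sσ / √(s²σ² + 2τ²/m)` (m frequencies, per-ear noise τ), which
`noise_sd_for_target_correlation` inverts; correlation-recovery experiments
tune τ for r = 0.5 and check the mean sample r over 500 cohorts of 20
animals. Recovery experiments use efficacy 10 ± 3% so the truncation at 0 is
negligible and no threshold reaches the instrument bounds.

## FluxOR trace quantification

A trace is F(t) for one ROI with t = 0 at thallium addition; recordings run
to 120 s. F₀ is the sample nearest t = 0 (the definition ties F₀ to the
stimulus time point; an optional pre-stimulus average of several frames is
available for noisy data). ΔF₀₋₁₂₀/F₀ = (F(120) − F₀)/F₀ uses the raw
nearest samples, no smoothing. The influx slope is ordinary least squares of
F on t over [0, 120] s with its standard error; the window endpoints are
config. The ratio is invariant under rescaling F by a positive constant;
the slope scales linearly. Nonpositive F₀ flags the ratio undefined.
Image-stack support covers single-channel (frames, h, w) arrays with
externally supplied boolean ROI masks (mean pixel intensity per frame); no
automatic hair-cell segmentation. Group comparison reports mean ± sd of
ratio and slope per group in deterministic (alphabetical) order with Welch
t-tests and one-way ANOVA as convenience output.

The simulator draws F(t) = F₀ + slope·t + Gaussian noise per frame, one
slope per experimental group (zero for inhibitor controls), F₀ ~
Normal(100, 5) a.u., 2-s frames over 120 s. Stack mode writes each trace
value uniformly into a disjoint rectangle on a grid (construction guarantees
disjointness; a gap < 1 px is rejected), so extracted pixel-mean traces
reproduce the table to machine precision.

## Problem sizes and numerical checks

Acceptance-style experiments run at: 100 000 reads per sample across editing
rates 0.3–30% (recovery within 3 binomial SE of the truth table, per-read
agreement ≥ 99.9% of called reads); 500 cohort replicates × 20 mice (mean
sample r within 0.05 of the tuned 0.5); 1000 flux replicates at noise 5% of
F₀ (slope within 3 SE in ≥ 95%); 200 random alignment instances ≤ 200 nt
against the DP oracle; 100 random 500-nt sequences plus the donor against
the guide-enumeration regex oracle. These sizes give the property checks
comfortable statistical power while keeping a full run to a few minutes on
one CPU.

## Known limitations

- No PCR bias, chimeras, amplification noise, UMI handling, paired-end
  merging or read-length modelling; reads are clean substrings plus
  substitution errors.
- Single-marker phasing only; no haplotype inference beyond the one
  synonymous tag, and `other`-marker reads are discarded, not rescued.
- The efficacy denominator and cut-site window are assay-underspecified
  choices, config-exposed and echoed in outputs rather than hidden.
- The headline in vivo quantities of the original study derive from deposited
  animal sequencing data; this package reproduces the *method* and validates
  it on synthetic ground truth, not those per-animal numbers.
- Flux image support assumes externally drawn ROI masks and a single
  channel; dye chemistry and membrane-potential inference are out of scope.
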