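# Methods

## Gene model and coordinates

All coordinates are 1-based, inclusive, gene-relative on the sense strand.
A `GeneModel` is an ordered list of exon intervals; introns are derived.
Only plus-strand models are supported — strand handling lives in the read
simulator and classifier (which search both orientations of both mates),
not in the gene model.  Splice-acceptor offsets use the field convention
that the last intron base is −1, the first exon base is +1, and position 0
does not exist; under it, gene position 781 is the −2 position of the
alternate exon-3 acceptor whose exon starts at 783.

Variants are single-base substitutions or length-preserving block
replacements (the two operations used in ectopic-expression mutagenesis of
these genes); reference bases are checked before application and all other
positions are guaranteed unchanged.

## The synthetic fixture

`make_fixture_alleles` builds one ~2.95-kb eight-exon gene and four alleles
standing in for two common HLA-C-like alleles, a null allele, and its
co-expressed comparator.  The layout is chosen so that every positional
anchor of the biology sits at its conventional coordinate: the canonical
exon-3 acceptor at 719 preceded by the G-rich element 705–714 (a perfect
SP1 consensus match, (G/T)GGGCGG(G/A)(G/A)(C/T); note a perfect match
necessarily contains two pyrimidines, so its pyrimidine fraction is 0.2,
not 0), the pyrimidine-rich tract 769–778, the cryptic acceptor at 783
whose −2 position (781) is A on the null analog and G on the others, and a
cryptic intron-5 acceptor at 2520, 18 nt upstream of the exon-6 start
(2538).  Exon 6 is 33 bp and exon 7 is 48 bp so the "entire exon" tags have
their standard lengths; other exon and intron lengths are synthetic, with
intron 3 absorbing the distance between the fixed exon-3 and exon-6
anchors.  The canonical ORF starts inside the exon-1 tag and terminates at
a planted stop in exon 8, downstream of the final junction; exon 5 (the
transmembrane exon) is a multiple of 3 so skipping it is frame-preserving,
and the alternate exon-3 acceptor removes 64 nt, forcing a frameshift.

Alleles are identical across every tag, junction window and splice-signal
region — so tags are allele-shared, as in real paralogous/allelic pairs
with conserved exon ends — and differ only at 10-bp discriminator sites
tiled ~40 nt apart through all unconstrained regions (plus the single base
at 781 on the null).  This emulates the dense polymorphism of real HLA
alleles.  A single discriminator (as a minimal design would suggest) cannot
support per-allele analysis at the exon-4/exon-5 ends: with 2×100-nt pairs
and 250-nt fragments no read pair can span from those junctions back to an
exon-3 site, so allele assignment would be impossible exactly where the
per-allele profiles are measured.  The tiling spacing and the placements
immediately flanking each tag/window block were chosen so that, at the
default fragment size, every junction-covering pair also covers at least
one discriminator regardless of the junction category.  Discriminator
candidates are rejected at draw time if they (or their reverse complements)
occur anywhere in any in-progress allele sequence, and exonic candidates
must keep the canonical reading frame stop-free; a final verification pass
(tag/window uniqueness in both orientations, acceptor AG contexts, ORF
integrity, discriminator privacy) triggers a deterministic rebuild with a
new derived seed in the rare case a cross-check still fails.

## Splice programs, isoforms and expression

A `SpliceProgram` is a categorical distribution per exon 3' end over
{canonical, alternate_acceptor(position), skip_to_exon(n), unspliced}.
Each simulated pre-mRNA resolves the 3' end of every exon it visits
independently; exons bypassed by skipping or by a downstream acceptor never
present their own end.  This per-end independence mirrors how short-read
data are analyzed (each exon end is measured separately) and is an explicit
simplification: joint isoform structure across ends is not modeled, and the
reports say so.  `enumerate_isoforms` expands a program into the complete
chain space with exact probabilities; `sample_isoforms` draws molecules
multinomially; `transcribe` concatenates retained segments (retained
introns verbatim).

Steady-state expression applies a multiplicative `degradation_factor`
(default 0.1, configurable) to PTC-flagged isoforms, standing in for
NMD-like decay.  The recovery scenarios install *measured RNA-level*
proportions as generative truth, so they use factor 1.0 — degrading again
would double-count decay that the measured proportions already reflect.

## Read simulation

Fragments are drawn proportional to weight × transcript length, with
gaussian length (default mean 250, sd 30, truncated at the read length) and
uniform start; mate 1 is the fragment prefix, mate 2 the reverse complement
of the suffix; reads are error-free with fixed Q40 (a configurable uniform
substitution rate exists for robustness experiments only, since the
classifier is specified with exact matching).  A truth table records the
source allele, isoform and coordinates of every pair.

Two deliberate choices in the *recovery scenarios* (not in the generator
defaults):

* **Fixed fragment size (sd 0).**  With dispersed lengths, short fragments
  lose discriminator coverage downstream of the exon-5 end (where 128 nt
  are allele-shared: exon 6 + exon 7 + the exon-8 window), and long
  fragments truncate junction sampling near transcript 3' ends for short
  isoforms.  Both effects make sampling category-dependent by ~1 point —
  a property of library geometry, not of the classifier — and would
  confound a recovery experiment run at binomial tolerance.
* **Read-level weight correction** (`fragment_pool_weights`): the number of
  fragment placements that cover a junction block inside one read scales as
  1/(L − fragment + 1) while fragment counts scale as weight × L, so
  isoform weights are divided by L/(L − fragment + 1).  The installed
  proportions are read-level observations; the correction makes expected
  classifiable-pair proportions equal the installed probabilities at every
  exon end (verified: residual |z| ≤ 1.3 at 200,000 pairs).

## Junction classification

Tags: 60-bp exon suffixes (exons 1–5), entire exon 6 (33 bp), entire exon 7
(48 bp); windows: 20/47/32 bp.  Matching is exact (0 mismatches; a k ≤ 1
knob exists for robustness experiments).  References per exon end are the
spliced continuation starting at each downstream exon (canonical and skip
categories) and the genomic continuation (unspliced); reference collisions
are retained and classify as unclassified.  Windows matching no reference
are rescued as alternate acceptors only when they occur exactly once in the
allele's pre-mRNA downstream of the exon end and are preceded by AG —
uniqueness prevents false positives, and the AG requirement encodes the
universal 3'-splice-site dinucleotide.  Allele assignment requires exactly
one allele's discriminators in either mate (either orientation); pairs with
none or both are ambiguous.  Pooled (gene-level) classification accepts an
outcome supported consistently by at least one allele's references/rescue
and returns unclassified on conflict.  Proportions are reported over
classifiable pairs (the plotting denominator, with a 0.5 % suppression
flag) and over all pairs including unclassified; both denominators are
emitted because aggregate figures can be quoted either way.

## Expression quantification

Discriminator-assigned pair counts are normalized to pairs per 10⁴
on-target pairs (any fixed scale preserves the ratios all downstream claims
use; the hybrid-capture normalization of the original assay is external to
this package) and expressed as a percentage of a reference allele.
Ambiguous pairs are excluded from numerator and denominator.  With fragment
sampling proportional to weight × length, relative expression recovers
weight ratios only when transcript lengths are comparable; the expression
recovery scenario therefore uses identical canonical transcripts for both
alleles, and no TPM-style length correction is attempted.

## qPCR standard-curve quantification

Per (sample, primer pair) series (≥ 3 distinct dilutions; twofold steps
1/5…1/40 by default): OLS of Cr on log₁₀(dilution factor) — the only model
under which an efficiency is defined — gives A = 10^(−1/slope) and
E = A − 1; plate efficiency is the arithmetic mean of per-sample E values
(averaging E, not slopes; the two differ and a test pins the distinction).
Initial concentrations are N0 = A^(−Cr) on an arbitrary common scale.  The
target-vs-control relation across a dilution series is fitted as a power
law f(x) = a·x^b on log-log axes: both axes are concentrations proportional
to the same dilution, so the true relation is a power law with b = 1; the
"exponential" reading (y = a·e^(bx)) is available as a sensitivity switch.
The relative level of a sample is the mean of f(g)/g at the minimum and
maximum observed control concentration — the implemented reading of an
endpoint-averaging rule whose verbal description is ambiguous — and fold
differences are level ratios.  Noiseless round trips recover template
ratios to 1e-6 relative tolerance for A ∈ {1.8, 1.9, 2.0} and ratios from
1/30 to 30; with Cr noise sd 0.2 the median fold error over 200 replicates
stays below 25 %.

The Cr simulator inverts the same model: Cr(d) = [ln(threshold) −
ln(N0·d)]/ln(A) + gaussian noise, which makes the noiseless pipeline an
exact round trip and the noisy pipeline a calibrated robustness suite.

## Consequence prediction

Frame effect is the net transcript-length delta vs the canonical chain
(valid as a coding delta because every modeled alteration lies between the
start codon and the canonical stop); a delta not divisible by 3 is a
frameshift.  Translation runs from the start codon to the first in-frame
stop, proceeding into retained introns; a transcript without a stop is
flagged nonstop rather than erroring.  PTC status uses the standard NMD
heuristic — stop more than 50 nt upstream of the final exon-exon junction,
strict inequality at the boundary, distance configurable.  Protein fate is
positional, per the exon-domain organization of class I genes: PTC →
truncated_unstable; in-frame loss of exon 5 (transmembrane) → soluble;
otherwise membrane_bound.  No sequence-based domain prediction is
attempted.

## Study-condition scenarios

The packaged scenarios install printed observations as generative truth:

* `sample2_analog`: null-analog exon-2 end — alternate acceptor 53.6 %,
  canonical 53.6/6 ≈ 8.9 % (the alternate product is six-fold higher than
  the canonical), remainder unspliced; exon-5 end — 35 % canonical, 8.7 %
  alternate, 56.3 % unspliced (the printed 35/8.7/56 sums to 99.7; the
  remainder is folded into the unspliced share, consistent with its printed
  precision); comparator exon-5 end — 96 % canonical, remainder unspliced.
  The null allele's template share w = 14/53.6 ≈ 0.261 follows from the
  pooled 14 % alternate-acceptor share (detected only on the null); its
  exon-4-end rates follow from the pooled 14 % skipping (with a small 2 %
  comparator skip rate) and 5 % cryptic-acceptor share.  Exon ends 1, 3, 6
  and 7 are fully canonical so the recovery experiment stays controlled.
  50,000 pairs at 2×100 nt by default; runs in well under a minute on one
  CPU.
* `sample1_analog`: two identical-length canonical transcript pools with
  the null at 9.8 % steady-state abundance; recovery of the relative
  percentage by counting and normalization.
* `g781a_panel`: noiseless dilution-series tables for 781 G/A/C/T variants
  (truths 1, 1/27, 1, 1) against a shared GFP control, quantified by the
  full pipeline.

All generators are deterministic under a fixed seed and every scenario
report is byte-identical on rerun.

## What passing tests do and do not show

The generator produces error-free reads, exact fragment chemistry, a single
gene with allele-shared exon ends, and independent per-end splice outcomes.
Passing recovery tests therefore demonstrates correctness of the
measurement pipeline under its stated assumptions — not robustness to
sequencing error, capture bias, PCR duplicates, cross-gene tag collisions,
or correlated splicing across ends, none of which are modeled.  Known
limitations: no 5'-splice-site (donor) discovery; no BAM/SAM ingestion
(FASTQ only); no between-sample normalization; the mismatch-tolerant
matching knob and substitution-rate knob exist but ship with exact/zero
defaults.
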