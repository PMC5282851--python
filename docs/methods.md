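# Methods

`panelpost` post-processes somatic variant calls from targeted amplicon
panels sequenced out of FFPE (formalin-fixed, paraffin-embedded) tissue.
Formalin fixation deaminates cytosine, so FFPE libraries carry an excess
of C:G>T:A substitution calls, concentrated below 10% allele frequency
(AF); badly degraded specimens additionally produce artifacts at 9–20%
AF that no fixed AF threshold separates from real subclonal mutations.
The package implements the analysis chain around that problem: artifact
spectrum QC with concentration-informed per-sample cutoffs, recurrent-
artifact and germline filtering, read-backed phasing with complex-variant
reconstruction and protein-level reinterpretation, and matched-normal-free
copy-number estimation by bootstrap pseudo-controls. A seeded synthetic
cohort generator supplies ground-truthed inputs for every stage.

## Artifact burden model and per-sample cutoffs

Per-sample artifact counts are modelled as negative binomial with mean

    lambda(c) = exp(a − b·log c),

where `c` is the pre-normalization library concentration (ng/µl), a
proxy for input DNA integrity. The log-linear form is the simplest
strictly monotone positive-valued choice; `b` defaults to 1 and `a` is
set so the default 26-sample cohort carries ≈3180 low-AF artifact calls.
The negative-binomial size parameter defaults to 3.5, which reproduces
heavy sample-to-sample overdispersion and a Spearman rank correlation of
counts against concentration near −0.8 on the default concentration
ladder. The fitted model (Poisson GLM of counts on log concentration,
statsmodels; cohort-constant fallback with a warning when concentrations
are degenerate or fewer than 3 clean samples exist) is combined with a
truncated-Beta model of artifact AFs — Beta(1.2, 30) truncated to
(0, 0.10] — to set each sample's reporting cutoff: the smallest AF `f`
such that the expected number of artifacts at or above `f`,
`lambda(c)·P(AF ≥ f)`, does not exceed `alpha` (default 1 expected
artifact). Cutoffs never drop below the clinical floors of 5% AF for
therapy-response variants and 2.5% for resistance variants, and are
monotone non-increasing in concentration by construction.

## Spectrum QC and degraded-sample flagging

Variants are cross-classified by the 12 raw substitution classes (plus
`indel`/`mnv`) and half-open AF bins, default (0, 0.10] and (0.10, 1]; a
2.5%-step fine binning is available for AF-profile curves. The raw
12-class table is primary; the 6-class strand-symmetric view (C>T and
G>A both → C:G>T:A) is derived on demand and never stored. Per-class
enrichment between the two bins uses Fisher's exact test (two-sided,
hypergeometric summation) with Benjamini–Hochberg correction across the
12 classes. The concentration–burden association is Spearman's rho with
average ranks; p-values use the t approximation for n ≥ 10 and the exact
permutation distribution below that.

A sample is flagged degraded when its count of >10% AF calls exceeds the
cohort median by more than `max(3·MAD, 5)` — the absolute floor of 5
keeps tight cohorts (MAD ≈ 0) from flagging ordinary somatic carriers —
or when its pre-normalization concentration falls below the 1.5 ng/µl
trigger, the boundary below which the high-AF artifact regime appears.

## Post-processing chain

Order: primer exclusion → blacklist → germline call → phasing/merge →
annotation → thresholds. Primer footprints carry no independent evidence
(the bases are copied from the oligo), so calls covered only by primers
are removed; a call in one amplicon's primer but another's insert is
kept. The recurrent-artifact blacklist admits sites seen in at least 40%
of samples (rounded to the nearest count, never fewer than 2) with
median AF < 10%; recurrent *high*-AF sites are routed to germline
discrimination instead. Origin calls use an offline database table:
population frequency ≥ 1% → germline; COSMIC-catalogued with population
frequency < 0.1% → somatic; everything between is surfaced as ambiguous
rather than auto-resolved. Germline calls are logged but excluded from
the curated somatic report.

A variant pair is phased when the fraction of mutant-carrying reads
bearing both variants is ≥ 0.9 (the fully phased textbook case is 1.0).
Phased pairs within 100 bp are re-applied to the reference and reduced
to a minimal, left-aligned single REF/ALT record; if the merged record's
protein consequence is inframe, it replaces the parents (two "frameshift"
calls that are really one inframe delins — the classic amplicon false
negative), otherwise both parents are kept and a call downstream of a
co-phased frameshift is marked `expressed = false` (present in the
genome, absent from the protein, hence non-actionable). Annotation is
codon-aware against user-supplied transcript models with HGVS-p-style
3-letter names; the full HGVS grammar is out of scope.

Indels whose span sits within one read length of an amplicon end — where
one read orientation terminates inside the event (distance < read length
and distance + length > read length − 20 bp margin) — are exempted from
strand-bias filtering and marked "realignment recommended" instead of
being dropped.

Final filtering keeps a call when its gene is in the configured target
set and AF clears the sample's cutoff, or, for all other panel genes
(where only major clones matter clinically), when AF ≥ 10%. Non-recurrent
calls confined to degraded samples are presumed artifacts and dropped.
The filter is idempotent.

## Copy number

Coverage rows (samples) are scaled by their median amplicon depth — a
library-size factor deliberately robust to focal amplification: scaling
by the row *total*, the obvious alternative, lets one strongly amplified
gene (e.g. 17.6× across 8 of 212 amplicons, +63% of total) deflate every
other gene in that sample and compress the estimate itself. Columns are
then divided by their across-sample median; fully dropped-out amplicons
are removed with a warning. For each (sample, gene), B = 1000 bootstrap
replicates resample the other samples with replacement; the replicate
fold is the mean over the gene's amplicons of sample depth divided by
the replicate's per-amplicon background *median* (again robust: a mean
background would let amplified samples elsewhere in the cohort
contaminate the pseudo-control). The reported fold is the median of the
bootstrap distribution — guaranteed to lie inside the 2.5/97.5-percentile
CI — and a call is significant when the CI excludes 1 *and* the fold is
beyond 1.5× in either direction; the numeric gate is ours and
configurable. Within-chromosome normalization divides the sample's
target/reference mean-depth ratio by the across-other-samples median of
the same ratio, cancelling whole-chromosome and sample-wide effects;
reference genes flagged amplified trigger a contaminated-baseline
warning.

## Synthetic cohort generator

The generator emulates the statistical structure of a 26-sample FFPE
amplicon cohort: four degraded libraries at 1.0–1.3 ng/µl, the rest
log-spaced from 1.9 to 12; artifact burden from the lambda(c) model
above; substitution classes drawn with 0.44 joint mass on C>T/G>A and
the remainder uniform; low-AF artifacts from the truncated Beta; a
high-AF component (Beta(2, 2) rescaled onto 9–20% AF, negative-binomial
count with mean 30) only in samples below the 1.5 ng/µl trigger; five
recurrent C>T artifact hotspots in ~55% of samples; a planted set of
somatic singletons (including a 4%-AF hotspot below the 10% floor) and
shared germline variants; one fully phased frameshift+missense pair; and
EGFR (5.7×, 17.6×) and MET (1.65×) amplification events in the coverage
matrix. Coverage is mean depth × per-sample × per-amplicon × per-cell
lognormal factors (σ = 0.1 each) with 0.5% dropout. All draws flow from
one seeded generator, so identical config + seed is bit-reproducible.
Truth labels live in a sidecar TSV, never in the VCFs.

What the generator does **not** emulate: base-level reads (no FASTQ,
qualities or alignment), sequence-context (trinucleotide) signatures,
PCR duplicates, tumor purity, or caller-specific error modes. Passing
tests therefore demonstrate that the post-processing logic is correct
under the modelled statistical structure, not that the pipeline's
thresholds are optimal for any particular instrument or fixation
protocol.

## Numerical and design choices

- Coordinates are 1-based inclusive internally (VCF convention); BED is
  converted at the boundary. Gene→chromosome mapping comes from the
  panel manifest so synthetic mini-genomes need no genome build.
- The demo panel allocates 212 amplicons over 48 genes (EGFR 8, MET 5,
  the rest 4–5) at synthetic coordinates; the mini-genome reference is a
  position-hashed deterministic sequence.
- Merged-variant normalization trims shared suffix/prefix and left-aligns
  within the supplied reference window; parents are recorded for audit.
- Rank ties get average ranks; AF bins are half-open (low, high] so a
  boundary AF of exactly 10% counts as low.
- Problem sizes in the test-suite replicate checks (100 seeded cohorts;
  B = 1000 bootstrap; one test sample per null seed) were chosen as the
  smallest sizes at which the binomial/bootstrap error bands in the
  corresponding assertions are meaningful.

## Known limitations

- The cutoff construction assumes the artifact AF distribution is shared
  across samples; only the burden scales with concentration.
- Protein annotation handles single-transcript, CDS-only models; splice,
  UTR and multi-transcript effects are out of scope.
- The bootstrap CI is a percentile interval; no BCa correction.
- Germline discrimination is only as good as the offline frequency table
  supplied; absent entries default to frequency 0 (never auto-germline).
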