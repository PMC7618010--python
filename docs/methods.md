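# Methods

## Problem setting

Tumors inactivated by a pathogenic frameshift or stop-gain lesion in a
homologous-recombination gene respond to PARP inhibition and then, under drug
pressure, frequently acquire *reversion* events that restore protein function.
`revtrace` detects and classifies these events in targeted-panel reads from
serial plasma (ctDNA) samples, summarizes their dynamics, relates emergence to
survival, and — for tumors whose lesion is a homozygous deletion, which cannot
revert — quantifies the selection of copy-retaining subclones from whole-genome
BAF/logR tracks.

## Reversion detection

**Representation.** Coordinates are 1-based inclusive; indels use VCF anchored
representation and are left-aligned (the standard normalization loop) before
any comparison. Left-alignment makes event identity and microhomology calls
deterministic inside repeats; reversion identity across timepoints is exact
left-aligned (pos, ref, alt) equality.

**Candidate discovery.** Reads that are exact substrings of the reference or
pathogenic haplotype carry no new information and are skipped. The rest are
infix-aligned to a local reference window with affine gap penalties (match +1,
mismatch −2, gap open −6, extend −0.2, free end gaps on the reference window
only). Affine gaps matter twice: unit-cost edit distance shatters long
deletions into spurious fragment pairs, and it can rewrite a double
substitution as an indel pair, which would corrupt codon pileups. Indels seen
in ≥ 3 reads become candidates.

**Haplotype enumeration.** Candidates combine with the pathogenic lesion into
target haplotypes: reference, pathogenic, every pathogenic-plus-combination of
≤ 2 events whose net length change (with the lesion) is 0 mod 3, and
pathogenic-spanning deletions with net change 0 mod 3 on their own. Two events
per haplotype keeps enumeration polynomial and covers the reported complex
class. A restored haplotype must show no stop codon in the restored frame
between the lesion and the window end (the operational meaning of "functional
reading frame"); distinct event sets that produce an identical haplotype
sequence (alternative decompositions in repeats) are collapsed so reads are
never split across indistinguishable targets.

**Read assignment.** Each read is scored against each haplotype with a
quality-masked penalty: mismatches at bases with phred ≥ 20 and all alignment
gaps count; lower-quality bases are ignored. The read goes to the unique
minimum-penalty haplotype. Ties are resolved by parsimony: when one tied
haplotype's event set is a subset of every other's (a read consistent with the
pathogenic haplotype and with a reversion haplotype whose extra event it does
not cover), the read supports the least-specific haplotype; ties without a
subset relation stay unassigned, so ambiguous evidence never supports a call.
A strict ties-to-unassigned rule was tried first and discards nearly every
pathogenic-haplotype read once several reversion haplotypes exist, deflating
every denominator; the subset rule keeps the conservative property that
matters (no ambiguous support for any reversion call) without that artifact.
Support for a reversion haplotype additionally requires overlapping one of its
events with ≥ 15 aligned nucleotides.

**Calling.** One call per frame-restored haplotype with ≥ 3 supporting reads
(the false-positive floor); class deletion/insertion/complex by event
composition, `stopgain_substitution` for codon replacements. Allele fraction
is supporting reads over all assigned reads at the locus; it understates the
clone fraction by the probability that a clone read covers the event, which is
acceptable for monitoring and is exactly measurable against truth labels in
simulation. Samples whose overall realigned-read percentage is below 0.9 % —
interpreted as percent of reads, following the tool parameter it mirrors — are
flagged, not filtered; baseline-timepoint calls are reported with a flag
rather than suppressed. Stop-gain reversions are called from codon-level
pileups (reads covering all three positions): any codon that is not a stop,
not the reference, not the pathogenic codon, with ≥ 3 reads.

**Microhomology.** For left-aligned deletions of ≥ 2 nt, the MH length is the
longer of two junction comparisons — the deleted sequence's 5′ end against the
retained sequence immediately 3′ of the deletion, and its 3′ end against the
sequence immediately 5′ — capped at the deletion length; 2–6 nt is flagged
MMEJ-consistent. Single-nucleotide deletions are not evaluable.

## Synthetic cohort

The generator produces inputs with the statistical structure the analysis
assumes, not a sequencing-machine emulation:

- **Locus**: random sequence at a target GC with no frame-0 stop codon, like a
  CDS-centred window; the frame-restoration check needs an open downstream
  frame, which a uniformly random sequence cannot provide.
- **Reads**: amplicon-style single-end 150 nt reads that all cover the
  variant-site anchor, at the panel's raw depth (default 4,600×); substitution
  errors only, at a uniform rate (indel errors are deliberately absent so
  truth labels stay unambiguous). Per-base qualities are drawn in 28–40.
- **Reversion events**: mixture of deletions, insertions and two-event complex
  combinations in the proportions observed in panel cohorts of this kind
  (82:10:22); a configurable fraction of deletions is drawn from junctions
  with 2–6 nt microhomology. Events are placed close to the pathogenic site
  but at least 8 matching bases away from its footprint: an indel flush
  against the lesion collapses with it into a substitution-like difference on
  the haplotype, which is a different (and for an indel caller, invisible)
  variant class.
- **Trajectories**: the pathogenic clone decays exponentially to a nadir
  (default day 56, at 1 % of the initial AF) and regrows logistically;
  reversion clones grow logistically from their birth times. The dynamics are
  shown but not parameterized in the literature; logistic growth is the
  standard minimal clone model. Observed AFs are binomial at the detection
  depth by construction.
- **Survival**: piecewise-exponential inversion of
  λ(t) = h₀·exp(β·count(t)) with independent exponential censoring.
- **BAF/logR tracks**: per-bin Gaussian noise around the closed-form mixture
  signal, with bins randomly flipped around 0.5 to emulate unphased germline
  alleles. Default noise (BAF sd 0.03, logR sd 0.15 per 10 kb bin) is chosen
  to match ~60× whole-genome coverage with realistic overdispersion.

What the generator does *not* model — GC-dependent coverage, indel sequencing
errors, fragment-length biases, germline SNP spacing, contamination — bounds
what passing tests show: the pipeline is correct and well-calibrated under the
assumed noise structure, not validated against platform artifacts.

## Longitudinal summaries and rates

Shannon diversity uses supporting-read counts as proportions (reads are the
directly observed quantity) and natural logs; 0 or 1 call gives H = 0.
Per-patient reversion rates come from a Gaussian LMM on counts over months
(1 month = 30.44 days) with per-patient random intercept and slope, fitted by
maximum likelihood (ML, not REML, so log-likelihoods compare across
fixed-effect structures); per-patient slopes are the fixed slope plus the
empirical-Bayes (BLUP) deviation. The count response is treated as Gaussian,
matching the linear-model convention for these rates; no Poisson variant.
Exactly linear per-patient data (zero residual) is a likelihood boundary the
optimizer cannot reach; it is detected and the exact σ²→0 limit (per-patient
least squares) returned.

## Survival modeling

The reversion count enters as a right-continuous step covariate in
(start, stop] counting-process form; covariate updates use only samples drawn
at or before the chosen cycle, and the pipeline truncates covariate records at
each endpoint's event time. The Cox partial likelihood with Efron tie
correction is maximized by Newton–Raphson with step-halving to |Δβ| < 1e−8;
monotone likelihood is detected and the coefficient capped at ±15 with a
warning. The fit is a fixed-effect time-varying Cox model: with one event per
patient a per-patient frailty is weakly identified, so the random-effect
variant is deliberately out of scope. Proportional hazards use the
Grambsch–Therneau global score test on Schoenfeld residuals against
KM-transformed event times, with the average information substituted for the
per-event variance. Landmark KM groups patients by the covariate known at the
landmark cycle (default C4D1 = 16 weeks under 28-day cycles), with time
measured from treatment start. Kendall's τ-b (scipy, asymptotic p) is computed
on observed times with censored observations included as-is and flagged — the
convention for small cohorts with near-complete follow-up.

## Copy-number mixture model

Segmentation is an exact O(n²) dynamic program minimizing summed
within-segment squared error over all sample × {BAF, logR} channels plus
penalty × breakpoints (default penalty 15), with breakpoints shared across
samples; bins are winsorized at 3 MAD and channels standardized so BAF and
logR weigh equally. The locus mixture fixes state 1 to (0,0) and grid-searches
state 2 (total copies ≤ 4) with the fraction f optimized continuously per
state; confidence intervals resample bins.

Two numerical choices matter. First, the observed BAF summary is the band
deviation δ of the symmetric two-component mixture {0.5 ± δ}, estimated by EM:
folding noisy bins and averaging biases the deviation upward by E|noise| when
the true δ is small, which systematically promoted spurious unbalanced states.
Second, states with all-equal or all-A allele content are observationally
equivalent along shared (n̄, BAF) manifolds (e.g. (1,0) at f and (2,0) at
(1+f)/2); a small complexity penalty (10⁻³ per copy) breaks these near-ties
toward the lowest total copy number, which also prevents boundary noise from
promoting a higher-copy equivalent.

Samples at purity ≤ 10 % are marked non-evaluable, mirroring the
tumor-fraction inclusion rule for cfDNA copy-number analysis. f ≥ 0.95 (or
≤ 0.05) is labelled clonal — the literature reports clonal/subclonal calls
without a numeric cut, so the threshold is a recorded package choice. Ploidy
reconciliation: when two samples' rounded ploidies disagree, the lower
goodness-of-fit sample is re-fitted over a ±0.6 ploidy window around the
better sample's solution (the window width is not stated anywhere; ±0.6 is a
recorded choice). Genes take the state of the majority-overlap segment; BED
input is 0-based half-open, converted at the boundary; a segment log₂ ratio
below −2 flags a deep deletion.

## Problem sizes

Defaults keep every check cheap on one CPU: demo cohorts use 4–6 patients at a
few hundred reads per sample; statistical calibration uses 100 replicates for
slope and hazard-ratio recovery, 500 for the Wald type-I error, a 45-point
(ρ, ψ, f) grid for clonality, and 200-bin instances against the exhaustive
segmentation oracle. Full-depth (4,600×) detection runs in about a second per
sample.

## Known limitations

- No intronic/splice reversion modeling and no de-novo SNV calling outside the
  window; candidate discovery sees only events present in reads.
- A secondary event flush against the pathogenic indel (net substitution) is
  outside the indel caller's class; the generator excludes the configuration,
  and real delins reversions of this shape would need a substitution-aware
  candidate step.
- Allele fractions are support-read fractions, biased low by event-coverage
  geometry; truth tables quantify the bias in simulation.
- The mixture model is locus-level with two states; genome-wide haplotype
  phasing and > 2-state deconvolution are out of scope.
- Kendall τ ignores censoring; with heavier censoring a survival-aware rank
  statistic would be needed.
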