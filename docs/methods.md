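# Methods

## The assay and its in-silico model

The sexing assay is a single TaqMan-MGB reaction: one primer pair flanking
a 74 bp amplicon of the Zinc-Finger gene (present on both X and Y) and two
allele-specific 13 nt MGB probes, ZFX on VIC and ZFY on FAM, differing at
two of their thirteen positions. Two design features carry the
specificity and are what the `sequences` module checks in silico:

1. the final 3′ base of the forward primer is a G in all elephantine taxa
   but an A in most other mammals (including humans), so priming-site
   scans enforce an exact 3′-terminal anchor (default: the single last
   base) on top of a total mismatch budget;
2. MGB probes are treated as fully specific: probe binding is predicted
   only on an exact, ambiguity-free match of the probe (or its reverse
   complement) inside the amplicon. A single mismatch in the probe window
   — the canid-ZFY situation — predicts amplification without fluorescent
   detection.

Amplicon lengths are reported inclusive of both primers (hence 74 bp for
the reference design); coordinates are 0-based half-open internally.
IUPAC ambiguity codes are accepted on references only; they satisfy primer
compatibility but never count toward probe binding (conservative signal
prediction). Melting-temperature/thermodynamic modelling is out of scope;
the published Tm values are metadata.

The true flanking sequence of the locus is not bundled; tests build
synthetic templates by construction (primer + insert + reverse-complement
primer), which exercises every code path without claiming the real
genomic context.

## Quantification

Cq uses the single-threshold method, per dye: the threshold is 10% of the
mean plateau fluorescence of the run's positive wells for that dye.
FAM and VIC get separate thresholds because the FAM probe's response runs
substantially higher than VIC's. Choices that the instrument literature
leaves open are declared here and configurable:

- baseline = mean of cycles 3–10, subtracted per trace;
- plateau = mean of the last 5 cycles of the baseline-subtracted trace;
- a well qualifies as positive for threshold averaging when its plateau
  exceeds a 100 RFU noise floor (aligned with the calling threshold);
- the crossing is linearly interpolated between bracketing cycles; with
  noisy multi-crossing traces the first crossing wins (warning logged).

The standard curve is ordinary least squares of Cq on log10(nominal
copies); nominal standard copies are treated as exact (Poisson degradation
of standards is a simulator option, not a fitting concern). Efficiency is
`10^(−1/slope) − 1`; the inverse transform gives absolute copies per
reaction, with extrapolation outside the fitted Cq range allowed and
flaggable via the stored fit range.

## Genotype calling

Endpoint rules on the final cycle: an allele is detected iff its channel
has a Cq AND its final RFU ≥ `detect_rfu` (default 100). Both → XY,
one → XX or YY, no Cq anywhere → negative, a Cq without a detection →
inconclusive. The inconclusive category is load-bearing: in a 40-cycle
run, low-copy wells cross the threshold late and never approach plateau,
so their endpoint fluorescence is non-discriminant; treating them as
absent would silently convert low-template males into females. The
allele↔dye mapping (X→VIC, Y→FAM) is explicit configuration, never
inferred. NTCs and extraction blanks must be negative; any positive
control marks the whole run contamination-suspect.

## Dropout model

For a true heterozygote amplified from U total Zinc-Finger copies per
reaction, the per-reaction dropout probability is

- calibrated (default): `P_XX(U) = 2^−(U/2 + 1)`. This closed form is an
  empirical calibration against the published mammoth cohort: recomputing
  every specimen's `(P_XX)^n` from its printed mean total CN and
  discriminant replicate count reproduces all ten non-floored printed
  risks at one-decimal-percent precision (a mandatory test). It is an
  empirical match, not a mechanistic derivation, and is flagged as such.
- poisson: each allele enters the tube as an independent Poisson(U/2)
  draw; conditional on the reaction containing any template, the
  probability that exactly one allele is present simplifies to
  `2/(e^(U/2) + 1)` (limit 1 as U→0).

Both are strictly decreasing in U; the calibrated form is bounded by 1/2
(at U=0 one of two alleles is always "the" survivor), while the Poisson
form exceeds 1/2 below U≈3.5. The two are never mixed within a run; the
simulator exposes both as outcome models so their disagreement at low U is
testable rather than hidden.

The specimen-level false-female risk is `(P_XX)^n`, with U the mean of
per-reaction total CN over positive reactions and n the number of
discriminant replicates. A per-replicate-U product variant was
considered and rejected as the default: only the means are published, and
the means reproduce the published risks. Rendering follows the cohort
table: one-decimal percent, floored at "<0.1%", "na" when n=0.

## Consensus

Decision order per specimen: no discriminant replicate → undetermined;
≥2 Y-bearing replicates (XY or YY) → confirmed male, with YY interpreted
as X-dropout and co-occurring XX as Y-dropout; exactly one Y-bearing
replicate → putative male (random contamination cannot be excluded);
all-XX → female, confirmed only when `(P_XX)^n` < 1% (configurable).
Inconclusive and negative replicates count toward neither n nor
Y-evidence. Known-sex specimens are validation fixtures: a mismatch
raises a flag, never a changed call. The published cohort's aggregate
male count is internally ambiguous in the source material; the package
asserts the per-specimen decisions and the female/consistency tallies,
not a cohort male total.

## Simulator

The generator's defaults are the study conditions: triplicate reactions,
40 cycles, 98% efficiency, Cq 38.0 at one copy, FAM plateau 1000 RFU vs
VIC 700 RFU with lognormal sd 0.10, additive baseline noise sd 2 RFU, Cq
noise sd 0.15 cycles, and specimen mean total CN drawn lognormally
(median 20 copies, log-sd 2.0 — spanning roughly 0.5–1000, three orders
of magnitude). `sex_ratio` is the probability a specimen is male
(default 0.5). Each run carries per-dye standard series (1e5→1 copy,
triplicate at the lowest level), two NTCs and two extraction blanks.

Traces are logistic with growth rate ln(1+efficiency) per cycle,
calibrated so the 10%-of-plateau level is crossed at the target Cq; a
crossing within a few cycles of the end therefore yields a low endpoint
RFU, reproducing the inconclusive phenotype mechanically. Molecule
counts are Poisson per allele; standards carry nominal copy labels by
default (a `poisson_standards` flag enables degraded standards for
robustness studies).

What the simulator does not emulate: PCR inhibition, probe crosstalk,
multiplex competition, fragment-length-dependent degradation, or
plate-position effects. Passing end-to-end tests therefore demonstrate
correctness of the analysis logic under idealized stochastic kinetics,
not robustness to every real-world artifact.

One known tension in the source material is deliberately left visible:
sensitivity experiments report all reactions positive at two nominal
template copies, whereas Poisson sampling at mean 2 predicts ~13.5% empty
tubes; nominal dilution labels and realized molecule counts are not the
same thing, and the simulator models the latter.

## Numerical and testing choices

- Problem sizes: Monte-Carlo checks use 1e5 reactions for dropout-curve
  agreement (3 conservative binomial s.e.), 1e4 batches for the
  low-template modal-positives check, 4000 simulated males for the
  false-confirmed-female bound, and a 50-specimen 384-well cohort for
  end-to-end recovery.
- The pooled dropout estimator counts each detected allele as a trial for
  its counterpart's dropout; within-reaction trials are negatively
  correlated, so the independent-binomial standard error is conservative.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  configs produce byte-identical plates.
- `replicates_needed` guards the `ceil(log(target)/log(p))` computation
  against floating-point edge cases with an explicit minimality check.
- Absent Cq is encoded as an empty field in the endpoint dialect (0 and 40
  are legal cycle values); parsers never coerce absence to a number.

## Known limitations

- The calibrated dropout curve is an empirical closed form; outside the
  calibration range (U beyond ~900 or heavily inhibited reactions) only
  its monotone-decay behaviour, not its exact values, should be trusted.
- The endpoint dialects are defined by this package (instrument export
  schemas vary); a mapping from a specific instrument is the user's
  responsibility.
- Consensus assumes replicates are independent amplifications of the same
  extract; cross-extract reconciliation and contamination modelling beyond
  the dropout class are out of scope.
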