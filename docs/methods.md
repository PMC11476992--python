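# Methods

## The analysis problem

During emmetropization — the first weeks after hatching, when the chick
eye elongates to match its optical power — the vitreous humor changes
composition. The workflow implemented here quantifies those changes in
two arms:

* **Discovery (SWATH-MS / DIA).** Vitreous from all animals of one age
  is pooled per eye (one right-eye OD pool, one left-eye OS pool) at
  days 7, 14, 21 and 28 post-hatch, and each pool is injected three
  times (24 injections). Fragment-ion (transition) peak areas extracted
  against an ion library are rolled up to peptide and protein areas,
  normalized across injections, and screened for differential
  expression against the day-7 baseline.
* **Validation (MRM-HR).** A short panel of candidate proteins is
  re-quantified in individual animals (n = 4 per day, one random eye
  each) at days 7 and 14, normalized to GAPDH, and tested with unpaired
  t-tests.

Because pooling destroys biological replication in the discovery arm,
no per-protein variance exists there and no p-value is computed: the
screen is a fold-change filter whose error control comes from requiring
*bilateral concordance* — the two independently processed eye pools
must both pass the cutoff in the same direction. This is documented
prominently: the discovery arm involves **no hypothesis test and no
multiple-testing correction**; those belong to the validation arm only.

## Roll-up (DIA arm)

Transition areas are summed to peptide areas (top 6 transitions by
area, ties broken by fragment label) and peptide areas to protein areas
(top 10 peptides, ties by peptide string), after filtering the ion
library to ≥ 90% peptide confidence and removing peptides mapping to
more than one accession. Identification FDR is treated as a property of
the library produced upstream; no decoy machinery exists here. Empty
input at any level yields a *missing* value, never zero — zeros are
meaningful measurements and must survive round-trips.

The per-protein supporting-peptide count feeding the ≥ 2-peptide filter
is, by default, the number of distinct peptides quantified for the
protein in any injection (capped at 10), mirroring how vendor pipelines
treat the count as a library-level property. A conservative alternative
(`peptide_count_stat="min"`, the minimum over injections where the
protein is observed) is exposed in `RollupConfig`; note that with 24
injections it disqualifies most 2-peptide proteins under even a few
percent missingness, which is why it is not the default.

## Most-likely-ratio normalization

Loading and spray variation multiply every area of an injection by an
unknown factor. Since most proteins are unregulated, the per-protein
log2 ratios between an injection and a reference column pile up at the
log factor; the "most likely ratio" is the mode of that distribution.
The estimator here: Gaussian KDE with Silverman bandwidth, evaluated on
a 512-point grid spanning [min − 1, max + 1] of the observed ratios;
the factor is 2^mode. Below 50 shared proteins the mode is unstable and
the estimator falls back to the median, flagged in the result. A
numerically degenerate ratio set (spread < 1e−9) short-circuits to its
exact value, since the KDE bandwidth would underflow. The default
reference is a per-protein median pseudo-sample; a named injection can
be pinned instead (its factor is then exactly 1). With the
pseudo-reference, factors are identified only up to a common scale, so
recovery is assessed after centering the log factors.

The vendor tool that performs this normalization in practice does not
publish its algorithm; this estimator is the package's own documented
choice, not a claim of bit-identity.

## Differential-expression filter

Per eye, FC = mean over technical replicates at the contrast day /
mean at day 7 (arithmetic mean by default; median available). A protein
is UP when both eye FCs ≥ 1.5, DOWN when both ≤ 0.7, else not called.
The asymmetric cutoffs (0.7, not 1/1.5) follow the published filter and
are configurable. Proteins with fewer than 2 supporting peptides are
excluded. The reported "AVE FC ± SD" uses the two-value sample standard
deviation |a − b|/√2, which reproduces the published spreads; display
rounding is half-away-from-zero to 2 decimals, but all assertions are
numeric with a ± half-rounding-unit tolerance. Cross-timepoint
intersection keeps proteins called in every contrast with the same
direction throughout. Heatmap summaries standardize each protein row to
(area − row mean)/row sample SD; rows observed once or with zero
variance are emitted as zeros and flagged rather than standardized.

One caveat established while validating against the published table:
an SD re-derived from eye FCs printed at 2 decimals carries up to
0.01/√2 ≈ 0.007 error from the inputs' own rounding (one published row
prints eye FCs 0.54/0.55 with spread 0.00, meaning the unrounded values
were nearly equal). Tests therefore hold means to ± 0.005 and spreads
to ± (0.005 + 0.01/√2).

## Targeted arm

Transitions with S/N below 20 are discarded (inclusive: snr ≥ 20 is
kept; a strict > gate is a config flag, and boundary rows are rare).
Peptide intensity is the *mean* of the top-3 surviving transition
areas; protein intensity the mean of the top-3 peptide intensities —
deliberately different from the DIA arm's sums, matching the two arms'
respective processing conventions. When fewer than k items survive, the
mean of the survivors is used. Each protein is divided by the GAPDH
intensity of the same injection, which removes per-injection scale
exactly (a global scaling of one injection provably changes nothing
downstream); GAPDH missing in any injection is a hard error naming the
injection. Fold change is the day-14 group mean over the day-7 group
mean, and significance comes from a pooled-variance Student t-test
(Welch by flag) at α = 0.05, reported per protein without multiplicity
correction. Zero pooled variance is flagged as degenerate, with no
p-value fabricated.

Transition-list construction for acquisition filters candidate
fragments to y/b ions, fragment charge 1, precursor charges {2, 3},
keeps the 5 most intense per peptide (ties by m/z ascending), and
reports peptides with no qualifying fragment.

## Synthetic data

The simulator generates the study design with known truth so every
stage is testable without deposited raw data. Signal model per
transition area:

    area = 2^(baseline_p + offset_pep + effect(p, day, eye) + bias_inj)
           × fraction_t × noise

with protein baseline ~ N(17, 2) in log2 (arbitrary intensity units),
fixed peptide offsets ~ N(0, 1), fixed per-peptide Dirichlet(1, …, 1)
transition fractions, per-injection bias ~ U(−1, 1) log2 applied to
every area of the injection (exactly what MLR must remove), and
mean-one log-normal noise at CV 0.10 per observation. Pooling is
simulated by sharing one biological abundance per (protein, day, eye)
across technical replicates; the targeted arm replaces it with
per-animal variation at CV 0.20. Effects: 10% of proteins are
differentially expressed with per-day log2 magnitudes ~ U(0.8, 2.5),
one sign per protein shared by both eyes plus per-eye jitter
(SD 0.10 log2); 5% are *decoys* with opposite signs in the two eyes,
built specifically to be rejected by the bilateral filter; the rest are
null. One null protein is the housekeeping analog "GAPDH", pinned to a
high baseline (mean + 1 SD) because a housekeeping standard is by
definition abundant and stable. Peptide-level dropout is abundance
dependent, P(miss) = logistic((12 − log2 area)/1.5), giving ~5%
missingness concentrated in low-abundance proteins; replicate CVs and
missingness rates of the real study are unreported, so these are
explicit config choices, not estimates. Targeted-arm S/N is area over a
noise floor placed so that 10% of transitions fall below 20.

A single master seed expands into per-component substreams
(structure, truth, library, SWATH noise, MRM-HR noise), so the two arms
share matched truth and either can be regenerated independently;
identical configs give byte-identical tables.

What the simulator does *not* model: chromatographic peak shape,
retention time, interference, shared peptides between accessions,
search-engine behavior, or the day-4 baseline (no proteomics was done
there). Passing tests therefore demonstrate the pipeline's correctness
and calibration under the stated generative model, not performance on
real spectra.

## Problem sizes and numerical choices

End-to-end checks run at 1,000 proteins × 24 injections (~1.1 M
transition rows) for normalization and filter recovery; Monte-Carlo
calibration of the targeted arm uses 1,000 simulated cohorts for the
null rejection rate (binomial 95% interval around 0.05) and 200 cohorts
for recovery of a spiked twofold change, at 50–200 simulated proteins
per cohort — sizes chosen to put Monte-Carlo error well below the
effects being measured. Determinism everywhere: top-k ties broken
lexically, canonical sort order on write (two writes of the same
records are byte-identical), and all randomness flows from explicit
seeds.

## Known limitations

* The MLR estimator is a documented stand-in for an unpublished vendor
  algorithm; factors match simulation truth, not vendor output.
* Protein inference is unique-peptide mapping only; shared peptides are
  dropped, never apportioned.
* The discovery arm's published dataset-level counts (library size,
  per-contrast DEP counts, 92% vs 27% quantifiable fractions) depend on
  deposited raw spectra and search engines and are out of scope; the
  package reproduces their direction-level analogues on the simulator.
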