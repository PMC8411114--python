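# Methods

`phoscale` re-implements, as a tested library, the statistical analysis of a
label-free phosphoproteomics time course of homeostatic synaptic scaling:
cultured cortical neurons treated with bicuculline (Bic, down-scaling) or
tetrodotoxin (TTX, up-scaling) for 5 min, 15 min or 24 h, each compared with
untreated controls, in 4 biological replicates injected in 3 technical
LC-MS/MS runs per sample.

## From site table to phospho-events

The unit of analysis is the *phospho-event*: one
(protein accession, residue position, residue, multiplicity) combination.
Site-table rows are

1. cleaned of decoy (`Reverse = "+"`) and contaminant rows;
2. restricted to class-I sites, i.e. modification-site localization
   probability strictly greater than 0.75 (configurable; class II = 0.5–0.75
   and class III < 0.5 tallies are reported);
3. expanded by multiplicity: each `___1/___2/___3` intensity slot that is
   quantified in at least one sample becomes its own event.  Slots never
   quantified produce no event — they could never pass the valid-value
   filter and would only inflate the multiple-testing burden.

Multi-accession protein groups are keyed by their leading accession.  A raw
intensity of exactly 0 is treated as *not quantified* everywhere; no
downstream code observes a raw zero.  No imputation is performed at any
stage.

## Normalization

Event intensities are log2-transformed and each sample's median (over its
quantified events) is shifted to the grand median (median of the per-sample
medians).  After this step every sample's median is exactly equal; the
grand-median re-centering preserves the intensity scale for reporting and
has no effect on fold changes.  One subtlety: shifting a single sample can
change *which* per-sample median is the grand median, so the normalized
output is shift-invariant only up to a common additive constant; fold
changes and all test statistics are exactly invariant.

## The differential test

For each event and condition `(treatment, timepoint)` the pairwise data
matrix holds the treated samples and the same-timepoint controls (up to
4 bio x 3 tech x 2 arms = 24 columns).  Events are tested only if

* (a) every biological replicate has at least one quantified technical
  replicate in the treated arm *and* in the control arm, and
* (b) at least 50 % of the event's designed cells are quantified
  (evaluated against the designed, not the observed, column count, so the
  criterion does not drift with instrument dropouts).

The model is a random-intercept linear mixed model fitted by maximum
likelihood:

    y_ij = mu + beta * 1[treated] + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2),

with the biological replicate as the single random effect; technical
replicates enter as residual-level observations.  `beta` is the log2 fold
change (treated − control).  The treatment effect is tested by a
likelihood-ratio test against the intercept-only null with the same random
effect, both fitted by ML (REML likelihoods are not comparable across
fixed-effect specifications), with the statistic referred to chi-square(1).
No boundary or small-sample correction is applied; the empirical type-I
error at alpha = 0.05 is verified by simulation to lie near 0.05–0.065 for
the 24-observation design.  p-values are Benjamini–Hochberg corrected
within each condition; `regulated` means q < 0.01.

Numerically, for fixed variance ratio lambda = sigma_b^2/sigma_e^2 the
covariance `V = I + lambda Z Z'` is block diagonal over replicates, so
(mu, beta, sigma_e^2) have closed-form GLS solutions and the likelihood is
profiled to a 1-D function of log lambda.  It is maximized over a
log-spaced grid `[1e-8, 1e4]` (25 points) plus the exact lambda = 0
boundary, refined by a bounded scalar minimizer (convergence tolerance
1e-12 on log lambda).  At lambda = 0 the fit coincides with OLS exactly;
when the data contain one observation per replicate, sigma_b^2 and
sigma_e^2 are confounded, the profiled likelihood is flat, and the fit
falls back to the lambda = 0 boundary by convention.  The implementation
agrees with a dense grid-search oracle (explicit V inversion) to 1e-6 and
with the reference mixed-model fitter (lme4, ML) to ~1e-6 on random
datasets, including singular boundary fits.

Events passing the valid-value filter but violating the model's
preconditions (fewer than 2 replicates, a missing arm, n < 4) are reported
as *untestable*, never silently dropped.

## Exclusive events

An event quantified in every biological replicate of exactly one treated
condition, while failing that all-replicates criterion in every other
sample group (all controls included), is *exclusive* to that condition:
it is excluded from statistical testing and reported separately.  A strict
mode additionally requires zero detection outside the condition.  Exclusive
and tested event sets are disjoint by construction.

## Temporal classes and reciprocity

Per treatment, each event's *signature* is the regulated triple over
(5 min, 15 min, 24 h).  The default mapping is

| signature | class |
|---|---|
| (1,1,1) | persistent |
| (1,0,0), (0,1,0), (1,1,0) | early |
| (0,0,1), (0,1,1), (1,0,1) | late |
| (0,0,0) | none |

The mapping is fully configurable; the shipped `expanded_persistent`
preset moves (0,1,1) to persistent (regulated at 15 min and 24 h but not
5 min).  The rare (1,0,1) pattern is mapped to late by default — no total
mapping is forced by the data, and the preset system records the choice.
A timepoint at which the event was not tested contributes a 0 bit and a
preserved `untested` annotation.

Direction per treatment is the common sign of the log2 fold changes at the
significant timepoints (`mixed` if signs disagree).  For each phase, events
in that phase under both treatments form the cross-treatment overlap; an
overlap event is *reciprocal* when its directions are opposite and neither
is mixed.  Events regulated in at least k of the 6 conditions (default
k = 4) feed the combined fold-change clustering.

## Clustering

Fold-change profiles (events x up to 6 conditions, missing where untested)
are clustered on pairwise-complete Euclidean distance,
`d = sqrt(p/m * sum over m mutually observed columns)`, rows with fewer
than 2 observed values excluded with a report.  Agglomeration is ward.D2:
Lance–Williams updates on squared dissimilarities, merge heights the
square roots of the updated criterion, ties broken deterministically by
the smallest cluster index.  Merge heights are verified against a
from-scratch Ward-criterion recomputation and against the scipy
implementation on complete data.

## Kinase-substrate enrichment

Substrate relations (species-filtered, in-silico predictions excluded by
default) are matched on (case-folded gene, residue, position).  When
several events (multiplicities) cover one site, their fold changes are
averaged into one site-level value.  A kinase with m matched sites gets

    z = (s_bar − p_bar) * sqrt(m) / delta,

with `p_bar`/`delta` the mean/SD of all site-level fold changes in the
chosen background, a two-sided normal p, and BH correction across kinases.
The default background is the condition's significantly regulated events
(`regulated_only`); `all_tested` is available for sensitivity analysis.
The minimum substrate count defaults to 1.

Gene-set overrepresentation is the classical hypergeometric upper tail on
user-supplied GMT sets, run separately for proteins with up- and
down-regulated events, with the detected phosphoproteome (proteins with at
least one quantified event) as background.

## Synthetic data

The generator emulates the study design at the level the pipeline
consumes.  Log2 intensity of event e in sample s is
`baseline_e + b_{e, bio(s)} + Delta(condition(s), profile_e) + eps_{e,s}`,
with one random intercept per (event, biological replicate) shared across
all samples of that replicate — this makes the paired treated/control
design informative exactly as the fitted model assumes — and defaults
baseline ~ N(23, 2), sigma_b = 0.25, sigma_e = 0.2, |Delta| ~ U(0.5, 1.5).
Effect profiles are step functions: early (5/15 min), late (24 h),
persistent (all), persistent-reciprocal (persistent, signs flipped between
treatments), exclusive (present in all replicates of one condition, at
most 3 elsewhere), null.  Missingness is MCAR (rate 0.02) plus an
intensity-dependent MNAR component `P(missing | y) = 1/(1 + exp((y −
y0)/s))` with y0 = 20, s = 1 — roughly 5 % dropout at the baseline mean,
steeply increasing below it, a realistic shape for MS detection limits.
85 % of rows are class I; ~1 % each decoy (`REV__`) and contaminant
(`CON__`) rows are spiked in.  The default scale (500 proteins, ~3 sites
each, ~2,000 events) runs the full pipeline in well under 5 minutes on one
CPU; tests and the acceptance script use 25–120 proteins (roughly 200–500
events) to keep the default suite fast.

What the generator does *not* emulate: peptide sequences and spectra,
retention-time effects, correlated multi-site phosphorylation, LFQ
ratio-compression, batch structure beyond the replicate intercept.
Passing recovery tests therefore demonstrate correctness of the statistics
under the model's own assumptions, not robustness to every artifact of
real MS data.

### Evaluation definitions

* *Sensitivity / empirical FDR* per condition count tested events whose
  planted effect at that condition is nonzero.
* *Temporal-class accuracy* is reported twice: over all detected events,
  and over events whose three timepoints were all actually tested.  A
  signature bit censored by the valid-value filter carries no class
  information (a persistent event untestable at 5 min necessarily reads
  (0,1,1)); such events retain their `untested` annotation in the output
  and are scored separately.  Recovery claims use the fully-informed
  metric; both are emitted.
* *Reciprocity recall* is computed over planted reciprocal events testable
  in all six conditions — events the statistics could possibly call.

### A deliberate artifact worth knowing about

Because MNAR censoring preferentially removes down-shifted observations,
treated samples with many strong planted effects have slightly inflated
observed medians; median normalization then transfers a small negative
offset (~0.1–0.3 log2 units) onto null events in those samples, which at
the mixed model's high precision can become significant.  This is a
faithful property of median normalization under intensity-dependent
missingness — present in real data too — not an implementation defect; it
is visible as elevated per-condition empirical FDR in the strong-effect
end-to-end scenario, while the calibration and FDR studies (no structural
asymmetry) meet their nominal levels.

## Known limitations

* chi-square(1) reference for the LRT is mildly anticonservative at 24
  observations (empirical size ~0.055–0.065 at nominal 0.05); no
  Satterthwaite/Kenward–Roger correction is applied.
* One random effect only; no peptide-nested or tech-rep random effects.
* No moderated variance shrinkage across events.
* KSEA matches sites by position + residue; sequence-window matching is
  not implemented (mismatch counts are reported).
* The agglomeration implementation is O(n^3) and intended for the
  hundreds-of-events matrices the k-of-6 selection produces.
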