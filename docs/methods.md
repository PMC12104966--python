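# Methods

This note documents the models implemented in `lynxmon`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter when reproducing results.

## Genetic monitoring (`popgen`)

**Heterozygosity.** Observed heterozygosity Ho is the fraction of
non-missing genotypes that are heterozygous; expected heterozygosity is
Nei's unbiased estimator, He = 2n/(2n−1)·(1 − Σᵢ pᵢ²), computed per locus
from the n genotypes typed at that locus. Missing data are handled by
locus-wise deletion (per-locus n varies) and multi-locus summaries are
unweighted means over loci — the standard treatment for microsatellite
panels. A genotype is stored as an ordered pair of positive integer allele
identifiers; 0 marks a missing pair (half-missing pairs are rejected at
construction).

**Effective inbreeding and fitness projection.** Inbreeding is measured
against the source population as Fe = 1 − H_focal/H_ref with H_ref a
supplied constant (default 0.592, the source-population estimate on the
same marker panel); it is not recomputed because the source sample is not
among the package's inputs. Expected inbreeding depression follows the
lethal-equivalents model δ = 1 − exp(−(2B/2)·Fe) with 2B = 12 diploid
lethal equivalents by default; remaining relative fitness is 1 − δ. A focal
sample more heterozygous than the reference yields a negative Fe: it is
returned (and exported) as-is with a flag, while δ is evaluated at
max(Fe, 0) so the projection stays in-domain. The closed form gives
δ(0.32) = 0.85 and δ(0.19) = 0.68 at two decimals; note that δ(0.08) =
0.3812 rounds to 0.38 — two-decimal outputs at a rounded Fe input can
differ in the last digit from projections made at the unrounded trajectory
value.

**Traveling window.** The window unit is the individual: one genotype per
individual, ordered by sample date with ties broken lexicographically by id
for reproducibility. Window k covers individuals [k·step, k·step+width);
defaults width = 40, step = 1. Each window reports He, Fe, δ and fitness.
With step = width the windows partition the series exactly (tested).

**Scenarios.** The three reinforcement scenarios select nested subsets
before windowing: remnant-only (remnant and unknown-origin animals),
core reinforcement (adds animals translocated to the core area and their
descendants), fully connected (adds the stepping-stone subpopulation).
Translocated animals known to have died before reproducing or to have
dispersed beyond potential mates are removed via an explicit exclusion-list
argument, because that knowledge comes from field records rather than the
genotypes.

**Private alleles and parentage.** An allele is private if it occurs among
candidates and never in the reference sample (a single reference occurrence
disqualifies it); an individual carrying at least one private allele is an
F1 candidate. Parentage is by simple exclusion: a single candidate is
excluded when it shares no allele with the offspring at more than
`mismatch_tolerance` jointly typed loci (default 0; raise it to absorb
genotyping error); a (mother, father) pair is compatible when at every
jointly typed locus, allowing the same number of failures, the offspring's
two alleles can be partitioned one-from-each-parent. Pair compatibility is
verified in the tests against exhaustive enumeration of allele partitions.

## Spatial capture–recapture (`scr`)

**Model.** Detection of individual i at trap j follows the half-normal
encounter model p = p0·exp(−d²/2σ²) with d the distance from the latent
activity center; p0 uses a logit link, σ a log link. Supported covariates:
session (survey year, factor), sex (binary, female reference), camera-site
location type (marking site / forest road / other, marking-site reference)
and a local behavioral response *b* that is trap-specific and permanent
within a session — once an individual is caught at trap j, later occasions
at j use the responded state. σ may depend on sex. Activity centers are
uniform over the state space (homogeneous density; no density covariates).

**State space.** A regular lattice anchored at the minimum trap coordinate
(hence deterministic for a given trap array), keeping cells whose center is
within the buffer of at least one trap; defaults 15 km buffer and 2.5 km
cells, as appropriate for a wide-ranging felid with σ on the order of
kilometers. Estimates are insensitive to buffers beyond ~3σ (tested).

**Likelihood and abundance.** The likelihood is conditional on detection:
each detected individual contributes Σ_s π(s)·Pr(history|s) / p̄, with p̄
the cell-marginal probability of at least one detection under naive
(pre-response) parameters. Occasions are collapsed to per-trap binomial
counts — split into the two behavioral states when *b* is in the model —
which is algebraically exact because detection probability is constant
within a state; the vectorized likelihood is verified against brute-force
enumeration over cells, traps and occasions to 1e−10. Abundance is
Horvitz–Thompson per session and sex stratum, N̂ = n/p̄, and density
D̂ = N̂/area·100 per 100 km². The abundance variance uses the Poisson
(expected-abundance) form n/p̄² plus a delta-method term for parameter
uncertainty, because the estimand is the intensity of the point process
rather than the realized N; confidence intervals are lognormal (delta
method on the log scale). Occasion structure is a user choice; the
generators use 10 binary occasions per session, and real detections can be
binned with any rule before assembly (`io.capture_dataset_from_frames`).
Unknown-sex individuals are not modeled (out of scope); sex must be known
or imputed upstream.

**Optimization.** L-BFGS-B from fixed start values (logit p0 = −2, log σ =
log(half the median inter-trap distance), coefficients 0), convergence at
gradient-norm 1e−5, standard errors from the numeric central-difference
Hessian; a singular Hessian yields missing SEs, never a fabricated value.

**Validation scale.** The parameter-recovery study runs 100 replicates on a
6×6 trap grid at 2.5 km spacing, 7.5 km buffer (3σ), 10 occasions, three
sessions sharing one parameter vector, at true density 1.0/100 km²,
p0 = 0.1, σ = 2500 m — a scaled-down analogue of a regional camera-trap
survey, sized so the whole study runs in well under a minute. Observed:
mean relative bias of D̂ about −3 %, 95 % CI coverage 95/100.

**Season and turnover.** The closure filter keeps detections dated
Aug 15–Feb 15 inclusive and assigns the session to the year of the August
boundary (a January record belongs to the previous year's session); it is
idempotent. Turnover between consecutive survey years is
|S_t ∩ S_{t+1}|/|S_t| on identified-individual sets.

## Kill-site detection (`predation`)

The cluster sweep is single-pass and strictly chronological: the earliest
unassigned fix seeds a candidate; each later unassigned fix joins when it
is within `radius` of the running centroid and within `window` of the
cluster's latest member; the centroid is recomputed after every join; a
candidate with at least `min_fixes` members is emitted and its fixes
retired. Defaults: 200 m, 2 days, 2 fixes. The "2-day window" is
interpreted temporally (maximum gap between a joining fix and the latest
member), the reading consistent with the GLC literature. Members are not
re-checked against the final centroid, so late drift can leave early
members slightly outside the radius — a documented property of the
single-pass rule, not corrected. Ties in time are impossible after
deduplication; duplicate timestamps are dropped keeping the first. The
predicted kill time is the first member fix; feeding time is last minus
first member fix. Kleptoparasitism is a simple proportion of monitored
kills with a bear visit, with a Clopper–Pearson interval. Because the
cluster rule's anchoring details vary between field protocols, absolute
kill counts from real data are not a validation target; the implementation
is instead held to exact agreement with an independent restatement of the
same rule on random tracks, and to ≥90 % recall of simulated kills.

## Survival (`survival`)

Tracking periods carry one of six end statuses. The default policy excludes
disappeared animals (fate unknown) and treats every mortality category as
an event; alternatives keep disappeared animals as censored at last
contact, or count only human-caused mortality (suspected/confirmed illegal
killing, roadkill) as events with natural deaths censored. Two tracking
periods of a recaptured animal enter as independent records. The
Kaplan–Meier estimator uses the standard convention of processing deaths
before censorings at tied times; variances are Greenwood's. Six-month
survivorship is read off the curve at S(183 d). The k-sample log-rank test
accumulates observed-minus-expected event counts with hypergeometric
covariances. Both estimators agree with the lifelines implementations to
1e−10 on random data, and the log-rank test's type-I error is calibrated
(0.034–0.066 at nominal 0.05 over 2000 null replicates).

## Synthetic data (`synthdata`)

All randomness flows from one seed through per-stage `SeedSequence` spawn
keys, so stages can be regenerated independently and identical
configurations produce byte-identical files (manifest with SHA-256
checksums).

**Drift generator.** Source allele frequencies are Dirichlet draws per
locus, resampled until the gene diversity 1 − Σp² is within 0.01 of the
target (default 0.592; 6 alleles per locus, 19 loci). Six founders start a
Wright–Fisher population at effective size 20 for 40 yearly generations —
deliberately fast drift so a 40-individual window resolves the decline
within a short series. Reinforcement is staged: 8 immigrants join the core
breeding pool over 4 generations (and remain in it), the pool stepping up
to size 50, while 12 immigrants found a separate stepping-stone
subpopulation breeding among itself and sampled in every later generation.
Immigrant alleles occupy a disjoint identifier range, so private-allele
detection has known truth. Staged arrival plus pool growth keeps the
immigrant allele mass in the final window moderate and ordered across
scenarios; a single-generation injection was rejected because the admixed
fraction then drifts with high variance (immigrant genes can vanish), and
because heavy admixture makes a window's pooled diversity exceed even a
pure outbred pool, inverting the intended scenario ordering. What the
generator does not emulate: overlapping generations, family structure in
sampling, genotyping error and allelic dropout, mutation, or realistic
lynx generation time — so passing tests demonstrate estimator correctness
on idealized histories, not robustness to laboratory noise.

**SCR sampler.** N ~ Poisson(D·A) activity centers uniform over the state
space, Bernoulli detections from the same half-normal model the estimator
fits (with optional sex and behavioral effects); only detected individuals
enter the dataset, and the truth block retains everything. Matching
generative and fitted models is intentional: the recovery study tests the
estimator, not model misspecification.

**Track generator.** Kills arrive with gamma inter-kill intervals (mean
4.37 d, shape 2) and gamma handling times (mean 2.41 d, shape 2, truncated
below the interval); during handling, fixes sit on the kill site with
uniform jitter below 80 m (under half the cluster radius); between kills
the animal walks a correlated random walk (von Mises turning, κ = 4) with
2 km steps, far beyond the radius, so travel fixes essentially never
cluster (negative control: ≥95 % of no-kill tracks yield zero clusters).
Fix schedules are regular (default 3/day; recall calibrations use 8/day).
GPS measurement error and irregular duty cycles are not modeled.

**Survival generator.** Exponential event times per group with uniform
censoring and a configurable mortality-cause mix; group sizes default to
the monitored cohort sizes (22 translocated, 10 first-generation offspring,
18 remnant) with hazards chosen so group mortality fractions resemble the
monitored ranges.

## Pipeline and formats

All inputs and outputs are plain CSV with ISO-8601 dates; coordinates are
projected meters and no geodesy is performed (the CRS is free-text
metadata). Readers and writers round-trip losslessly (tested). The pipeline
(`report.run_pipeline`, or `lynxmon report --config`) runs whichever stages
have inputs, skips missing stages with a logged warning, rejects unknown
configuration keys, and writes per-stage CSVs plus a plain-text summary;
identical configurations reproduce byte-identical outputs. All
field-protocol constants (40-individual window, 2B = 12, H_ref = 0.592,
15 km/2.5 km state space, 200 m/2 d/2 fixes, Aug 15–Feb 15 season) surface
as named defaults overridable without code edits.

## Known limitations

* SCR: no data augmentation, open-population dynamics, density surfaces,
  telemetry integration, or unknown-sex mixtures; the conditional
  likelihood + Horvitz–Thompson route matches the estimand but is an
  approximation to full-likelihood multi-session software.
* Cluster analysis has no kill/non-kill discrimination beyond the threshold
  rule and no prey-species model.
* Survival offers no Cox regression, competing risks, or frailty.
* Parentage is exclusion-only; no likelihood-based assignment and no
  genotyping-error model beyond the mismatch tolerance.
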