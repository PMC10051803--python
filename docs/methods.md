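# Methods

## The problem

Administrative health records describe a patient with cerebral palsy (CP)
through reimbursed items — assistive devices above all — but not through
clinical motor assessments. The package asks, and answers quantitatively,
two questions: (1) how well can the GMFM-66 gross-motor score (0–100,
interval-scaled) be predicted from the device pattern plus age and CP
subtype, and (2) at what sample sizes does the predicted score (the
Medical Device Score, MDS) still detect a true group difference that the
real GMFM-66 would detect. The GMFCS severity level is never used as a
predictor: it is a clinician-assigned classification that administrative
databases lack, and the whole point is to work without it.

## Data model and preparation

A cohort is one record per patient: age (years), sex, CP subtype
(bilateral spastic / unilateral spastic / dyskinetic / ataxic / mixed),
GMFCS level I–V, GMFM-66, and a set of device codes. Devices pass through
an optional grouping map (code → group, identity by default) and then a
minimum-count filter: devices used by fewer than 5 patients cohort-wide
are dropped from the catalog and from every record — the threshold is
inclusive (count ≥ 5 stays), and patients are never removed. Features are
one binary indicator per retained device (lexicographic order), the
continuous age, and a five-column subtype one-hot. Sex, though carried in
the data model, is not a default predictor. The train/holdout split is a
uniform 70/30 partition with round-half-up sizing (1581 patients → 1107
train / 474 holdout).

## Predictors

Four families: random forest (production model), RBF support vector
regression, a feed-forward net, and gradient-boosted trees (XGBoost). All
receive the identical feature matrix; kernel and neural models run on
standardized inputs. Hyperparameters are the implementing libraries'
defaults — no tuning protocol is part of the method, and the run manifest
records the library versions that define those defaults. The net uses a
single hidden layer sized to the feature count, capped at 32, with
fixed-seed initialization. Predictions are clipped to [0, 100] (the
GMFM-66 range) and flagged when clipping occurred. A zero-variance
training outcome degrades to a constant predictor with a warning.

For any analysis that needs an MDS for *every* patient (the power grid),
the default is cross-fitting: 5-fold out-of-fold prediction, so no
patient's score comes from a model that saw that patient. In-sample
prediction is available behind a flag (`insample_mds`, CLI `--mds-mode
insample`) because it is unknowable whether the original analysis used
out-of-fold scores; cross-fitting is the defensible default since
in-sample optimism would overstate the MDS's power.

## Agreement statistics

Lin's concordance correlation coefficient is computed with n-divisor
(biased) moments, following Lin's original definition; the divisor choice
changes small-sample values, so it is fixed rather than configurable.
Degenerate inputs are resolved explicitly: two constant vectors with equal
means are a 0/0 and raise an error; a pure location shift between
constant vectors gives 0. Confidence intervals for CCC/MAE/RMSE are
percentile bootstrap over whole patient pairs, 2000 replicates by default;
replicates on which a metric is undefined (e.g. a constant resample) are
redrawn and counted, and the rare percentile-method pathology where the
interval excludes the point estimate is flagged. The floor/ceiling
diagnostic reports, per GMFCS level, the signed error mean (MDS −
GMFM-66), absolute error mean, and quartiles of both score sources.

## The power procedure

Two finite populations with a prescribed GMFM-66 mean difference d are
built from the cohort by split selection: k candidate partitions into
equal halves (790 + 790 from 1581; for odd N one uniformly chosen patient
is left out per candidate), and for each target d the candidate whose
realized difference is closest to d, ties broken by candidate order.
Group A is by convention the higher-mean group.

Pure selection cannot reach large targets on a large cohort: the mean
difference between complementary random halves of 790 has a standard
deviation near one GMFM-66 point, so no feasible number of candidates
ever differs by 5–10 points. The selected candidate is therefore refined
by a deterministic minimal exchange: greedy extreme-pair swaps between the
halves while a full swap still undershoots the target, then one
fine-tuning swap chosen by a two-pointer scan to land the realized
difference within 10⁻³ of the target. The refinement preserves group
sizes and is part of the default pipeline (`refine=False` restores pure
selection); the grid records both target and achieved difference. The
selection and the difference are always defined on the *true* GMFM-66
scale — the question is whether each score source detects a difference
that truly exists.

Empirical power for a cell (n, d, source): over `reps` repetitions, draw
n patients per group without replacement, apply the significance test to
the drawn values, and report the rejection percentage. The default test
is Welch's two-sample t-test at α = 0.05 (robust to the unequal variances
that split selection induces); Student's t and Mann–Whitney are
selectable. Within each repetition the *same* drawn patients are scored
with both sources, so the two power columns differ only through the score,
not through sampling noise. When both pools passed to `estimate_power`
are identical (the type-I calibration experiment), 2n values are drawn
without replacement and split in half, making the two subsamples disjoint
and exchangeable — independent draws from a shared pool would overlap and
bias the measured size below the nominal α. Defaults are the full design:
10,000 candidate splits and 10,000 repetitions per cell, both
configurable downward.

An analytic companion, `analytic_t_power`, gives closed-form Welch power
via the noncentral t with Welch–Satterthwaite degrees of freedom; the test
suite uses it (and an independent statsmodels implementation) as the
oracle for the Monte-Carlo estimator.

## The synthetic cohort generator

The study population is available only on request, so the generator is a
first-class, tested component that emulates the published structure of
that population; its defaults are the study conditions, not tuning knobs.

* **GMFCS mix**: categorical with the published level counts
  118/289/592/470/112 (of 1581).
* **Score given level**: Normal truncated to [0, 100] with means
  85/65/50/35/15 for levels I–V and common SD 8 — the published material
  does not report per-level score distributions, so these are assumptions
  chosen to give moderate between-level overlap; they are fully
  configurable and flagged as assumptions.
* **Subtype given level**: the published level-conditional percentages
  (bilateral spastic dominant everywhere; unilateral spastic concentrated
  at level I; dyskinetic at level V), rows renormalized from printed
  rounding.
* **Age**: Normal(8.1, 4.3) truncated to the published range
  [2.2, 25.5] years, independent of level (the published per-level age
  means vary little). Sex: Bernoulli with the published female share.
* **Devices given score**: independent Bernoulli per device with
  probability `base_rate · exp(−(s − center)² / (2 width²))` — each
  device occupies a motor-ability niche. Independence is a simplification;
  no co-occurrence data are published. Empty device sets are legitimate
  and retained (they concentrate at both scale extremes, which is exactly
  what drives the floor/ceiling effect).

The 12-device catalog is calibrated in two steps. Shapes first: niche
centers and widths are set so that the *realized* device-user mean scores
reproduce the four published anchors (therapy bike 71.19 > shoe inserts
61.06 > roller board 30.29 > passive wheelchair 26.20); because the score
mixture pulls user means toward the population center, the anchored
peaks sit beyond their published user means (e.g. the therapy-bike niche
peaks at 84 to realize a user mean near 71). Rates second: each base rate
is solved numerically (trapezoidal integration over the truncated-normal
score mixture) so the marginal usage frequency hits its target; targets
are the published shares with their ordering preserved (transtibial
orthoses 13.2% first, active wheelchair 12.8% second, then posterior
walker, standing frame, night splints; unnamed devices below). The
published percentages are read as shares of prescribed device records
rather than patient-level rates — the publication does not state the
denominator, and patient-level rates summing to under one device per
patient would make the device pattern far less informative than the
published prediction accuracy implies. Patient-level targets are the
shares doubled (≈1.8 devices per patient), which puts the random-forest
holdout concordance near the published value (CCC ≈ 0.73 vs 0.75).

A single integer seed drives all sampling; per-stage substreams are
derived with fixed offsets so stages never perturb one another, and
generation is bit-for-bit reproducible. The shipped YAML
(`mdsc/data/default_config.yaml`) is the exact dump of this calibration
and is verified against the in-code builder by a test.

What the generator does **not** emulate: device co-occurrence structure,
any age–device interaction, longitudinal change (the design is
cross-sectional), item-level GMFM administration, and measurement error
in the GMFM-66 itself. Passing tests therefore demonstrate that the
pipeline's statistics behave correctly under a faithful joint structure —
not that the trained model would reach the same accuracy on real claims
data.

## Numerical choices and problem sizes

Bootstrap: 2000 replicates (1000 in the batch script); percentile
endpoints by linear-interpolation quantiles. Split refinement tolerance
10⁻³ GMFM points. Power cells are vectorized: subsampling by row-wise
argsort of uniform draws, processed in blocks of 2000 repetitions.
The test suite scales the Monte-Carlo down where the full design adds
nothing to the property under test: the monotonicity check runs the full
8×8×2 grid at 1000 repetitions and 2000 candidate splits; the attenuation
and floor/ceiling checks run five independent end-to-end replicates at
500 repetitions; the type-I calibration uses the full 10,000 repetitions.
The batch script runs the complete grid at the full 10,000/10,000 design.

## Known limitations

* The per-level GMFM-66 distributions are assumptions; real cohorts will
  have different overlap, hence different attainable accuracy.
* Device independence given the score understates the redundancy of real
  prescriptions; real-data accuracy could be lower at equal marginals.
* The split-refinement step constructs group pairs the random-division
  candidate pool cannot supply; achieved differences are exact by
  construction, at the cost of groups that are no longer purely random
  partitions (their within-group variances shrink slightly as d grows).
* MAE near 9 GMFM-66 points means the MDS is a group-level instrument
  only; nothing in the package supports individual clinical assessment,
  by design.
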