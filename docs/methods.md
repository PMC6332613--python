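# Methods

This note documents the models, conventions, and design choices behind
`tvindex`: what is computed, which parameters matter, what the synthetic
generator does and does not emulate, and where the genuinely open design
decisions were made.

## The index

For each monitored variable v ∈ {MAP, BIS, MAC}, every retained
measurement x is standardized against the pooled study population:
z = (x − μ_v) / σ_v, where μ_v and σ_v are the mean and *sample* SD
(divisor n − 1) over all retained values of v across all cases. The SD
convention is immaterial at realistic data volumes but is fixed for
reproducibility. Fitting is strictly population-level; per-case
standardization would erase exactly the between-case differences the
index is meant to expose.

Within a case, a *timepoint* is a distinct timestamp at which at least
one of MAP, BIS, or MAC exists (simultaneous recordings share one
timepoint). Timepoints are grouped five at a time in chronological
order into non-overlapping windows; the final window keeps the 1–4
remaining timepoints. Per-variable window means are simple means over
all of that variable's values at the window's timepoints — duplicates
(e.g. two arterial readings at one timestamp) all enter the mean, since
no deduplication rule is defensible without device metadata.

TVI(window) = mean z(MAP) + mean z(BIS) + mean z(MAC), defined only
when all three means exist. Missing data are never interpolated or
carried forward; a window without concurrent data simply has no TVI
value, and a case none of whose windows has a TVI value is excluded
from the study set (logged in the exclusions table). Because window
means are linear, the mean of z-scores equals the z-score of the raw
window mean — an algebraic identity the test suite uses as an oracle
(tolerance 1e-9) and which makes the z-then-average order of operations
equivalent to average-then-z.

### MAC

Total MAC at a timestamp is Σ_agents (end-tidal % / 1-MAC equivalent),
with equivalents isoflurane 1.17%, desflurane 6.6%, sevoflurane 1.8%,
nitrous oxide 105%. MAC is deliberately not age-adjusted. Sums above 3
are artifacts, removed *after* summation (no per-agent bound exists).
Sums ≤ 0.001 are clinically negligible — the anesthetic is considered
not in use — and are dropped from the MAC stream with an audit reason
rather than entering windows as near-zero measurements; treating them
as real measurements would let pure-oxygen periods masquerade as
ultra-deep anesthetic exposure.

### Artifact filter

Strict-inequality limits: MAP retained iff 10 ≤ MAP ≤ 250 mmHg, BIS iff
1 ≤ BIS ≤ 100 (BIS = 0, the monitor attach/detach artifact, falls below
the lower bound), MAC iff ≤ 3. Boundary values are retained. When
arterial and noninvasive MAP coexist at the same timestamp (after
rounding to the reader's precision, default one second), only the
arterial value is kept; the match window is exact timestamp equality
because no wider matching rule is defensible a priori. The filter is a
partition (retained ∪ removed = input) and idempotent; removed rows are
written to an audit CSV with reasons.

## Pattern discovery

Profiles vary in window count, so each is embedded on a fixed grid of
L = 20 positions: window i of W maps to proportion i/(W−1) (0 for a
single-window profile), a present TVI value lands at position
round(p·(L−1)), collisions are averaged, and unfilled positions take the
fill value — 0 by default, i.e. the population-average TVI, treating
missing windows as uninformative (`profile_mean` fill is available for
sensitivity analysis). This embedding is this package's explicit design
choice for vectorizing variable-length profiles; it preserves the
temporal shape that profile heatmaps display while making all profiles
comparable.

Clustering is Euclidean Lloyd k-means, best of 10 seeded starts with at
most 100 iterations (scikit-learn's implementation behind this module's
interface). k = 3 is the canonical analysis; a k-sweep (2/4/5) is
available for exploration. The three clusters are named elevated /
mixed / depressed by ranking their member profiles' pooled mean TVI;
ties are broken by cluster size (larger = more central label) and
logged. No other clustering family is offered — the grid embedding plus
k-means *is* the method under study.

A consequence of zero-fill worth knowing: profiles with few windows have
mostly-zero feature vectors and therefore gravitate toward whichever
cluster has near-zero mean TVI (mixed). Short cases are genuinely
harder to classify under this featurization; the synthetic generator's
duration spread (below) was chosen with this in mind.

## Events and outcomes

Intraoperative hypotension (IOH) is evaluated on *raw measurements*:
any recorded MAP < 55 mmHg. Triple-low-state (TLS) exposure is evaluated
on *window means*: a window qualifies iff its raw-scale MAP, BIS, and
MAC means are all present and strictly below 75 mmHg / 45 / 0.8; the
per-case count of qualifying windows is the cumulative TLS exposure.
The asymmetry (raw vs window means) mirrors the two criteria's clinical
definitions. Raw-scale window means are carried through the pipeline
alongside z-means so thresholds never require back-transformation.

Deaths are classed by postoperative day d: d ≤ 30, 31 ≤ d ≤ 365,
366 ≤ d ≤ 730; later deaths and survivors with ≥ 730 days of follow-up
count as survival beyond 730 days, survivors with shorter follow-up as
unknown. Cluster characterization reports, per pattern: profile and
distinct-patient counts, repeat-surgery/emergent/ASA/sex proportions
(Wilson 95% intervals), mean age and mean MAP/BIS/MAC/z/TVI (normal-
theory t-intervals), medians (procedure length, TVI values per profile,
MAP measurements and TVI values per hour) with percentile-bootstrap
intervals, IOH/TLS proportions, and mortality proportions per window.
A patient-level sensitivity recalculation counts each patient once per
cluster (a patient appearing in two clusters counts once in each),
keeping a death in its earliest mortality window.

Pearson correlations between variable pairs are computed over
window-level means where both variables are present (≥ 3 complete
windows required; constant series report NA). Window means rather than
raw measurements are used because the raw streams are asynchronous; a
raw-measurement mode would require a pairing rule the data do not
supply.

## Statistics

*Bootstrap median CI.* The point estimate is the sample median; the
95% interval is the 2.5/97.5 empirical percentiles of `n_boot`
resampled medians, each resample drawn with replacement at
`sample_size`. Defaults are the full-scale procedure (10,000 × 1,000,000);
the characterization tables default to 1,000 resamples at the data's own
size — the estimator is identical, only Monte-Carlo precision differs.
Resampling is chunked to bound memory; a constant sample yields a
zero-width interval.

*ROC AUC.* The normalized Mann–Whitney U statistic with midrank ties:
the probability that a random event case outranks a random non-event
case, ties counting ½. This satisfies AUC(s) + AUC(−s) = 1 exactly and
is invariant under strictly monotone score transforms; the test suite
checks it against exhaustive pair enumeration and an independent
library implementation.

*Paired AUC comparison.* Cases are resampled with replacement (paired
scores together, 2000 replicates by default); both models' AUCs are
recomputed per replicate; the observed ΔAUC divided by the bootstrap SD
of Δ is referred to the standard normal for a two-sided p-value.
Single-class resamples are redrawn under a capped budget. Inputs are
canonically sorted first, so results are invariant to input order under
a fixed seed. No analytic (DeLong) variance is offered; the bootstrap is
the method under study. The 30-day mortality contest scores model A as
−(median TVI) — depressed TVI means higher risk, so the sign flip makes
all scores "higher = riskier" and reported AUCs are orientation-correct
by construction, never silently folded — and model B as the TLS window
count.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not operating-room physiology. Per case: a latent regime (elevated /
mixed / depressed, prevalences 891/2931/1474 of 5296) sets the MAP, BIS,
and MAC means (86.5/82.3/76.6 mmHg, 45.3/41.8/38.0, 0.98/0.817/0.666);
the case's latent means are drawn around the regime's with small
between-case SDs (1.0 mmHg / 0.7 / 0.02); measurements are independent
truncated-normal draws around the latent means. MAP is charted roughly
every 3 minutes, BIS and agents roughly every 5, with ±20% gap jitter;
BIS and agent concentrations share charting events (one machine stream),
so MAP and BIS/MAC timestamps rarely coincide — exercising the
distinct-timepoint windowing rule. A shared per-event depth factor gives
BIS–MAC correlation −0.45 (window-level correlations land near the
−0.4 observed in practice). Agent concentrations are back-solved from
target MAC through a single agent (sevoflurane) so the agent→MAC round
trip is exact; a multi-agent mode (isoflurane + nitrous oxide split)
covers the summation path. Artifacts (out-of-limits MAP, BIS = 0,
MAC > 3) are injected at rate 0.005 per measurement; 4% of cases get a
contiguous mid-case gap in agent charting covering ~one third of the
monitoring span (the bypass-perfusionist charting gap), which produces
the expected run of TVI-less windows. A fraction of patients (15%)
undergo repeat surgery. Durations are log-normal with median 1.8 h.

Mortality: under the default `regime` link, death probabilities per
window are the per-cluster values 0.8/2.7/5.6% (30-day), 4.9/6.7/7.4%
(31–365), 3.3/3.8/4.3% (366–730). Under the `logistic_tvi` link, the
30-day probability is expit(−4.0 − 2.0·z) where z is the case's
standardized latent TVI — death concentrates in the depressed tail,
where TLS window counts saturate, which is exactly the setting in which
a continuous index should beat a cumulative threshold count. Survivors
carry 800 days of follow-up so mortality classes are never unknown in
synthetic runs.

**Calibration and what passing tests do not show.** The free dispersion
parameters were set so that the planted regimes are *identifiable*:
within-case SDs of 10 mmHg / 6.5 / 0.17 keep window-averaged noise below
the ~1.2-TVI-unit gaps between adjacent regime means, and the duration
log-SD of 0.5 limits the short-profile collapse described above. Two
consequences: the pooled synthetic SDs (~10.7 mmHg / 7.0 / 0.20) and the
duration quartiles (~1.3–2.5 h) are tighter than real intraoperative
data, and the regimes are cleanly separated three-component mixtures
rather than a continuum. Recovery tests (adjusted Rand index ≥ 0.8
against the planted truth) therefore validate the *pipeline machinery* —
filtering, windowing, embedding, clustering, labeling — not a claim that
real cohorts contain three well-separated patterns. Real data are also
not emulated in their drug pharmacology, autoregulation dynamics,
electrosurgical interference, or inter-stream dependence beyond the one
depth factor.

## Numerical conventions and degenerate inputs

- Timestamp rounding: one second (configurable), applied at ingest;
  source-precedence matching uses exact rounded equality.
- Grid placement uses round-half-up on p·(L−1).
- Population fitting requires ≥ 2 values and nonzero variance per
  variable; in the full pipeline, a variable absent from the entire
  cohort yields no TVI windows and the affected cases are excluded with
  a logged reason rather than aborting the run.
- `window_proportion(i, 1) = 0.0` (single-window profiles sit at the
  grid origin); `temporal_proportion` rejects zero-length spans.
- k-means requires ≥ k distinct feature vectors; `window_size = 1` runs
  are valid through windowing (every timepoint its own window) but
  rarely yield enough TVI windows for clustering, since a single
  timepoint seldom carries all three variables.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); a run manifest records every seed,
  parameter, and input hash, and identical manifests imply
  byte-identical outputs.

## Problem sizes used in the test suite

The default study cohort for end-to-end checks is 2000 cases (seed 17),
matching the published heatmap sample size. The mortality-model ordering
property uses 50 replicates of 1000 cases under the logistic link —
large enough that the paired AUC difference (≈ +0.04, SD ≈ 0.02) is
resolved reliably. Bootstrap-median coverage uses 100 replicates of a
5000-value standard-normal sample with 1000 resamples of 5000 draws —
the full-scale resampling scheme at reduced Monte-Carlo precision.

## Known limitations

- Equal weighting of the three variables is definitional, not optimized
  for prediction.
- The window statistic is a mean; a median would resist within-window
  outliers more strongly.
- The grid embedding is one defensible vectorization among several
  (padding, truncation, summary statistics); conclusions about cluster
  membership of *short* profiles are sensitive to the zero-fill choice.
- Medication tables are descriptive only (administration proportions,
  total doses); no pharmacokinetics or pharmacodynamics.
- The apparent AUCs in the mortality contest are in-sample; no
  train/test split or cross-validation is performed.
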