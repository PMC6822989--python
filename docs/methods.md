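# Methods

`striaseq` implements a complete analysis chain for striatal single-unit
recordings made during a discrete-trial fixed-ratio lever-press task, in
which each trial starts with lever insertion, the animal completes a fixed
ratio of presses (1 or 5), the lever retracts, and the animal collects
reward at a port. The chain covers unit screening, peri-event
normalization, a two-level response-type taxonomy, cross-stage label
transfer, region-identity (DLS vs DMS) population decoding, and
trial-by-trial spike–behavior correlation, plus a synthetic session
generator that makes every stage testable with known ground truth.

## Task structure and domain types

A `Session` holds up to 30 `Trial`s separated by 1 min inter-trial
intervals (ITIs), plus its `Unit` set. The seven sequence events analyzed
throughout are lever insertion, presses 1–5, and the reward port entry.
All timestamps are seconds from session start; every window in the package
is half-open `[t0, t1)`. Omission trials (ratio not completed within 60 s)
are retained in the session but excluded from all per-trial analyses.

## Unit screening

Putative fast-spiking interneurons are units with mean rate > 20 Hz and
waveform half-valley width < 0.15 ms; units with rates in the closed
interval [12.5, 20] Hz — or fast-firing units with wide waveforms — are
left unclassified; everything else is a putative medium spiny neuron
(MSN), the analyzed population. Tonically active neurons are not
separated. Units whose baseline rate is below 0.5 Hz are excluded
(boundary inclusive: exactly 0.5 Hz is kept).

## Peri-event normalization

Each unit's activity is binned around each of the seven events in 51 bins
of 10 ms whose centers run from −250 to +250 ms (51 rather than 500/10 =
50 because the grid is defined by its centers; the center bin straddles
the event and is assigned to neither the pre- nor post-event window).
Rates are trial-averaged and z-scored as `(F_i − F_mean)/F_sd`, where
`F_mean` and `F_sd` are the mean and SD of the binned, trial-averaged rate
over a 5 s baseline window starting 20 s before the lever insertion of
each trial, inside the ITI (a per-event re-anchored variant is available
via `AnalysisConfig.baseline_per_event`). Baseline windows that would
precede the session start are dropped. Computing the baseline on the same
trial-averaged scale as the PSTH makes one z unit equal one SD of
per-bin Poisson noise, which is the scale all downstream thresholds
assume.

Task-responsiveness is tested in twelve 250 ms windows — post-insertion,
pre- and post- each press, pre-port-entry — by comparing per-trial window
rates against per-trial baseline rates with Welch's t-test (Student's
available via config). A unit is task-responsive (TRN) if any window is
significant at p < 0.01, and is classed EXC or INH by the sign of its mean
z across the concatenated vector. Under the null and independence the TRN
rate would be 1 − 0.99¹² ≈ 0.114; the shared baseline sample and the
discreteness of small spike counts move the realized null rate a few
points (measured ≈ 0.13–0.14 on 500-unit null cohorts), which the test
suite accepts within ±0.04.

## Two-level response taxonomy

**Level 1 (Phasic vs Non-phasic).** Features are the spectral power of the
357-element concatenated z vector (effective sampling rate 100 Hz) below
1 Hz and in [1, 4) Hz. Two implementation choices matter here:

- The DC term is *included* in the low band. The vector is z-scored
  against the ITI baseline, so a sustained rate change during the sequence
  appears largely as an offset of the event-locked vector; that offset is
  precisely the low-frequency signature that separates sustained from
  transient units. (Excluding DC, as one might to guard against trivial
  offsets, removes most of the sustained units' signal and collapses the
  separation.)
- Powers are estimated by a multitaper average (3 DPSS tapers,
  time-bandwidth 2) rather than a single periodogram. One periodogram of
  a 3.57 s vector gives the low band only a handful of chi-squared degrees
  of freedom; taper averaging stabilizes the per-unit estimates at a
  modest resolution cost.

Before Ward clustering the band powers are square-root transformed — the
classical variance stabilizer for chi-squared power estimates. Log,
standardized and whitened variants are config options but not defaults:
both standardization and whitening rescale the structureless per-unit
power dimension up to parity with the discriminative band balance, which
lets Ward subdivide the large transient-unit cloud instead of cutting
between the transient and sustained groups.

The number of clusters is chosen by the Calinski-Harabasz (CH) index over
K = 2..10 on the Ward tree. CH is undefined at K = 1, so a single cluster
is declared only when a permutation test cannot certify the K = 2
solution at α = 0.05. The permutation scheme shuffles each feature column
independently across units — destroying joint cluster structure while
preserving marginals — re-clusters, and recomputes CH;
p = (1 + #{permuted CH ≥ observed}) / (n_perm + 1). The cluster whose
centroid carries the larger mid-band share is named Phasic.

**Level 2.** Within each level-1 class, activity is amplitude-normalized
as `(F_i − F_mean)/F_|max|` (F_|max| = absolute maximum deviation from
baseline) and reduced to three phase features: mean normalized activity at
initiation (0–250 ms post insertion), execution (±125 ms around each
press), and termination (250 ms pre port entry). Ward + CH on these raw
features yields Start/Stop/Middle within Phasic (named by the largest
initiation centroid, then the largest termination centroid, remainder
Middle) and EXC/INH within Non-phasic (by the execution centroid
ordering).

A sensitivity sweep re-runs level 1 over a grid of band cutoffs and
reports the fraction of cells reproducing the default outcome.

## Cross-stage transfer

A random forest (500 trees, seeded; tree count and depth are unreported in
the source analysis, so sklearn defaults are used) is trained per level-1
class on the extended-stage phase features and labels, reporting
out-of-bag error. Early-stage units are first split Phasic/Non-phasic by
the same Fourier procedure per session, then labeled by the forest.
Per-session region × class contingency tables feed Pearson chi-squared
tests.

## Region decoding

Each unit contributes its 12-element vector of mean window z-scores (or
its leading principal-component scores in the PCA variant; PCA is fit on
training folds only to avoid leakage, with a global-fit config switch).
Per repetition the larger region is subsampled to the smaller one's count,
and stratified 10-fold cross-validated LDA (pooled covariance, small
shrinkage 1e-6 against singular folds) yields a mean held-out accuracy;
50 repetitions give the accuracy distribution. The shuffled control
permutes region labels once per repetition and is otherwise identical.
p = (1 + #{shuffled ≥ mean(true)}) / (n + 1), so the floor at 50
repetitions is 1/51 ≈ 0.0196. The extended-stage ensemble sweep draws
ensembles of 60–600 units (sizes infeasible for the cohort are skipped)
without replacement.

## Trial-by-trial correlation

Three fixed epoch/variable pairings: firing 0–500 ms post insertion vs
first-press latency; firing between first and last press (count divided
by sequence duration) vs response rate; firing 0–500 ms post retraction
vs port-entry latency. Spearman rank correlation with average-rank ties;
the p-value uses the t-approximation for n ≥ 10 trials and the exact
permutation distribution below that; unit-variable pairs with fewer than
10 usable trials are dropped. The population-level control permutes each
unit's behavior vector 1000 times, recomputes all correlations, and
locates the observed count of significant units (p < 0.05) in the null
count distribution: p = (1 + #{null ≥ observed}) / (n + 1).

Response rate per trial is presses divided by the lever-availability time
(insertion to retraction); the alternative (n−1)/sequence-duration form is
a config switch since the exact denominator is not printed in the source.
The devaluation ratio is devalued/(valued + devalued) — 0.5 means equal
responding — with ratios above 0.45 read as devaluation-insensitive; the
formula itself is a package choice, as only the 0.45 threshold is printed.

## Synthetic sessions

The generator draws behavior first (log-normal first-press latency,
inter-press intervals, and port-entry latency; optional omissions and
within-sequence port entries; 60 s ITIs), then simulates each unit as an
inhomogeneous Poisson process (thinning; no refractoriness, which is
irrelevant at the 10 ms analysis scale) from a rate profile composed of a
baseline plus one archetype's modulation:

- `phasic_start` / `phasic_stop`: a Gaussian bump (SD 40 ms) 125 ms after
  insertion / before the reward port entry. Bumps are biphasic: a broad
  rebound suppression (SD 0.2 s, depth capped at 90% of baseline) cancels
  80% of the bump's spike mass, as commonly seen in striatal phasic
  responses.
- `phasic_middle`: a bump at every press (65% mass rebound); per-unit
  amplitude is set so total modulation power matches the single-bump
  archetypes.
- `sustained_exc` / `sustained_inh`: a multiplicative plateau from 1 s
  before insertion to 1 s after the port entry (anticipation and
  persistence), with 0.25 s ramps; gains and baseline scalings are chosen
  so excitation and inhibition have matched modulation magnitude
  (inhibition is floor-limited, so INH units draw from the
  higher-baseline part of the rate distribution and stay under the
  12.5 Hz screening bound). Press-locked transients ride on the plateau
  (bipolar for EXC; weak positive "release" transients for INH).
- `non_responsive`: constant baseline.

Phasic amplitude is parameterized in trial-averaged z units
(`amp_z`, default 6 for start/stop) rather than as a baseline multiple:
detectability is treated as a unit property, matching the z-score scale
(|z| ≈ 2–8) of real recordings, and converted per unit via
`amp = amp_z · sqrt(baseline / (bin width × trial count))`. Per-unit
log-normal jitter of amplitudes and widths plus per-press structure makes
the classes continua rather than point templates.

Cohort mixtures default to the two recording stages: the early stage has
region-distinct mixtures (DLS dominated by sustained excitation, DMS by
sustained inhibition with boundary excitation, ~20–25% non-responsive),
13 sessions (3 ratio-1 then 10 ratio-5) of 37 DLS + 81 DMS units; the
extended stage pools 338 DLS + 410 DMS units with a *matched* mixture
per region whose class proportions are the pooled extended-stage taxonomy
proportions (Start 110 : Stop 163 : Middle 362 : INH 53 : EXC 60 of 748).

Firing–behavior coupling multiplies a unit's rate within a behavioral
epoch by `max(0, 1 + sign · strength · z_v)`, where `z_v` standardizes the
trial's realized behavioral value under the generative distribution. At
the default strength 0.5 a negatively coupled unit recovers a negative
Spearman correlation in ≥ 90% of replicates over 30 trials.

### What the generator does and does not emulate

It reproduces the trial structure, Poisson-scale count noise, archetypal
response shapes, stage-dependent mixtures, and behavior coupling that the
analyses key on. It does not model bursting/refractoriness, slow
nonstationarity, correlated noise across units, waveform shape (beyond
the two scalar screening fields), or electrode drift. Passing tests
therefore certify that the pipeline recovers structure *of the assumed
form* at realistic signal-to-noise — not that real recordings contain
that structure.

## Numerical choices and degenerate inputs

Ties in spike timestamps are removed at generation (measure-zero);
zero-variance t-test inputs return p = 1 with the unit simply not counted
as responsive; units with zero baseline SD or flat responses are flagged
and excluded; decoding folds that end up single-class are refolded with a
new seed (up to 5 attempts); ensembles larger than half the cohort are
skipped with a warning; contingency tables with empty rows/columns are
dropped from the per-session reports. Chi-squared tests never apply a
continuity correction — required to reproduce the printed reference
statistics. All randomness flows from explicit seeds; the pipeline output
is a pure function of (inputs, config, seed).

## Problem sizes used in the test suite

The suite exercises the taxonomy at half the default extended scale
(169 + 205 units, still ≥ 150 per region), decoding on three pooled early
sessions, and the null calibrations on 500-unit non-responsive cohorts;
the acceptance script runs the full default extended cohort (338 + 410).
These sizes keep full runs to a few minutes while leaving every
statistical margin wide (e.g., the CH preference for the two-cluster
level-1 solution holds with ~30–40% margin at both scales).

## Known limitations

The CH criterion prefers subdividing elongated continua; the default
square-root feature transform was chosen (and is documented above)
precisely because other common transforms let that preference override
the true two-group structure. Real cohorts whose band-power geometry
differs strongly from the synthetic one may need the config switches.
The devaluation-ratio formula, the exact response-rate denominator, the
t-test variant, and the permutation schemes are reasonable
reconstructions where the source analysis leaves details unstated; each
is config-switchable or documented here.
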