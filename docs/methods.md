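# Methods

## Data model and scope

The unit of analysis is an epoch block: one individual × session array of
shape `[C channels, T time points, N trials]` with a sampling rate,
channel names and identity labels. Continuous (resting) recordings enter
by reshaping into fixed-length pseudo-trials. The package deliberately
stops short of raw-data preprocessing (filtering, artifact rejection,
head-position correction): its inputs are already-epoched recordings, read
from a small HDF5 container or imported from FIF epoch files.

Resampling uses polyphase FIR decimation (`scipy.signal.resample_poly`),
i.e. a linear-phase anti-alias low-pass with compensated group delay.
Zero-phase behaviour matters here because the temporal-correlation feature
encodes evoked latencies; a causal filter would shift them.

## Features

All three features are deliberately simple, interpretable summaries:

* **sp** `[C×C]`: Pearson correlation between channels over the
  concatenated time–trial axis. Captures stable inter-sensor covariance —
  a proxy for anatomy and correlated regional activity.
* **tp** `[T×T]`: Pearson correlation between time points over the
  concatenated channel–trial axis. Captures stimulus-locked temporal
  structure, e.g. individual processing latencies.
* **fq** `[B]`: mean one-sided power spectrum (density scaling) over
  channels, trials and Welch segments, with a Tukey(0.25) taper and a
  100-sample window; `B = window/2 + 1` bins at `sfreq/window` Hz spacing.
  The window defaults to `min(100, T)`; trials longer than the window are
  tiled with 50 % overlap. No detrending is applied — the estimate is the
  plain tapered periodogram. Absolute spectral normalization is
  irrelevant downstream because similarity is correlation-based
  (location/scale invariant).

For similarity, sp and tp are vectorized as the upper triangle excluding
the identically-1 diagonal (configurable to full-matrix flattening); fq is
used as is. Degenerate inputs (constant channels, time points or feature
vectors) raise immediately rather than propagating NaN correlations.

## Identification protocol

Per run: the protocol z-scores each side by channel (each with its own
statistics — source and target are never normalized jointly), samples `n`
trials without replacement, featurizes, builds the `K×K` Pearson
similarity matrix between target and source vectors, and assigns each
target to its argmax source independently ("labeling with replacement" —
no bipartite constraint). R runs (default 100) average over the sampling
variability. When source and target are the same recording (detected by
object identity or identical session id + identical data), a fresh
disjoint trial split (default fraction 0.5, resplit every run) guards
against leakage. Exact argmax ties resolve to the lowest source index and
are flagged; ties have measure zero on continuous data.

Metrics:

* identification accuracy, per individual and pooled, with empirical SEs
  over the pooled correctness indicators;
* rank accuracy `rank_i / K`, with ties mid-ranked so its chance level is
  exactly `(K+1)/2K` even in degenerate cases;
* differential identifiability `100 × (mean diag − mean off-diag)`,
  evaluated per run and averaged (a flag switches to evaluating the
  run-averaged similarity matrix; the two coincide in expectation since
  the statistic is linear in the matrix);
* permutation significance: the null permutes the true identity labels of
  target individuals within each run and recomputes pooled accuracy;
  `p = (1 + #{null ≥ observed}) / (1 + B)`, `B` defaulting to 4999 so the
  smallest attainable p is 0.0002. Caveat: the test's exchangeability
  unit is the run. Runs that resample trials from the *same* underlying
  session pair are highly dependent (the realized session effects are
  fixed), so the p-value quantifies evidence against chance matching
  *within this cohort's realized data*, not across hypothetical cohorts.
  The calibration test therefore checks uniformity under exchangeable-run
  nulls, and cohort-level null calibration is checked on the accuracy
  scale across independently generated cohorts.
* classical pooled-variance two-sample t test (two-sided) for
  clean-vs-degraded comparisons; both-samples-constant input is rejected
  as degenerate.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis relies on,
not any particular instrument. Per individual it draws a signature with
three axes:

* **spatial**: a `[C×L]` mixing of `L = 8` latent sources (unit-norm
  columns), `mix_k = normalize(M0 + strength · D_k)` with a shared base
  `M0` and individual deviation `D_k`;
* **temporal**: an evoked Gaussian bump with individual latency
  (0.2 ± 0.09 s) and width (log-normal around 0.05 s), added to every
  source in "task" mode and omitted in "rest" mode;
* **spectral**: a damped AR(2) oscillation (pole radius 0.97) with an
  individual peak frequency in 6–12 Hz and power ~1.5× the 1/f
  background; each of the L sources jitters its peak by up to ±1.5 Hz and
  its power log-normally around the individual's values, giving a
  multi-peak spectral fingerprint.

Latency and peak frequency are assigned by a random permutation of an
evenly spaced grid (plus small jitter) rather than i.i.d. draws: a cohort
of *distinct* individuals has guaranteed pairwise separation on these
axes, which matches how real cohorts behave (two people are essentially
never identical on every axis at once) and scales to zero with
`signature_strength`. All individual deviations scale with
`signature_strength` (bounded parameters use `min(strength, 1)` so their
ranges hold); strength 0 collapses the cohort onto one common signature —
the null cohort.

Session-to-session change models head repositioning and instrument drift:
per (individual, session) the mixing columns receive a random perturbation
of relative scale `session_perturbation` and the channel gains drift
multiplicatively (SD `0.2 × session_perturbation`). Sensor noise is white
with SD `noise_sd`. Trials are `mix · (oscillation + 1/f background +
evoked) · gain + noise`, with stochastic oscillator phase and 10 % evoked
amplitude jitter per trial.

Defaults (`K=8, S=2, C=24, T=100, N=150, sfreq=200, strength=1,
perturbation=0.1, noise_sd=1`) define the reference regime: strong,
stable individual signatures with mild session change, sized so a block
resembles a downsampled 0.5 s-epoch study at desk scale. Every random
quantity derives from the single cohort seed through a fixed
`SeedSequence` spawn-key scheme (signatures, per-(individual, session)
perturbations and per-block trial noise on separate keys), so a cohort is
a pure function of its spec.

What the generator does *not* emulate: biophysical lead fields and head
geometry, physiological artifacts (blinks, cardiac), non-stationarity
within a session, and realistic inter-feature dependence. Passing tests
on this cohort therefore demonstrate that the pipeline recovers the kinds
of structure it is designed for — they are not evidence about any real
dataset's effect sizes.

## Statistical validation design

* **Null calibration** is Monte-Carlo over independently generated null
  cohorts (not over runs): within one cohort the realized session
  perturbations are fixed, so run-level indicators are strongly dependent
  and a run-based SE would be badly anticonservative. Across 20 cohorts,
  identification accuracy, rank accuracy and differential identifiability
  must sit within 3 MC SEs of `1/K`, `(K+1)/2K` and 0.
* **Signal regime**: at the default strong-signature settings, all three
  features must reach ≥ 0.95 cross-session accuracy (K=8, n=100, R=100).
* **Attribution**: planting a signature on one axis only (spatial
  differences confined to one sensor group; latencies confined to two
  time segments; spectral peaks in 6–12 Hz) must make the corresponding
  sub-feature grid cell the most accurate in ≥ 90 % of 20 cohort seeds.
* **Monotonicity**: pooled accuracy is non-decreasing in the number of
  trials `n` and non-increasing in `session_perturbation` (adjacent-pair
  checks on small grids, one Monte-Carlo inversion allowed). The
  perturbation sweep uses the spatial feature, the axis the perturbation
  acts on.

Problem sizes in the test suite (cohort channel counts, trials, run
counts) are chosen as the smallest that make these statistical checks
stable; they are stated in each test.

## Random-forest baseline

The topomap baseline treats single time-point channel vectors as samples
and scores a 256-tree random forest under stratified 10-fold
cross-validation. Following the protocol's normalization convention, the
train and test folds are z-scored by channel *separately and
independently* (a flag restores conventional train-fitted scaling). Other
forest hyperparameters are scikit-learn defaults. This is a baseline, not
a contribution: it answers whether instantaneous spatial patterns alone
carry identity information.

## Design choices where the design was open

* Within-session split fraction 0.5, resplit every run (flags for both).
* Z-scoring precedes trial sampling (flag-free; the block statistics are
  the stable quantity).
* The sensor-group map ships as a contiguous 8-way split over channel
  order for position-free cohorts, with an octant constructor for real
  2-D sensor positions and CSV override; results that depend on the
  grouping are reproducible only relative to the chosen layout.
* Cross-modality experiments re-draw the spatial mixing per modality while
  sharing temporal/spectral signatures, so only tp and fq are evaluated
  across modalities (sp lives in sensor space and does not transfer).
* Frequency sub-features use 10 Hz windows stepped at the bin spacing;
  canonical band slices (delta…gamma) are provided as an alternative.

## Known limitations

Closed-world identification only (every target individual is present in
the source set; no abstention). No learned similarity metrics. No
multiple-testing correction across features or session pairs. The
permutation p-value's cohort-level caveat above. Synthetic-cohort realism
limits as listed.
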