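# Methods

## Generative model

A surface-tethered molecule is simulated as a continuous-time Markov chain
with a strictly ordered backbone: absent → bound sub-step 1 → … → bound
sub-step *m* → enhanced (unwound bubble / locked clamp) → reverted low
state → (re-enhancement …), with irreversible photobleaching competing at a
single rate from every emitting state, and optional reversible blinking
overlaid on emitting segments. Holding times are exponential with the
per-state mean lifetimes; sub-steps are traversed in order, so the waiting
time from binding to first enhancement is a convolution of *m*
exponentials. The default *m* = 2 gives the peaked dwell density
`f(x) = (e^{-x/t1} − e^{-x/t2})/(t1 − t2)` with mean t1 + t2 and variance
t1² + t2². More sub-steps may contribute in reality; because the individual
lifetimes are weakly identified from dwell histograms, only the total is
interpreted, and the generator mirrors that by fixing *m* = 2.

Per-condition sub-step lifetimes are not separately identifiable from the
published totals, so the presets split each total roughly 40/60 (e.g.
3.0 + 4.5 s for the consensus +2-probe construct); everything downstream
only constrains the sum.

### Trajectory classes are observational

The class taxonomy (I: no transition before signal loss; II: low → high
transition observed; III: starts high; IV: transient open-clamp
excursions) describes realized trajectory *shapes*, not distinct molecular
species. The ensemble generator therefore rejection-samples each trace
until its realized path matches the class drawn from the mixture, so
requested proportions are exact class proportions by construction, and
Class-II-only ensembles contain a transition before bleach in every trace.
A consequence worth keeping in mind: Class-II dwells are implicitly
conditioned on the transition occurring before photobleaching and before
the end of the recording, which biases recovered totals a few percent low —
the same censoring the experimental analysis carries.

## Rendering and noise

* **UIFE**: each frame's noiseless value is the occupancy-time-weighted
  mean of the state emission levels (defaults 200/450 counts; 190/456 for
  the Myx condition, i.e. 2.4-fold) plus background; optional Poisson shot
  noise, then additive Gaussian read noise (default sd 25 counts). The
  scenario presets use pure Gaussian noise of sd 25. The published data do
  not state per-state noise or background levels; these defaults are this
  package's own, chosen to look like EMCCD photon-count traces at the
  reported levels.
* **FRET**: noiseless frames obey I_DD = T·(1 − E*), I_DA = T·E* with
  donor-excited total T = 500 counts and I_AA = 600 counts while the
  acceptor is alive. Noise perturbs the proximity ratio directly
  (E*_obs = E* + N(0, 0.04)) before splitting T, so the per-frame E*
  scatter is exactly the configured sd; optional Gaussian count noise can
  be added on top (off by default). This choice makes "E* noise sd" a
  direct, checkable condition instead of an emergent property of count
  noise.
* **Movies**: emitters are pixel-integrated 2-D Gaussians (erf-based, flux
  conserved), pixel centres at integer coordinates.

Frame times follow the imaging conditions per scenario (50 ms UIFE, 200 ms
for the slow G/C construct; 100 ms FRET, 400 ms slow FRET), and the slow
scenarios use a 400 s bleaching lifetime versus 100 s otherwise, reflecting
the lower excitation duty at long frame times.

## Curation

Heuristics operate on a median-filtered (k = 3) trace with a configured
noise sd (robustly estimated from first differences when unset):

* *Emitting* frames exceed background + 3 sd; episodes are contiguous
  emitting runs.
* *Intensity upon binding* = mean of the first 5 emitting frames (the
  window is this package's definition); UIFE traces brighter than 750
  counts are excluded.
* *Blink vs second binding*: a background gap (≥ 2 frames) whose recovery
  level matches the pre-gap level (within max(4 sd, 25%)) is a blink; a
  gap of ≥ 3 frames with a different recovery level is a second binding
  event. Both exclude the trace.
* *Bleach steps* are counted on plateau-segmented traces; interior
  plateaus shorter than 4 frames are ignored because a partial-occupancy
  frame at a transition edge masquerades as an intermediate level for 1–3
  frames, whereas a genuine intermediate bleach level persists. For FRET
  the step counters run on the kinetics-independent streams I_DD + I_DA
  and I_AA, so state transitions are invisible to them; more than one
  downward step on either excludes the trace (multi-step bleaching).
* FRET range bounds (median I_DD in 100–1000, median I_AA in 200–1000
  counts) are applied to the per-trace median of emitting frames — the
  published rule does not say per-frame vs summary, and the median is
  robust to transition frames. Kept FRET traces are truncated at the first
  donor/acceptor bleach; traces with fewer than 5 frames between binding
  and bleach are excluded as unanalysable.

Curation never modifies intensity values and is idempotent on kept,
truncated traces.

## State inference

Maximum-likelihood Gaussian-emission HMM, fitted globally over all curated
traces jointly by Baum–Welch, replaces the variational-Bayes trace
idealization used interactively in the original workflow; agreement is
asserted at the level that matters here — recovered state means and dwell
kinetics. Numerical choices:

* K fixed: 3 for intensity traces (one near-zero state), 2 for Class-II E*
  trajectories; no model selection over K.
* Emission sd floored at 1e-3 (rescaled units) to prevent variance
  collapse on noiseless data; observations are I_Cy3* = I_Cy3/1000 or E*.
* Convergence: relative total log-likelihood change < 1e-8 or 500
  iterations; the per-iteration history is retained and is monotone.
* 10 seeded restarts (first restart: deterministic quantile
  initialization); restarts are triaged with a 25-iteration burst and only
  the best is run to convergence — EM monotonicity makes the concatenated
  history still monotone.
* Undefined frames (e.g. E* where I_DD + I_DA ≤ 0) are treated as missing:
  emission likelihood 1, so they inform transitions but not emissions.
* States are reported sorted by ascending mean; Viterbi ties break toward
  the lower state index. Both make results label-deterministic.

`hmmlearn` serves as an independent cross-check in the test suite, never as
the implementation.

## Classification and kinetics

* A transition must persist ≥ 2 frames (the ~100–400 ms effective temporal
  resolution makes single-frame flicker uninterpretable); "starts at" means
  the state of the first ≥ 2 emitting frames.
* Class IV is detected on raw E*: ≥ 3 consecutive frames below 0.30.
  Three frames (rather than two) keeps the false-positive rate negligible
  (P ≈ 2×10⁻⁷ per frame at E* = 0.40, sd 0.04) while real ~0.6 s
  excursions span ~6 frames at 100 ms.
* Class-II dwell = (first high/locked frame − first emitting frame) ×
  frame time. Class-I durations are recorded as censored and reported as a
  censoring fraction but excluded from fits, matching the Class-II-only
  analysis; no bleach-rate correction is applied.
* Dwell histograms use bin width 4 × frame time (binning is unstated in
  the source workflow) and are fitted by least squares to
  `A (e^{-x/t1} − e^{-x/t2})` with moment-based initialization, followed by
  two reweighted passes with Poisson weights computed from the *model*
  counts (weights from observed counts would systematically favour
  downward-fluctuating bins and bias the fit low; model-based reweighting
  is unbiased and reaches near-maximum-likelihood efficiency while
  remaining a histogram fit). The swap symmetry of (t1, t2) is resolved by
  the convention t1 ≥ t2 > 0, A > 0.
  An unbinned MLE on the normalized density is computed alongside; the two
  totals agree within ~10% on well-sampled data and disagreement flags
  binning artifacts. t2 collapsing below a quarter bin width flags a
  single-exponential-like sample.
* Initial-binding E* is the mean of the first five frames (0.5 s at
  100 ms) after binding, pooled across traces into a Gaussian histogram
  fit.
* The derived downstream-unwinding time is the difference between the +2-
  and −9-probe totals, with standard errors propagated in quadrature from
  the fit covariances; a negative difference is reported but flagged.

## Problem sizes and what passing shows

Recovery runs use 300 Class-II traces per condition (200 for the
fold-enhancement check; 1,000 mixed-class traces for the classification
check), sizes comparable to the experimental ensembles and sufficient for
the ~5–15% tolerances involved. The generator emulates the kinetic and
photophysical structure of the real data — sequential sub-steps,
bleaching, blinking, partial-occupancy frames, class mixtures — but not
optical artifacts (drift, chromatic offsets, EM-gain excess noise, focus
variation) or non-specific surface binding. Passing recovery therefore
demonstrates that the analysis chain is unbiased at the stated noise and
sampling levels, not that it is robust to every instrumental pathology of
real movies.

## Known limitations

* Sub-step lifetimes t1, t2 are reported but nearly exchangeable when
  similar; trust only their sum.
* Censoring by bleaching/recording end biases totals a few percent low at
  the default lifetimes (and is why recovered values sit slightly below
  the generator sums).
* The localizer fits single emitters only; overlapping spots (< 1 px) are
  warned about at render time, not deconvolved.
* Blinking is excluded, not repaired; no FRET gamma correction is applied
  (E* is the uncorrected proximity ratio throughout).
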