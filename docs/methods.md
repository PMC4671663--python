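# Methods

`soundhue` re-implements, as a tested pipeline over synthetic data, the
computational chain of a crossmodal experiment in which listeners
continuously matched a colour patch to music excerpts using a physical
interface navigating CIE L\*a\*b\*. This note documents the models,
conventions, and design choices; every empirical statement here is
computed by the test suite or the analysis scripts, not asserted.

## The hybrid colour response space

The response space is the Lab box L ∈ [0, 100], a\*, b\* ∈ [−100, 100],
discretised at 2 Lab units (51 × 101 × 101 = 520,251 cells). A cell is
*visible* when its colour lies inside the display gamut; invisible
cells "borrow" the colour of the Euclidean-nearest visible cell, so the
entire physical input range remains meaningful to the user.

Pinned conventions:

* **Gamut** = sRGB (IEC 61966-2-1), the standard target for a
  calibrated LCD. White point D65 from its chromaticity
  (x, y) = (0.3127, 0.3290), 2° observer; the XYZ↔RGB matrices are
  derived exactly from the sRGB primaries and that white so the
  neutral axis maps bit-exactly (L\* = 100 → RGB (1, 1, 1)).
* **Boundary tolerance**: a linear channel in [−10⁻⁹, 1 + 10⁻⁹] counts
  as inside, making the census reproducible across floating-point
  dialects.
* **Tie-break**: an invisible cell equidistant from several visible
  cells borrows from the one earliest in (L, a, b) lexicographic grid
  order. Snapping of continuous points to grid cells rounds half-way
  coordinates downward for the same reason.
* **Distance** is unweighted Euclidean in (L, a, b); no ΔE2000
  weighting, since patch arithmetic throughout the pipeline (means,
  distances) is defined in the same plain Lab metric.

Under these conventions the census is 102,527 visible colours (19.7%
of cells; 80.3% borrow). The count is sensitive to the display profile
assumed: a narrower (hardware-calibrated) gamut yields fewer visible
cells, and no deposited profile exists for the original apparatus, so
the sRGB figure is the package's reproducible reference point.

Interface mapping: tablet (x, y) → (a\*, b\*) affinely
(a = −100 + 200x, b = −100 + 200y), pen pressure → patch size, throttle
→ L (all channels in [0, 1]; mappings linear, continuous, and
separate). A lifted pen produces no patch. The grid build takes a few
seconds; it is memoised in-process and can be cached on disk keyed by
(step, gamut, white point).

## Synthetic study data

No response data are deposited with the study this emulates, so the
generator is a first-class module defining the conditions under which
everything downstream is tested: 27 stimuli × 22 participants (9
female), 15 s excerpts sampled at 10 Hz (~150 frames × 4 channels ≈ 600
values per response — the frames×channels reading of that count).

* **Stimulus pool.** Valence and Energy are drawn near-uniformly on
  [1, 9]; Tension decreases with Valence and increases with Energy.
  The discrete emotion dominating each (Valence, Energy) quadrant is
  raised above a 2-point floor (Happy: V+E+, Tender: V+E−, Sad: V−E−;
  Anger and Fear share V−E+ and are split by Tension). Beauty and
  Liking share a latent preference factor with noise chosen to give
  r ≈ 0.94. The 19 audio features are linear in (Valence, Energy) plus
  Gaussian noise, with signs following the observed pattern: timbral
  brightness/flux features track Energy, tonal clarity features track
  Valence, and Loudness/Roughness/Tempo are uncoupled (as expected for
  loudness-normed stimuli).
* **Emotion → colour target.** A fixed linear map with coefficients
  chosen once to reproduce the reported direction pattern (happy →
  light yellow, anger → large red-yellow, sad → small dark blue-grey,
  energy → larger/lighter/yellower), clipped to legal ranges. The
  literature gives directions, not coefficients; the magnitudes (e.g.
  L = 50 + 14v + 10e − 10t on centred unit ratings) were set for
  plausible spreads and never revisited.
* **Envelopes.** Pen-up gap of 1–4 s, a reflected-Gaussian random-walk
  search phase until the 5 s settling point, then jitter (noise_sd = 4
  Lab units) around the settled target. The settled target is
  `m · emotion_target + (1 − m) · distractor` with mediation strength
  m ∈ [0, 1] and a per-(participant, stimulus) uniform random
  distractor — m is the single dial that creates or destroys the
  emotion-mediation effect downstream. A per-participant constant
  offset (participant_sd = 6 Lab units) and an optional female
  patch-size shift (−0.08, ≈ 0.7 pooled SD) add idiosyncrasy and a
  plantable gender effect.

What the generator does *not* emulate: real raters disagree far more
than these simulated ones, whose targets all derive from one shared
emotion→colour map — synthetic Cronbach α is therefore near 1 rather
than the 0.4–0.75 band typical of real continuous colour responses.
Passing tests show the pipeline recovers structure it is pointed at;
they do not show that real listeners behave this way. Audio features
are simulated summaries, not extracted from audio.

## Response summarisation

Participants search before settling, so samples are weighted: zero for
the first half, a linear ramp from the midpoint to the three-quarter
point, then a constant maximum. Convention (1-based index i, h =
⌊n/2⌋, q = ⌊3n/4⌋): w_i = 0 for i ≤ h, (i − h)/(q − h) for h < i ≤ q,
else 1. The endpoint convention is ours — the published description
fixes only the shape — and the test reference is an explicit-summation
oracle, not a constant. Samples are snapped through the hybrid grid
*before* averaging (matching what was on screen), pen-up samples get
zero weight (the patch disappears rather than persisting), and a
response with no weighted pen-down sample is flagged missing and
excluded with a log count.

## Selection, agreement, and planned tests

* **Extreme-stimulus selection** scores each excerpt by
  `rating(target) − max(other four)` for discrete scales, by
  `rating − max(other two)` (high pole) or `rating − min(other two)`
  (low pole) for dimensional scales, and by mean(Beauty, Liking) for
  Preference. Slot arithmetic yields 26 labelled slots (5·2 + 3·2·2 +
  2·2); the de-duplicated stimulus list is reported with its count
  rather than forced to a fixed size, and ties break on stimulus id.
* **Agreement** is raw-score Cronbach α with participants as items and
  stimuli as cases (sample variances, n − 1). Discordance screening is
  a single pass: each participant's a\* column is correlated with the
  mean of the others' and flagged when r < 0; the exclusion decided on
  a\* applies to all four parameters jointly. No iteration to
  convergence — one shot, as in the narrative this mirrors.
* **Planned tests.** Shapiro–Wilk screens normality. The five-group
  discrete comparison uses the tie-corrected Kruskal–Wallis H (χ² p on
  k − 1 df) with a Tukey-HSD follow-up on the raw values at familywise
  α = 0.05 — a parametric follow-up to a rank omnibus, kept
  deliberately because it is what the analysed study narrates; a
  rank-based Dunn–Šidák follow-up is available behind a flag.
  High/low contrasts use the two-sided Mann–Whitney U: closed-form
  exact when nm ≤ 400 with no ties, full tie-aware enumeration
  (symmetric two-sided tails) when ties occur at total n ≤ 12,
  otherwise the tie-corrected normal approximation with continuity
  correction. Effect sizes are Cohen's d with (n − 1) pooling; group
  medians carry percentile-bootstrap 95% CIs.

## Correlation screening

Each audio feature and patch parameter is Box-Cox transformed per
variable (shift = max(0, ε − min) with ε = 10⁻⁶ · range, λ by
profile-likelihood; post-transform Shapiro p is reported, not gated
on), then Pearson-correlated. Cells are tiered at the Dunn–Šidák
per-test level α_c = 1 − (1 − α_fw)^(1/m) and at nominal 0.05. m
defaults to the number of computed cells (19 × 4 = 76); m = 80 is
available as a knob to reproduce the historical α_c = 0.00064, which
corresponds to a 20-feature table.

## PLS mediation comparison

Three PLS2 models predict (Size, L, a\*, b\*) jointly from nested
candidate pools — audio features only; plus dimensional ratings; plus
discrete ratings — all at two latent components, so extended models
differ only in available information, not complexity. The fit is a
NIPALS-equivalent SVD iteration (weights from the dominant singular
vector of XᵀY, regression deflation), standardising predictors and
responses on the *training folds only*; a unit test pins it to
scikit-learn's PLSRegression.

Predictive performance: 9-fold cross-validation (folds of 3 at
n = 27), R² = 1 − SS_res/SS_tot over the assembled out-of-fold
predictions, median over repeated random fold assignments, with
percentile-bootstrap CIs over the repetition values. Adjusted R²
charges p_eff = 2 (the latent components) by default; pool size is a
config option, since "adjusted for the number of predictors" is
ambiguous when candidate pools approach n. The noise floor repeats the
identical pipeline after replacing the responses with uniform random
interface inputs pushed through the colour engine (one CV pass per
simulated input set, drawn per stimulus). The mediation verdict for a
response is non-overlap: the extended model's CI lies strictly above
Model 1's.

Under this (standard, predictive) R² definition the chance level at
n = 27 is *negative* (≈ −0.4); a historical positive chance-level
figure of 0.458 is not recoverable and is not reproduced — the
definition here is pinned and documented instead. Default repetition
counts are 500 for the analysis scripts and tests and 5,000 for full
runs; medians stabilise well below 500 (the repetition-doubling test
bounds the Monte-Carlo movement).

## Numerical and degenerate-input choices

Constant predictor columns are dropped with a warning; constant
samples are rejected by Shapiro, Box-Cox, Cronbach α (zero total-score
variance), and Cohen's d (zero pooled SD) with explicit errors rather
than NaNs. Bootstrap and fold randomness funnel through
`numpy.random.Generator` seeded per stage; the pipeline manifest
records seeds and SHA-256 digests, and a re-run with the same config
is byte-identical.

## Known limitations

* The gamut census depends on the display profile; only the sRGB
  figure is reproducible here (see above).
* Synthetic inter-rater agreement is optimistic (shared emotion map),
  so the discordant-rater screen is exercised on planted fixtures, not
  on the generator's default output.
* The Tukey-HSD follow-up assumes homoscedastic normal groups that the
  rank omnibus deliberately does not; interpret pairwise stars
  accordingly (or use the Dunn flag).
* The qualitative-interview arm of the original mixed-method design is
  out of scope, as are audio feature extraction and loudness norming.
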