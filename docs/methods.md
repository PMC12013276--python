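# Methods

## The observable: activity and cumulative activity

A plate-scale time-lapse recording of an amoeba microcosm (cysts inoculated
next to a bacterial lawn, one frame every 30 s) is reduced to a single scalar
per frame pair: the number of pixels whose absolute intensity change between
consecutive frames strictly exceeds a threshold θ. Moving trophozoites change
pixels; dormant cysts and the substrate do not. The per-pair counts A(t) are
the *activity*, and their running sum CA(t) — the *cumulative activity*, in
activity units (AU) — is the quantity modeled downstream. Differences are
computed in a widened signed domain, so 8/16-bit frames cannot wrap around.

The threshold is estimated from inactive regions at the start of the
recording: θ = mean + k·SD (population SD) of |ΔI| over the ROI pixels of the
first n frame pairs, floored at one intensity level, with defaults k = 5 and
n = 10. When no ROI is supplied, the 10% of pixels with the lowest temporal
variance are used — with one subtlety: selection happens on a leading block
of frames *disjoint* from the pairs the statistic is computed on. Selecting
and measuring on the same frames picks out the pixels that happened to be
quiet in exactly those frames and underestimates the noise scale; with the
split, a static background with Gaussian sensor noise σ per frame gives
|ΔI| half-normal with mean ≈ 1.128σ and SD ≈ 0.853σ, hence θ ≈ 5.39σ at
k = 5 and an expected false-positive fraction of ≈ 1.4×10⁻⁴ per pixel — the
calibration the tests enforce (bounded at 5×10⁻⁴ per pixel).

No registration, illumination correction or smoothing is applied; the
statistic is aggregate and deliberately simple.

## The two-phase model

Cumulative activity follows two phases: excystation and substrate
exploration by the inoculum, then (on substrates that support proliferation)
colonization of the lawn:

    CA(t) = cIA · (1 − e^{−(t−tx)/tp}) · [t ≥ tx]  +  cCA / (1 + e^{−(t−tc)/tg})

* `cIA` (AU): amplitude of the inoculum plateau;
* `cCA` (AU): amplitude of the colonization phase;
* `tx` (h): excystation delay — the quiescent stretch before activity starts;
* `tp` (h): exploration decay time of the inoculum activity;
* `tc` (h): time at which the logistic colonization phase reaches half its
  plateau;
* `tg` (h): growth time, the inverse logistic rate.

The printed exponential term is negative for t < tx; since CA is a running
sum of nonnegative counts it cannot decrease, so the inoculum term is defined
as exactly zero before tx. The derived *relative colonization activity*
cCA/(cCA + cIA) is the fraction of total activity attributable to
colonization, with 0/0 → 0 by convention.

## Fitting

`fit_two_phase` runs bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`) over all six parameters, with
amplitudes bounded by [0, 10·max CA] and times by (0, 2·window]; these bounds
prevent runaway logistic fits. Initialization is deterministic and
scale-free:

1. an inoculum-only (3-parameter) fit on the early window — by default
   min(24 h, 0.3·window), since the inoculum plateau completes within the
   first ~24 h of a standard ~200 h recording and proportionally sooner in
   compressed synthetic recordings. In this stage tp is bounded by the early
   window itself; otherwise the exponential degenerates into a linear ramp
   that absorbs the start of the colonization rise;
2. the logistic is initialized from the smoothed residual's half-rise time,
   with tg₀ a quarter of its 10–90% rise duration; an undetectable residual
   rise parks the logistic beyond the window.

Because the two phases can overlap heavily (tc within a few tg of tx), a
single basin of attraction is not enough: the fit is multi-started (5 starts
by default) with additional deterministic starts that split the total
amplitude between the phases at fixed fractions (0.05/0.3/0.7) and one
pure-inoculum start. The best solution by cost wins; near-exact ties prefer
the lower cCA (the more conservative attribution). The whole procedure is
deterministic for fixed inputs.

Diagnostics: RMSE, R², parameter names pinned at bounds, an implausibility
flag when tc ≤ tx, and a convergence flag. An all-zero curve returns a
degenerate result (all amplitudes 0, not converged) instead of raising.
Curves must have ≥ 20 strictly increasing time points; decreasing CA values
warn and are clipped to a running maximum.

## Censoring

When colonization is not observed inside the recording window the
colonization parameters are not identified, only bounded. The fit flags
`colonization_absent` when the fitted tc ≥ 0.95·window or the fitted cCA is
below 2% of the total amplitude (both configurable). A censored fit reports
relative colonization exactly 0.0 and emits tc and tg at the window end,
rendered textually as ">200" for a 200 h recording. The raw fitted values
remain available in `FitResult.params`; censoring is a reporting convention,
not a mutation of the estimate.

Known limitation: with ~10% increment noise on a genuinely colonization-free
curve, the fitted spurious cCA occasionally lands just above the 2% floor,
producing an uncensored tc at an arbitrary position. The amplitude floor
trades this false-negative rate against prematurely censoring weak but real
colonization; 2% is the default, and replicate aggregation reports how many
replicates were censored so such cases are visible.

## Synthetic microcosms

Two generators provide inputs with known ground truth.

`sample_curve` draws per-interval increments Normal(μᵢ, (cv·μᵢ)²) truncated
at zero, where μᵢ is the exact model increment over the interval; cv = 0
reproduces the model exactly. Truncation keeps curves nondecreasing and is
negligible for cv ≲ 0.3.

`render_stack` renders frames: discs of additive contrast on a uniform
background with Gaussian sensor noise (no optics model — the statistic is
differencing-based, so shape realism is irrelevant). Cysts are static discs
in a band near the lawn edge, placed without overlap by rejection sampling.
Each amoeba excysts at `tx + Exp(spread)` hours (a shifted exponential; the
shift is the nominal tx), random-walks with per-frame Gaussian steps for an
Exp(tp)-distributed active period, and re-encysts in place. Colonizers
activate at logistic(tc, tg)-distributed times on the lawn, move for a short
fixed burst and freeze — so the expected cumulative colonization activity is
logistic with half-time tc *by construction*, matching the model's second
term. Pixel counts per moving disc are bounded by two disc areas per pair
(disc rasterization uses the strict interior, keeping areas ≤ πr²), which is
what makes the scene's nominal amplitude predictions interpretable as upper
bounds.

The reference scene (the generator defaults) is a 128×128 px field, 2,400
frames at 30 s — a 20 h window holding time-compressed dynamics (tx = 2 h,
tp = 1 h, tc = 10 h, tg = 1 h, 30 cysts, 80 colonizers): rendering the full
~200 h at 30 s/frame would take 24,000 frames for no additional coverage of
the pipeline's behavior, so reference scenes compress the dynamics while
keeping the two-phase shape. What the rendered scenes do **not** emulate:
bacterial lawn texture and growth, illumination drift, focus changes, amoeba
shape change, and crowding interactions. Passing recovery tests therefore
demonstrate the pipeline's correctness on data obeying its model
assumptions, not robustness to those real-world artifacts.

## Replicate statistics

Per-condition summaries report mean ± dispersion per parameter. The
dispersion defaults to the sample SD (SEM by flag): SD is the conservative
reading for N = 3–4 replicates of the printed magnitudes. Censored
tc/tg enter the statistics capped at the window end and are counted; a
condition whose replicates are all censored renders ">window" instead of a
mean.

Conditions are compared per metric by one-way ANOVA followed by Tukey's HSD
at α = 0.05 (family-wise control across the pairwise comparisons; no further
multiple-testing correction, and no two-way or mixed designs). The pairwise
outcome matrix is condensed into a compact letter display with the
insert-and-absorb algorithm: starting from one letter containing all
conditions, each significant pair splits every letter containing both, and
letters that become subsets of another are absorbed. Two conditions share a
letter exactly when their comparison is non-significant — a property the
tests verify against the significance matrix directly, and against a
permutation-test oracle on small samples. Zero variance in all groups yields
a single shared letter with a degenerate-variance warning.

## Numerical and interface choices

* Logistic terms are evaluated with `scipy.special.expit`; the inoculum
  exponential with `expm1` — no overflow or cancellation for extreme
  parameter ratios.
* Curve units are raw pixel counts (AU) by default with an optional constant
  scale; the fit is scale-equivariant, and absolute AU magnitudes of any
  particular camera/optics combination are not reproducible from counts
  alone.
* Frame-pair timestamps use the later frame of each pair: activity is
  observed upon the second frame.
* CSV outputs are comma-separated UTF-8 with '.' decimals, hours for time,
  floats at 6 significant digits; identical configs and inputs give
  byte-identical data files. Each CLI run writes a manifest (version, config
  hash, input hashes, per-stage parameters such as the estimated threshold).
* All stochastic components are pure functions of (spec, seed) using
  numpy's `default_rng`; the fit itself is deterministic.

## Problem sizes used in the test suite

Recovery batteries use 0–200 h curves at 0.5 h resolution (401 points), 20
noiseless and 50 noisy (10% CV) parameter draws within ranges bracketing the
published fits (cIA ∈ [30, 400], cCA ∈ [0, 2000], tx ∈ [1, 8] h,
tp ∈ [3, 15] h, tc ∈ [20, 120] h, tg ∈ [1, 10] h). The image-pipeline
closure test renders the full reference scene; the pixel-count oracle runs
200 randomized stacks up to 16×16 px against a literal per-pixel loop.
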