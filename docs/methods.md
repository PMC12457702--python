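# Methods

## The estimation problem

Heterologous action spectroscopy infers the wavelength of maximum
sensitivity (λ_max) of an opsin from the light-intensity dependence of a
downstream cellular response measured at several stimulus wavelengths.
Cells co-expressing the opsin and the bioluminescent Ca²⁺ reporter aequorin
are flashed (1 s) at each of several wavelengths over a ladder of
intensities (12.5–16 log₁₀ photons·cm⁻²·s⁻¹); the peak fold-over-baseline
luminescence is the response, normalized within each independent experiment
to the maximum observed across all wavelength × intensity combinations.

The key assumption is univariance: a pigment's response depends only on the
number of photons it absorbs, so a stimulus of wavelength λ and photon flux
I behaves like a stimulus of *effective intensity* I·S(λ; λ_max), where
S is the pigment's relative sensitivity. If the candidate λ_max is correct,
responses from all wavelengths collapse onto a single dose–response curve;
if it is wrong, the collapsed data scatter and any single curve fits them
poorly. Goodness of collapse — the residual sum of squares (RSS) of one
fitted curve — is therefore an objective function over candidate λ_max.

## Pigment template

S(λ; λ_max) is the Govardovskii et al. (2000) A1 nomogram: an α-band

    S_α(λ) = 1 / [exp(A(a − x)) + exp(B(b − x)) + exp(C(c − x)) + D],
    x = λ_max/λ,  A = 69.7, B = 28, C = −14.9, D = 0.674,
    b = 0.922, c = 1.104,
    a = 0.8795 + 0.0459·exp(−(λ_max − 300)²/11940)

plus a β-band (cis-peak) Gaussian

    S_β(λ) = 0.26·exp(−((λ − λ_mβ)/b_β)²),
    λ_mβ = 189 + 0.315·λ_max,  b_β = −40.5 + 0.195·λ_max,

renormalized to unit peak over 300–800 nm. The peak is located by a coarse
grid scan refined with a bounded scalar search, so normalized templates
peak at 1 to floating precision. λ_max is restricted to [330, 600] nm, the
nomogram's validity region with margin around the 350–550 nm search range.

Notes:

- The β-band defaults **on**, because UV/violet stimuli (365–405 nm)
  interact with the β-band of blue-shifted pigments; it is a switch
  (`include_beta_band`) since analyses differ on its inclusion.
- For UV pigments (λ_max ≲ 380 nm) the β-band sits just below 300 nm and
  drags the template's overall argmax a couple of nm short of λ_max; the
  normalized sensitivity at λ_max itself is then ~0.998–0.999 rather than 1.
- The α-band is *not* exactly a function of λ_max/λ alone: the parameter
  `a` drifts with λ_max (UV band-narrowing). Scale invariance
  S(λ; λ_max) = S(kλ; kλ_max) holds to machine precision only with `a`
  held fixed, which is how the property is tested.
- Stimuli are treated as monochromatic at their nominal peak wavelength;
  LED bandwidth convolution is out of scope.
- Only the A1 chromophore is implemented; A2 raises `NotImplementedError`.

## Dose–response model

Against effective intensity x the normalized response follows the
generalized log-logistic (5PL):

    f(x) = c + (d − c) / (1 + exp(b·(ln x − ln e)))^f

with lower/upper asymptotes c, d, slope b (negative for an increasing
curve), inflection dose e (linear scale) and asymmetry f > 0. Evaluation
uses `exp(−f·softplus(t))`, stable for any dose including 0 (which maps to
the limiting asymptote).

Fitting is unweighted nonlinear least squares (`scipy.optimize.least_squares`,
TRF, analytic Jacobian) in the parameterization (b, c, d, ln e, ln f) with
bounds keeping the optimizer in the physically meaningful basin for
max-normalized data: c ∈ [−0.5, 0.5], d ∈ [0.5, 2], f ∈ [0.1, 10], e within
three decades of the observed dose range, b ∈ [−20, 20]. Start values are
heuristic (c₀ = min, d₀ = max, e₀ = dose at half-range, b₀ = ±1 by trend,
f₀ = 1), with up to two perturbed restarts on failure. The `converged` flag
is honest: constant responses or optimizer failure return
`converged=False`, never fabricated parameters. Effective doses are floored
at 10⁻³⁰ before taking logs, preserving "this stimulus is ineffective"
without −∞.

All replicates of a genotype are fitted jointly (one curve through all
points); whether the original analyses pooled or averaged replicates is not
documented, and pooling uses all information without extra assumptions.

## λ_max search and bootstrap

`rss_objective(λ)` computes effective intensities for every admitted point,
fits one 5PL and returns its RSS (+∞ on non-convergence so the outer search
can continue). `minimize_lambda` evaluates a 5-nm coarse grid over the
search range (default 350–550 nm) and then runs a bounded scalar
(Brent-style) refinement inside the bracket around the best grid point,
with xatol = 0.01 nm. The pre-scan guards against multimodality: with
UV-only stimulus sets, a long-wavelength candidate's β-band can mimic UV
sensitivity and create a second RSS minimum (this is demonstrated in the
test suite). On every tested dataset the result agrees with a 1-nm
exhaustive grid within 1 nm.

Uncertainty: a nonparametric bootstrap resamples the admitted rows with
replacement to the original count (unstratified — the simplest reading of
"resampling from the original dataset"), repeats the full search per
replicate, and reports the **mean of 100 replicate minima** as the point
estimate, with a 2.5–97.5 percentile interval attached as added reporting.
Non-convergent replicates are dropped from the mean; >20 % failures record
a warning, >80 % is an error. Per-replicate RNG streams are derived from
one root seed by counter (`SeedSequence(seed, spawn_key=(i,))`), so results
are bit-reproducible and independent of execution order.

Wavelength subsets default to the assay designs: {365, 385, 405, 435} nm
for UV pigments and {385, 405, 435, 460, 490} nm for blue-shifted variants
— the stimuli for which responses approach saturation; 525-nm data are
accepted in input files but excluded from estimation by default. All
subsets are overridable per run.

## Synthetic data generator

The generator draws each (wavelength, intensity, replicate) response as
5PL(effective dose under the true template) plus additive Gaussian noise on
the normalized scale (default sd 0.05), truncated at 0, then applies the
same per-replicate max-normalization as the real assay. Defaults mirror
the assay design: stimuli at 365/385/405/435/460/490/525 nm, 8 intensities
evenly spaced over 12.5–16 log₁₀ photons·cm⁻²·s⁻¹ (the printed range; the
actual ladder spacing is not published), 3 replicates, truth 5PL
b = −1.5, c = 0, d = 1, e = 10¹⁴, f = 1 (a half-saturating dose in the
middle of the ladder).

Because the generative model is exactly the model the estimator assumes,
passing recovery tests demonstrates the correctness of the inference code,
not robustness of the method to real-data features it does not emulate:
LED spectral bandwidth, intensity calibration error, reporter consumption
and desensitization, plate-position effects, non-Gaussian or
heteroscedastic noise.

Optional luminescence time courses are cosmetic emulations of the raw
assay: baseline 1.0 for 10 s, a difference-of-exponentials transient
(τ_rise = 2 s, τ_decay = 6 s) sampled every 2 s, multiplicative log-normal
measurement noise. The kernel is normalized over the *sample grid*, so the
sampled peak equals 1 + amplitude_scale·5PL(dose) exactly; with
amplitude_scale = 100, saturating flashes give ~80–130-fold-over-baseline
peaks. The estimator consumes only extracted peaks.

## Problem sizes and numerical choices

- Recovery simulations use the full designs (96 points for the UV design,
  120 for the shifted design) with 100 bootstrap iterations; statistical
  property tests use 20–25 simulated datasets per condition, and the
  bootstrap-coverage check 25 runs at 30 iterations.
- Tolerances: template values agree with an independent evaluation to
  1e-6 relative; the 5PL fit RSS never exceeds a profiled brute-force grid
  minimum; the bounded search agrees with a 1-nm exhaustive grid within
  1 nm; recovery at assay noise is within ±5 nm of truth.
- Degenerate inputs (single wavelength, <4 intensities, <6 points,
  constant responses, all-zero replicates) are refused with messages naming
  the offending unit, never silently fitted.

## Known limitations

- The 95 % percentile interval is bootstrap reporting, not a calibrated
  confidence interval; percentile bootstrap under-covers at these sample
  sizes (coverage ≳ 80 % in simulation).
- Estimation near the search boundaries is flagged (`at_boundary`) but not
  corrected; a truth outside the admitted range surfaces as a flagged
  boundary estimate.
- With UV-only stimulus subsets, β-band mimicry limits identifiability at
  the long-wavelength end of the search range; including ≥1 mid-visible
  wavelength resolves it.
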