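# actionspec

Estimation of an opsin's wavelength of maximum sensitivity (λ_max) from
heterologous-cell irradiance–response data, with a synthetic-data generator
emulating the aequorin Ca²⁺ assay so the whole pipeline is testable without
laboratory data.

## Who this is for

Photobiology and optogenetics labs that characterize opsin variants by
action spectroscopy: cells co-expressing an opsin and a bioluminescent Ca²⁺
reporter are flashed at several wavelengths (e.g. 365–525 nm) over a ladder
of intensities (12.5–16 log₁₀ photons·cm⁻²·s⁻¹), and the spectral
sensitivity of the pigment is inferred from how response amplitude depends
on wavelength and photon flux.

## The method

By univariance, a flash of wavelength λ and photon flux I is equivalent to
an *effective intensity* I·S(λ; λ_max), where S is the Govardovskii A1
pigment template. For a candidate λ_max, all data are collapsed onto one
effective-intensity axis and a 5-parameter logistic

  f(x) = c + (d − c) / (1 + exp(b·(ln x − ln e)))^f

is fitted by least squares; the residual sum of squares (RSS) measures how
well the collapse worked. λ_max is the minimizer of the RSS over a bounded
range (default 350–550 nm, Brent-style search preceded by a 5-nm grid
pre-scan). Uncertainty comes from a nonparametric bootstrap (100
resamples of the data rows with replacement; the mean of the replicate
minima is the point estimate, with a 2.5–97.5 percentile interval).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a blue-shifted opsin variant (true λ_max = 447 nm) under the
standard assay design and re-estimate it:

```python
import actionspec as ax

cfg = ax.SimulationConfig(true_lambda_max=447.0, noise_sd=0.05,
                          n_replicates=3, seed=7)
ds = ax.generate_dataset(cfg, wavelength_subset=ax.SHIFTED_WAVELENGTH_SUBSET)
est = ax.estimate_lambda_max(ds, n_boot=100, seed=1)
print(f"lambda_max = {est.point_estimate:.1f} nm "
      f"[{est.ci_low:.1f}, {est.ci_high:.1f}] "
      f"({est.n_boot_converged}/{est.n_boot_requested} replicates)")
```

```
lambda_max = 447.1 nm [444.9, 448.9] (100/100 replicates)
```

The point estimate is the bootstrap mean; the bracket is the percentile
interval; with 5 % additive noise and 3 replicates the true 447 nm is
recovered within a nanometre here. The same pipeline is available from the
shell:

```sh
actionspec simulate --lambda-max 447 --noise-sd 0.05 --seed 7 --out synth.csv
actionspec estimate --input synth.csv --genotype simulated \
    --wavelengths 385,405,435,460,490 --n-boot 100 --seed 1 --out result.json
actionspec template --lambda-max 447 --out curve.csv   # sensitivity curve
```

Input CSVs are tidy tables with columns `genotype, replicate,
wavelength_nm, log10_irradiance` and either `response` (normalized) or
`raw_peak` (per-replicate max-normalization applied on load).

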