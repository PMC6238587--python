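# oxykin

Progress-curve kinetics for Clark-electrode oxygen-consumption assays of
sulfhydryl oxidases (Ero1α, Ero1β, Erv1p and relatives).

Ero1-family enzymes generate disulfide bonds de novo, reducing O2 to H2O2,
and are activated from a disulfide-locked resting state only after injection
into the assay — their oxygen traces show a characteristic lag phase, a
linear maximal-rate phase, and (for the human Ero1s) a remarkably sharp,
cooperative shutoff as oxygen runs out. `oxykin` turns such traces into
kinetic parameters: it normalizes and smooths the trace, differentiates it
to a consumption-rate series, estimates the electrode background from the
pre-injection drift, fits the rate law below by nonlinear least squares with
model selection by residual randomness, and reports k_cat, K_M, the Hill
coefficient, the activation rate constants and the activation halftime. A
forward simulator generates traces with the same statistical structure, so
every estimator in the package is validated by parameter recovery against
known ground truth.

## The model

The observed consumption rate (μM/s) as a function of time and dissolved
oxygen is

    f([O2], t) = x·[O2] + a(t − t_i) · V_max · [O2]^n / ([O2]^n + K_M^n)

where `x` is the electrode's oxygen-proportional background (s⁻¹, estimated
from a 60-s linear fit to the pre-injection phase), `t_i` the injection
time, `V_max` the maximal rate, `K_M` the half-saturation oxygen
concentration, and `n` the Hill coefficient for oxygen. The activation
profile `a(τ)` is built from sequential (pseudo) first-order steps with only
the terminal state active:

* one-step, A → B:   `a = 1 − e^(−k1 τ)`
* two-step, A → B → C: `a = (k2(1 − e^(−k1 τ)) − k1(1 − e^(−k2 τ)))/(k2 − k1)`
* activation + inactivation, A → B → C with only B active:
  `a = k1(e^(−k1 τ) − e^(−k3 τ))/(k3 − k1)`

k_cat is V_max divided by the enzyme concentration (one O2 per turnover),
and the halftime of activation is the time at which `a` crosses 1/2.
Candidate models are tried simplest-first; the first one whose fit converges
with random residuals (Wald–Wolfowitz runs test on decorrelated residual
signs) is kept. Titration series — k_cat, rate constants or halftimes
versus substrate concentration — are fitted to a single pseudo-first-order
saturating law parameterised by its half-maximal concentration.

## Worked example

Simulate a 1 μM Ero1α–PDI run (250 μM O2, injection at 240 s, 0.1 s
sampling, 0.5 μM measurement noise) and re-fit it with the two-step
cooperative model:

```python
from oxykin import SimulationConfig, simulate_trace, analyze_trace
from oxykin.presets import ERO1A_PDI

cfg = SimulationConfig(params=ERO1A_PDI.params, spec=ERO1A_PDI.spec,
                       total_duration=2800.0, noise_sd=0.5, seed=42)
trace = simulate_trace(cfg)
res = analyze_trace(trace, spec=ERO1A_PDI.spec)
p = res.params
print(f"k_cat       : {res.derived['kcat']:.3f} s^-1")
print(f"K_M         : {p.km:.2f} uM")
print(f"Hill n      : {p.n:.2f}")
print(f"k1, k2      : {p.k1:.2f}, {p.k2:.2f} min^-1")
print(f"halftime    : {res.derived['halftime']:.2f} min")
print(f"runs-test p : {res.runs_test_p:.2f}")
```

prints

```
k_cat       : 0.643 s^-1
K_M         : 4.98 uM
Hill n      : 4.90
k1, k2      : 0.95, 1.25 min^-1
halftime    : 1.55 min
runs-test p : 0.29
```

against the generating truth k_cat = 0.64 s⁻¹, K_M = 5.0 μM, n = 5.2,
k1 = 1.04, k2 = 1.12 min⁻¹ (halftime 1.56 min). k_cat, K_M and the halftime
come back within a percent or two; the individual rate constants of a
nearly-degenerate two-step scheme scatter more (their ordered pair is only
weakly identified), while their halftime — the quantity that matters — is
stable. The runs-test p of 0.29 says the residuals carry no structure:
the model is adequate.

The same pipeline is available from the shell:

```sh
oxykin fixtures -o fixtures/ --seed 1          # canonical synthetic traces
oxykin fit fixtures/ero1a_pdi_noise0.5.csv -o out/ --model two_step
oxykin simulate --config my_run.yaml -o sim/ --seed 7
```

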