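# kmdkit

Locate the **kinetically derived maximum dose (KMD)** — the exposure region
where systemic elimination kinetics begin to saturate — from toxicokinetic
time–concentration data.

Dose-setting for regulatory toxicology studies should keep all doses on one
side of kinetic saturation: above it, different modes of action are engaged
and interpretation changes. kmdkit implements a saturation-based KMD
workflow for toxicokineticists and risk assessors:

1. **Model** elimination as a system-wide Michaelis–Menten process,
   `dC/dt = −Vmax·C/(Km+C)`, the aggregate saturable behaviour of all the
   enzymes and transporters driving elimination.
2. **Estimate** `Vmax` and `Km` from an elimination time course by Bayesian
   MCMC (truncated-normal priors, half-Cauchy noise scale, Normal likelihood
   on the exact Lambert-W solution of the ODE), or by maximum likelihood.
3. **Find the knee** of the Michaelis–Menten rate curve `v = Vmax·S/(Km+S)`
   with the kneedle algorithm, on windows anchored at the 90%/95%-of-Vmax
   concentrations (`S = 9·Km` and `19·Km`). The knee of the curve on
   `[0, Smax]` has the closed form `sqrt(Km·(Km+Smax)) − Km`, independent of
   Vmax.
4. **Report the KMD as a region** — lower bound, midpoint, upper bound —
   propagating the Km posterior uncertainty through the knee computation.

## Worked example

The packaged example is alcohol elimination by hepatic alcohol dehydrogenase
(truth `Vmax = 175` mg/dL·h⁻¹, `Km = 11.8` mg/dL, starting concentration
`c0 = 19·Km = 224.2` mg/dL, 49 samples, 5% proportional noise):

```python
import kmdkit as kk

ds = kk.default_example_dataset(seed=1)
summary = kk.fit_mm_bayes(ds, kk.alcohol_example_priors())
region = kk.compute_kmd_region(summary)
print(kk.format_report(kk.kmd_report(region, summary)))
```

prints

```
KMD region (knee of the system-wide Michaelis-Menten curve)
  lower    :   25 mg/dL  (raw 24.82, window 0-118.3)
  midpoint :   38 mg/dL  (raw 37.75)
  upper    :   51 mg/dL  (raw 50.73, window 0-249.7)
  window anchors at 90% and 95% of Vmax
posterior marginals:
   vmax: mean 179.43, 95% CI [171.26, 187.75], rhat 1.008
     km: mean 13.14, 95% CI [8.98, 17.37], rhat 1.007
  sigma: mean 4.61, 95% CI [3.78, 5.65], rhat 1.007
     c0: mean 226.01, 95% CI [223.00, 228.95], rhat 1.007
```

The credible intervals cover the truth; the region says a study run below
~25 mg/dL stays clearly on the unsaturated side of elimination. With the
published posterior for this example (`Km` mean 11.97, CI [11, 13]) and
anchors from the true Km, the region is 25 / 34 / ~42.5 mg/dL — see
`examples/03_find_kmd_region.py`.

The `examples/` directory has one short script per capability (simulate,
fit, find the region, reproduce the slope table). A thin CLI wraps the same
functions:

```bash
kmdkit simulate --vmax 175 --km 11.8 --c0 224.2 --seed 7 --out tk.csv
kmdkit fit --data tk.csv --out posterior.json
kmdkit kmd --posterior posterior.json --out report.json
kmdkit run --seed 1 --outdir kmd_run    # end-to-end
```

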