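# n2opulse

Source attribution of pulsed soil N₂O emissions.

When long-dry soils are wetted, they can release brief, intense pulses of
nitrous oxide. Working out *which* microbial (or abiotic) process produced
that N₂O — nitrification, nitrifier denitrification, bacterial or fungal
denitrification, chemodenitrification, and how much was subsequently reduced
to N₂ — requires chaining several quantitative steps. `n2opulse` implements
that chain as a tested library for soil biogeochemists:

1. **Chamber fluxes** — OLS slope of the N₂O mole fraction over the last
   90 s of a 2-min closure, gated to zero when the slope is not significant
   (p > α), converted with the ideal gas law:
   F = (dC/dt)·(PV/RT)·M_N / A  (ng N m⁻² s⁻¹), plus peak/cumulative pulse
   summaries and the open-system *δ¹⁵N tail index.
2. **Isotopocules** — δ notation per isotopocule
   (δ = (R_sample/R_std − 1)·10³), site preference SP = δ¹⁵Nα − δ¹⁵Nβ,
   δ¹⁵N_bulk = (δ¹⁵Nα + δ¹⁵Nβ)/2, and per-isotopocule calibration against
   USGS 51/52 reference gases with 1/[N₂O] and [CO₂] dependency terms.
3. **Keeling plots** — δ regressed on 1/[N₂O]; the intercept is the isotopic
   signature of the soil-derived source.
4. **¹⁵N tracer mass balance** — atom-fraction-scale two-pool bookkeeping,
   f_tracer = (x_mix − x_native)/(x_tracer − x_native), exact at 2 at%
   enrichment where delta-scale arithmetic breaks down.
5. **Source partitioning** — substrate-corrected endmember boxes in
   (SP, δ¹⁵N, δ¹⁸O) space, Rayleigh trajectories of N₂O → N₂ reduction
   (closed: δ = δ₀ + ε ln f; open steady state: δ = δ₀ − ε(1 − f)),
   inversion for the fraction of N₂O remaining, and Monte-Carlo propagation
   of endmember/ε uncertainty.
6. **qPCR quantification** — standard-curve fits (Cq vs log₁₀ copies),
   amplification efficiency E = 10^(−1/slope) − 1, copies per gram of soil,
   and replicate-majority detection calls.

A seeded synthetic module (`n2opulse.synthetic`) generates every input the
pipeline consumes — wetting pulses sampled by scheduled chambers, two-source
Keeling mixtures, endmember mixtures overprinted by reduction, analyser
calibration runs, and qPCR plates — so the whole chain is testable without
instruments.

## Worked example

```python
import numpy as np
from n2opulse import *
from n2opulse.partition import build_endmembers

cfg = default_config(seed=0)

# a wetting pulse peaking at 414 ng N m-2 s-1, sampled every 30 min
scn = PulseScenario(noise_sd_ppb=2.0, seed=0)
ests = [fit_flux(s, deadband_s=30.0) for s in gen_chamber_series(scn, cfg.chamber_geometry)]
summ = summarize_pulse(ests, window_h=5.0, t0_s=0.0)
print(summ.peak_flux, summ.time_of_peak_h, summ.cumulative_flux_h)

# attribute a strongly reduced bacterial-denitrification signature
boxes = build_endmembers(cfg.endmembers, cfg.substrates)
start = tuple(boxes["bacterial_denitrification"].centroid())
mix = MixtureScenario(points={"bacterial_denitrification": start},
                      f_rem=0.05, noise_sd=2.0, n_samples=6, seed=7)
readings = gen_isotopocule_samples(mix, cfg)
pt = tuple(np.mean([r.point for r in readings], axis=0))
res = classify_point(pt, boxes, cfg.rayleigh)
print(res.process, res.f_rem, res.residual)
```

Output (abridged):

```
peak flux  : 412.7 ng N m-2 s-1 at 0.5 h
cumulative : 516.0 (ng N m-2 s-1) h over 11 closures
mean SP 13.1 permil -> bacterial_denitrification, f_rem=0.048, residual=0.77 permil
```

Read: the noisy chamber record recovers the 414 ng N m⁻² s⁻¹ pulse peak at
0.5 h; the isotope samples sit well above the bacterial-denitrification SP
range (−7.5 to 3.7‰), but the classifier explains them as that endmember
displaced along the reduction trajectory with only ~5% of the N₂O
remaining — elevated SP alone does not rule out denitrification.

## Command line

Each stage is also exposed as a thin CLI over the library:

```bash
n2opulse simulate --seed 7 --out demo/            # synthetic inputs
n2opulse flux      --in demo/chamber.csv      --out flux.csv
n2opulse isotopes  --in demo/isotopocules.csv --out iso.csv
n2opulse partition --in iso.csv               --out part.csv
n2opulse qpcr      --in demo/qpcr.csv         --out qpcr.csv
```

`--config run.yaml` supplies chamber geometry, fit windows, endmember boxes,
Rayleigh ε values, substrate signatures and reference standards; see
`n2opulse.config.default_config()` for the full schema and defaults, and
`docs/methods.md` for what each parameter means.

## Acceptance script

`scripts/acceptance.py` recomputes the package's worked-example target from
scratch (the site preference of the USGS 51 reference gas from its certified
site-specific deltas, via `site_preference`) and writes it as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
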