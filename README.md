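# outgrowth

Agent-based simulation of variant-cell outgrowth in contact-inhibited
epithelial cultures, with the analysis layer that links growth-plateau
width to the initial variant fraction and models radiation-accelerated
selection.

## The problem

Primary human mammary epithelial cells (HMEC) cultured from normal
breast tissue stop dividing after 5-20 population doublings and enter a
senescence-like arrest ("stasis").  Rare variant cells (vHMEC), which
have epigenetically silenced the cell-cycle inhibitor p16, escape stasis
and slowly take over the culture: the cumulative population-doubling
curve climbs, flattens into a plateau while senescent normal cells
dominate the surface, then resumes as variant colonies fill the dish.
Ionizing radiation shortens that plateau — not by creating new variants,
but by prematurely senescing the radiosensitive normal cells and freeing
surface area for the radioresistant variants.

`outgrowth` implements this system as an on-lattice agent-based model:
cells are quasi-circular pixel footprints (21 px = 175 um^2 uncrowded,
compressible to 6 px = 50 um^2) on a 400 x 400 grid, dividing every 26 h
while local space permits, converting permanently to an enlarged
senescent state at a class-specific division limit (7 for normal cells,
40 for variants in the standard scenario), serially passaged at 80%
confluence with senescent cells lost at replating.  The analysis layer
computes PD = log(A/B)/log 2 bookkeeping, detects growth plateaus,
fits the inverse power law W = a f^(-b) between plateau width W and
initial variant fraction f, and inverts it — so an observed plateau
width estimates how many variant cells a primary culture started with.
A dose-response module fits per-class exponential senescence-survival
curves e^(-alpha D) and applies stochastic radiation-induced senescence
to running simulations.

## Worked example

```python
from outgrowth import (SenescenceAssay, fit_alpha, detect_plateau,
                       fit_plateau_power_law, infer_initial_fraction)
from outgrowth.fixtures import dose_response_table, growth_curve_table

# recover a radiation dose-response coefficient from a noisy assay table
assay = SenescenceAssay(dose_response_table(alpha=0.4, noise_sigma=0.05,
                                            seed=7), normalized=True)
fit = fit_alpha(assay)
print(f"alpha = {fit.alpha:.3f} / Gy   (R^2 = {fit.r_squared:.3f})")

# detect a growth plateau in a PD curve with a planted 20-day stall
curve = growth_curve_table(baseline_rate=0.85, pre_days=8, plateau_width=20)
est = detect_plateau(curve)
print(f"plateau: {est.width:.1f} days starting day {est.start:.1f} "
      f"(baseline {est.baseline_rate:.2f} PD/day)")

# invert plateau width -> initial variant fraction from sweep results
points = [(0.0025, 34.9), (0.01, 5.6), (0.035, 3.4)]
pl = fit_plateau_power_law(points)
f = infer_initial_fraction(pl, 23.0)
print(f"W = {pl.a:.3g} * f^(-{pl.b:.2f});  W = 23 d -> f = {f*100:.2f}%")
```

prints

```
alpha = 0.403 / Gy   (R^2 = 1.000)
plateau: 19.1 days starting day 8.5 (baseline 0.85 PD/day)
W = 0.139 * f^(-0.89);  W = 23 d -> f = 0.32%
```

The first line shows the fitter recovering the true per-Gy senescence
rate (0.4) from a 5-point assay with 5% multiplicative noise.  The
second recovers a planted plateau to within the 2-day smoothing window.
The third fits the plateau-width power law to simulated sweep points and
inverts it at a 23-day plateau, estimating that such a culture started
with ~0.3% variant cells.

Full simulations run through presets:

```python
from outgrowth import run_serial_culture, detect_plateau
from outgrowth.config import preset

cfg = preset("serial_passage")   # 1,200 cells, 0.25% variants, 7/40 limits
record = run_serial_culture(cfg.dynamics, cfg.passaging, cfg.seeding, seed=10)
print(detect_plateau(record))
```

which takes about a minute and reports a plateau of ~27 days starting
near day 8 (at ~6.6 cumulative PD) for that seed.  The same scenario is
available from the shell:

```
outgrowth simulate --preset serial_passage --replicates 5 --out-dir results
outgrowth sweep --fractions 0.0025,0.006,0.01,0.02,0.035 --plot
outgrowth fit-dose-response --assay assay.csv
outgrowth analyze --record results/growth_serial_passage_rep0.csv
outgrowth render --preset serial_passage_irradiated --days 3
```

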