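# Methods

`outgrowth` simulates the long-term population dynamics of primary human
mammary epithelial cell (HMEC) cultures, in which rare variant cells
(vHMEC, with epigenetically silenced p16) escape the senescence-like
arrest ("stasis") that halts normal cells, and eventually take over the
culture.  The model is an on-lattice agent-based simulation with a small
analysis layer; its purpose is to reproduce and interrogate three
emergent phenomena:

1. the plateau in cumulative population doublings (PD) when most normal
   cells enter stasis, followed by resumed exponential growth as variant
   colonies take over;
2. the inverse power-law relation between the plateau width W (days) and
   the initial variant fraction f, which can be inverted to estimate the
   variant load of a primary culture from its growth curve alone; and
3. the shortening of the plateau after ionizing radiation, driven purely
   by the differential radiosensitivity of normal versus variant cells
   (radiation-induced senescence of normal cells frees surface area into
   which radioresistant variants expand).

## The lattice and cell footprints

The culture surface is a 400 x 400 pixel grid with exclusive pixel
occupancy.  The calibration is 21 pixels = 175 um^2 (one pixel ~ 8.33
um^2), so the uncrowded cell footprint of 21 px matches light-microscopy
measurements of these cells, and the fully compressed footprint of 6 px
is 50 um^2.  Footprints are 8-connected, quasi-circular blobs maintained
by nearest-to-centroid accretion.  1,200 cells are plated per passage
(~20% seeding by count) and cultures are harvested at 80% area coverage
(~6,000 uncrowded cells).

## Cell rules

Each cell carries a class (normal / variant), a state (proliferative /
senescent), a division count with a class-specific limit, and a cycle
phase.  The cycle lasts 26 h for both classes; phases are initialized
uniformly at random at every plating so the population divides
asynchronously.  The timestep is 1 h.  On cycle completion:

* **Space-gated division.**  If at least one uncrowded footprint's worth
  of free pixels lies within the division search radius (7 px, about 1.3
  cell diameters) of the cell's footprint, a daughter is placed there at
  full size.  The neighbourhood is a plain Chebyshev window: a free
  pocket behind one flat senescent neighbour is usable (the daughter
  displaces past it), but space further away is not — divisions are
  strictly local, so colonies grow at their rim, at ~5 px (~one cell
  diameter) per cycle.
* **Compressed division.**  With less free space, the mother's own
  pixels plus the nearby free pixels are split into two connected
  daughters, each compressed as far as the 6-px minimum.  A cell that
  cannot fit two minimal daughters is blocked: its completed-cycle timer
  is held, and the attempt repeats as soon as any nearby pixel is freed.
  Blocked cells still *re-spread* into free pixels they can reach, so a
  compressed cell creeps into opening space even when it cannot divide.
* **Senescent conversion.**  A division that brings a cell to its limit
  converts it permanently to the senescent state.  Senescent cells never
  divide; on conversion they enlarge once, locally, toward twice the
  uncrowded area (42 px = 350 um^2) — senescent epithelial cells are
  conspicuously enlarged and flat, and their occupied area is what makes
  a mostly-senescent culture still reach harvest confluence.  After
  enlargement the footprint is static.
* **Non-reattachment.**  At subculture, senescent cells in the plating
  aliquot fail to reattach and are lost (see below).

Division counting is symmetric: both products of a division carry the
mother's count plus one.  A rim lineage therefore accumulates one
division per cycle, which means a variant colony founded by a single
cell can genuinely exhaust the 40-division variant limit before filling
the grid — visible in sweeps as plateaus that never end at very low
initial fractions.

## Serial passaging and PD bookkeeping

When the grid reaches 80% coverage the culture is harvested: the plating
aliquot (1,200 cells, or the whole harvest if smaller) is drawn from the
suspension, senescent members of the aliquot are discarded (they do not
reattach), and the survivors are re-dispersed at random, at uncrowded
size, on a fresh grid, keeping their class and division count.

Cumulative PD uses the experimental bookkeeping: each passage adds
log2(A/B) with A the number of cells collected and B the number plated
(not the number that attached).  Because B includes the senescent cells
that fail to attach, PD under-counts true doublings during stasis — and
that undercount is precisely what produces the visible plateau in the
PD-versus-days curve.  Within a passage the curve reports
max(0, log2(n(t)/B)), which keeps it continuous and non-decreasing.

Aliquot sampling is proportional by default: each (class, state)
subpopulation contributes its largest-remainder share of the 1,200,
individuals drawn uniformly within the subpopulation.  The model
represents a ~1.2 x 10^6-cell culture with ~6 x 10^3 agents; per-agent
multinomial sampling would inflate composition drift roughly 30-fold
over the real experiment and can extinguish the rare variant clone by
bookkeeping alone.  (Uniform sampling is available as
`PassageConfig(sampling="uniform")`.)

A passage that has not reached the saturation trigger after
`max_passage_days` (default 28) is subcultured anyway, mirroring the
experimental protocol: stalled, senescent-dominated cultures are still
trypsinized and replated on a roughly monthly schedule.  This matters
for a specific spatial failure mode: the oldest cells of a variant
colony sit on its rim, so when rim lineages exhaust the 40-division
budget they senesce into a crust that entombs still-proliferative
interior cells; the scheduled subculture releases them, as
trypsinization does in the dish.

## Radiation

The surviving (non-senescent) fraction after an acute dose D follows
e^(-alpha D) per class.  `fit_alpha` fits alpha by bounded nonlinear
least squares on the natural scale (log-linearization would overweight
near-zero fractions); R^2 is reported on the same scale.  Defaults
alpha_normal = 0.4/Gy and alpha_variant = 0.02/Gy are fixed by four
assay bounds (2 Gy senesces >40% of normal and <5% of variant cells;
>=6 Gy senesces >90% of normal cells; 10 Gy senesces <20% of variant
cells).  `irradiate` converts each proliferative cell independently with
probability 1 - e^(-alpha_class D); conversions are permanent and follow
the same enlargement rule as replicative senescence.  The irradiated
preset applies 2 Gy at plating time of the first passage; because no
division occurs before ~26 h, applying the dose at plating versus
mid-first-cycle is statistically indistinguishable, and a post-exposure
recovery interval is subsumed by the first passage's growth.
The pre-existing-senescence-corrected induction index is
(Ps(D) - Ps(0)) / (1 - Ps(0)).

## Growth analysis

`detect_plateau` interpolates the cumulative PD curve onto a uniform
grid (0.125 d), computes a centred moving-window rate (2-day window) and
takes the baseline as the realized mean rate of the first passage
(~0.87 PD/day).  The plateau is the longest contiguous stretch with rate
below 25% of baseline; a plateau still open at the end of the record is
flagged *censored* (the culture never resumed — extinct, quiescent, or
horizon-limited) and its width treated as a lower bound.  The threshold
and window are exposed because "significantly sub-exponential" admits no
unique test; widths shift by a few days under threshold changes, which
is comparable to the replicate spread.

`fit_plateau_power_law` fits log W = log a - b log f by ordinary least
squares; `infer_initial_fraction` inverts f = (a/W)^(1/b), warning when
extrapolating beyond the fitted range.  Censored sweep points are
excluded from fitting.  `relative_standard_error` interpolates replicate
PD curves onto a shared time base and reports SE/mean per timepoint
(where the mean exceeds 1 PD; a relative error near zero is
meaningless), plus the maximum.

## Emergent behaviour and problem sizes

With the defaults above (no quantity fitted to any simulation output at
run time), the standard serial-passage scenario (limits 7/40,
f = 0.25%, five replicates, 60-day horizon) produces: plateau onset at
~6.6 cumulative PD on day ~8; a plateau of ~17-28 days; resumed
exponential growth to >25 PD by day 60; and a maximum replicate RSE of
cumulative PD of ~4-8%.  Sweeping f = 0.1%-3.5% (two replicates per
fraction, stopping each run once the curve has passed ~11.5 PD) gives
monotone decreasing widths whose power-law fit, inverted at
W = 23 days, returns an initial fraction of ~0.2-0.35%.  At the lowest
fractions the width is partly set by the monthly subculture schedule
(an entombed single-founder colony is rescued by replating rather than
by reaching confluence), so the power law steepens below ~0.2%.

## What the synthetic generators do and do not capture

The fixture generators (`dose_response_table`, `growth_curve_table`,
`lattice_state`) draw from the model's own forms — exponential survival
with lognormal noise, piecewise-linear PD curves with a planted plateau,
uniformly seeded lattices.  They validate the fitting and detection
machinery against known truths; they do not emulate biological
heterogeneity (per-cell cycle-time variation, plating-efficiency losses
for proliferative cells, paracrine effects, motility), so passing these
tests demonstrates correctness of the estimators, not realism of the
biology.  Likewise the simulation represents a culture ~200-fold
smaller than the experiment; finite-size effects (founder-number
stochasticity at low f, the division-budget ceiling above) are artefacts
of that scale, mitigated but not removed by proportional replating.

## Numerical choices and degenerate inputs

Deterministic tie-breaking (lexicographic) makes every geometric
operation reproducible; all randomness flows from one seeded generator
per simulation, and replicate i uses seed base + i.  Division order is
reshuffled every step to avoid spatial bias.  Blocked cells are parked
until a pixel is freed within their search window (free space appears
only through erasure, so parking is exact, not approximate).  Degenerate
analysis inputs raise typed errors: non-positive counts in the PD
formula, records shorter than the smoothing window, power-law fits with
fewer than three distinct fractions or non-decreasing widths, dose
tables without two distinct doses.  A best-fit alpha that would be
negative is clipped to zero with a warning; alpha = 0 is reported
exactly when it fits no worse than the interior optimum.

## Known limitations

* No cell motility, apoptosis, or paracrine signalling; senescent cells
  are spatial obstacles only.
* Compression applies to the dividing cell (and its daughters), not to
  neighbours; a colony interior can strand occasional cells below the
  divisible size.
* The division-count budget interacts with rim-limited growth (see
  above); plateau widths for initial fractions below ~0.2% are lower
  bounds.
* The 80% trigger, 21/6-px footprints and 26-h cycle are treated as
  exact; real cultures vary in all of them.
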