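# foragemap

Behavioural maps from GPS telemetry and resource maps from imaging
spectroscopy, combined into a statistical comparison of where sympatric
mountain ungulates (chamois, ibex, red deer) concentrate their foraging.

The package is aimed at movement ecologists and remote-sensing scientists
who want to ask: *do co-occurring herbivore species use areas of different
forage quantity (plant biomass) and quality (plant nitrogen content)?* It
chains four stages, each usable on its own:

1. **GPS screening** — resample fixes to a common 4 h interval, trim
   capture days, and flag location errors with a two-stage rule: gross
   outliers by distance from a windowed location median (μ = 50 km within a
   20 h window, Δ = 200 km overall) and out-and-back "spikes" whose inbound
   and outbound speeds both exceed α = 1.5 km h⁻¹ with turn cosine below
   −0.97.
2. **Time-local convex hulls** — a utilisation-distribution method that
   respects the spatial *and* temporal structure of telemetry. Fixes *i*, *j*
   are neighbours under the time-scaled distance

   ```
   TSD(i, j) = sqrt(Δx² + Δy² + (s · v_max · Δt)²)
   ```

   with the time weighting *s* chosen so that 60% of points are
   "time-selected" (their nearest-neighbour sets change when time enters the
   metric). A local convex hull is built around every fix from its
   neighbours (cumulative-distance *a*-method by default), each hull is
   scored by its revisitation rate — the number of separate visits (NSV)
   under a 12 h inter-visit gap, normalised to NNSV — and hulls are merged
   in decreasing NNSV order until 30% of all fixes are enclosed. That 30%
   isopleth is the animal's **core foraging area (CFA)**.
3. **Spectral resource models** — for ground plots with clipped-biomass and
   nitrogen reference data, every ordered band pair's simple ratio index
   (SRI = band *i* / band *j*) is correlated with the response; the 100 best
   pairs are fitted with linear, exponential and second-order polynomial
   models, validated by leave-one-out cross validation, and the minimum-AIC
   model is selected and judged by Theil's U, adjusted R², RMSE and the
   share of samples predicted within 20% error. Non-grassland cells
   (forest, rock, snow, water) are masked by fully constrained linear
   spectral unmixing at a 50% grass-fraction threshold, and the selected
   models predict biomass and nitrogen on the full 2 m raster.
4. **Species comparison** — raster cells inside each species' CFAs become
   observations of a baseline-category (multinomial) logit with chamois as
   reference: logit 1 contrasts ibex, logit 2 red deer, with predictors
   BiomRS = biomass/100 and N (%). Five candidate forms (intercept-only,
   each single predictor, main effects, interaction) are compared by ΔAIC
   and likelihood-ratio tests; fit is diagnosed per logit with the
   Hosmer–Lemeshow statistic and ROC AUC, and robustness to the CFA
   delineation is probed by re-running the analysis on ±6 m buffered
   polygons.

A synthetic-data module generates trajectories with a known patch-revisit
itinerary, hyperspectral scenes with *planted* band-ratio relations and
endmember mixing, ground-truth plot tables, and species cell-use following
a known preference logit — so every stage can be verified against ground
truth without any field data.

## Worked example

```python
from foragemap import (TrajectoryConfig, simulate_trajectory, GPSScreener,
                       TLoCoH, SceneConfig, generate_scene, sample_plots,
                       SRIRegressor)
from foragemap.synthetic import Patch

# a 43-day, 4-hourly trajectory commuting between two foraging patches
traj = simulate_trajectory(TrajectoryConfig(
    patches=[Patch(0, 0, 25), Patch(300, 0, 25)], seed=1))
flagged = GPSScreener().fit_transform(traj)
print(f"{len(flagged)} fixes, {int((flagged.flag_stage1 | flagged.flag_stage2).sum())} flagged")

est = TLoCoH(method="a", a="auto", s="auto",
             a_candidates=[300, 600, 1200, 2400]).fit(flagged)
print(f"s = {est.s_:.4g} (ptsh = {est.ptsh_:.3f}), a = {est.a_:.0f} m")
print(f"30% CFA area = {est.cfa_.area:.0f} m^2")

# a synthetic grassland scene with a planted biomass band ratio
scene = generate_scene(SceneConfig(n_rows=50, n_cols=50, n_bands=12,
                                   noise_sd=0.004, pure_grass=True, seed=3))
plots = sample_plots(scene, 51, seed=11)
reg = SRIRegressor(response="biomass", top_n=20).fit(plots, plots["biomass"].to_numpy())
print(f"best biomass model: bands {reg.band_pair_}, form {reg.form_}")
```

prints

```
259 fixes, 0 flagged
s = 0.001474 (ptsh = 0.598), a = 300 m
30% CFA area = 5274 m^2
best biomass model: bands (6, 4), form polynomial2
```

The screener flags nothing on a clean track; the time weighting lands on
the 60% time-selected-hull target; the CFA concentrates on the two planted
patches; and the band-ratio search recovers exactly the band pair (6, 4)
and quadratic form that the scene generator planted.

`run_study` (and the `foragemap run` CLI subcommand) executes the whole
chain — scene, plots, model selection, unmixing, rasters, trajectories,
screening, CFAs, multinomial comparison, diagnostics, buffer sensitivity —
from a single config and seed, and writes the report bundle (model cards as
JSON, selection and coefficient tables as CSV, CFAs as GeoJSON, the
resource raster as TIFF).

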