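# tcellmech

A quantitative toolkit for cell-mechanosensing assays: the bespoke numerical
procedures used when characterising how T lymphocytes respond to substrate
stiffness, packaged as a reusable, tested pipeline. It covers four
independent stages plus matching synthetic-data generators:

1. **Migration-track analytics** (`tcellmech.tracks`) — per-cell 2D
   trajectories (µm positions at a fixed frame interval) are reduced to
   instantaneous speeds, the maximum excursion (largest distance between any
   two points of a track), and an arrested/migrating call: a cell is
   *arrested* when its maximum excursion over a 5-min window is strictly
   below 10 µm, i.e. below 2 µm/min (the threshold scales linearly for
   non-standard durations). Cohort summaries report % arrested and the mean
   ± SEM instantaneous velocity of migrating cells.
2. **Hertz indentation fitting** (`tcellmech.indentation`) — raw cantilever
   pairs (base displacement D, tip displacement d) become force-indentation
   data via F = k(D − d), δ = d, and the incompressible spherical Hertz
   model F = (16/9)√R·E·δ^{3/2} is fitted for the cell Young's modulus E by
   a closed-form least-squares slope (the model is linear in E).
3. **Gel rheology conversion** (`tcellmech.rheology`) — parallel-plate gap
   sweeps G′(gap) are reduced to the plateau modulus (the maximum over the
   sweep) and converted to Young's modulus by E = 2(1+ν)G′ with ν = 0.45
   for polyacrylamide (factor 2.9).
4. **Ligand surface density** (`tcellmech.density`) — the theoretical
   accessible streptavidin density of streptavidin-acrylamide
   copolymerised gels: acrylamide molarity × molar ratio, diluted by the
   hydration swelling factor, times the accessible surface depth. Minority
   coating species (e.g. anti-CD3 at 1:10) are derived from it.

The synthetic generators (`tcellmech.synth`) forward-simulate each stage's
inputs — two-population migration cohorts, noisy Hertz force curves,
saturating gap sweeps — under fixed seeds, with named fixtures carrying the
per-condition anchoring values and their provenance labels.

## Worked example

```python
from tcellmech import (summarize_cohort, simulate_tracks,
                       track_params_from_fixture, shear_to_young,
                       GelRecipe, GelGeometry, site_density, species_density)

# migration: 100 synthetic cells on a stiff ICAM-1-coated gel
params = track_params_from_fixture("icam-100kPa", n_cells=100, seed=1)
s = summarize_cohort(simulate_tracks(params))
print(f"{s.percent_arrested:.1f}% arrested, "
      f"velocity {s.velocity_mean:.2f} ± {s.velocity_sem:.2f} µm/min")
# 2.0% arrested, velocity 15.36 ± 0.42 µm/min

# rheology: plateau G' = 2212 Pa → Young's modulus
print(f"E = {shear_to_young(2212.0, nu=0.45):.1f} Pa")
# E = 6414.8 Pa

# functionalization: accessible streptavidin and anti-CD3 densities
strept = site_density(GelRecipe(acrylamide_pct=5.0), GelGeometry())
print(f"streptavidin {strept:.1f} /µm², aCD3 {species_density(strept, 10):.2f} /µm²")
# streptavidin 30.3 /µm², aCD3 3.03 /µm²
```

The velocity line says that, of 100 simulated cells, 2 moved less than the
10 µm/5 min arrest threshold and the remaining migrating cells averaged
15.36 µm/min — within sampling error of the 15.5 µm/min the fixture
encodes. The gel with plateau shear modulus 2212 Pa is a 6.4 kPa substrate;
the 5%-acrylamide recipe exposes about 30 streptavidin and 3 anti-CD3
molecules per µm².

The same stages are scriptable from the shell:

```bash
tcellmech simulate --list
tcellmech simulate tracks --fixture icam-100kPa --seed 1 --out spots.csv
tcellmech tracks summarize --in spots.csv --out summary.json
tcellmech rheo convert --in sweeps.csv --nu 0.45 --out moduli.csv
tcellmech density estimate --recipe pa-6.4kPa --out report.json
```

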