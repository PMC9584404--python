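# leptoflow

Individual-based biophysical modelling of leptocephalus larval
dispersal and settlement connectivity.

Many reef and flats fishes — bonefish among them — broadcast-spawn
offshore and disperse as leptocephalus larvae for weeks to months
before settling into nearshore nursery habitat. Where those larvae end
up, and which islands exchange recruits, is governed by the interplay
of ocean circulation (gyres that retain, boundary currents that
export) and larval biology (buoyancy, vertical behaviour, thermal
tolerance, a finite competency window). `leptoflow` is a tested,
reusable implementation of that coupled model for researchers who want
to run dispersal experiments under controlled, analytic ocean
conditions: it generates 4-D synthetic ocean fields with prescribed
thermoclines, gyres, jets and coastlines, releases ontogenetically
parameterized particles from thermocline-anchored spawning stains,
transports them with a CFL-checked Forward Euler scheme plus a 3-D
uniform-δ random walk, applies mortality/settlement rules, and
computes the standard connectivity and development-environment
statistics.

## The model in brief

- **Transport:** dx = u·dt + δ·√(6·K_h·dt), δ ~ U[−1,1] per axis, so
  ⟨dx²+dy²⟩ = 4·K_h·dt; K_h from Okubo's power law
  K_h = 0.0103·l^1.15 (cgs). Vertical walk scaled by local kz with
  reflecting boundaries (well-mixed condition). Timestep bounded by
  dt ≤ 0.7·dGrid/Umax.
- **Release:** upper spawning depth = (observed upper depth ÷ observed
  thermocline) × model thermocline; lower extent at the strongest
  sub-thermocline temperature gradient; 10 000 particles uniform in
  depth over the band, area-uniform in a 150 m stain.
- **Biology:** ontogenetic density ratio → Stokes buoyancy
  w = (2/9)·g·r²·Δρ/μ; competent larvae (41–71 days post spawn) held
  in the top 2 m; lethal limits 14/32 °C (strict); pre-competent land
  contact is lethal ("onshore mortality").
- **Settlement:** named GeoJSON island zones; settlement on post-step
  position during the closed competency window.
- **Statistics:** per-day fate proportions, gridded densities,
  max-normalized settlement KDE, connectivity matrix (totals +
  fraction of iterations settled), settlement footprints, coefficient
  of dispersal (chord ÷ path, haversine R = 6371 km), Kruskal–Wallis +
  Dunn–Bonferroni island contrasts with Hedges' g and bootstrap CIs.

## Worked example

Translate an observed spawning rush onto a model water column and run
the two-zone retention experiment:

```python
import numpy as np
import leptoflow as lf
from leptoflow.scenarios import retention_experiment

# thermocline-proportional spawning depths
event = lf.SpawningEvent(release_time=0.0, lon=-77.0, lat=24.0,
                         insitu_upper_depth=63.7, insitu_thermocline=75.9)
depth = np.linspace(0.0, 200.0, 41)
temp = lf.TwoLayerTemperature(thermocline_m=50.0, thickness_m=8.0).at(depth)
upper, lower = lf.derive_depth_range(event, depth, temp)
print(f"proportion {100*event.depth_proportion:.2f}%  "
      f"release band {upper:.2f}-{lower:.1f} m")

# gyre-strength sweep: retention vs export
print(retention_experiment(gyre_strengths=(0.10, 0.14, 0.18),
                           n_iterations=10, n_particles=500, seed=3))
```

prints

```
proportion 83.93%  release band 41.96-60.0 m
   gyre_strength  settled_prop_gyre  iter_fraction_gyre  mean_cod_gyre  settled_jet
0           0.10             0.0010                 0.4       0.178089         4995
1           0.14             0.1326                 1.0       0.117492         4306
2           0.18             0.1446                 1.0       0.079869         4218
```

The observed upper spawning depth sat at 83.93 % of the in-situ
thermocline, which maps to a 41.96 m release depth on a 50 m model
thermocline. In the sweep, strengthening the retention gyre raises the
gyre-fed island's settled share of larvae (0.1 % → 14.5 %) and the
fraction of replicate simulations reaching it (0.4 → 1.0), while its
settlers' mean coefficient of dispersal falls (0.178 → 0.080): retained
larvae orbit the gyre, so their along-track paths grow relative to the
spawn-to-settlement chord. Larvae that escape ride the jet to the
downstream island with far straighter paths.

There is also a CLI (`leptoflow field | release | run | analyze |
pipeline`) driven by a YAML run configuration; `leptoflow run --config
run.yaml` renders the field, derives the release, runs all iterations
and writes trajectories (NetCDF), the settlement table and analysis
CSVs together with a manifest of seeds and digests.

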