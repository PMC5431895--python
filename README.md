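# memstate

Markov state model (MSM) analysis of membrane insertion for peripheral
peptide–ligand complexes, with a ground-truth synthetic data generator
that makes every stage of the pipeline testable end to end.

## The problem

Peripheral membrane proteins such as the PKC C1b domain bind one
leaflet of a bilayer, and different bound ligands (phorbol esters,
bryostatins and their analogs) can stabilise different insertion
geometries of the complex. Those geometries are summarised by two
collective variables:

- **depth** `d` (nm) — the signed distance of the binding-site centroid
  (mean position of the M9/T12/L21/V25 alpha carbons) from the plane
  through the centre of the membrane, and
- **tilt** `θ` (degrees) — the angle between the membrane plane and the
  body axis drawn from that centroid to the centroid of the F3/G35/N48
  alpha carbons and the structural zinc.

Distributed MD campaigns produce thousands of short trajectories with
arbitrary starting configurations, so a raw histogram over `(d, θ)` is
biased by how the runs were seeded. The pipeline implemented here
recovers *equilibrium* free-energy landscapes from such data:

1. **featurization** — seven featurizers (backbone dihedrals, RMSD to a
   reference, reciprocal interatomic distance distributions, water-shell
   counts at 0.3 and 1.0 nm, lipid-shell counts, and an exponentially
   weighted peptide–phosphorus distance), combined 0-or-1 per subsystem
   into 35 featurizations;
2. **tICA** — the slowest decorrelating linear combinations from the
   generalized eigenproblem `C̄ v = λ (C₀₀ + g I) v` at lag `t`;
3. **clustering** — mini-batch k-means into `k` states;
4. **MSM** — maximum-likelihood reversible transition matrix at lag
   τ = 4.5 ns (detailed balance enforced; ergodic trimming first);
5. **model selection** — GMRQ cross-validation over `(featurization,
   t, g, k)`: the sum of the first m = 6 MSM eigenvalues evaluated on
   held-out trajectories;
6. **landscape** — every frame weighted by `π_s / n_s` of its state,
   `F(d, θ) = −kT ln p`, basin `ΔG = −kT ln(P_shallow / P_deep)` and
   `ΔΔG` between systems, with trajectory-bootstrap confidence
   intervals.

Because the real MD datasets of interest are far beyond desk scale, the
package ships a first-class synthetic generator: overdamped Langevin
dynamics on a designed two-well potential over `(d, θ)` whose basin
populations are known exactly by quadrature, plus a toy atomistic
embedding (peptide pseudo-atoms, leaflet phosphorus planes, z-graded
waters) so the geometric and neighbor-count featurizers run on real
coordinates.

## Worked example

Recover the deep/shallow free-energy gap from 50 × 75 ns synthetic
trajectories started mostly in the (less stable) shallow state:

```python
import numpy as np
import memstate as ms
from memstate.featurize import FeatureMatrix
from memstate.landscape import basin_deltaG_from_frames

cfg    = ms.two_well_config(seed=0, n_trajectories=50, frames_per_trajectory=300)
basins = ms.default_basins()
cvs    = ms.sample_langevin(cfg)

feats = [FeatureMatrix(t, ["d", "theta"], cvs.frame_interval) for t in cvs.trajectories]
tica  = ms.fit_tica(feats, lag_time=2.0, gamma=1e-4, n_components=2)
tics  = [ms.transform(tica, f) for f in feats]
km    = ms.fit_minibatch_kmeans(tics, k=40, seed=1)
states = ms.assign(km, tics)

res = ms.bootstrap_deltaG(cvs.trajectories, states, basins, 4.5, cvs.frame_interval,
                          kT=cfg.kT, B=100, level=0.95, seed=2, n_states=40)
print(f"oracle dG      : {ms.exact_delta_g(cfg, basins):.3f} kcal/mol")
print(f"estimated dG   : {res.delta_g:.3f} kcal/mol "
      f"(95% CI [{res.ci_lower:.3f}, {res.ci_upper:.3f}])")
```

```
oracle dG      : 0.900 kcal/mol
estimated dG   : 0.953 kcal/mol (95% CI [0.825, 1.153])
```

The oracle line is the exact basin free-energy difference of the
generating potential (2-D quadrature of `exp(−U/kT)`); the estimate is
what the MSM pipeline recovers from the biased trajectories, with a
bootstrap interval from resampling whole trajectories. A raw histogram
of the same data underestimates the gap because three quarters of the
trajectories start shallow.

The orchestrated version of the same analysis, including the GMRQ scan
over featurizations and hyperparameters, runs from the shell:

```sh
memstate config > run.yaml   # inspect/edit the defaults
memstate run --config run.yaml --seed 7 --out runs/demo
```

and writes `cv_truth.csv`, `topology.pdb`, `gmrq.csv`, `landscape.csv`,
`deltag.json` and a `manifest.json` with per-stage checksums; re-running
an unchanged configuration reloads every stage from its cache.

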