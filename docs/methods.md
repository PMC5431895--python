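# Methods

## The estimation problem

Many short trajectories, seeded along an insertion coordinate, sample a
peptide–ligand complex at a lipid bilayer. The quantity of interest is
the equilibrium free-energy surface over two collective variables —
insertion depth `d` and tilt `θ` — and in particular the free-energy
difference between a deep and a shallow insertion basin,

    ΔG = −kT · ln(P_shallow / P_deep).

Short trajectories do not individually equilibrate and their starting
points are not Boltzmann-distributed, so plain histograms are biased.
The pipeline removes that bias with a reversible Markov state model:
the stationary distribution π of the estimated transition matrix
replaces the empirical state frequencies, each frame carrying weight
`π_s / n_s` (with `n_s` frames observed in state `s`).

## Synthetic ground truth

### Potential

The generator evolves `(d, θ)` directly under

    U(d, θ) = − Σᵢ Aᵢ exp(−(d−dᵢ)²/2σ_{d,i}² − (θ−θᵢ)²/2σ_{θ,i}²)
              + c · [ (d−d_c)² + ((θ−θ_c)/S)² ],      S = 30°

i.e. inverted Gaussian wells plus a harmonic confinement. The angle is
an ordinary (non-periodic) coordinate; its physically meaningful range
(≈ ±90°) is maintained by the confinement, not by wrapping. The scale
`S` puts 30° of tilt on the same confinement footing as 1 nm of depth,
so a single strength constant `c` (kcal/mol, default 1.5) confines both
coordinates comparably.

Two named conditions are frozen as package defaults:

| condition | deep well (d, θ, A) | shallow well (d, θ, A) | exact ΔG |
|---|---|---|---|
| `two_well_config` | (1.15 nm, 12°, 3.4) | (1.80 nm, 38°, 1.9962) | 0.900 kcal/mol |
| `deep_only_config` | (1.15 nm, 12°, 4.2321) | (1.80 nm, 38°, 1.2) | 1.900 kcal/mol |

Both use widths (0.14 nm, 9°). The odd-looking amplitudes were solved
by root-finding on the quadrature ΔG so that the *designed* gaps are
exactly 0.90 and 1.90 kcal/mol — the landscape scales the method is
meant to resolve; they were fixed before any estimator was evaluated
and are not tuned thereafter. Basin rectangles split the plane at the
midpoint depth d = 1.475 nm (`default_basins()`).

`kT` defaults to 0.5961 kcal/mol (300 K). Diffusion constants are
(0.1 nm²/ns, 90 deg²/ns), giving intra-well relaxation of a few hundred
ps and well-hopping times of a few to tens of ns — slow processes that
an MSM at τ = 4.5 ns can resolve but a 125 ns trajectory cannot fully
average over. Default datasets are 200 trajectories × 500 frames at
0.25 ns/frame with 75% of starts in the *shallow* (minority) well, so
raw histograms are visibly biased and reweighting is load-bearing.

### Integrator

Euler–Maruyama, `x⁺ = x − (D/kT)∇U·Δt + √(2DΔt)·ξ`, sub-stepped at
Δt = 2.5 ps between recorded frames. A conservative curvature bound
(Σ A/σ² + confinement) is checked against `(D/kT)·|U''|·Δt < 1` with a
warning otherwise; excursions beyond ten times the confinement span
abort with a message naming the timestep. All trajectories integrate
in lock-step as one vectorised array, and every artifact is
bit-reproducible from `(config, seed)`.

### Quadrature oracle

`exact_basin_populations` integrates `exp(−U/kT)` by 2-D Simpson
quadrature over the confinement-limited domain (well boxes ± 7σ joined
with the region where the confinement exceeds 40 kT), refining from n
to 2n−1 points per axis and insisting on ≤ 1e-6 relative change.
`exact_histogram_masses` gives per-bin reference masses on an arbitrary
grid for L1 landscape comparisons.

### Atomistic embedding

`embed_frames` realises each `(d, θ)` frame as coordinates: a rigid
pseudo-peptide template (50 residues with N/CA/C backbones, CB side
chains, one zinc, an 8-atom ligand ring; canonical residue numbering)
placed with its binding centroid at depth `d` and its body axis tilted
by `θ` at a random azimuth; phosphorus markers on jittered lattices at
±2.0 nm; water oxygens drawn per frame from a z-graded density (bulk
above the phosphate plane, linear decay through the headgroup region,
zero inside the 1.2 nm hydrocarbon half-width). Two deliberate
numerical choices keep the geometry exact:

- per-leaflet z-jitter is re-centred every frame, so each leaflet's
  mean plane — and hence the membrane centre recovered downstream — is
  exact rather than jittered at the 1/√n level;
- thermal jitter (default 0.01 nm) is applied to all peptide atoms
  *except* the eight that define the collective variables (the named
  alpha carbons and the zinc).

Together these guarantee `compute_cv(embed_frames(d, θ)) = (d, θ)` to
machine precision while still exercising dihedral/RMSD/neighbor-count
featurizers with non-constant signals. The waters are resampled
independently per frame (no water dynamics): sufficient for per-frame
density featurizers, deliberately not a solvent model.

What the generator does **not** emulate: lipid tails and headgroup
chemistry, electrostatics, peptide conformational change coupled to
insertion, anisotropic diffusion along the landscape. Passing tests
demonstrate that the *estimators* are correct and calibrated on data
with the right statistical structure (many short, biased-start,
Markovian-at-lag trajectories); they say nothing about force fields or
sampling adequacy of any real system.

## Estimators

**tICA.** Means and both covariance matrices are accumulated over the
union of the lagged windows (pairs never span trajectory boundaries),
and `C̄ = (C₀τ + C₀τᵀ)/2` is symmetrized, which bounds all generalized
eigenvalues by 1 in magnitude. Regularization adds `g·I` to the metric
`C₀₀` (ridge). Eigenvector signs are fixed by making each component's
largest-magnitude loading positive. Constant feature columns are a
hard error naming the column.

**Clustering.** scikit-learn `MiniBatchKMeans` (seeded); assignment is
an explicit nearest-centre rule with ties to the lowest index so that
held-out frames always map to a training state. When k equals the
number of distinct points the distinct points are the centres
(inertia 0) without iteration.

**Reversible MSM.** Sliding-window counts at τ = 4.5 ns, rounded down
to whole frames when needed; ergodic trimming to the largest strongly
connected component (scipy's connected_components); then the classic
self-consistent iteration on symmetric fluxes
`x_ij ← (c_ij+c_ji)/(c_i/x_i + c_j/x_j)` until `max|ΔT| < 1e-10`
(cap 10⁶ sweeps). Row-stochasticity, detailed balance, `πT = π` and a
real spectrum are asserted after every fit. Implied timescales are
`−τ/ln λᵢ₊₁`, reported as NaN (and logged) for non-positive
eigenvalues.

**GMRQ.** The score of a trained model on test state sequences is
`trace[(AᵀS_test A)⁺ (AᵀC̄_test A)]` with `C̄_test` the symmetrized test
counts, `S_test` their diagonal overlap, and `A` the leading m = 6
eigenvectors of the *symmetrized training count* problem
`C̄ v = λ S v` embedded with zero rows on trimmed states. Using the
count-matrix eigenvectors (rather than those of the reversible-MLE
matrix) is what makes the variational identity — self-score equals the
training eigenvalue sum — exact to machine precision; the MLE remains
the estimator used for π and all thermodynamics. The stationary
eigenvector is included in the m (scores live in (0, m]); the
convention is recorded in the search output. States never visited in
the test fold contribute zero rows, handled by pseudo-inverse with
rank logging. Cross-validation is a 50% trajectory-level shuffle
split, 5 repeats by default; the search is an exhaustive seeded grid.

**Landscapes and ΔG.** 2-D weighted histograms (default 40 × 40 over
the sampled range padded 5%); `F = −kT ln p` min-shifted to zero with
empty bins undefined (NaN), never zero. Basins are user-specified
rectangles; `propose_basins` suggests rectangles by splitting between
the two lowest local minima. Positive ΔG means the shallow basin is
less populated. Bootstrap CIs resample whole trajectories (respecting
autocorrelation), re-estimating the MSM per replicate while keeping
the tICA projection and clustering from the full fit (B = 200 default,
percentile interval); replicates with an empty basin are dropped and
counted, with >20% dropped an error.

**Water coordination** is a distance-only criterion (unique water
oxygens within 0.35 nm of any target atom, minimum image) because the
synthetic waters carry no hydrogens; a donor–H–acceptor angle test
would require explicit hydrogens.

## Design choices where the design was open

- Solvent-shell "density" is a raw count within the radius (a density
  times a constant shell volume); no volume normalisation.
- The weighted lipid metric is `Σⱼ exp(−d_ij/σ)` with σ = 0.3 nm:
  smooth, bounded, monotone in proximity. The lipid *shell* variant
  uses a 1.0 nm radius (phosphorus spacing ≈ 0.6 nm makes 0.3 nm
  shells almost always empty).
- Reciprocal-distance distributions use a fixed 50-bin histogram over
  [0, 10] nm⁻¹, row-normalised.
- RMSD superposes on heavy atoms; dihedrals use the IUPAC sign
  convention encoded as (sin, cos) pairs to avoid wrap discontinuities.
- Periodic boundary handling is minimum-image on orthorhombic boxes
  only.
- tICA is fit on pooled trajectories (standard for MSM pipelines), and
  lagged pairs use the sliding window, as does transition counting.
- The pipeline reports one landscape per top-scoring model plus their
  bin-wise mean; basin ΔG uses the single best model.

## Problem sizes used by the test suite and acceptance script

Langevin datasets of 200 × 500 frames (main recovery), 50 × 300 frames
× 50 replicate datasets (bootstrap calibration), and a 12 × 150-frame
atomistic end-to-end run were chosen to give each check comfortable
statistical margin; the generator is vectorised, so all of them
regenerate from seeds in seconds.

## Known limitations

- The reversible MLE assigns no uncertainty to π beyond the bootstrap;
  there is no Bayesian MSM sampling, hidden-state modelling, or
  coarse-graining.
- Free energies are equilibrium-only: no mean first-passage times or
  rates between basins are reported.
- Triclinic boxes, per-leaflet landscapes and 3-D collective variables
  are out of scope.
- Basin rectangles are user responsibility; the proposal helper is a
  convenience, not a watershed analysis.
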