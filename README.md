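# ertrack

Single-particle tracking analysis of secretome mRNA translation on the
endoplasmic reticulum (ER).

mRNAs encoding secretory and membrane proteins are translated on the ER
surface, and single-molecule imaging shows that actively translating
transcripts move in a confined manner while untranslated ones diffuse
freely. `ertrack` is a library + CLI for researchers analysing such
experiments. It covers the full quantitative chain:

- **Trajectory I/O** — TrackMate-dialect XML and a documented CSV schema
  (`track_id, frame, t_s, x_um, y_um, intensity`), mask-based removal of
  nuclear localizations.
- **Confinement classification** — per-trajectory mean squared displacement
  at 1 s lag, `MSD_τ = Σ[(x_{i+1}−x_i)² + (y_{i+1}−y_i)²]/n`; a trajectory
  is *translating* when `MSD_τ=1s < 0.055 µm²` (ribosome tracks use an
  effective cutoff of 0.04 µm²), and the translating fraction is
  translating / total classified.
- **Ensemble diffusion** — `MSD(τ) = 2nD_app τ + 4σ²` fitted on the first
  four lags (n = 2 dimensions, σ the localization error).
- **Diffusion mixtures** — up to three species fitted to the displacement
  CDF, `CDF(r) = 1 − Σ A_x e^{−r²/4D_x t}` with `ΣA_x = 1`.
- **Spatial statistics** — ER-junction detection (skeleton branch points),
  nearest-organelle distances, colocalization fractions within a radius,
  SunTag-to-mRNA puncta matching (≤2 px), and distance-binned intensity
  profiles (0.75–4.25 µm in 0.5 µm bins, normalized at 4.25 µm).
- **Kinetics** — FRAP normalization to the 10-frame pre-bleach plateau and
  half-saturation times t½ of optogenetic ER–lysosome recruitment traces
  via saturating-exponential fits.
- **Synthetic data** — Monte Carlo Brownian/confined mixtures with per-axis
  steps `N(0, 2DΔt)`, tubule networks with known junction coordinates, and
  kinetic traces with known t½, so every stage is testable against ground
  truth.

## Worked example

```python
import numpy as np
import ertrack as et

# 1. simulate a mixture: 86% confined (translating) mRNA
ts, truth = et.simulate_mixture(
    confined_fraction=0.86, free_d=0.1, confined_d=0.5,
    confinement_radius=0.1, n_particles=1000, n_steps=12, seed=1)

# 2. classify by per-trajectory MSD at 1 s lag
msds = et.classify_trajectories(ts.trajectories)
frac = et.translating_fraction(msds)
print(f"translating fraction: {frac:.3f} (truth 0.860)")

# 3. decompose pooled displacements into diffusive species
sample = et.pooled_displacements(ts.trajectories)
fit = et.fit_cdf_mixture(sample, n_components=2, seed=1)
for a, d in zip(fit.fractions, fit.diffusion_coefficients):
    print(f"species: fraction {a:.2f}, D = {d:.3g} um^2/s")

# 4. recruitment kinetics round trip
trace = et.synth_kinetic_trace("recruitment", plateau=1.0,
                               rate=np.log(2)/7.9, dt=0.5, duration=120.0)
print(f"fitted t_half: {et.fit_half_time(trace).t_half:.2f} s")
```

Output:

```
translating fraction: 0.860 (truth 0.860)
species: fraction 0.13, D = 0.109 um^2/s
species: fraction 0.87, D = 0.00162 um^2/s
fitted t_half: 7.90 s
```

The classifier recovers the constructed 86% translating fraction exactly at
this sample size; the CDF decomposition separates the free population
(fitted D ≈ 0.11 µm²/s against the true 0.1) from the confined one, whose
small fitted D is an *effective* coefficient set by the 0.1 µm confinement
radius rather than the within-trap mobility; and the recruitment fit
returns the constructed half-saturation time of 7.9 s.

The same analyses are available from the shell via the `ertrack` console
script (`simulate`, `classify`, `cdf-fit`, `junctions`, `proximity`,
`frap`, `recruit`, `report`); every output directory receives a
`manifest.yaml` recording inputs, thresholds, seed and version.

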