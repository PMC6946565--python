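# gcclutch

Molecular-clutch simulation and single-molecule trajectory analysis for
neuronal growth cones.

Growth cones — the motile tips of growing axons — advance when transmembrane
adhesion receptors (here N-cadherin) transiently couple the rearward-flowing
actin network to the substrate: the *molecular clutch*. `gcclutch` provides
the computational toolkit for studying this coupling with single-molecule
methods, entirely on synthetic data:

* **Clutch simulator** — a stochastic model of individual actin molecules in
  a virtual 2D conical growth cone (radius 12 µm, half-angle 45°).  Molecules
  cycle between free diffusion (D = 3 µm²/s), retrograde flow
  (V = 0.05–0.15 µm/s, lateral D′ = 0.003 µm²/s) and adhesion-bound
  near-immobility (D″ = 0.001 µm²/s), governed by polymerization (k_poly),
  clutch coupling/uncoupling (k_c, k_u), and depolymerization (k_d) rates.
  The ratio k_c/k_u is the coupling strength of the clutch.  mEos2
  photophysics (random activation, exponential bleaching) and camera
  integration (sum 5 × 50 ms frames, keep one of two) turn ground-truth
  trajectories into realistic sptPALM-like observations.
* **Trajectory analysis** — time-averaged MSD per track, the anomalous
  power-law fit MSD = 4Dt^α (confined α < 0.5 / Brownian / directed α ≥ 1.5),
  the directed fit MSD = 4Dt + V²t², initial-slope diffusion coefficients
  with the confined/mobile split (D < 0.015 µm²/s), track filtering
  (> 7 frames), growth-cone centroid kinematics with pause detection, and
  EB3 comet metrics.
* **Nanodomain mapping** — super-resolved localization maps (25 nm pixels),
  intensity-threshold segmentation of confinement nanodomains with
  logistic-edge (sigmoid) sizing, domain densities, and growth-cone
  morphometry via the Shape Index S.I. = 4π·Area/Perimeter².
* **FRAP** — the three-parameter diffusion/reaction recovery model
  F(t) = φ(1 − e^(−k_diff·t)) + (1 − φ)(1 − e^(−k_reac·t)) with synthetic
  curve generation and bounded nonlinear fitting.
* **Optical tweezers** — Stokes-drag trap calibration (F = 6πRηV),
  escape-force computation (F_esc = κ·R), bead-track escape analysis and
  escape probabilities.

Fitting follows the model/results convention familiar from statsmodels:
construct a model from data, call `fit()`, read estimates and diagnostics
off the returned results object (`summary()`, `plot()`).

## Worked example

Simulate the default condition (400 molecules, 160 s at 50 ms steps,
k_c = 0.2 s⁻¹, k_u = 0.05 s⁻¹, V = 0.10 µm/s), push it through the
photophysics/camera observation chain and classify the surviving tracks:

```python
import gcclutch as g

cfg = g.SimConfig(seed=0)             # defaults are the standard condition
kept, table, fractions = g.analyze_simulation(cfg)
print(len(table), "tracks analyzed")
print(fractions.round(3).to_string())
```

```
68 tracks analyzed
confined    0.118
brownian    0.750
directed    0.132
```

Of the 400 simulated molecules, 68 survive blinking/bleaching, camera
down-sampling and the > 7-frame filter.  Most classify as Brownian (free
monomers and mixed-state tracks); 13% are directed (molecules riding the
retrograde flow) and 12% confined (clutch-bound).  Raising the coupling
strength k_c/k_u shifts weight out of the directed class; raising V_flow
shifts weight into it — the simulator's two central predictions, exercised
in `tests/test_acceptance.py`.

Fit a noisy synthetic FRAP curve:

```python
import numpy as np
res = g.fit_frap(g.simulate_frap_curve(0.5, 0.15, 0.005, noise_sd=0.02,
                                       rng=np.random.default_rng(1)))
print(res.summary())
```

```
FRAP diffusion/reaction fit
---------------------------
free fraction phi   :   0.4963
k_diff (1/s)        :   0.1533
k_reac (1/s)        :  0.00502
residual SSE        :   0.0696
points fitted       : 201
```

The generating parameters (φ = 0.5, k_diff = 0.15 s⁻¹, k_reac = 0.005 s⁻¹)
are recovered within 1–2%.

Trap physics is a one-liner: at the calibrated stiffness of 4.7 pN/µm and an
escape distance equal to the 0.5 µm bead radius,

```python
>>> g.escape_force(4.7, 0.5)
2.35
```

pN — the minimal force the actin flow must transmit through N-cadherin to
pull a bead out of the trap.

A command-line interface wraps the same functionality:

```sh
gcclutch simulate --n-molecules 400 --k-u 0.05 --seed 0 --out tracks.csv
gcclutch analyze tracks.csv --out-dir results/
gcclutch pipeline --seed 0 --out-dir run0/   # full run with manifest
gcclutch fixtures                            # small example inputs
```

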