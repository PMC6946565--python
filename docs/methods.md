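# Methods

This note documents the models implemented in `gcclutch`, the parameters
that matter, the numerical choices made where the design was genuinely
open, and the limits of what the synthetic-data tests demonstrate.

## 1. The clutch simulator

### Geometry and states

The growth cone is a flat 2D wedge: apex at the origin, radius 12 µm,
half-angle 45°, matching the fan-like lamellipodium of cultured hippocampal
growth cones.  The leading edge is the arc r = 12 µm; retrograde flow moves
material toward the apex.  Each molecule carries one of three kinetic
states:

| state | motion | entered from | left by |
|---|---|---|---|
| FREE  | Brownian, D = 3 µm²/s | initial; FLOW (depolymerization, base) | polymerization in the 0.5 µm edge band (k_poly = 0.5 s⁻¹) |
| FLOW  | radial drift −V·Δt (V = 0.05–0.15 µm/s) + lateral noise D′ = 0.003 µm²/s | FREE, BOUND | coupling (k_c = 0.2 s⁻¹), depolymerization (k_d = 0.05 s⁻¹), forced disassembly at the 4 µm basal band |
| BOUND | Brownian, D″ = 0.001 µm²/s | FLOW only | uncoupling (k_u, varied 0.001–0.8 s⁻¹) |

Free monomers never bind adhesions.  Each event with rate k fires in a step
when an independent uniform draw falls below k·Δt; config validation
rejects any k·Δt ≥ 1.  The ratio k_c/k_u ("coupling strength") is the
clutch's effective affinity.

### Numerical scheme

Euler–Maruyama stepping at Δt = 50 ms for 160 s (3200 frames).  Per-step
event order is fixed and documented so trajectories are bit-reproducible:
polymerization test → motion update → coupling/uncoupling test →
depolymerization test → forced disassembly at the base.  Each molecule
consumes a fixed draw schedule (2 position-initialization draws, then
2 normals + 4 uniforms per step, used or not), so a trajectory is a pure
function of its substream; the ensemble spawns one `SeedSequence` substream
per molecule id from the master seed.

Boundary handling is not dictated by the physics and was chosen as: FREE
molecules reflect at the leading edge and the straight sides (mass
conserving); FLOW and BOUND molecules have their small lateral noise
clamped to the wedge (their dynamics are dominated by drift/immobility, not
by the noise, so reflection vs clamping is immaterial there).

### Observation model

mEos2 photophysics: a molecule turns fluorescent at a uniform random time
in [0, 150] s and bleaches after an exponential time.  The mean fluorescent
lifetime defaults to **2.0 s**, calibrated by direct Monte Carlo so that,
after camera down-sampling and the > 7-frame filter, surviving track
lengths have a median of ≈ 9–11 frames — the regime typical of sptPALM
recordings of actin-mEos2.

Camera integration: positions are averaged in groups of 5 consecutive
50 ms frames (the trajectory-level equivalent of summing the corresponding
images — blur-free because molecule identity is kept), then one group of
two is retained, producing 320 frames at 0.5 s from a 3200-frame path.
The original experimental chain instead renders images and re-tracks them;
keeping ground-truth identity avoids re-implementing a localization/
tracking stack and preserves the frame arithmetic exactly.  One
consequence: fast free monomers, which blur out of real recordings, remain
as analyzable Brownian tracks here and dilute the class fractions.  Where a
regime-pure subset is needed (e.g. the flow-velocity closure below),
`select_by_state` filters on the simulator's ground-truth states instead —
the explicit counterpart of the blur-based elimination.

## 2. Trajectory analysis

The time-averaged MSD uses all ordered same-lag pairs.  The anomalous fit
MSD = 4Dt^α is an ordinary least-squares line in log–log space over the
first quarter of available lags but never fewer than 4 (8-frame tracks,
the shortest analyzable, would otherwise offer too few points); α is
clamped to [0, 2].  Class boundaries follow the printed conventions:
directed at α ≥ 1.5 (inclusive), confined at α < 0.5, Brownian between.
The directed fit MSD = 4Dt + V²t² uses nonnegative least squares so both
D and V² respect their physical sign; a zero quadratic term on a non-zero
curve is flagged degenerate rather than reported as a velocity.

The initial-slope diffusion coefficient is the OLS slope of the first
4 MSD points divided by 4; a negative slope gets the sentinel
D = 10⁻⁵ µm²/s, which always classifies as confined.  The confined/mobile
cut defaults to D < 0.015 µm²/s (N-cadherin imaging context) with
0.022 µm²/s for the Vangl2 context; both are plain parameters.  The
resolution-based derivation of such cut-offs, res²/(4·n·Δt), is exposed as
`resolution_d_threshold`; note that with the canonical inputs
(0.11 µm, 4 points, 20 ms) it evaluates to ≈ 0.038 µm²/s, not 0.015 — the
printed thresholds are kept as the defaults and the formula is provided
as-is for transparency.

On regime-pure simulated tracks the classifiers behave as designed:
FREE-only tracks are predominantly Brownian, FLOW-only tracks (V = 0.1
µm/s) predominantly directed.  BOUND-only tracks are confined by the
mobility (D) classifier — their residual D″ motion is slow but
unconstrained, so the α classifier correctly sees Brownian scaling; the α
notion of confinement requires spatially bounded motion, which the clutch
model does not impose on the bound state.

Growth-cone kinematics: mean velocity = total centroid path length /
acquisition time (µm/min).  A pause is a maximal run of ≥ 60 s in which
every position stays within `pause_eps` of the run's first position;
`pause_eps` is unavoidably a judgment call ("no movement" at 1 frame/min)
and defaults to 0.5 µm, logged and configurable.

## 3. Nanodomain mapping and morphometry

Localizations are binned into a 2D histogram at 25 nm pixels (counts are
conserved exactly).  The segmentation threshold defaults to the map mean +
2 SD (over the cone mask when supplied) — the threshold rule is
configurable and recorded, since any fixed choice is arbitrary; note that
relative thresholds adapt to overall density, so cross-condition density
comparisons should fix an absolute threshold.  Connected components
(8-connectivity, ≥ 3 pixels) become domains.  Sizing fits each axis's
summed intensity profile with a product of rising and falling logistic
edges; the size is the distance between the two half-maximum edge
midpoints, which matches the "extent of the fluorescent area" notion and
is robust to peak shape.  Non-convergent fits fall back to the above-half-
maximum extent and are flagged.

The Shape Index 4πA/P² uses the pixel-count area and the marching-squares
(0.5-level) contour length after a light 3-point circular moving average:
the raw sub-pixel contour carries a half-pixel staircase zigzag that
inflates the perimeter of smooth shapes by up to ~10% (biasing a disk's
S.I. to ~0.91), while straight-edge pixel counting is worse; the smoothed
contour returns S.I. ≈ 0.98–1.02 for disks over a wide radius range, π/4
within 3–5% for squares, and stays ≤ 1 + discretization tolerance on
random blobs.

## 4. FRAP

The recovery is parameterized as

F(t) = φ·(1 − e^(−k_diff·t)) + (1 − φ)·(1 − e^(−k_reac·t)),

with φ the free-receptor fraction, k_diff the fast (diffusive
replenishment) rate and k_reac the slow adhesive-bond turnover rate.  This
two-exponential reaction-dominant form is a modelling choice standing
behind the (φ, k_diff, k_reac) interface: it does not resolve bleach-spot
geometry, so k_diff is an effective replenishment rate, not a diffusion
coefficient.  Fitting is bounded nonlinear least squares (φ ∈ [0, 1],
rates positive), initialized from the biphasic structure — the amplitude
reached by ~20 s estimates φ, the fast half-time sets k_diff — and
canonicalized so k_diff ≥ k_reac (the form is symmetric under swapping the
phases).  Fits with k_diff/k_reac < 5 are flagged weakly identified: with
overlapping phases the decomposition is ill-conditioned.  The
`turnover_change` utility reports the percent change of k_reac between two
fitted conditions, the comparison form used for long-term adhesion
turnover.

## 5. Optical tweezers

With lengths in µm, viscosity in Pa·s, speeds in µm/s and forces in pN,
the Stokes drag is numerically F = 6πRηV (the SI prefactors cancel
exactly).  Trap stiffness κ = F/δ from the steady-state displacement under
a known flow; the minimal escape force is κ·R, the trap force at a bead
displacement equal to the bead radius.  Escape detection requires the
displacement to exceed the escape radius for 2 consecutive samples
(rejecting single-frame tracking spikes); the post-escape velocity is the
OLS slope of displacement vs time restricted to the 1–4 µm displacement
band.  Mean escape times average only beads that escaped (the explicit
`escaped_only` convention); the escape probability counts escapes within
the first 60 s over all recorded beads.

## 6. Problem sizes and determinism

Default study conditions: 400 molecules × 3200 steps per condition
(~2 s of compute per condition), 100-replicate FRAP recovery studies,
2-minute bead recordings at 5 Hz.  The test suite runs these at full scale;
exploratory sweeps in the tests use the same generator with smaller
ensembles where a direction, not a precise fraction, is asserted.  All
stochastic stages consume `numpy.random.Generator` streams derived from
explicit seeds; identical seed + config reproduces every output file
byte-for-byte.

## 7. What the synthetic tests do and do not show

The generators emulate the *structure* of the real data — three-regime
trajectories with blinking and slow-sampling artefacts, biphasic recovery
curves, dwell-then-drift bead tracks — under exactly known ground truth,
so the tests demonstrate correctness of the estimators and the predicted
qualitative dependencies (directed fraction falling with coupling strength,
rising with flow speed; clutch-bound ensembles forming denser nanodomains).
They do not reproduce experimental group comparisons: no localization
error, tracking mismatches, heterogeneous expression levels, cell-to-cell
variability or drift are modelled, and the study's measured effect sizes
(velocity changes, turnover-rate decreases, domain-density increases
between genotypes) require the original microscopy recordings.  Those
numbers are outside what desk-scale synthetic data can or should claim.
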