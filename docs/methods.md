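# Methods

`astroca` simulates cytosolic Ca²⁺ dynamics of single astrocytes and
astrocyte networks on raster templates that encode cell morphology, and
provides the event- and pattern-level statistics used to characterise the
simulated activity. This note documents the model, its parameters, the
numerical scheme, the synthetic-data generator, and the design decisions
taken where the design was genuinely open.

## Spatial model

Each pixel of a 2D raster is either extracellular (class III) or contains
astrocyte cytosol, graded by the **astrocyte volume fraction** (AVF,
symbol `r ∈ [r_min, 1]`, `r_min = 0.085`): `r = 1` in the soma and thick
branches (class I), `r = r_min` in the unresolved mesh of thin perisynaptic
processes (class II, "gliapil"). AVF is obtained from a fluorescence-like
intensity image as `r = max(I/I_max, r_min)` on pixels whose relative
intensity exceeds a background threshold (default 0.02; the delineation of
zero-signal pixels from dim gliapil is not physically constrained and is
exposed in config).

AVF fixes the **surface-to-volume-ratio weight**

    s(r) = 1 / (1 + exp[(r − 0.5)/0.1]),

a decreasing logistic with `s ≈ 0.98` at `r = r_min` and `s ≈ 0.007` at
`r = 1`. `s` partitions calcium handling between plasma-membrane fluxes
(dominant in leaflets) and ER fluxes (dominant in soma/branches). The
slope constant 0.1 is exposed in config. A simpler reciprocal form of this
link that circulates in the literature is singular at `r = 0.5` and takes
negative values above it; the logistic is the form consistent with the
stated limits and is the one implemented.

Templates are stored as 8-bit RGB PNGs: blue > 0 marks astrocyte pixels,
red encodes `round(255·r)` (quantization error ≤ 1/255), green carries the
cell-domain label. Templates can therefore be drawn or edited in any image
editor and compiled directly.

## Point dynamics

Per-pixel state: cytosolic Ca²⁺ `c`, ER Ca²⁺ `e`, IP₃ `i`, extracellular
glutamate `g` (all µM) and the slow IP₃-receptor inactivation gate
`q ∈ [0, 1]`:

    dc/dt = (1 − s) J_ER + s J_pm + J_diff
    de/dt = −(1 − s)/c1 · J_ER
    di/dt = s (I_Glu + I_Ca) − (i − i₀)/τ_IP3 + I_diff
    dg/dt = (g_amb − g)/τ_Glu + ξ(t) + G_diff
    dq/dt = a2 [d2 (i + d1)/(i + d3)] (1 − q) − a2 c q

with Li-Rinzel-type ER exchange

    J_ER   = J_IP3 + J_leak − J_pump
    J_IP3  = c1 v1 (m∞ n∞ q)³ (e − c),  m∞ = i/(i + d1),  n∞ = c/(c + d5)
    J_leak = c1 v2 (e − c)
    J_pump = v3 c²/(k3² + c²)

plasma-membrane exchange

    J_pm  = J_in + J_Glu − J_out
    J_in  = v5 + v6 i²/(k2² + i²)
    J_Glu = γ g
    J_out = k1 c

and plasma-membrane IP₃ production

    I_Ca  = v4 (c + (1 − α) k4)/(c + k4)          (PLCδ, Ca²⁺-stimulated)
    I_Glu = v_g g^0.7/(g^0.7 + k_g^0.7)           (PLCβ, glutamate-driven)

ER calcium is a dynamic variable (no total-calcium conservation
constraint); the `(1 − s)/c1` factor makes ER release/uptake conservative
up to the ER/cytosol volume ratio `c1`. In leaflets (`s → 1`) the ER is
effectively frozen and all production terms act at full strength; in the
soma (`s → 0`) only ER exchange and IP₃ equilibration remain.

## Parameters

Operating point (µM, s, µm units):

| group | values |
|---|---|
| calcium handling | v4 = 0.1, v5 = 0.01, k1 = 1.0, k3 = 0.05 |
| glutamate drive | τ_Glu = 0.1 s, A = 27, g_amb = 0, p_syn = 0.005–0.01 Hz |
| diffusivities | D_Ca = D_IP3 = 10, D_Glu = 0.02 µm²/s |
| morphology | r_min = 0.085 |
| IP₃R kinetics | c1 = 0.185, v1 = 6, v2 = 0.11, v3 = 0.9, d1 = 0.13, d2 = 1.049, d3 = 0.9434, d5 = 0.08234, a2 = 0.2 |
| membrane / IP₃ | v6 = 0.2, k2 = 1.0, k4 = 1.1, α = 0.8, v_g = 0.062, k_g = 0.78 |
| lumped (calibrated) | i₀ = 0.42 µM, τ_IP3 = 7.143 s, γ = 7 /s, d_rel ≈ 60 ms (see below) |
| numerics | dt = 0.002 s, δx = 0.275 µm (single cell) / 0.55 µm (network), save stride 0.5 s |

Every parameter carries a provenance tag in the serialized config:
`table1` (the published operating point), `prototype-default` (standard
constants of the underlying Li-Rinzel/three-variable glutamate-driven
kinetics), `calibrated` (fixed by the package's own calibration, below) or
`design`.

τ_Glu is a time constant in seconds (0.1 s ⇒ ~100 ms clearance), which is
the physically meaningful reading of the published value.

### Calibration of the lumped parameters

`i₀`, `τ_IP3` and `γ` close equations that the underlying prototype model
does not contain in this form; they were fixed once, by simulation scans
of the qualitative regime, and are not tuned per experiment:

* CICR requires a loaded store. With the standard IP₃R constants the ER
  equilibrates at `e − c = J_pump/(c1(v1(m∞n∞q)³ + v2))`; regenerative
  release needs `e ≳ 10 µM`, which in turn needs baseline IP₃ around
  0.4 µM in the branches. `i₀ = 0.42 µM` places every pixel class in a
  **stable but excitable** state: no pixel oscillates spontaneously at
  zero drive, while a Ca²⁺ kick of ~0.1 µM at `r ≥ 0.5` triggers a full
  CICR spike.
* `γ` sets the Ca²⁺ response to a quantal glutamate transient. Scans over
  `γ ∈ {1, 2, 4, 6, 7, 8, 10}` × `i₀ ∈ {0.42, 0.46}` at both drive levels
  showed an ignition threshold and an over-merging ceiling: at `γ ≤ 4`
  (with `i₀ = 0.42`) quantal events rarely or never recruit whole-cell
  waves at the low drive level, and small-event counts grow with drive
  (every extra quantum stays an isolated blip); at `γ = 10` waves merge
  into repeated >100 s events and the large-event count *decreases* at
  high drive. The corridor reproducing the reference phenomenology at both
  drive levels — intermittent whole-cell waves whose count grows with
  `p_syn`, small-event counts that *fall* with `p_syn` (blips absorbed
  into waves), bounded event durations — is roughly `γ ∈ (6.5, 10)`;
  `γ = 7 /s` with `i₀ = 0.42` (mid-corridor) is the frozen default. The
  calibration criteria are these regime properties only — not the
  published distribution slopes.
* `τ_IP3 = 7.143 s` is the reciprocal of the standard first-order IP₃
  degradation rate (0.14 /s).

## Synaptic drive

Each astrocyte-mask pixel is bombarded by an independent homogeneous
Poisson train of quantal glutamate release events (rate `p_syn` per
pixel). Each event raises the local release rate by `A = 27 µM/s` for a
duration `d_rel` — a rectangular rate pulse, so overlapping events add and
each event releases `A·d_rel` of glutamate in total. Without diffusion the
transient peaks at the closed form `A τ_Glu (1 − e^{−d/τ_Glu})`, which
saturates at `A τ_Glu = 2.7 µM`; `d_rel` is calibrated by bisection
(seeded by inverting the closed form) so that a single event in one pixel
of a uniform patch — with glutamate diffusion to its neighbours enabled —
peaks at the reference quantal transient amplitude of 1.2 µM. At the
default grid steps this gives `d_rel ≈ 62 ms` (δx = 0.275 µm) and
`≈ 60 ms` (δx = 0.55 µm), i.e. a fast synaptic-scale transient that rises
for tens of milliseconds and clears with τ_Glu = 100 ms. The alternative
"integral" reading — a pulse of height `A/d_rel` injecting exactly `A` per
event — was rejected: reaching the 1.2 µM peak then requires seconds-long
pulses that deposit ~20× more glutamate per event, which saturates the
IP₃ pathway, makes every response whole-cell and destroys the power-law
shape of the event-size distribution. `d_rel` remains a first-class
config parameter.

## Diffusion

Cytosolic Ca²⁺ and IP₃ diffuse on the astrocyte mask (4-connectivity,
no-flux at the template edge and at the astrocyte boundary); glutamate
diffuses everywhere. Treating the gliapil as a porous medium, the
effective diffusivity scales as `r²D`. For an edge `(i, j)` the pairwise
flux is

    F = D r̃²/δx² (c_i − c_j),   r̃ = √(r_i r_j),

applied as `−F·r̃/r_i` to pixel `i` and `+F·r̃/r_j` to pixel `j`. The
geometric-mean form was chosen because it (i) reduces to the standard
`r²`-scaled 5-point Laplacian for uniform AVF, (ii) implements the
volume-ratio scaling of concentration changes between pixels of unequal
AVF, and (iii) conserves the AVF-weighted mass `Σ r c` exactly (to machine
precision in the tests). Alternatives (arithmetic mean, upwind) can be
swapped behind `diffusion_rates`. Gap junctions between neighbouring cells
are the same diffusive edges across domain borders; "unlinking" a cell
severs its inter-domain Ca²⁺/IP₃ edges while glutamate continues to
diffuse.

## Integration

Classic fixed-step RK4, `dt = 0.002 s`. The only stochastic input is the
piecewise-constant pulse train, so evaluating `ξ` at the RK4 stage times
is exact and no Itô correction arises; the stage at `t + dt` evaluates the
forcing at `(t + dt)⁻` so pulses aligned to step boundaries stay constant
within a step (this keeps the single-pixel linear response exact to
~10⁻¹³). Stability: the naive forward-Euler diffusive bound is
`δx²/(4 D max r²)`; at `δx = 0.275 µm`, `D = 10` and `r = 1` this is
1.89 ms < dt, but the RK4 real-axis stability bound (`2.785/λ_max`,
`λ_max = 8D r²/δx²`) is 2.63 ms and admits the published step. The solver
computes and reports both bounds per grid instead of assuming safety.
States are clamped at zero with a counter (RK4 can undershoot on the stiff
pump terms); runs report the clamp count. Fixed seeds give bitwise
identical recordings.

The hot loop is a fused numba kernel over compact per-mask-pixel arrays;
it is cross-checked in the test suite against the pure NumPy right-hand
side and against closed-form solutions.

## Event statistics

Recordings (default save stride 0.5 s) are thresholded per pixel at 25%
above the local baseline; contiguous suprathreshold TXY components
(26-connectivity by default; time is treated like space) are discrete
events. The baseline estimator is the per-pixel 20th percentile of the
recorded trace — robust to sparse transients; median and burn-in-state
alternatives are exposed. Event area is the spatial footprint × δx²;
duration is frame-inclusive at the save stride.

CCDFs (survival functions) of areas and durations are fitted with a
least-squares line in log-log coordinates over a window, by default the
10th–90th percentile of the sample, which excludes both the
single-pixel/one-frame discreteness floor and the whole-cell saturation
bend at large areas. The fit uses one point per *distinct* sample value:
with heavily tied samples (single-pixel areas, stride-quantized durations)
a per-sample regression would enter vertical tie columns that bias the
slope towards zero. For a power-law PDF with exponent α the CCDF slope is
α − 1; the estimator recovers Pareto exponents within ±0.1 at n = 10⁵ in
the tests. The window is always reported with the slope.

## Network tilings

Seed points on a regular lattice (spacing ≈ cell density, default 50 µm)
are jittered with Gaussian σ = 10 µm displacements, Voronoi-partitioned
(computed by mirroring seeds across the box edges so all cells are finite,
then clipping), and each patch receives the library offspring whose convex
hull minimises a Procrustes-style dissimilarity: both boundaries arc-length
resampled to 64 points, centred, residual minimised over rotation and
cyclic shift, no scaling. Augmentation libraries are built from progenitor
images by random rotation (0–360°), shear and ±20% stretch; progenitor
stacks are max-projected and block-max downsampled (block max preserves
thin processes).

The draft tiling is relaxed by an active-contour scheme. Energy terms:
pairwise overlap area (repulsion), uncovered length of shared Voronoi
edges (adhesion/gap), and bending-plus-area deviation from the undeformed
contour (shape penalty); weights default 1:1:1. Vertex forces follow the
same three terms; a backtracking step control accepts a move only if the
total energy does not increase and all contours remain simple, so the
energy is non-increasing along the iteration. The discretization, step
sizes and stopping rule are this package's choices — config-exposed, not
canonical. Finally each offspring's AVF map is warped into its settled
contour by radial interpolation anchored at the contour centroid (exact
for star-shaped contours, approximate otherwise), rasterised, and
contested pixels resolved to the lowest cell id.

## Pattern analyses

Cellwise traces are AVF-weighted domain means (a half-filled pixel
contributes half; plain mean available). Spikes are upward threshold
crossings merged within a 5 s refractory window. Spike-triggered averages
use centred windows, dropping windows truncated by the recording edges.
The repeatability score tiles the template with 5 × 5 µm patches at 50%
overlap, selects patches with more than 10 spikes reaching 0.5 µM,
averages 50 s windows around their spikes over the raster of all patches,
and scores the fraction of points of the averaged raster above 0.2 µM;
scores are projected back to pixels with averaging over patch overlaps.
The fraction is taken over *all* points of the averaged raster (not only
suprathreshold patches) — the simplest reading, documented here.
Template perturbations: unlink (sever a cell's gap-junction edges),
flatten-AVF (replace `r` in a region by its regional mean), ablate (turn
region pixels extracellular). Perturbed runs reuse the unperturbed spike
trains so differences are attributable to the template.

## Synthetic astrocytes

The generator emulates a max-projected confocal stack of a dye-filled
astrocyte: a flat bright soma disc; primary branches drawn as persistent
random walks with linearly tapering width (1.4 → 0.35 µm) and intensity
(1 → 0.15); medium-intensity secondary walks branching off the primaries
(0.3–0.6 of soma intensity); and a gliapil halo of blurred thin walks at
0.25–0.35 of soma intensity. After the intensity → AVF mapping this yields
a continuous class I → II distribution dominated by low-AVF periphery
(~45% of astrocyte pixels below r = 0.1, ~13% above 0.75), which is what
gives the model its microdomain-size event scale. What the generator does
**not** emulate: real branch topology statistics, anisotropic cells,
imaging noise and depth attenuation, and 3D structure — so passing tests
show the machinery behaves correctly on plausible morphology, not that the
statistics of any particular real dataset are reproduced. Real progenitor
images (TIFF/PNG, max-projection + downsampling helpers) can be
substituted everywhere a synthetic progenitor is used.

## Problem sizes of the shipped checks

The validation suite and the results-reproduction script run the
single-cell drive study on three synthetic cells of 28 µm extent at
δx = 0.55 µm with 500 s recordings after 200 s burn-in — miniature
relative to real astrocytes (~60 µm) and to the reference protocol
(27 templates, 2500 s after 2000 s burn-in at δx = 0.275 µm), chosen so
the full study completes in minutes on one CPU. Event-count levels and
the exact slope values depend on this scale; the qualitative contrasts
(drive-level ordering of slopes and of large/small event counts, the
AVF-dependence of baselines, the whole-cell bend) are the quantities the
checks assert. The `full_config()` preset records the reference-scale
settings for batch use.

## Known limitations

* 2D only; the raster format reserves no plane axis and 3D is not
  implemented.
* The intermediate-AVF event scale, and hence the fitted CCDF slopes,
  depend on the synthetic morphology; slopes are reproduced as desk-scale
  stand-ins, not exact values. In particular, the simulated area/duration
  distributions carry a quantal plateau — single-release responses of
  near-identical 3–6-pixel footprint — below their median. The default
  10–90th-percentile fit window straddles this plateau and yields slopes
  of ~1–1.6, substantially shallower than the reference 2.3–4.1 even
  though the drive-level *ordering* of the slopes and the whole-cell bend
  are reproduced. Fitting only the tail above the plateau (pass an
  explicit `window` to `fit_slope`) roughly doubles the area slopes and
  brings duration slopes near the reference; the default window is kept
  because it is the package's declared, pre-registered estimator and is
  always reported alongside the slope.
* The active-contour relaxation is a heuristic energy descent; it
  guarantees non-increasing energy and simple contours, not a global
  optimum.
* No neuron-feedback loop, no Na⁺/NCX biophysics (lumped into `J_Glu`),
  no mitochondrial calcium, no correlated presynaptic spike patterns.
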