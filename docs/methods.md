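# Methods

`ionflux` analyzes ion conduction through pentameric ligand-gated ion
channels (pLGICs) the way a computational-electrophysiology study does:
count full permeation events in a trajectory, convert counts to currents,
fit per-polarity slope conductances, decide which extracellular route each
conducted ion took, profile the pore geometry, estimate 2D free-energy
surfaces for ion translocation, and analyze single-channel recordings.
Because microsecond all-atom MD and wet-lab patch clamp are out of reach for
a test suite, every stage is validated against synthetic generators with
known ground truth. This note records the models, the defaults, and the
choices that were genuinely open.

## Coordinate and sign conventions

The channel axis is +z with the extracellular side up; "outward" means
−z → +z. A fixed uniform field E_z across a periodic box of z-length L_z
imposes a transmembrane potential ΔV_m = E_z·L_z. ΔV_m > 0 drives cations
outward, and outward cation current is reported positive; with these two
conventions an outwardly rectifying channel has γ_o/γ_i > 1. Units are Å,
ns, mV, pA, pS, kcal/mol throughout.

## Permeation events and currents

An event is a complete traversal of the transmembrane gate slab
(z_lower → z_upper or the reverse) during which every frame between the
planes lies within the pore cylinder radius r_pore. The detector folds
unwrapped coordinates back onto the primary cell with an explicit periodic
image index, so an ion that leaves through one bulk and re-enters through
the other is never miscounted as a gate crossing. Partial entries that
return to the entry side produce nothing; an optional buffer margin
(disabled by default, 2 Å when enabled) widens the band an ion must clear
before it counts as outside, suppressing double counts from single-frame
jitter at a plane. Whether wrapped or unwrapped coordinates feed the state
machine is an implementation choice other pipelines rarely document; here
the coordinates are unwrapped and the behaviour is pinned by an exhaustive
frame-by-frame oracle that must agree exactly on every fixture.

Current uses net signed flux, I = z·e·(N_out − N_in)/T, with
e/ns = 160.218 pA per crossing. At the voltages where conductance is fit
the two readings of "events per time" (net vs gross) coincide in practice,
and at 0 mV only net flux is physically meaningful; a `gross` toggle is
exposed. Slope conductances come from ordinary least squares on all
replicate currents of one polarity, the 0 mV points entering both fits,
with no constraint through the origin; the slope standard error is the
regression SE. The rectification ratio is γ_o/γ_i.

## Pathway classification

pLGICs admit ions to the extracellular vestibule through an apical (axial)
aperture or through lateral intersubunit fenestrations. The classifier
locates the transit between extracellular bulk and vestibule adjacent to
the gate crossing — the last one before entry for inward events, the first
after exit for outward — and inspects the whole transit window: frames
inside the aperture tube (r < r_apical above the vestibule ceiling) mark it
apical, frames beyond the fenestration inner radius inside the fenestration
z-band mark it lateral, and the fenestration sector is the azimuthal fifth
(configurable phase) at the passage frame nearest the vestibule. A window
showing neither signature, or an ion that reached the vestibule from the
intracellular side (a vestibule return), stays `unassigned` — logged, never
dropped, so apical + lateral + unassigned always equals the event count.
Judging the whole window rather than a single frame pair matters for
diffusive trajectories, where the boundary is crossed over many frames.

## The synthetic channel

The generator runs non-interacting overdamped (Brownian) ions,
x ← x + (D/k_BT)F dt + √(2D dt)η, in an idealized channel built from soft
flat-bottom walls (k = 5 kcal/mol/Å²): a membrane slab pierced by the pore,
a vestibule shell carrying five fenestration holes (60% of each sector
open), a ceiling with the apical aperture, periodic in all directions.
Overdamped dynamics is the cheapest dynamics with a well-defined stationary
distribution, and crossing statistics are all that matter here. Two
features deserve note:

* the pore confinement sits 2 Å inside the detection radius r_pore, so
  thermal penetration of the soft wall can never carry an ion past the
  radius the event definition checks — without the margin, rare excursions
  invalidate transits and bias currents low;
* the vestibule shell extends down through the membrane band, sealing the
  wall-slab junction (a gap there lets ions ratchet under the shell).

Ground truth is emitted by the generator itself: events from the
frame-exhaustive oracle on the emitted frames, pathways from step-resolution
region tracking with full-shell hysteresis (bulk ↔ vestibule flips only; a
grazing touch of the fenestration cylinder without traversing the shell
never registers, and an intracellular excursion resets the state).

**Ohmic mode** replaces the channel by a uniform tube spanning the periodic
box. Uniform density is then the exact stationary state at any field, so
the I–V relation is exactly linear and the programmed conductance has the
closed form γ = 1000·n·D·z²·(e·mV)·(pA/crossing/ns)/(k_BT·L_z²) — about
387 pS at the defaults (n = 20 ions, D = 20 Å²/ns, L_z = 80 Å, 300 K).
The default campaign mirrors the fixed-field protocol: ΔV_m ∈ {−250, −100,
0, +100, +250} mV, three replicates per potential, 150 ns per replicate.
At those sizes the fitted slope carries a sampling SE of roughly 4–5%, so
recovery within 15% holds with wide margin. What the tube does **not**
emulate: access resistance, ion–ion correlations, saturation, selectivity —
so passing tests demonstrate the counting/fitting pipeline, not channel
physics.

Scripted waypoint trajectories supply exact fixtures (each ion one
prescribed crossing, apical or lateral with known sector), used for the
1000-event classification benchmark.

The two-state patch generator samples a continuous-time open/closed Markov
chain at 20 kHz, open level = baseline + γV (pS·mV → pA via 10⁻³), with
plain Gaussian noise (σ = 1 pA default; no Bessel-filter emulation).
Defaults: γ = 90 pS, rates 50 s⁻¹ each, 10 s traces.

## Pore profiling

The profiler reports, at each station along an axis or polyline path, the
largest sphere centred in the normal plane touching no atom — maximizing
f(c) = min_i(|c−x_i| − R_i) by a deterministic multi-start Nelder–Mead
search seeded from a fixed 1 Å lattice (no simulated annealing:
reproducibility was preferred, and accuracy is pinned by a dense grid-search
oracle). The centre is softly constrained to within the lattice extent
(3 Å default) of the nominal axis: past the finite atom cloud the clearance
of any structure grows without bound, and the bound is what keeps the
sphere on the pore centre line. Negative optima are reported as radius 0
with an `occluded` flag; stations with no atoms in reach are flagged `gap`.
vdW radii come from a fixed Bondi-style table (user-overridable), because
maximal-sphere radii depend directly on the radius set.

Synthetic ring structures realize a prescribed profile r(z); note that in
sloped sections the inscribed sphere is clipped by narrower neighbouring
rings, so the exact construction truth is
min_z′ √((r(z′)+R)² + (z′−z)²) − R (provided as `analytic_open_radius`),
which reduces to r(z) at flat sections and local minima — the hourglass
waist is exact by construction.

## 2D ABF free energies

The estimator accumulates instantaneous collective forces on a 2D grid
(0.1 × 0.1 Å² bins). The bias applied is the negative running mean force
scaled by a linear ramp min(1, N/N₀) with N₀ = 250; a hard step at N₀
destabilizes the toy sampler and has the same fixed point, so the ramp is
the default and the interpretation is documented rather than guessed.
Windows are z-slabs (10 Å default) with a flat-bottom transverse bound
(10 Å default, k = 10 kcal/mol/Å²); the toy sampler runs many independent
walkers sharing one accumulator (multiple-walker ABF), which vectorizes
cleanly, and records −∇U plus Gaussian noise (1 kcal/mol/Å default) as the
force sample to emulate estimator noise.

The free energy is the scalar field whose forward-difference gradient best
matches the negative mean-force field, solved as a sparse least-squares
problem. Equations are weighted by the (N₀-capped) sample support of each
bin pair and bins below a minimum count are dropped from reporting: fringe
bins visited a handful of times otherwise inject large noise into the
surface. A pure curl field has no potential; the weighted residual is
reported so that case is detectable. Disconnected sampled regions integrate
separately (each anchored to min 0) with a warning. Energies are anchored
to min 0, or to the mean over a user-designated bulk band when given.

Convergence follows the usual ABF practice: PMF RMSD between checkpoints
(computed over jointly sampled bins, mean-shift removed) must stay below
0.1 kcal/mol across a 5 ns hold window while sampling entropy
(S = −Σ p ln p over sampled bins) and sampling heterogeneity plateau.
Heterogeneity here is the coefficient of variation of sampled-bin counts —
zero iff uniform; this definition is this package's own, stated rather than
inherited. Windows are stitched in z-order by the constant minimizing the
mean squared difference on the overlap, merged count-weighted, and
re-anchored.

## String-method pathways

Minimum free-energy paths are relaxed on the reconstructed surface with
fixed endpoints: 100 images move down the bilinearly interpolated gradient
component perpendicular to the path, then reparameterize to equal arc
length. Three numerical choices proved necessary and are defaults:

* a deterministic transverse bow (amplitude 2 steps) in the initial
  string — a straight segment can lie exactly on an unstable symmetry axis
  where the perpendicular gradient vanishes identically;
* light curvature smoothing (0.2) each iteration, suppressing sawtooth
  limit cycles in steep wells without measurably biasing the converged path;
* convergence judged on the curve, not the images: every 25 iterations the
  largest distance from the new images to the previous polyline is compared
  with 10⁻³ Å, which ignores images drifting tangentially along a static
  path. The step size is 0.25 of a grid cell; larger steps oscillate in
  steep basins.

On two-basin test surfaces the path's peak matches a dense-grid Dijkstra
minimax oracle to < 10⁻³ kcal/mol; a continuous path can never dip below
that saddle, which the tests also assert.

## Single-channel analysis

All-points histograms (0.1 pA bins) are fit with a sum of two Gaussians by
nonlinear least squares, initialized at the two tallest separated peaks;
among candidate peak pairs the largest combined weight wins, implementing a
dominant-conductance rule for patches with multiple open levels. Zero-noise
traces collapse each level into a bin or two, where least squares is
ill-posed; per-peak moments are then exact and used as a fallback. The
single-channel current is |μ₂ − μ₁|, invariant to baseline shifts; its sign
follows the holding potential. Per-patch γ_o/γ_i are OLS slopes per
polarity; patches are summarized per construct by averaging per-patch γ
(per-patch fits first, then aggregation — the alternative of pooling raw
currents across patches is not used, and the choice is deliberate).

Paired comparison of γ_o vs γ_i uses the classical paired t-test (n−1 df),
with degenerate inputs handled explicitly (identical lists → t = 0, p = 1;
equal nonzero differences → ±∞ flagged as p → 0). Cross-construct
comparison is one-way ANOVA (explicit sums of squares) followed by
Dunnett's many-to-one test at family-wise α = 0.05. The Dunnett critical
value is estimated by Monte Carlo from the exact joint null of the k−1
comparison statistics (shared control, pooled χ² variance; ≥10⁵ draws,
fixed seed) instead of tabulated quantiles; at k = 2 it reproduces the
two-sided t critical value to Monte Carlo error, it grows monotonically
with k, and its accept/reject decisions match an independent
implementation on test data.

## Problem sizes

Defaults were chosen so the full validation battery — the 15-replicate
fixed-field campaign, the 1000-event classification benchmark, two ABF
surfaces plus stitching, string paths with Dijkstra oracles, and a 200 000
sample patch trace — completes in a few minutes on one CPU, while leaving
each statistical criterion several standard errors of headroom.

## Known limitations

Ions are independent; there is no water, lipid, selectivity or saturation,
so conductances of the synthetic channel have no physiological meaning —
they are known quantities to be recovered. The pore profiler constrains
sphere centres near the nominal axis and will underestimate radii of
strongly off-axis cavities. The ABF sampler works directly in collective
variable space (no orthogonal degrees of freedom, no Jacobian corrections).
Only orthorhombic boxes are supported. Dwell-time/burst analysis and
sub-conductance enumeration are out of scope of the recording analysis.
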