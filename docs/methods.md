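# Methods

This note records the conventions, estimators and parameter choices behind
`shoalkit`, and what the synthetic-data tests do and do not establish.

## Trajectories and velocities

Trajectories are tables `(frame, id, x, y, z)` in mm at a fixed frame rate
(15 Hz throughout, matching the camera convention).  Velocities are forward
differences assigned to the earlier frame, `v(t) = (x(t+1) − x(t)) · fps`.
Tracking gaps are left as gaps: no velocity is defined across a missing
detection, and no interpolation happens at this layer — downstream
estimators simply skip missing pairs.  Windowing cuts the recording into
consecutive, disjoint 120 s blocks (the timescale on which the scalar
descriptors decorrelate); a shorter tail is discarded and each block is
treated as a steady state.

## Behavioural quantities

Per frame: mean speed v₀, polarisation Φ (zero-magnitude velocities are
excluded with a logged count rather than raising — stationary detections
are tracking noise), and the arithmetic mean nearest-neighbour distance
l_nn (Euclidean; a periodic minimum-image variant serves the simulation
box through the same function).

The scalar-series ACF is the standard mean-subtracted, biased estimator
normalised to 1 at lag 0 (statsmodels, FFT).  The orientation ACF is *not*
mean-subtracted: it averages ô(t)·ô(t+Δ) over individuals and all valid
time origins, giving exactly 1 at lag 0.

### Relaxation-time fit

τ comes from a least-squares line through log C(Δ) over the leading lags
where the (plateau-corrected) ACF exceeds a floor of 0.2, with at least 3
points; the floor excludes the noise tail.  In strongly ordered groups the
orientation ACF does not decay to zero but to a plateau near Φ² — the
collective direction persists far longer than any individual heading, in a
periodic simulation box essentially forever.  The fit therefore estimates
a plateau p as the mean of the last quarter of lags and fits
(C − p)/(1 − p), applying the correction only when p > 0.05 so that a
clean exponential is fitted exactly.  Choosing lag ranges of at least ~5τ
keeps the tail estimate unbiased.  For simulation sweeps the remaining
run-to-run variance of τ (the slow collective mode is a single noisy
realisation per run) is reduced by averaging over independent replicates.

The per-window state is then ⟨v₀⟩, ⟨Φ⟩, ⟨l_nn⟩ (frame means averaged over
the window), τ fitted within the window, l_p = ⟨v₀⟩τ and κ = l_p/⟨l_nn⟩.
τ is fitted per window, consistent with treating windows as steady states.
ε is attached from the spatial layer (below).

## Pair correlations in a confined arena

The tank is modelled as the paraboloid z = c·r² (c = 0.734·10⁻³ mm⁻¹,
i.e. 0.734 m⁻¹) capped by a flat water surface; the default water level of
150 mm gives a bowl of ~450 mm rim radius.  Because the volume is
irregular and non-periodic, g(r) is normalised by Monte-Carlo: the
observed pair-distance histogram (summed over analysed frames) is divided
by the mean histogram of `n_reference` uniform configurations of the same
N drawn in the same arena.  Bins are linear, default 5–10 mm for fish
scales; bins with an empty reference are NaN.  The peak search excludes
the first bin (body-size depletion makes r → 0 unreliable), and
ε = −ln(peak height): more cohesive ⇒ higher peak ⇒ more negative ε.

C(r) subtracts each frame's mean velocity, accumulates fluctuation dot
products and pair counts into distance bins across all frames, and divides
at the end (time-averaged estimator).  Empty bins are NaN, never 0.  A
variant rescales distances by the window's ⟨l_nn⟩; raw (mm/s)² values are
always retained, and a display normalisation by the first occupied bin is
available since plotted normalisations vary between studies.

## The inertial Vicsek model

Synchronous update; neighbour sets are metric (minimum-image distance
≤ ξ = 1) and include the agent itself, so an isolated noiseless agent
keeps its heading.  The cap noise draws cos θ uniformly on [1 − 2η, 1] and
the azimuth uniformly — exactly uniform on the cap of area 4πη.  A
neighbour sum that cancels exactly (measure-zero) falls back to the
agent's own heading, as does a vanishing inertia mixture.  Velocities are
renormalised to v₀ every step; positions stream forward with the updated
velocity and wrap periodically.  Neighbour search uses a periodic KD-tree;
a brute-force minimum-image oracle verifies exact agreement in the tests.

Reference parameters: ρ = 1 ξ⁻³, v₀ = 0.1 ξ/dt, α = 0.63.  The default
system size is N = 50 — the size of the observed groups, and the size at
which the model's ordered state at η = 0.65 sits at ⟨Φ⟩ ≈ 0.64; the
polarisation near the transition is strongly N-dependent (at N = 1000 the
same parameters give ⟨Φ⟩ ≈ 0.53), so like must be compared with like.
Runs use 2000 equilibration and 5000 measurement steps; Φ is recorded each
step, and state snapshots support the trajectory-level estimators.
κ on the model is measured through the same kinematics code paths as fish
data: τ from the orientation ACF of per-agent unit velocities (plateau
correction as above), l_nn from minimum-image nearest-neighbour distances
averaged over snapshots.  χ = N·var(Φ) over the measurement phase.

In the dilute, zero-inertia limit each agent redraws its heading from the
cap every step, so the per-step mean cosine is 1 − η and
τ = −1/ln(1 − η) ≈ 1/η steps *in the cap-area parametrisation*.  The
classical η⁻² law for the persistence length ℓ = v₀τ holds in the angular
noise *amplitude*: a cap of opening half-angle θ has area fraction
≈ θ²/4, hence τ ≈ 4/θ².  The scaling study therefore sweeps the cap
opening angle over [0.05, 0.3] rad and recovers the log–log slope −2.

## Macroscopic-state reduction

The planar model Φ = a·l_p + b·l_nn + c is ordinary least squares with an
intercept, unstandardised (units mm⁻¹), pooled over all groups' windows by
default; a condition-number guard rejects collinear designs.  The κ–Φ
collapse interpolates the model sweep curve piecewise-linearly in κ
(sweep grids are coarse) and reports the RMS vertical deviation of data
points inside the overlapping κ range; no per-group refitting.  The
isotropic baseline — mean and SD of Φ for N independent uniform headings,
the disorder floor of a finite group — is Monte-Carlo (exact 1 for N = 1,
≈ 0.13 for N = 50, ∝ N^{−1/2}).

## Synthetic recordings

The generator runs the same alignment dynamics inside the bowl arena:
alignment over a metric range (default 60–100 mm), optional cohesion as a
unit-vector bias toward the group centroid added before the noise,
cap noise per step, optional inertia (default α = 0: in that limit the
requested relaxation time maps exactly to the noise via
τ_steps = −1/ln(1−η), which keeps the ground truth well-defined for
recovery tests).  Walls reflect: headings mirror off the paraboloid normal
and the water surface, positions mirror vertically, with a radial
pull-back near the rim.  Output is subsampled at an integer number of
simulation steps per camera frame, then degraded by isotropic Gaussian
position jitter and random dropout (never emptying a frame entirely).  A
piecewise schedule of (time, relaxation time, cohesion) emulates the slow
drift of a freshly introduced group from schooling to shoaling.
Defaults — 50 fish, 15 Hz, cruising speeds 25–40 mm/s (~1 body length/s),
relaxation times 0.15–1 s, nearest-neighbour distances 20–60 mm — are
chosen to sit in the observed behavioural range.

What the generator does *not* emulate: identity switches and occlusion
artefacts, body shape and burst-and-coast gait, wall-following behaviour,
or any attraction rule beyond the centroid bias.  Passing the recovery
tests therefore shows the estimator chain is correct on clean Vicsek-like
motion in a tank, not that real fish follow this model.  Two biases are
real and expected: wall reflections shorten the measured τ relative to the
nominal one (recovery tests use slow swimmers in a deep bowl to keep wall
encounters rare), and alignment interactions add collective persistence on
top of individual reorientation.

## Scales and run times

Simulation checks use group-sized systems (N = 50) with the full
2000 + 5000-step protocol, replicated over independent seeds where a
quantity (κ near the transition) is fluctuation-dominated; the dilute
scaling study uses 150–200 independent walkers for 15–20k steps.  The
bundled analysis drivers generate 600 s recordings by default (five 120 s
windows each); all defaults are arguments.

## Known limitations

- κ of deeply ordered periodic-box states is dominated by the slow
  collective mode; it is reported as measured but carries large error bars
  at low η even after replicate averaging.
- The RDF reference assumes the arena model is exact; a mis-specified
  arena biases g(r) at large r.  Whether reference sampling should model
  surface effects differently is configurable via user-supplied arenas.
- The behavioural-dataset JSON reader accepts a synonym map
  (`BEHAVIOURAL_KEY_SYNONYMS`) because external key naming varies; extend
  it for new sources.
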