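# Methods

This note documents the models, parameter choices and numerical conventions
behind `bocswarm`, and what the synthetic test conditions do and do not show
about real data.

## Visual geometry

Individuals are non-transparent ellipses.  `a` and `b` throughout the package
are **semi**-axis lengths (mm); the aspect ratio `b/a` defaults to 0.1 for
fish-style trajectory analysis and 0.3 for simulated agents — elongated
bodies in both cases.  The eye is the boundary point at `center + a·ĥ`, with
`ĥ` the heading unit vector.

Tangent points are computed in the neighbor's body frame, where the polar
line (chord of contact) of the external eye point with respect to the ellipse
gives both tangency points in closed form:  with body-frame eye coordinates
(e_x, e_y), P = e_x/a, Q = e_y/b and R² = P² + Q² (> 1 outside the body), the
tangency parameters are φ ± arccos(1/R) with φ = atan2(Q, P), and the chord
length is

    β = (2/R²) √((R² − 1)(a²Q² + b²P²)).

No iterative root finding is involved; the whole N×N chord matrix is
evaluated vectorized.  An eye on or inside a neighbor's boundary is a
degenerate-geometry error in the scalar API and an ignored (NaN) pair in the
vectorized one.

**Occlusion.**  A neighbor is discarded iff its entire angular interval at
the eye is covered by the union of the intervals of agents with strictly
smaller eye-to-center distance; partial occlusion keeps the neighbor with its
full β.  This conservative full-coverage rule is one admissible reading of
non-transparent bodies and is verified against brute-force ray casting.  The
production path sweeps neighbors in distance order while maintaining a union
of disjoint arcs, making each test exact at O(log k).  Equal-distance
neighbors never occlude one another.

**Frontal weighting.**  fp = ((1 + v̂·x̂)/2)^α with α ≥ 0; α = 0 disables the
anisotropy (the simulator's convention), α = 1 is the default for trajectory
analysis, α ≈ 10 effectively restricts perception to the frontal half-plane.

**Windows.**  g_ij(T, τ) sums the n = round(τ/Δt) transients ending at frame
T; a τ that is not an integer multiple of Δt is rounded with a logged
warning.  In `build_boc_matrix`, pair visibility (range and occlusion) is
evaluated at the observation frame T — the decision instant — not per frame
inside the window.  When an agent's speed is zero its last heading defines
both the ellipse orientation and fp.

## Trajectory analysis

Motion salience is the max-normalized vector of column means of **G**(T, τ)
(diagonal excluded); an all-zero matrix yields all-zero salience with a
warning rather than an error.  Baseline cues substitute the per-pair summand:
Σ fp/d_ij for the inverse-distance cue, Σ |Δ bearing|/Δt · fp for the
bearing-change cue (bearing measured in the focal body frame), and Σ fp for
the frontal-weight-only cue.  The exact functional forms of the first two are
design choices; they encode the hypotheses "closer neighbors dominate" and
"laterally drifting neighbors dominate" in the same accumulation template as
the BOC cue.

The alignment function ξ_ij(λ) averages v̂_i(t)·v̂_j(t+λ) over the shrinking
valid overlap only (no padding); the lag grid step equals Δt.  Flat maxima
are resolved toward the smallest |λ| and then toward the negative lag, and an
exactly zero λ* yields no edge — synchronized pairs carry no hierarchy.
Spearman correlations use average ranks for ties and are reported as missing
(NaN) when either vector is constant.

The U-turn detector finds sign changes of the group-mean angular velocity
about the tank center that are stable for at least `s_pre` = `s_post` = 0.5 s
on each side; these thresholds are configuration values, not claims about any
particular dataset.  Segment grids step the window end time by `stride`
starting at `start + τ`, keeping every `[T − τ, T]` strictly inside the
window.

## Swarm model

Both scenarios share: jittered hexagonal initial placement inside a disk
(spacing 60 mm, jitter 0.15·spacing), common +x initial heading, initiator =
front-most agent along the heading, per-agent selection of a single visible
neighbor per step (BOC argmax with ties to the smallest id, or uniform
random), and the occlusion rule above.  The BOC used for selection is the
α = 0 accumulation over the last τ = 0.69 s (3 frames).

*Collective spin*: positions are fixed; a non-initiator synchronously copies
its selected neighbor's motion state; spinning agents rotate by ω_max·Δt per
step (ω_max = 0.83 rad/s); the initiator spins from step 25 until its
cumulative rotation reaches 2π (33 steps at Δt = 0.23 s) and then stops.

*Collective turn*: agents move at constant speed v0 and update headings by
v̂_i ← normalize(v̂_i + k_a·v̂_sel).  The sum is renormalized so speed stays
exactly v0, and the per-step heading change of **every** agent is clamped to
ω_max·Δt — the turn-rate limit of a differential-drive platform.  The clamp
is not cosmetic: an exactly antiparallel informed direction (θ_info = π) is a
fixed point of the bare alignment rule, and only the initiator's gradual
rotation through intermediate headings (at ω_max, toward its held direction
n̂) lets the turn nucleate.  Pairs closer than r_rep = 40 mm receive a gentle
separating displacement −k_rep(r_rep − d)x̂_ij (k_rep = 0.2) after alignment.

Parameter defaults (all config-exposed, echoed into run manifests): Δt =
0.23 s, ω_max = 0.83 rad/s, k_a = 1 (plain averaging of own and selected
heading), v0 = 20 mm/s, a = 15 mm, b = 4.5 mm, R_visual = 100 mm for spin and
200 mm for turn (the two experiments are parameterized independently),
activation step 25 (spin) / 50 (turn), 70 (spin) / 250 (turn) steps per run.
ω_max and the aspect ratio are literature-anchored; the remaining values are
this package's own calibration, chosen so that the model sits in the regime
where the qualitative contrasts are well-posed: the spin wavefront can cross
the largest group well before the initiator's 2π completes, the random
policy's reach saturates below the group scale, and a θ_info = π turn can
propagate before the group disperses.  With a visual range comparable to the
whole group diameter the random policy also reaches everyone and the
contrasts degenerate — the interesting regime is local perception.

Runs are bit-reproducible: all randomness (placement jitter, random-policy
draws) comes from one `numpy` generator seeded from the config.

## Metrics

C(r) uses velocity fluctuations û_i = v̂_i − ⟨v̂⟩ computed over *responders*
only: agents that started spinning by the evaluation step (spin; evaluated
when the initiator completes 2π) or whose final heading lies within π/2 of n̂
(turn; evaluated at the last step).  The smoothed δ filter is realized as
fixed-width distance bins, default the mean nearest-neighbor distance; r₀
interpolates linearly between the bins bracketing the first sign change and
is missing when C never crosses zero.  A naive O(N²) recomputation is kept in
the tests as the oracle for the binned implementation.

Transfer speed fits are ordinary least squares (slope and intercept both
reported, the fit is not forced through the origin).  Spin ranks order by
first-spin step with ties broken by distance to the initiator and then id;
never-spinners are excluded and counted, not treated as infinite lags.  Turn
ranks follow the pairwise-score recursion: w_ij = +1 if λ*_ij < 0, −1 if
λ*_ij > 0, 0 on ties; κ ascending in W_i (ties: earlier heading-change frame,
then id); delays t_i = Σ_{κ_j<κ_i}(t_j + |λ*_ij|)/(κ_i − 1) with t = 0 at
κ = 1; transfer distance = subgroup radius l_r(t_i)/ρ with ρ = 1.

Responsiveness integrates 1 − V̂(t)·n̂ by the trapezoid rule over
[t0, t1], defaulting to [activation, end of run].

## Camera emulation

The pinhole camera sits at the agent's eye with the optical axis along its
heading; image x points to the viewer's right, image y up.  Each neighbor is
an ellipsoid (semi-axes a, b, and a height defaulting to b) resting on the
ground plane, sampled on a fixed deterministic 64×32 surface mesh; the
bounding box of the projected vertices stands in for a detector output.  The
mesh bounds the box error at ~10⁻³ relative — visible in the tests'
tolerances.  The camera-side BOC estimate is Σ|A(t) − A(t−1)|/Δt over the
window.

An important geometric fact, measured and documented rather than hidden: the
tangent chord β includes extent *along* the line of sight (it is steeply
sensitive near end-on views), which an image-plane bounding box cannot see.
Across fully random orientations and rotation rates the two cues therefore
rank neighbors differently in a large fraction of scenes.  The premise that
the camera pipeline can stand in for the exact cue holds in the regime where
it is actually used — scenes in which one neighbor maneuvers at a clearly
distinct rate (≥ 0.5 rad/s against ≤ 0.02 rad/s residual jitter, distances
90–200 mm, frontal bearings): there the argmax agreement exceeds 95%.  With
comparable maneuver rates across neighbors the agreement degrades toward
~50%, and a dimension-based or distance-normalized camera cue would be needed.

## Synthetic data

The generators produce exactly the structures the analyses are meant to
detect: staggered-lag heading chains (with von Mises heading noise of
concentration 1/σ², σ ∈ {0, 0.05, 0.1, 0.2} rad in the recovery sweeps),
orbit reversals in a circular tank, in-place rotating neighbors, heading
gradients along a line, and static grids.  They emulate clean kinematics
only: no tracking gaps, no burst-and-coast speed modulation, no wall
hydrodynamics, no body deformation.  Passing the recovery tests therefore
shows the *inference machinery* is correct, not that real fish satisfy its
assumptions; analyses of real tracking data should treat the CSV loader's
validation (rectangularity, finite coordinates) as a minimum, not a
sufficient, check.

## Known limitations

- Vision is two-dimensional; the camera module idealizes detection geometry
  and does not rasterize images.
- The simulator is kinematic: no collision dynamics beyond the soft
  repulsion, no wheel-level control, no actuation noise.
- The occlusion rule is all-or-nothing; partially hidden bodies keep their
  full chord.
- β has no continuous-time definition here; all rates are finite differences
  at the frame interval.
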