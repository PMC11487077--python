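# bocswarm

Vision-based interaction in collective motion, built around a single visual
cue: the **body orientation change (BOC)** of neighbors as seen from a
first-person view.

Animals in groups — schooling fish, flocking birds, robot swarms — must decide
*which* neighbor to attend to when the group responds to a sudden event.
`bocswarm` implements a complete pipeline for the hypothesis that the most
informative neighbor is the one whose *body orientation is changing fastest*
in the focal individual's visual field:

1. **Visual geometry.** Each individual is a non-transparent ellipse with
   semi-axes *a* (major) and *b* (minor); its eye sits on the boundary at the
   front of the major axis.  A neighbor *j*'s apparent body is the chord
   β_j(t) between the two points where rays from the eye are tangent to its
   ellipse.  The accumulated, frontally weighted chord-change rate

       g_ij(T, τ) = Σ_{t=T−τ+1}^{T}  |β_j(t) − β_j(t−1)| / Δt · fp(t),
       fp(t) = ((1 + v̂_i(t) · x̂_ij(t)) / 2)^α,

   quantifies the neighbor's BOC.  Nearer bodies can fully occlude farther
   ones (exact angular-interval union test).
2. **Trajectory analysis.**  For a tracked group, the N×N BOC matrix
   **G**(T, τ) is reduced to a per-individual *motion salience* (max-normalized
   column means).  Leader–follower relations come from the time-lagged
   directional alignment ξ_ij(λ) = ⟨v̂_i(t)·v̂_j(t+λ)⟩: the sign of the
   argmax lag λ*_ij orients each pair's edge, and leadership is the normalized
   out-degree L_i = d_i^out/(N−1).  Salience and leadership are compared by
   Spearman rank correlation, with inverse-distance, bearing-change and
   frontal-weight-only cues as baselines.
3. **Swarm simulation.**  A kinematic self-propelled model runs *collective
   spin* (stationary agents propagating an in-place rotation triggered by one
   initiator) and *collective turn* (moving agents re-aligning after one
   informed agent turns by θ_info), with each agent reacting to the single
   visible neighbor of maximal BOC — or to a uniformly random one as the
   baseline policy.
4. **Collective-response metrics.**  Polarization φ, velocity-fluctuation
   correlation C(r) and correlation length r₀ (its first zero), information
   transfer speed V_s (slope of transfer distance versus response lag),
   response accuracy δ_resp(t) = ⟨v̂_i·n̂⟩ and responsiveness
   R = ⟨1 − V̂(t)·n̂⟩ over the response window.
5. **Camera emulation.**  A pinhole model projects each neighbor as an
   ellipsoid onto an image plane; the change of its bounding-box area is a
   camera-side BOC estimate that needs no tangent geometry, for robot swarms
   with onboard vision.

## Worked example

Recover a planted leadership hierarchy and correlate it with BOC salience,
then run a collective-spin experiment:

```python
import numpy as np
from bocswarm import (planted_chain_turn, leader_follower_network, leadership,
                      build_boc_matrix, motion_salience,
                      salience_leadership_correlation, BOCParams,
                      SimConfig, run_experiment, trace_metrics)

# a 6-fish chain: agent 0 turns first, each follower copies with a 1-frame lag
data = planted_chain_turn(6, lag_frames=1, noise_sigma=0.05, seed=0)
net = leader_follower_network(data, 0, data.n_frames - 1)
L = leadership(net).values
G = build_boc_matrix(data, T=30, params=BOCParams(tau=1.5, alpha=1.0, dt=data.dt))
S = motion_salience(G).values
print("leadership:", np.round(L, 2))
print("salience:  ", np.round(S, 2))
print("spearman rho:", round(salience_leadership_correlation(S, L), 3))

m = trace_metrics(run_experiment(SimConfig(N=50, scenario="spin", policy="boc", seed=0)))
print("all spinning before initiator done:", m["all_spinning_before_initiator_done"])
print("V_s = %.0f mm/s, r0 = %.0f mm" % (m["V_s"], m["r0_mm"]))
```

Output:

```
leadership: [1.  0.8 0.6 0.4 0.2 0. ]
salience:   [1.   0.78 0.44 0.37 0.49 0.15]
spearman rho: 0.829
all spinning before initiator done: True
V_s = 311 mm/s, r0 = 188 mm
```

The leadership vector descends exactly in the planted chain order; the BOC
salience of the early movers is highest, and the two rank orders correlate
strongly (ρ = 0.83).  In the spin experiment the rotation state reaches all
50 agents before the initiator finishes its 2π turn, with an information
transfer speed of ~310 mm/s and a correlation length of ~190 mm.

## Command line

```bash
bocswarm fixtures --kind planted_chain_turn --param n=8 --seed 1 --out chain.csv
bocswarm analyze chain.csv --dt 0.1 --tau 1.5 --out analysis_out
bocswarm simulate --scenario spin --policy boc --policy random -n 50 --seed 0 --out sims
bocswarm metrics sims/spin_boc_N50_seed0/trajectory.csv --dt 0.23 --out m_out
```

Every run writes a `manifest.json` (resolved configuration, seed, version,
input hashes) so deterministic runs reproduce bit-identically.  All files use
mm, s and rad.

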