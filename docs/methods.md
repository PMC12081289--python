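# Methods

This note documents the models, parameters and numerical choices behind
`compmap`, and what the synthetic benchmarks do and do not establish.

## Worlds and optimal policies

Discrete worlds are rectangular grids (0-based `(col, row)` coordinates,
origin at the southwest corner) with actions north/east/south/west. Walls
are blocked *edges* between adjacent cells, never filled cells: a wall is a
straight run of blocked edges carrying its two end cells, because each wall
is represented downstream by two vector-cell populations, one anchored on
each end. Blocked moves are no-ops rather than errors so that rollouts are
total. Sampled worlds are rejected (up to a configurable attempt budget)
unless every cell can reach the reward. Optimal policies minimize steps to
reward; distances come from unweighted Dijkstra on the open-edge graph and
ties between equally good actions break by the fixed action order.

Continuous arenas are 1 m × 1 m with line-segment walls and a point reward;
the agent moves 5 cm per step along a continuous heading and a move that
would cross a wall or leave the arena is a no-op (contact rule chosen for
symmetry with the grid case). The continuous optimal policy is computed on
a fine 8-connected discretization (2.5 cm spacing by default) with edges
removed where they cross a wall; headings point along the Dijkstra
predecessor direction. Both the 5 cm step and the discretization are
package choices: the model itself does not prescribe them.

## Vector codes and conjunctions

The discrete object-vector code concatenates, in fixed action order, one-hot
signed distances from the agent to the object along each action; actions
pointing away from the object clamp to −1 regardless of magnitude. The
one-hot range is −1…D−1 with D = max(width, height), so any in-range offset
activates exactly four cells and decodes uniquely. The continuous code is a
population of isotropic Gaussian fields (width 5 cm) whose preferred vectors
tile a square ±1 m grid at 10 cm spacing around the object — spacing, extent
and width are package choices, sized so a 1 m arena is covered with a few
fields of overlap.

Conjunctions are outer products: all pairwise products of two parent codes.
At the rate-map level the same operation is an elementwise product of maps,
which converts an object-vector map (a field at a fixed vector from *every*
object) into a landmark-cell map (fields at only those objects whose
location happens to align with the grid partner's peaks).

## Tracking, memory and fusion

On discovering an object (adjacent cell on grids; within 5 cm in arenas)
the agent initializes the object's vector relation and stores it in a
key-value memory keyed by location. Each subsequent transition updates the
relation two ways: noisy path integration (discrete: correct update with
probability 1 − e_PI, otherwise one of the four action-adjacent neighbor
offsets; continuous: Gaussian noise on the step's direction and magnitude)
and retrieval of previously stored relations at the observed new location
(discrete: probabilities proportional to retrieval counts; continuous: a
softmax at unit temperature over cosine similarities between memory keys and
the query location, over entries within a 5 cm cutoff). The fused estimate
samples (discrete) or averages (continuous) the two sources with weight
w = 0.5 — the weight is exposed in every entry point because no principled
value is implied by the model — and is re-encoded at the new location. An
empty retrieval degenerates cleanly to path integration.

## Policies that generalize

Policy networks are ReLU MLPs trained with Adam (scikit-learn's
`MLPClassifier`/`MLPRegressor`, seeded). Default hidden dimensions are
1000/750/500 (discrete; softmax over four actions) and 3000/2000/1000
(continuous; (sin, cos) heading regressed and renormalized at evaluation).
The benchmark recipes and acceptance checks run smaller nets (256/128/64)
and 4 multi-environment resampling rounds of 25 environments × 200 samples:
the reward-only discrete task is a ~30-dimensional input problem for which
these sizes are already far over-parameterized, and they keep the whole
suite on one CPU in minutes. A shared wall-embedding layer (an optional
speed-up, not needed for learning) is not implemented. Training pools all
sampled rounds into one supervised fit rather than interleaving batched
updates; the training distribution is identical.

Evaluation is greedy (argmax action / normalized heading), rolled out with a
budget of 4× the optimal path length (minimum 30 steps), counting the
fraction of start locations that reach the reward (within 5 cm in arenas).
A consequence worth knowing: a *misgeneralizing* deterministic policy
scores below a uniform-random baseline, because random walks diffuse to the
reward within the budget while a wrong vector field loops. The
generalization-asymmetry check therefore asserts the traditional code is
not significantly *above* the random baseline, and the compositional code
exceeds 0.9 on unseen worlds.

Latent learning is evaluated model-based: at each encounter of a
behind-wall state (a state whose optimal distance changes when walls are
removed), the agent plans with the optimal policy of the world it currently
*believes* in (known walls only) and the rollout runs in the true world, so
planning through an unknown wall stalls. The non-latent agent acquires the
wall representation the first time it stands on a wall-adjacent cell, after
which (path integration being noiseless here) it is wall-aware everywhere.

## Constructive replay vs Q backups

Replay trajectories start at the reward/home and extend along a random
policy over moving actions, or along a reverse-optimal policy that ascends
the distance-to-reward field; length caps at twice the grid diameter.
Constructive replay path integrates both the imagined location (key) and
the vector relation (value) — with noise, either can drift; it never reads
memory. Backward Q backups credit, after an imagined transition a → b, the
reverse action from b with the reward at a plus γ·max Q(a) (γ = 0.7,
α = 0.8, values initialized at zero).

The per-visit benchmark scores, after every replay step, whether the
current knowledge yields an *optimal* path from that step's location: the
memory agent retrieves the stored vector once and path integrates it along
a greedy walk; the Q agent follows greedy Q and fails wherever max Q = 0.
These curves run on reward-only worlds, where the vector read-out is exact;
that isolates the one-shot property from wall-avoidance planning.

The homing task places home at the center of a 9 × 9 grid (or a 1 m arena),
lets the agent explore randomly under path-integration noise, and scores
the distance from home after a greedy escape on the believed home vector.
The memory agent replays from home five times every four exploration steps
and fuses retrievals during behavior; the Q agent replays Q updates whose
*locations* are path integrated (credit can land on the wrong state) but
whose escape read-out observes the true location. The continuous variant
discretizes Q over 10 cm cells and 8 headings and uses 20-step replays.
The noise levels (e_PI ∈ {0.1, 0.2, 0.4}), exploration lengths
({16, 32, 64}) and replay counts ({1, 2, 5, 10}) are package choices; the
qualitative orderings (memory < pure path integration everywhere; memory
reaches a given error with fewer replays than Q) are the claims under test,
not the particular grid values.

## The synthetic home-well population

The population emulates a home/away-well arena recording: 10 grid cells
(triangular lattice, 120 cm spacing, rotated 6°, random translation per
cell), 20 object-vector cells (uniform direction, uniform 0–200 cm distance
from the home well; day-2 maps are day-1 maps translated with the home
well) and 40 sensory cells (uniform centers), each class rescaled to a
20 Hz population maximum. Conjunctions give 200 landmark and 400 place
cells, rescaled per class (one factor across both days, so cross-day
landmark changes remain construction-exact). Gaussian field variances are
0.02 m² (grid, sensory; σ ≈ 14.1 cm) and 0.012 m² (object-vector;
σ ≈ 11.0 cm); these widths, together with the ×25 replay rate scaling,
5 ms steps and 20-step trajectories, put the session at ≈30–34 Poisson
spikes per replay trajectory. The simulated arena is 2 m × 2 m (0–200 cm
object-vector distances require at least that extent) with 2 cm bins,
matching the analysis pipeline; default home wells sit at (60, 60) cm on
day 1 and (140, 120) cm on day 2.

A session holds 100 replay events in a repeating home, elsewhere,
elsewhere, elsewhere pattern spread evenly over 10–3000 s. Each trajectory
is a straight path of 100–300 cm over 20 steps, cut short at the arena edge
and — for elsewhere replays — at a 30 cm home exclusion zone. A landmark
cell's spikes in elsewhere replays are suppressed until the cell has spiked
in a home replay (the model's claim: elsewhere replays revisit, they do not
create). The ground-truth change map of a landmark cell for a replay at
time t₁, given its first home spike at t₀, is (t₀/t₁) of its full field
plus 0.5 Hz standard-normal noise smoothed with a 4 cm kernel; place-cell
changes are noise alone. Day-2 cumulative changes are (day-2 − day-1) maps
plus the same noise.

What the generator does **not** emulate: theta-paced behavioral spiking,
bursting/refractoriness, cell-to-cell rate heterogeneity beyond the
conjunction geometry, electrode drift, or any relation between behavior and
replay content. Pipeline results on these sessions validate the *analysis
chain* and the model's qualitative signatures — not distributional realism
of spike trains. Behavioral (between-event) spiking, needed only by the
rate-map and decoder-validation utilities, comes from a synthetic foraging
track (random-walk heading, constant 20 cm/s, reflecting boundaries) with
Poisson spikes from the ground-truth maps; the source recordings' behavior
is not modeled.

## Analysis pipeline

Rate maps: 2 cm bins, occupancy and spike counts smoothed with the same
4 cm-s.d. kernel before division (the kernel is renormalized over in-arena
bins by dividing by a smoothed mask), speed filter > 5 cm/s, bins below
0.2 s smoothed occupancy masked. Population rate: 1 ms histogram of spikes
during immobility (< 5 cm/s), smoothed with a 10 ms-s.d. kernel. Replay
events bracket a supplied ripple time between crossings of the pre- and
post-ripple mean rate; the mean is taken over nonzero 1 ms bins in a 500 ms
window on each side.

Decoding is memoryless per 20 ms window (slid by 5 ms):
log F = Σᵢ nᵢ log fᵢ(pos) − τ Σᵢ fᵢ(pos), normalized in log space; rates are
floored at 10⁻¹⁰ Hz. The decoded position is the posterior maximum with
near-ties resolved by their centroid. Leave-one-out excludes a neuron's
spikes *and* its rate map (both terms); with log maps precomputed this is a
cheap per-window adjustment. Spike locations interpolate linearly between
bracketing window centers; spikes outside the decoded span clamp to the
nearest endpoint and are flagged.

Two decoder properties measured on synthetic sessions deserve note. First,
decode error is bounded below by the conjunctive field width (~9–14 cm) and
by temporal windowing: at replay compression a 20 ms window spans tens of
centimeters of trajectory, so decodes are pulled toward the window-average
position. Second, leave-one-out cannot remove *all* information correlated
with the excluded cell: sibling conjunctions sharing its object-vector
parent have fields at the same location. The pipeline's guarantee — and
what the tests assert — is that exclusion removes the excluded cell's own
pull (shifts relative to the full decode are away from, never toward, its
field, and excluding a silent cell changes nothing).

Event classification follows three-part home criteria (animal ≤ 10 cm from
home, trajectory within 30 cm of home at least once, mean decoded position
≥ 40 cm from the animal) and mirrored elsewhere criteria (> 10 cm, never
within 30 cm, ≥ 40 cm); everything else is excluded. Time-matched controls
draw 10,000 candidate subsamples of the elsewhere events and keep the one
whose 5-bin event-time histogram best correlates with the home histogram.
Aligned change maps are translated so the interpolated spike's bin sits at
the canvas origin; a cell's multiple spikes within one event are averaged
first. Summaries report the mean within an 8 cm-radius origin ROI and a
50-point × 2 cm radial profile averaged over 20 uniform angles
(nearest-bin sampling). Home-shift generalization correlates the change map
aligned on the current home with a copy aligned on the previous home, over
jointly valid bins; replay/change overlap multiplies |change| by a
4 cm-smoothed map of interpolated spike locations (and, separately,
correlates instead of multiplying to isolate alignment from spike count).
All directional hypothesis tests are one-tailed in the model-predicted
direction. Nonlocal door spikes (the replay proxy for datasets without
decodable replay) require the animal within 10 cm of a closed door, moving
slower than 5 cm/s, and no place field of the spiking cell at the animal's
location; new-field emergence is regressed on the per-cell replay indicator
with mean firing rate as covariate (OLS, one-tailed t).

## Problem sizes and reproducibility

The default test/benchmark sizes are: 25 worlds for the per-visit and
latent-learning curves; 4 resampling rounds for multi-environment policy
training; 10–12 seeds per homing grid cell; one full 600-cell session
(100 events) for the pipeline checks; 6 population draws × 2 sessions for
the spike-yield estimate. Every stochastic entry point takes an explicit
`numpy.random.Generator` or integer seed, and identical seeds reproduce
byte-identical outputs on one machine (scikit-learn fits included).

## Known limitations

Replayed trajectories are straight (sessions) or policy-driven walks
(benchmarks), not sampled from any prioritization scheme; memories never
decay and have no capacity limit; the Hopfield/attractor implementation of
conjunctive memory is intentionally abstracted to a key-value store; wall
handling in the per-visit benchmark is restricted to reward-only worlds;
and the pipeline's empirical-scale statistics (tens of thousands of spikes
across animals) are out of reach of desk-scale synthetic sessions — the
package demonstrates sign and ordering effects at simulated n.
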