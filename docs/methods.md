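# Methods

## Task and environment

A square grid world contains a learning **Subordinate**, a static
**Dominant** and one food item.  Both agents see a 180° field of view
with unlimited range and no obstacles, so an agent's visual field is
the closed half-plane in front of its heading (the perpendicular line
through its own cell is included, as is the cell itself; the boundary
convention makes the egocentric frame geometry exact — the agent's own
row is part of its visual field).  The coordinate convention is
0-based `(row, col)` with the origin top-left; North decreases the row
index, East increases the column index.

Rewards: −0.1 per time step, +1000 for eating food the Dominant does
not see, −1000 for eating food it sees.  The per-step cost also applies
on the eating step, so terminal rewards are +999.9 / −1000.1; episodes
are cut off after `max_steps = 100`.  The Dominant never moves —
nothing in the task defines a Dominant policy and the visibility-based
reward needs a fixed point of view — so the visibility label is fixed
at spawn.  Blocked moves (off-grid or onto the Dominant's cell) leave
the position unchanged but still rotate the agent: movement and heading
stay coupled ("the agent always looks where it heads") even when the
body cannot follow.

### Scenario generator (the synthetic-data source)

All inputs are generated by the environment itself.  The main scenario
spawns the Subordinate anywhere in the leftmost column facing East, and
the Dominant and the food anywhere inside a shared 5×5 area with no
overlaps.  The area is centred on the grid (rows/cols 3–7 on 11×11,
4–8 on 13×13); the exact placement is not specified by the protocol,
so it is configurable through `ScenarioSpec`.  The grid is 11×11 for
egocentric-vision runs and 13×13 for allocentric-vision runs, sizes
chosen so the two networks have approximately equal parameter counts
(they agree within ~9%; both counts are asserted and reported in the
test suite rather than forced equal, since a single convolution over
different input sizes cannot match exactly).

Enumeration is lexicographic over food cell × Dominant cell (≠ food)
× 4 Dominant orientations × Subordinate cell, skipping any pairwise
overlap.  This yields 26,400 initial configurations on the egocentric
grid — matching the published dataset size — and 31,200 on the
allocentric grid.  The published allocentric count of 32,100 does not
follow from the stated spawn rules (25 × 24 × 4 × 13 = 31,200); the
extra 900 configurations are unexplained, so the enumerator follows the
stated rules and this discrepancy is documented rather than
reverse-engineered.  Because the Subordinate starts in the leftmost
column facing East, every enumerated configuration has the food inside
its initial field of view.

### Optimal-reward oracle

For an initial state the best achievable return is `max_steps ×
step_cost` when the food is observed (never eat), and `eat_reward + d ×
step_cost` otherwise, where `d` is the shortest-path length to the food
treating the Dominant as the single obstacle: the Manhattan distance,
plus 2 exactly when the Dominant sits strictly between the agent and
the food on a shared row or column (then every monotone path is blocked
and a one-cell sidestep is needed).  Both action frames reach any
neighbouring cell in one step, so the oracle is frame-independent; it
is verified against exhaustive breadth-first search over action
sequences in both frames.

## Observation encodings

**Allocentric** (fixed top-down camera): four n×n binary maps —
Dominant, Subordinate, food, observability (the Subordinate's visual
field) — plus a length-4 orientation one-hot per agent in (North,
South, East, West) order.  Dominant and food appear in their maps only
when inside the Subordinate's field of view.

**Egocentric**: the world is rotated so the Subordinate faces frame-up
and anchored at the bottom centre, cell (n−1, n−1), of an n×(2n−1)
frame; three maps (Dominant, food, observability — no self map, the
agent is always at its own origin) plus the Dominant's orientation
*relative* to the Subordinate's heading in (toward, same, left, right)
order.  "Toward" is defined by heading opposition (the Dominant faces
the reverse of the Subordinate's heading), a direction relation rather
than a pointing relation, matching the categorical structure of the
other three classes.

When the Dominant is outside the field of view, its position map *and*
its orientation one-hot are all zero in both frames: the information is
genuinely absent and anything the policy knows about it must come from
the LSTM's memory.  (In the allocentric frame the protocol explicitly
notes the Dominant-orientation input can change when visibility
changes, which entails masking.)

Actions: allocentric {North, South, East, West, no-move}; egocentric
{forward, backward, right, left, no-move}.  Every move displaces one
cell and sets the heading to the direction of travel (backward turns
the agent around); no-move preserves the heading in both frames.

## Network and learning rule

One 3×3 valid convolution with 6 filters (stride 1, no padding — the
minimal reading of "1 convolutional layer, 6 filters, kernel 3"),
ReLU; flattened and concatenated with the orientation vectors; two
32-unit ReLU layers; a 128-cell LSTM (zero state at episode start); a
shared 32-unit ReLU layer (FC_3) feeding both heads — a scalar state
value V and 5 advantages A — combined as

    Q(s, a) = V(s) + (A(s, a) − max_a′ A(s, a′)),

the max-subtraction form exactly as printed (not the more common
mean-subtraction variant), which makes max_a Q = V an exact identity.
FC_3 is placed once, after the LSTM, shared by both heads; the
published layer list for probing (…, LSTM, FC_3, output) names a single
FC_3, and a shared layer is the minimal architecture consistent with
it.  Hidden activations are ReLU throughout (the protocol does not
state them; ReLU is the convention in this model family).  Weights are
Glorot-uniform with a recorded seed, the recurrent kernel orthogonal,
the forget-gate bias 1 — the standard recurrent defaults.

Training: ε-greedy behavior (ε annealed linearly from 1.0 to 0.1 over
the first 75% of environment steps, constant after; argmax ties break
to the lowest action index for determinism); whole padded episodes
(length 100, zero-padded, masked) in a 1000-trajectory FIFO replay
buffer; batches of 16 trajectories unrolled from zero hidden state;
per-valid-step TD(0) targets `y_t = r_t` at termination else
`r_t + γ max_a Q(s_{t+1}, a; θ⁻)`; mean squared error over valid steps
(padded steps contribute exactly zero); Adam at 0.001 with the global
gradient norm clipped at 2; soft target update θ⁻ ← τθ + (1−τ)θ⁻ after
every gradient step.

Choices the protocol leaves open, fixed here and configurable in
`TrainConfig`: discount γ = 0.99 (conventional for 100-step episodes);
τ = 0.001 applied every gradient step (the standard small-τ reading of
"periodically τ-averaged"); one gradient update per completed episode
once the buffer holds a full batch (cadence unstated; per-episode
updates keep full-trajectory recurrent batches tractable); single
(non-double) Q-learning targets — only what is printed is implemented.
"Trained for 20 million steps" is read as environment steps; the log
counts both environment and gradient steps.  Evaluation rollouts use
ε = 0 and a fresh hidden state per episode.

## Supervised visibility baseline

The same architecture minus the LSTM, with a single sigmoid output and
binary cross-entropy (a two-class softmax is equivalent; one head had
to be fixed), trained with Adam 0.001, batch 64, on all enumerated
initial configurations with an 80/20 seeded split; accuracy curves are
averaged over 20 weight initializations (decision threshold 0.5).

## Evaluation and probing

*Behavioral*: greedy rollouts from every enumerated configuration;
a trial is "should eat" iff the Dominant does not see the food; correct
approach = food obtained within 100 steps, correct avoid = food never
obtained.  Counts are integers, so percentages re-sum exactly.

*Reward curves*: mean episode reward per consecutive 100-episode bin,
next to the mean best-achievable reward of the same episodes.

*Probing*: linear discriminant analysis decoding the visibility bit
from each layer's activations — input (flattened raw observation),
flatten (post-convolution), merge (with orientations), FC_1, FC_2,
LSTM, FC_3, output (the Q-values) — at the first time step with a zero
hidden state (the label is a property of the initial configuration),
on an 80/20 seeded split shared across layers.  When the within-class
covariance is singular (binary inputs make this likely at the input
layer) the discriminant falls back to a shrinkage-regularized solver
with a logged warning.

## Numerical implementation

The networks are implemented directly on NumPy in float32: im2col
convolution, dense layers, and an LSTM whose sequence unroll and
backpropagation-through-time run as numba-compiled kernels with
length-packed batches (finished episodes drop out of the active batch).
Every backward pass is verified against central finite differences in
float64 in the test suite.  Adam uses ε = 1e−7.  The single-step
inference path and the compiled sequence path agree to float32
rounding (~1e−6 relative); tests compare them at 1e−4.

## Scales used in tests and the acceptance script

Desk-scale choices, stated here as the package's own study sizes:

* The acceptance script runs the supervised comparison at full dataset
  scale (31,200 / 26,400 samples) with the full 20 initializations.
  The in-suite supervised test uses 5 initializations per frame;
  across-initialization means are stable well below the tolerances
  asserted.
* The RL comparison runs on a 7×7 grid with a centred 3×3 spawn area
  and 2×10⁵ environment steps, one seed per condition.  This budget is
  two orders of magnitude below the full protocol (2×10⁷ steps, seven
  seeds) and sits mid-learning: the ego-ego agent's reward curve is
  still rising at cutoff, and with a single seed the *reward* ordering
  between ego-ego and ego-allo is seed-dependent — ego-allo can
  transiently out-earn ego-ego by settling into the trivial never-eat
  policy (≈ −10 per episode) while ego-ego is still paying for
  exploratory mistakes.  The *behavioral* ordering (ego-ego's
  correct-approach rate far above ego-allo's, which stays near zero)
  is the robust desk-scale signal.
* Probe sanity checks use constructed separable/shuffled activations
  plus a briefly trained 5×5 checkpoint.

## What the synthetic scenarios do and do not show

The generator reproduces the study's spawn distributions exactly, so
environment-level results (enumeration counts, visibility labels,
optimal rewards) are the real quantities, not approximations.  The
learning results at desk scale show learnability and ordering of
conditions on a smaller world; they do not calibrate absolute
full-scale scores.  One published quantity did not reproduce at any
scale: the egocentric supervised classifier reaches ~99.9% validation
accuracy by epoch 20 on every initialization tried here, rather than
the reported ~83% mean.  The curve shape matches (a long stay at the
58.3% majority-class plateau before a sharp rise) and the reported mean
is consistent with a fraction of runs remaining on that plateau through
epoch 20 under unstated training details (activation functions,
initializer, optimizer internals of the original Keras setup); this
implementation's honest value is reported as computed.

## Known limitations

* No obstacles, limited vision range, >2 agents, or Dominant policies;
  the Dominant is strictly static.
* Full-scale (2×10⁷-step) training runs are supported but take far
  longer than a desk session; the published full-scale behavioral
  percentages are not asserted anywhere.
* The dueling network uses exactly the printed max-subtraction
  aggregation and single Q-learning targets; no double-Q, prioritized
  replay or n-step variants.
* In the allocentric frame a pure rotation without translation cannot
  occur (moves and rotations are coupled), so the "orientation bits
  change on rotation" behavior is only observable jointly with a move.
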