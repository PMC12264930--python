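# Methods

## The search problem

Retrosynthetic planning is cast as tree search over *states*: an ordered
collection of open molecules plus a depth counter (number of retro steps
taken from the target). An expansion model proposes scored single-step
disconnections ("actions") for the first open molecule not in stock; applying
an action replaces that molecule by its precursors and increments the depth
by one. A state is solved when every open molecule is a purchasable building
block. The engine treats molecule identifiers as opaque strings, so the same
machinery runs against real template-based models or the synthetic generator.

The search tree is a tree, not a graph: identical states reached by
different paths are distinct nodes. This matches the four-phase MCTS
formulation, keeps every node's statistics attributable to exactly one
path, and makes the conservation law below exactly testable. The cost is
some duplicated work on problems with many transpositions.

## The MCTS loop and its bookkeeping

Each iteration descends from the root by repeatedly taking the
highest-scoring child (selection) until it reaches an unexpanded or terminal
node. An unexpanded node is expanded: the expansion model is queried, the
top-B actions by prior are kept (stable sort, proposal order breaks ties;
B is the branching-factor cap), one child is created per kept action, and
*every* new child is simulated for a reward in [0, 1] which is
backpropagated from the child to the root. A terminal node (solved, at the
depth limit, or without actions) has its end-state reward credited again
along the selected path — a cheap iteration that reinforces or discourages
that line.

Two simulation modes exist:

* `value_prior` (default): the child's reward is its action prior. This
  mirrors engines whose value network scores nodes regardless of visit
  counts, which is the regime the selection enhancements were actually
  measured in.
* `rollout_each_child`: textbook random rollout — actions sampled in
  proportion to prior (or uniformly) until a terminal state; the reward is
  the end state's fraction-in-stock. This mode exists chiefly to exercise
  the 0.5^(d−n) success-probability law on the binary test problem.

The end-state evaluation is the fraction of open molecules in stock (1.0
for a solved state). It is a deliberate, simple choice: it is monotone in
progress toward solution and bounded in [0, 1]; nothing in the engine
depends on its exact shape.

**Conservation.** The package maintains an exact invariant: for every
expanded node, `n == sum(child.n)` and `W == sum(child.W)` (W to 1e-9), and
the root's visit count equals the engine's net reward-event count. A node's
creation-time reward (its "virtual first visit", which guarantees n ≥ 1
before any selection and keeps the UCT equations division-safe) is treated
as *provisional*: when the node is later expanded, that single prior-based
event is retracted from the node and its ancestors and replaced by its
children's simulation events. Internal-node statistics are therefore always
pure sums of frontier reward events, which is what makes the invariant
brute-force checkable.

**Stopping.** The loop stops at `max_iterations`, when the wall-clock
`time_limit_seconds` is exceeded (checked once per iteration, so timed runs
may overshoot by at most one iteration), or when no expandable node remains.

**Work units.** Besides wall-clock time, the engine counts deterministic
work units: per iteration, the selected path length plus the number of
children created. Benchmark CSV output reports `avg_time` and RCS in these
units, so identical (spec, config, seed) always yield byte-identical output;
wall-clock timing is still recorded per run and drives time limits. Work
units are a faithful proxy because per-iteration cost is dominated by
expansion-model calls and backpropagation, both linear in these quantities.

## Selection policies

With child statistics (W_i, n_i), parent visits n_k and constant C:

* UCT: `W_i/n_i + C·sqrt(ln(n_k)/n_i)`, C defaulting to 2.
* eUCT: C is replaced by `eC = C/(S_n + 1)`, where S_n in [0, 1] is the
  fraction of the iteration budget spent (elapsed/time-limit under pure time
  control). eC falls from C to C/2 across the run, shifting late iterations
  from exploration to exploitation — late exploration of rarely visited
  nodes has little chance of reaching a solved leaf before the budget ends.
* dUCT: the exploration weight is `C·incr·D_curr`, the depth of the node
  whose children are being compared (root = 0). Selection at the root is
  purely exploitative — weak first disconnections are pruned by trusting
  the priors where branching is largest — and increasingly explorative
  near the leaves, where fewer disconnections remain and the success
  probability is higher. dUCT starts from C = 1.5. Two standard variants:
  v1 = (incr 0.7, branching cap 20), v2 = (incr 0.5, branching cap 50).
  The increment must be matched to the expected tree depth; the defaults
  assume solving depths around four to five.

The exploration bonus uses the square-root form `sqrt(ln(n_k)/n_i)`
(the Kocsis–Szepesvári convention); `exploration_form: linear` switches to
the bare ratio for comparison. The dUCT depth convention is configurable
(`parent`, the default, or `child`, which makes root children compare at
depth 1). The eUCT schedule is implemented exactly as eC = C/(S_n+1), so the
full-progress value is C/2; descriptions of the same schedule sometimes
quote C/1.5, which is the value at 50% progress.

## Synthetic problem generator

The generator emulates the structural features the policies are sensitive
to, with no chemistry:

* **Branching profile**: `max(B0 − decay·depth, B_min)` actions per state —
  large and shallow, decaying with depth (defaults 50, 8, 3).
* **Stock curve**: the probability that a newly created solvable molecule is
  already purchasable rises linearly from `p_stock_start = 0.1` at depth 1
  to `p_stock_end = 1.0` at `d_max = 7`; the target itself is never in
  stock. With these defaults the label-guided solving route averages ≈ 4.1
  steps over 200 seeded instances (94% solvable), the four-to-five-step
  regime the depth-scheduled policy is designed for; this one-time
  calibration is asserted by a test.
* **Solvability labels**: every molecule carries a latent solvable/dead
  label embedded in its identifier. A solvable, non-stock molecule promises
  at least one "golden" action whose precursors are all solvable; every
  action of a dead molecule contains at least one dead precursor, and dead
  molecules are never in stock. By induction the labels decide per-chain
  solvability exactly, without materializing the exponential tree.
* **Priors**: an action's true value is its fraction of solvable
  precursors; the emitted prior is `rho·true + (1−rho)·noise` with
  `prior_fidelity` rho (default 0.8 — a good-but-imperfect value network).
  For single-precursor problems with `p_stock_end = 1`, the label-derived
  value is exactly the best achievable end-state reward, so rho = 1 yields
  perfect priors; with multiple precursors per action the global depth
  budget is shared across branches and the label value is an upper-bound
  heuristic rather than an exact optimum.

Everything is lazy and hash-seeded (blake2b over seed, molecule, depth), so
problems are deterministic, platform-independent, and need no up-front
materialization. What the generator does *not* emulate: chemical validity,
correlated actions (real templates overlap), transpositions (the same
precursor reached via different routes is a fresh identifier), and
expansion-model latency that in real systems is dominated by neural-network
inference. Passing tests therefore demonstrate properties of the search
policies on trees of realistic shape, not end-to-end chemistry performance.

A separate `binary_chain_problem(d)` constructs the binary thought
experiment — exactly two equal-prior actions per state, exactly one on the
unique solving path — for which a uniform random rollout from depth n
succeeds with probability exactly 0.5^(d−n).

## Bloom stock filter

Textbook optimal sizing for capacity n at target false-positive rate p:
`m = ceil(−n·ln p/(ln 2)²)` bits and `k = round((m/n)·ln 2)` hash functions
(k ≥ 1); the repository default p = 0.01 gives, at n = 10⁵, m = 958,506 and
k = 7, with analytic design-point rate ≈ 1.0%. Bit positions come from a
single seeded 128-bit blake2b digest split into two 64-bit halves with
double hashing (h1 + i·h2 mod m, h2 forced odd), fixed little-endian — the
same identifier maps to the same bits on every platform. There are no false
negatives by construction; false positives only ever overstate stock
membership (and hence solve metrics). The binary format is
`"RMBL" | version | m | k | hash_seed | n_inserted | raw bits`, all
little-endian fixed width. Identifier canonicalization is the caller's
responsibility; the filter hashes raw strings.

## Benchmark metrics and sustainability scoring

`summarize` reports solve %, total routes, routes per attempted molecule
*and* per solved molecule (both are useful: the former rewards solving more
targets, the latter measures route diversity on solved ones), mean time,
mean iterations, and the rate-correct score `RCS = solved / ΣT_i` over all
records — a speed–accuracy trade-off in which halving total search time
doubles the score.

Sustainability assessment is a pure function of caller-supplied per-step
flags for six pre-experiment CHEM21-derived metrics (solvent, temperature,
stoichiometry, element sustainability, atom economy, safety), each ordinal
1 (sustainable) … 4 (highly hazardous). A reaction's overall flag is the
weighted median under user slider weights (integers 0–10, not all zero):
flags sorted ascending carrying weights, first flag whose cumulative weight
≥ half the total. The inclusive ≥ makes equal weights reproduce the ordinary
lower median. A route's score sums per-metric means across steps; assessment
schemes that only emit flags 1–3 bound it to [6, 18], lower is better. No
condition prediction is performed — deriving the flags is upstream work.

## Route extraction and serialization

Solved leaves are replayed into route trees (product → action → precursor
branches). Routes are deduplicated by their step multiset, sorted by reward
and then discovery order, and truncated to `max_routes`. A solving route's
reward is its end-state reward, i.e. 1.0 by construction. Route JSON nests
molecule and reaction nodes with the target at the top; the route reward
rides on the top-level molecule node so the round trip is lossless.

## Numerical and design notes

* All tie-breaks (selection, exploitation argmax, branching cap) resolve to
  the lowest child / earliest proposal index, so runs are deterministic
  given (problem, config, seed); the only RNG is the rollout sampler, seeded
  from `SearchConfig.seed`.
* W is a running double-precision sum; conservation is asserted to 1e-9.
* Degenerate inputs: a target already in stock returns a single zero-step
  route with zero iterations; an expansion that proposes nothing marks the
  node terminal with its state reward; a fully exhausted tree ends the run
  early.
* `max_depth` defaults to 7: typical solving depth is four to five, and two
  extra levels of headroom cost little because branching decays with depth.
* Known limitations: no transposition merging (duplicate subtrees inflate
  node counts on highly symmetric problems); simulation from *each* new
  child makes one expansion cost B reward events, which is the literal
  four-phase description but is noticeably heavier at B = 50 than engines
  that reward only the expanded path; time-limited runs overshoot by up to
  one iteration.
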