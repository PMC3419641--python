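# Methods

## The stochastic update model

A model consists of `n` variables with finite, totally ordered level sets
`X_i = {0, …, c_i − 1}` (all `c_i ≥ 2`), one total update rule
`f_i : X → X_i` per variable, and one propensity pair
`(p_i↑, p_i↓) ∈ [0,1]²`. Time is discrete. In a step, every coordinate
independently either jumps to its rule image `f_i(x)` or keeps its value:

| relation            | move to `f_i(x)` | stay at `x_i` |
|---------------------|------------------|---------------|
| `x_i < f_i(x)`      | `p_i↑`           | `1 − p_i↑`    |
| `x_i > f_i(x)`      | `p_i↓`           | `1 − p_i↓`    |
| `x_i = f_i(x)`      | —                | `1`           |

The induced Markov chain has an edge `x → y` iff `y_i ∈ {x_i, f_i(x)}` for
all `i`, with weight the product of the coordinate terms; zero-weight edges
are omitted. Separate up/down propensities reflect that activation and
degradation are different biochemical processes even when encoded by the
same rule — the discrete analogue of separate synthesis and decay rate
constants.

Two structural facts are load-bearing and are enforced as tests rather than
assumed: the chain's absorbing states are exactly the fixed points of the
deterministic synchronous map `G = (f_1, …, f_n)` (propensities only rescale
positive weights, never create or destroy the self-loop-only property), and
for strictly positive propensities every synchronous or single-coordinate
asynchronous step of `G` is an edge of the chain.

## Numerical and representation choices

* **Truth tables are canonical.** Expression rules (grammar: integer
  constants, variable names, `+ − *`, comparisons, `min`/`max`, the level
  complement `not(v) = c_v − 1 − v`, and `a if cond else b`) are expanded
  exhaustively at parse time over the variables they reference. All target
  models have at most 48 states, so there is no reason to evaluate
  expressions lazily, and table equality gives a well-defined extensional
  model identity for round-trip tests.
* **Exact zero handling.** Successor enumeration iterates only over the
  `2^k` subsets of coordinates whose image differs from the current value,
  and drops a branch *before* multiplying when its factor is exactly 0
  (propensity 0 or 1). "Omit zero-weight edges" therefore holds bit-exactly,
  not via an epsilon.
* **Probabilities in double precision.** Weights are direct products of at
  most `n` factors; at the enumerated-graph scale (`n ≤ ~20`) no log-space
  accumulation is needed. Normalization `Σ_y w(x→y) = 1` is asserted to
  1e-12, mass conservation of 60-step exact propagation to 1e-9.
* **State indexing.** Distribution vectors and table rows are ordered by the
  lexicographic rank of states with variable 1 most significant; digit
  strings (`"0011"`, leftmost digit = variable 1) are defined whenever all
  cardinalities are ≤ 10.
* **Attractors** are the terminal strongly connected components of the
  positive-weight digraph (networkx condensation) — the recurrent classes of
  the chain. Singletons are fixed points, larger components cycles. DOT
  exports omit self-loops for readability; CSV exports always keep them.
* **Exact distributions** use a scipy sparse row-stochastic matrix and
  repeated vector–matrix products; this is the oracle against which the
  Monte-Carlo sampler is validated (4 standard errors per state at 100,000
  cells, steps 1/5/10).

## Simulation and reproducibility

`sample_step` draws one uniform per movable coordinate in ascending index
order; the induced successor law provably equals the kernel distribution,
which the tests verify empirically. Populations give every cell its own
generator via `SeedSequence(entropy=seed, spawn_key=(stream…, cell_index))`,
a counter-based scheme that makes per-cell streams independent of execution
order; sweeps extend the spawn key with the grid index. A
`(model, init, n_cells, steps, seed)` tuple reproduces a run bit-exactly.

Default problem sizes follow the study designs the bundled models come
from: 60 steps for the damage-response network, 10 steps and the
`{.1, …, .9}` antagonistic CI/CRO grid for the lambda switch, 100 cells for
population figures (larger counts only where a tolerance needs the
precision, e.g. 10,000 cells for outcome fractions).

## The bundled models

**Worked example.** `f1 = x2`, `f2 = x1 AND NOT x2`, propensities
`(.1, .2)` and `(.5, .9)`. The printed transition probabilities do not come
with their rule table; a brute-force search over all 256 Boolean rule pairs
(solving for consistent propensities against the 11 documented
probabilities) confirms this reading is unique — the check is kept as a
test.

**p53–Mdm2.** Variables `P` (p53; 0–2), `Mc`/`Mn` (cytoplasmic/nuclear
Mdm2), `Dam` (DNA damage), in that order. Rules: nuclear Mdm2 represses p53
(`P` climbs one level per step toward 2 when `Mn = 0`, falls toward 0
otherwise); `Mc = [P ≥ 1]`; `Mn = Mc OR (P = 0 AND Dam = 0)` — nuclear Mdm2
is driven by cytoplasmic Mdm2 and has a basal route that both p53 (which
blocks nuclear translocation) and damage suppress; `Dam` has image 0, so
repair happens purely through the damage degradation propensity (default
.05, i.e. a geometric repair time with mean 20 steps; the damping series
raises it to .10/.15/.20). The negative feedback `P → Mc → Mn ⊣ P` makes
single damaged cells oscillate until repair; de-phasing across cells turns
the population mean into a damped oscillation. Structural guarantees: unique
fixed point `0010` (damage absent, basal nuclear Mdm2 on), sole attractor.

**Phage lambda.** Variables `CI` (0–2), `CRO` (0–3), `CII`, `N`, in that
order. Logical images: CI is fully expressed when CRO is absent or CII is
present, else fully repressed; CRO is off under full CI and otherwise rises
to level 3 with autorepression back to 2; `CII = N AND CI < 2 AND CRO < 2`;
`N = CI < 2 AND CRO < 2`. The two multilevel genes move one level per step
toward their image (the unit-step convention of multi-valued logical
modeling); Boolean genes jump. This yields the bistable structure — fixed
point `2000` (lysogeny) and terminal 2-cycle `{0200, 0300}` (lysis) — and,
from the infection state `0000`, exact 10-step outcome splits of 94.7 %
lysogeny under the CI-favouring propensity set and 94.5 % lysis under the
CRO-favouring set.

These two models' update functions are transcriptions of the published
logical models of their systems, reconstructed under the constraints listed
above rather than copied from a machine-readable source. Every load
re-verifies the documented structure (fixed points, the lytic cycle, the
CI/CRO repression facts, monotone damage repair) and raises
`FixtureIntegrityError` instead of silently running a mistranscribed model.

## What the random-model generator does and does not show

`random_model` draws uniformly random truth tables over the full state
space and uniform propensities — maximally unstructured test inputs for the
kernel/analysis invariants (normalization, support correctness, fixed-point
correspondence, graph-vs-brute-force agreement). Random tables lack the
canalization, sparsity of inputs, and feedback architecture of curated
biological models, so property tests on them certify the *mathematics* of
the implementation, not the biological plausibility of any conclusion; the
bundled models cover the latter.

## Known limitations

* Only intrinsic noise is modeled; extrinsic noise (environment,
  temperature) would need propensities that vary between cells or over time.
* No continuous-time semantics and no per-reaction (Gillespie-style)
  embedding; a time step is an abstract update round.
* Full-graph analysis enumerates X and is capped (default 10⁶ states);
  beyond that only simulation is available.
* Propensities are inputs, not fitted quantities: the package provides no
  calibration against data.
* The asynchronous scheme is the fixed-order sequential variant; random-order
  asynchronous dynamics can be emulated but has no dedicated API.
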