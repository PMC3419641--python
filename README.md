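# sdds — stochastic discrete dynamical systems

`sdds` is a simulator and analysis library for multi-valued logical models
of gene regulatory networks with *stochastic function failure*. Each network
node `x_i` (a gene or protein with a small, ordered set of expression levels)
carries a triplet `(f_i, p_i↑, p_i↓)`: a logical update rule and a pair of
propensity probabilities. At each discrete time step every node looks at its
rule's image `f_i(x)`; if the rule calls for an increase the update fires
with probability `p_i↑`, if it calls for a decrease with probability `p_i↓`,
and otherwise the node holds its value. The result is a discrete-time Markov
chain on the finite state space `X = X_1 × … × X_n` whose edge weights are
products of coordinate factors,

```
w(x → y) = ∏_i π_i,x(x_i → y_i),   y_i ∈ {x_i, f_i(x)},
```

so intrinsic noise is modeled at the level of the biological function rather
than by flipping node states at random. The chain has the same fixed points
as the underlying deterministic synchronous map `G = (f_1, …, f_n)`, and it
contains the synchronous and fixed-order asynchronous trajectories of `G`
whenever all propensities are positive — which makes it a drop-in stochastic
refinement of classical logical models.

The package is aimed at systems biologists who want single-cell and
cell-population simulations (cell-to-cell variability, outcome fractions,
damped population averages) from a logical model without kinetic rate
constants. It ships three ready-made models:

* `example_2_1_1` — a two-variable Boolean illustration whose entire
  weighted transition graph (11 edges) can be checked by hand;
* `p53_mdm2` — the four-variable p53–Mdm2 DNA-damage response network
  (p53 ternary; cytoplasmic/nuclear Mdm2 and damage Boolean);
* `phage_lambda` — the four-gene lambda-phage lysis/lysogeny switch
  (CI ternary, CRO four-valued), bistable between the lysogenic fixed
  point `2000` and the lytic 2-cycle `{0200, 0300}`.

## Worked example

```python
>>> import sdds
>>> m = sdds.load_fixture("example_2_1_1")   # f1 = x2, f2 = x1 AND NOT x2
>>> sdds.transition_distribution(m, (0, 1)).successors
{(1, 0): 0.09000000000000001, (1, 1): 0.009999999999999998,
 (0, 0): 0.81, (0, 1): 0.08999999999999998}
```

From state `01` the chain moves to `00` with probability
`(1 − .1)(.9) = .81` — the activation of `x1` fails while the degradation of
`x2` fires — and follows the full deterministic image `10` with probability
`(.1)(.9) = .09`. State `00` is a fixed point (self-loop of weight 1).

Population-level biology comes out of the same kernel. With the
CRO-favouring propensity set, ten thousand infected cells split between the
two developmental outcomes:

```python
>>> lam = sdds.load_fixture("phage_lambda")
>>> from sdds.fixtures import LAMBDA_TABLE3, LAMBDA_LABELS
>>> t = sdds.classify_outcomes(lam.with_propensities(LAMBDA_TABLE3),
...         LAMBDA_LABELS, init=(0,0,0,0), n_cells=10_000, steps=10, seed=1)
>>> t.counts, t.unresolved
({'lysogeny': 354, 'lysis': 9481}, 165)
```

i.e. ~94.8 % lysis vs ~3.5 % lysogeny, with 165 cells not yet settled after
ten steps.

## Command line

```
sdds statespace  --model fixture:example_2_1_1 --out out/   # DOT + edge CSV
sdds fixedpoints --model fixture:phage_lambda
sdds simulate    --model fixture:p53_mdm2 --steps 60 --seed 7 --out out/
sdds population  --model fixture:p53_mdm2 --cells 100 --steps 60 --seed 7 \
                 --set Dam.down=0.10 --out out/
sdds sweep       --model fixture:phage_lambda --cells 1000 --steps 10 \
                 --labels lysogeny=2000 --labels lysis=0200,0300 \
                 --pair CI:CRO --seed 7 --out out/
```

`--model` accepts `fixture:NAME` or a path to a model file (JSON dialect or
flat truth-table TSV; see `docs/methods.md`). `--set VAR.up=0.8` overrides
propensities without editing the model. All randomness flows from `--seed`;
if omitted, a seed is drawn and reported so the run stays reproducible.
Every output file carries a header comment with a configuration hash.

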