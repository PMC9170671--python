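# fcassembly

Optimal assembly of pairwise forced-choice questionnaires under the MUPP-2PL
model.

Forced-choice questionnaires present statements in pairs and ask respondents
which they agree with more — a format that resists acquiescence and
socially desirable responding, at the cost of lower score precision. How the
statements are paired matters: the same item pool can produce questionnaires
whose trait-score reliabilities differ by 0.05-0.10. Pairing `N` items into
`J` blocks admits `N! / (J!(N-2J)! 2!^J)` candidates (~2.92·10⁴⁰ for
`N = 60, J = 30`), so `fcassembly` searches that space with an
estimation-of-distribution genetic algorithm (node-histogram sampling over
permutation genotypes) that maximizes the average posterior marginal
reliability

ρ̄² = (1/D) Σ_d [ 1 − Σ_l ( [I(θ_l) + Φ⁻¹]⁻¹ )_dd · w_l ],

where `I(θ)` is the MUPP-2PL test information matrix, `Φ` the trait
correlation matrix, and the θ_l form a {−2, 0, +2} per-trait quadrature grid
with normalized MVN(0, Φ) weights. The package is aimed at psychometricians
building forced-choice instruments from calibrated single-statement pools,
and at methodologists studying forced-choice assembly. It ships:

- the measurement model: block response probabilities, Fisher/posterior
  information, the reliability objective, exact assembly counts
  (`fcassembly.model`);
- the GA assembler with hard pairing constraints (hetero-dimensional blocks,
  equal blocks per trait pair, homo-/hetero-polar quotas) (`fcassembly.ga`);
- a budget-matched constrained-random baseline (`fcassembly.bruteforce`);
- a full trait-recovery simulation harness: pool/score generation, MUPP-2PL
  response simulation, vectorized MAP scoring, recovery metrics
  (`fcassembly.simulate`);
- CSV/JSON formats and a thin CLI (`assemble`, `bf-baseline`, `evaluate`,
  `simulate-study`, `make-fixtures`).

## Worked example

```python
import numpy as np
from fcassembly import GAConfig, bf_search, generate_item_pool, run_ga

rng = np.random.default_rng(2)
pool = generate_item_pool(D=5, N=60, polarity_mode="positive", rng=rng)

ga = run_ga(pool, np.eye(5), GAConfig(J=30), rng)
bf = bf_search(pool, np.eye(5), GAConfig(J=30),
               budget=ga.n_evaluations, rng=rng)
print(f"GA best reliability:  {ga.best_objective:.4f}")
print(f"BF best reliability:  {bf.best_objective:.4f}")
print(f"BF average candidate: {bf.mean_objective:.4f}")
```

prints

```
GA best reliability:  0.7144
BF best reliability:  0.6896
BF average candidate: 0.6392
```

The GA paired all 60 items into 30 blocks (six per trait, three per trait
pair) and reached a mean posterior marginal reliability of 0.714; the best
of an *equal number* of uniformly sampled feasible questionnaires managed
0.690, and the average random candidate — what assembling by structural
rules alone tends to give — only 0.639. Equivalent shell command:
`fcassembly assemble --pool pool.csv --blocks 30 --seed 2 --out q.csv`.

The `examples/` directory has one narrative script per capability:
assembling a questionnaire, benchmarking against the random baseline,
running a recovery simulation, and computing conditional error curves.

## Layout

```
src/fcassembly/   model.py ga.py bruteforce.py simulate.py io.py cli.py
tests/            unit, property and end-to-end suites
examples/         narrative scripts, one per capability
docs/methods.md   model, algorithm, design choices, limitations
```
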