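# polyconform

Deterministic dynamics of conformist and anticonformist transmission for
**polychotomous** cultural traits — traits with three or more discrete
variants, such as baby names, pottery motifs, or birdsong syllables.

Most classical models of conformity are dichotomous (two variants) and use
a single conformity coefficient. This package implements the general
polychotomous model: each offspring observes `n` role models, sees the
sample configuration `x = (x_1, …, x_m)` of variant counts, and adopts
variant `A_i` with probability

```
P(A_i | x) = x_i/n + D_i(x)/n
```

where the coefficients `D(x)` may vary freely across sample configurations
(conformist for some samples, anticonformist for others) subject to the
admissibility axioms (probability bounds, zero sum, absent variants never
adopted, permutation symmetry). Averaging over the multinomial
distribution of samples gives the exact frequency recursion

```
p_i' = p_i + (1/n) Σ_x D_i(x) · n!/(x_1!…x_m!) · p_1^{x_1} ⋯ p_m^{x_m}
```

iterated on the (m−1)-simplex. The library is aimed at cultural-evolution
theorists who want to explore, test, or extend these dynamics:

* **configurations** — enumeration of role-model sample states and their
  multinomial probabilities;
* **schemes** — conformity-coefficient schemes: the single-coefficient
  `n = 3` scheme, the two-coefficient `n = 4, m = 3` scheme, and the
  general class-I/II/III construction `D_i(x) = g_i(x)·d(x)` with one
  scalar per sample type, plus exact admissibility intervals for `d(x)`
  and full axiom validation;
* **dynamics** — the general enumeration engine (exactly
  permutation-equivariant in floating point), closed forms for the
  special cases, an exact-rational oracle, and trajectory iteration;
* **equilibria** — the symmetric equilibrium catalogue (corners, boundary
  equal splits, central polymorphism), the asymmetric interior equilibria
  at `n = 4, m = 3`, the aggregate conformity statistic α with the central
  stability condition `|1 + m/(m−1)·α| < 1`, corner stability from
  `D_1(n−1,1,0,…)`, finite-difference Jacobians in simplex coordinates,
  and a seeded fixed-point search;
* **longrun** — classification of trajectories as fixed point, exact
  period-k cycle, or nonconvergent; ergodic means; the conformist limit
  prediction (l tied maxima → 1/l each); a Lyapunov-style divergence-rate
  diagnostic for labeling chaos.

See `docs/methods.md` for the model assumptions, numerical design, and
known limitations.

## Worked example

Strong constant anticonformity with `n = 15` role models and `m = 3`
variants: every sample type carries the same coefficient `d(x) = −5.9`,
just above the admissible floor of −6 for a constant coefficient at
`n = 15` (compare −2 at `n = 3` — larger samples admit much stronger
anticonformity).

```python
import numpy as np
from polyconform import ClassificationScheme, iterate

scheme = ClassificationScheme(15, 3, -5.9)
traj = iterate([0.48, 0.501, 0.019], scheme, 10_000)
rep = traj.longrun
print(rep.classification, rep.period)
for pt in rep.cycle_points:
    print(np.round(pt, 3))
```

prints

```
cycle 2
[0.409 0.332 0.259]
[0.259 0.332 0.409]
```

an attracting *exact two-generation cycle*: variants 1 and 3 swap between
≈0.259 and ≈0.409 every generation while variant 2 holds at ≈0.332 — the
anticonformist push overshoots the central polymorphism each generation
instead of settling on it. With `n = 3` this cannot happen: any
anticonformist coefficient drives global convergence to `(1/3, 1/3, 1/3)`.
Analytically, the central polymorphism's stability is governed by the α
statistic:

```python
from polyconform import alpha_statistic, single_coefficient_scheme

stat = alpha_statistic(single_coefficient_scheme(-0.5))
print(stat.alpha, stat.multiplier, stat.verdict)
```

prints

```
-0.1111111111111111 0.8333333333333334 stable
```

i.e. α = 2D/9 = −1/9 and local multiplier `1 + (3/2)α = 5/6 < 1`, so under
anticonformity (`D < 0`) the central polymorphism attracts.

The same runs are available from the shell:

```
polyconform simulate --scheme-kind classification --n 15 --m 3 --d -5.9 \
    --p0 0.48,0.501,0.019 --generations 10000 --summary-json out.json
polyconform stability --scheme-kind n4m3 --D-prime -0.3 --D 0.9
polyconform reproduce-fig 3a --outdir figures/
```

`simulate` accepts a TOML/JSON config file (`--config run.toml`, flags
override), writes trajectories as CSV (17-significant-digit floats, so
rows round-trip bit-faithfully) and summaries as JSON validating the
schema shipped at `src/polyconform/data/summary.schema.json`. `equilibria`
reports every located fixed point with Jacobian eigenvalues and verdicts;
`sweep` grids the `(D′, D)` plane of the `n = 4, m = 3` scheme;
`reproduce-fig {1|2|3a|3b}` re-runs the published scenarios.

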