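# Methods

## Model

A discrete, selectively neutral cultural trait has `m` variants
`A_1, …, A_m` with population frequencies `p = (p_1, …, p_m)` on the
(m−1)-simplex. Each offspring samples `n` adult role models uniformly at
random and observes the sample configuration `x = (x_1, …, x_m)`,
`Σ x_i = n`, which occurs with multinomial probability
`P(x) = n!/(x_1!…x_m!) · Π p_i^{x_i}`. The offspring adopts variant `A_i`
with probability

    P(A_i | x) = x_i/n + D_i(x)/n,

where the conformity coefficient `D_i(x)` measures the deviation from
unbiased copying: positive values are conformist (the variant is adopted
above its sample frequency), negative values anticonformist. Averaging
over samples gives the deterministic one-generation recursion

    p_i' = p_i + (1/n) Σ_x D_i(x) · n!/(x_1!…x_m!) · Π_j p_j^{x_j}.

The model is an exact expectation over the full enumeration of
configurations — an infinite-population recursion, not a Monte-Carlo
simulation. Admissible coefficient schemes satisfy, at every `x`:

* bounds `−x_i < D_i(x) < n − x_i` (probabilities stay in (0, 1));
* zero sum `Σ_i D_i(x) = 0` (probabilities sum to one);
* P(i): `x_i = 0 ⇒ D_i(x) = 0` (absent variants are never adopted);
* P(ii): permutation symmetry — relabeling variants permutes `D(x)`
  identically.

These force `D(x) = 0` at fixation samples `(n, 0, …, 0)` and at all
integer equal-split samples (`(k, k, 0, …)` with `k = n/2`, etc.).

## Scalar-coefficient (classification) schemes

To reduce the many per-variant coefficients to one scalar per unordered
sample type, the counts of each configuration are classified relative to
the within-sample average `n/r` (`r` = number of variants present):
class I (`x_i ∈ {0, n/r, n}`), class II (above average), class III (below
average). A single coefficient `d(x)` is split as `D_i(x) = g_i(x)·d(x)`
with

    g_i = x_i / Σ_{z∈II} z             (class II)
    g_i = −(1/x_i) / Σ_{z∈III} (1/z)   (class III)
    g_i = 0                            (class I),

so the conformist mass `+d(x)` is shared by the over-represented variants
in proportion to their counts and the anticonformist mass `−d(x)` by the
under-represented variants in proportion to their *reciprocal* counts
(rarer variants are pushed harder). Counts at exactly `n/r` sit in class I
with zero weight; when class II is empty every weight vanishes, `d(x)` is
inert, and `d_bounds` reports a sentinel interval. This construction
reproduces the classical special cases exactly: at `n = 3` it is the
single-coefficient scheme (`g(2,1,0) = (1, −1, 0)`, admissible for
`−2 < D < 1`), and at `n = 4, m = 3` the two-coefficient scheme
(`g(3,1,0) = (1, −1, 0)`, `g(2,1,1) = (1, −½, −½)`; `−3 < D′ < 1`,
`−2 < D < 2`).

### Admissibility interval for d(x)

`d_bounds` returns the exact open interval of `d(x)` values that keep all
adoption probabilities in [0, 1]. The lower endpoint is
`−Σ_{z∈II} z`, where the class-II probabilities reach zero; it always
binds before the class-III ceiling constraint (for every `i ∈ III`,
`Σ_{II} z ≤ n − x_i ≤ (n−x_i)·x_i·Σ_{III} z⁻¹`). The upper endpoint is
the *minimum* of two constraints: `Σ_{II} z · (n/max_i x_i − 1)` (the top
class-II probability reaches one) and `min_{i∈III} x_i²·Σ_{III} z⁻¹`
(the smallest class-III probability reaches zero). The second constraint
is often quoted without the first being insufficient — and indeed the two
coincide for every sample type with `n ≤ 4` and whenever class III is a
singleton — but for richer samples it binds: at `n = 6`,
`x = (3, 2, 1, 0)`, the class-II constraint alone would allow `d < 3`
while any `d > 1` drives the count-1 variant's probability negative.
This was caught by a property test drawing random "admissible" conformist
schemes; the implementation uses the exact intersection.
`uniform_d_lower_bound(n, m)` scans all configurations and returns the
tightest lower bound admitting a single constant `d(x) = D` everywhere:
−2 at `n = 3` and −6 at `n = 15` (m = 3), so anticonformity can be far
stronger with larger samples.

Scheme parameters are accepted *at* an interval endpoint but a warning is
emitted when a value comes within 1e−9 of one (some probability is then
numerically 0 or 1); hard violations beyond a 1e−12 float tolerance raise.

## Numerical design of the step

The recursion is evaluated by a precomputed-table engine: per scheme, the
configuration matrix, multinomial coefficients and coefficient vectors are
built once; a step costs O(#configurations · m).

Three floating-point choices make the step *exactly* permutation
equivariant, not merely to rounding error:

* per-configuration monomials `Π p_j^{x_j}` multiply their factors in
  sorted order, so permuting tied entries of `p` gives bit-identical
  values;
* per-variant sums over configurations use `math.fsum` (correctly
  rounded, hence order-invariant);
* class-III reciprocal sums in `g_i` use `fsum`; class-II sums are
  integer-exact.

Consequently variants that start at exactly equal frequencies remain
exactly tied forever, which the conformist limit prediction
(`max_frequency_limit`: `l` tied maxima → `1/l` each) relies on — under
conformity a tie is dynamically unstable, and any ulp-level asymmetry
introduced by the summation order would be amplified to O(1). Tie
detection therefore uses exact float equality, documented in the API;
users who want tolerance-ties should round their inputs first.

Outputs are checked against the simplex each step: negative entries
within −1e−15 (float noise of the exact polynomial) snap to zero; larger
negativity or a unit-sum error beyond 1e−9 raises an internal-consistency
error, since an admissible scheme cannot produce either. An
exact-rational engine (`step_exact`, `fractions.Fraction`) serves as an
oracle for small cases, and closed forms for `n = 3` (any m:
`p_i' = p_i + D p_i (p_i − Σ p_j²)`) and `n = 4, m = 3` cross-check the
general engine to 1e−12.

## Equilibria and stability

Every scheme fixes the symmetric catalogue: `2^m − 1` points with `l`
variants at `1/l` (corners, boundary equal splits, central polymorphism).
The `n = 4, m = 3` scheme adds up to three asymmetric interior equilibria
`((−2D′−3D)/(2D′−3D), 2D′/(2D′−3D), 2D′/(2D′−3D))` and permutations,
valid when all coordinates lie in (0, 1) — which requires `D′` and `D` of
opposite signs — and always unstable.

Analytic verdicts: corners are stable iff `D_1(n−1, 1, 0, …) > 0`; the
central polymorphism is stable iff `|1 + m/(m−1)·α| < 1` with the
aggregate statistic `α = (1/(n·m^{n−1})) Σ_x D_i(x)·C(x)·x_i` (any `i`,
by symmetry). For the single-coefficient scheme `α = 2D/9`, so the
central point is stable exactly when `D < 0`; for the `n = 4, m = 3`
scheme `α = (4D′+3D)/27`, recovering the condition `D′ < −(3/4)D`.

Numerical verdicts come from the eigenvalues of the finite-difference
Jacobian of the map restricted to the simplex: the last coordinate is
eliminated (`p_m = 1 − Σ q_j`), which removes the spurious unit
eigenvalue along the constraint normal. Because the map is a polynomial
on all of R^m, central differences (h = 1e−6) are evaluated on its
polynomial extension even when a perturbation leaves the simplex — this
is exact analytic continuation, avoids one-sided-difference error at
corners and boundaries, and matches the analytic verdicts to ~1e−9.
Eigenvalue moduli within 1e−9 of 1 are reported "marginal", never
silently stable, since all the analytic conditions are strict
inequalities.

`find_fixed_points` runs Powell-hybrid root finding (scipy) on the
residual in simplex coordinates from the symmetric catalogue plus a
triangular lattice (spacing 0.05 for m = 3, 0.1 above), keeps roots on
the simplex with step residual < 1e−10, and deduplicates at 1e−8. The
search is heuristic: it reports what it finds and cannot certify
completeness (relevant for `n ≥ 5`, where additional asymmetric interior
equilibria may exist).

## Long-run classification

A recorded trajectory tail is classified as: `fixed_point` when
consecutive generations differ by < 1e−10 (sup norm) over the last 100
generations; else the smallest period `k ≤ k_max = 64` with
`|p_{t+k} − p_t|_∞ < 1e−9` over the last `10k` generations (`cycle`);
else `nonconvergent`. "Exact cycle" is machine-precision periodicity of
the deterministic map, not rational exactness. Note that weakly
attracting cycles need long runs: the `n = 15, d = −5.9` two-cycle
contracts at only ≈ e^−0.002 per generation and its periodicity residual
falls below 1e−9 only after ~6,000 generations.

The sensitivity diagnostic is a largest-Lyapunov-style estimate: a twin
trajectory displaced by `δ = 1e−9` is renormalized to separation `δ`
every generation, and the mean log growth rate is taken after discarding
a transient (first half by default). The separation is projected onto the
zero-sum tangent space each generation — the unit-sum normal direction is
an artifact of the polynomial extension on which the map is neutral, and
without the projection the estimate spuriously flattens to zero at
absorbing corners. A positive rate on a nonconvergent run is reported as
"chaotic"; this is a numerical label, not a proof (no shadowing or
interval arithmetic is attempted).

Dynamical regimes exercised by the test suite: pure conformity (every
effective `d(x) > 0`) converges globally to the equal split of the
initial maxima for all tested `n ≤ 6, m ≤ 4`; `n = 3` converges globally
for either sign of `D`; strong constant anticonformity at `n = 15, m = 3`
(`d = −5.9`) yields the attracting two-cycle
(0.259, 0.332, 0.409) ↔ (0.409, 0.332, 0.259); per-state anticonformity
at the admissibility floor + 0.1 yields chaotic fluctuation (divergence
rate ≈ +0.42) around an ergodic mean ≈ (0.334, 0.334, 0.332).

## Choices made where the design was open

* **`n = 5, m = 3` coefficient labels.** The four free scalar
  coefficients are keyed directly by unordered sample type: d(4,1,0),
  d(3,2,0), d(3,1,1), d(2,2,1). For the four-coefficient example
  scenario, the value assignment d(4,1,0) = −1.5, d(3,2,0) = 1.9,
  d(3,1,1) = 0.9, d(2,2,1) = −0.5 was selected because, among the
  admissible assignments of those four values to types, it is the one
  that reproduces the described portrait — six interior equilibria with
  two equal coordinates, three of them stable (at ≈(0.545, 0.227, 0.227)
  and permutations) — as verified by the fixed-point search. No numeric
  claims are attached to this scenario, since the label-to-type
  convention remains a package choice.
* **Enumeration order** is lexicographic descending on count tuples, so
  tables and CSV output are deterministic and reproducible.
* **Record policy** for long runs keeps full history up to 10⁵
  generations, otherwise the last 10⁴ plus every 100th.
* **Problem sizes in tests.** Convergence properties are verified on 200
  interior starts at `n = 3` (6,000 generations each) and 20 random
  strictly conformist scalar schemes at `n ≤ 6, m ≤ 4` (5,000
  generations); structural invariants run 500 property-based cases at
  `n ≤ 6, m ≤ 4`. The published 10,000-generation scenarios are run at
  full length (a run takes well under a second with the table engine).

## Known limitations

* Infinite-population determinism only: no drift, no finite-population
  or agent-based sampling noise.
* No selection, no content or demonstrator bias, no group structure, no
  temporal variation in coefficients.
* The fixed-point search and the chaos label are numerical heuristics;
  completeness of the equilibrium list for `n ≥ 5` and true chaoticity
  are not certified.
* Synthetic inputs (Dirichlet(1) starts, random admissible coefficient
  tables) exercise the mathematical model itself; they do not emulate
  any empirical distribution of cultural variants, so passing tests
  validate the dynamics, not fit to data.
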