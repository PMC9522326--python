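"""Conformity-coefficient schemes D(x) over role-model sample configurations.

Given a sample configuration ``x`` of ``n`` role models, an offspring adopts
variant ``A_i`` with probability ``x_i/n + D_i(x)/n``.  The deviation vector
``D(x) = (D_1(x), ..., D_m(x))`` encodes conformist (``D_i > 0``: adopted
above its sample frequency) or anticonformist (``D_i < 0``) bias.  Every
admissible scheme satisfies:

* bounds: ``-x_i < D_i(x) < n - x_i`` so probabilities stay in (0, 1);
* zero sum: ``sum_i D_i(x) = 0`` so the probabilities sum to one;
* P(i): an absent variant is never adopted — ``x_i = 0 => D_i(x) = 0``;
* P(ii): symmetry — permuting the entries of ``x`` permutes ``D(x)``
  identically, so in particular ``x_i = x_j => D_i(x) = D_j(x)``.

Together these force ``D = 0`` at fixation samples ``(n, 0, ..., 0)`` and at
every integer equal-split sample ``(k, k, 0, ...)``, ``(l, l, l, 0, ...)``
with ``k = n/2``, ``l = n/3``, ...

The *classification* construction reduces the many per-variant coefficients
to a single scalar ``d(x)`` per unordered sample type: with ``r`` variants
present, counts above the within-sample average ``n/r`` (class II) share the
conformist mass ``+d(x)`` in proportion to their counts, counts below it
(class III) share the anticonformist mass ``-d(x)`` in proportion to their
*reciprocal* counts, and counts at exactly ``0``, ``n/r`` or ``n`` (class I)
are untouched.  ``D_i(x) = g_i(x) * d(x)`` with the weights ``g`` defined by
:func:`g_weights`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .configurations import (
    SampleConfiguration,
    enumerate_configurations,
)

__all__ = [
    "ConformityScheme",
    "TabularScheme",
    "ClassificationScheme",
    "ClassPartition",
    "SchemeViolation",
    "DBounds",
    "single_coefficient_scheme",
    "two_coefficient_scheme_n4_m3",
    "classify",
    "g_weights",
    "d_bounds",
    "uniform_d_lower_bound",
    "adoption_probabilities",
    "validate_scheme",
]

BOUND_TOL = 1e-12
BOUND_WARN = 1e-9


class SchemeBoundError(ValueError):
    """A conformity coefficient violates its admissibility bound."""


class ConformityScheme:
    """Base class: a map from sample configurations to coefficient vectors.

    Subclasses implement :meth:`coefficients`.  ``n`` is the role-model
    count, ``m`` the number of variants.
    """

    def __init__(self, n: int, m: int, description: str = ""):
        if n < 1 or m < 1:
            raise ValueError(f"n and m must be positive, got n={n}, m={m}")
        self.n = int(n)
        self.m = int(m)
        self.description = description or type(self).__name__

    def coefficients(self, x: SampleConfiguration) -> np.ndarray:
        """The vector D(x) for a configuration of n into m parts."""
        raise NotImplementedError

    def configurations(self) -> list[SampleConfiguration]:
        return enumerate_configurations(self.n, self.m)

    def adoption_probabilities(self, x: SampleConfiguration) -> np.ndarray:
        return adoption_probabilities(x, self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.description} n={self.n} m={self.m}>"


class TabularScheme(ConformityScheme):
    """Scheme defined by an explicit table {configuration -> D(x)}.

    The table may cover only one representative per unordered type; the
    symmetry property P(ii) is then used to fill in all permutations.
    """

    def __init__(
        self,
        n: int,
        m: int,
        table: Mapping[Sequence[int], Sequence[float]],
        description: str = "tabular scheme",
        *,
        complete_by_symmetry: bool = True,
    ):
        super().__init__(n, m, description)
        self._table: dict[tuple[int, ...], np.ndarray] = {}
        for key, vec in table.items():
            key = tuple(int(c) for c in key)
            arr = np.asarray(vec, dtype=float)
            if len(key) != m or arr.shape != (m,):
                raise ValueError(f"table entry {key} has wrong length for m={m}")
            if sum(key) != n:
                raise ValueError(f"table key {key} does not sum to n={n}")
            self._table[key] = arr
        if complete_by_symmetry:
            self._complete_by_symmetry()

    def _complete_by_symmetry(self) -> None:
        from itertools import permutations

        for key in list(self._table):
            vec = self._table[key]
            for perm in permutations(range(self.m)):
                pkey = tuple(key[j] for j in perm)
                pvec = np.array([vec[j] for j in perm])
                if pkey not in self._table:
                    self._table[pkey] = pvec
        for x in self.configurations():
            self._table.setdefault(x.counts, np.zeros(self.m))

    def coefficients(self, x: SampleConfiguration) -> np.ndarray:
        key = tuple(x)
        try:
            return self._table[key]
        except KeyError:
            raise KeyError(f"configuration {key} not covered by {self.description}")


@dataclass(frozen=True)
class ClassPartition:
    """Partition of a sample's variant indices relative to the average n/r.

    ``r`` variants are present, so a present variant occupies ``n/r`` role
    models on average.  Class I holds counts at exactly 0, ``n/r`` or ``n``;
    class II holds counts strictly above the average (but below ``n``);
    class III holds counts strictly between 0 and the average.
    """

    x: tuple[int, ...]
    r: int
    class_I: tuple[int, ...]
    class_II: tuple[int, ...]
    class_III: tuple[int, ...]

    @property
    def sum_II(self) -> int:
        return sum(self.x[i] for i in self.class_II)


def classify(x: SampleConfiguration | Sequence[int]) -> ClassPartition:
    """Assign each variant index of ``x`` to class I, II or III."""
    counts = tuple(int(c) for c in x)
    n = sum(counts)
    if n == 0:
        raise ValueError("cannot classify the empty configuration")
    r = sum(1 for c in counts if c > 0)
    avg = n / r
    I: list[int] = []
    II: list[int] = []
    III: list[int] = []
    for i, c in enumerate(counts):
        if c == 0 or c == n or c == avg:
            I.append(i)
        elif c > avg:
            II.append(i)
        else:
            III.append(i)
    return ClassPartition(counts, r, tuple(I), tuple(II), tuple(III))


def g_weights(x: SampleConfiguration | Sequence[int]) -> np.ndarray:
    """Per-variant split weights g_i(x) of the scalar coefficient d(x).

    Class II splits the conformist unit mass in proportion to counts
    (``g_i = x_i / sum_{z in II} z``); class III splits the anticonformist
    unit mass in proportion to reciprocal counts
    (``g_i = -(1/x_i) / sum_{z in III} (1/z)``); class I gets 0.  When both
    II and III are nonempty the weights sum to +1 over II and -1 over III,
    so ``sum_i g_i = 0``.
    """
    part = classify(x)
    counts = part.x
    g = np.zeros(len(counts))
    if part.class_II:
        sum_II = float(part.sum_II)  # integer sum: exact
        for i in part.class_II:
            g[i] = counts[i] / sum_II
        # fsum: correctly rounded => invariant under permutations of x
        inv_sum = math.fsum(1.0 / counts[i] for i in part.class_III)
        for i in part.class_III:
            g[i] = -(1.0 / counts[i]) / inv_sum
    return g


@dataclass(frozen=True)
class DBounds:
    """Open admissibility interval for the scalar coefficient d(x).

    ``inert`` marks configurations whose class II is empty: every weight
    g_i is zero there, d(x) has no effect, and the interval is the whole
    real line.
    """

    lower: float
    upper: float
    inert: bool = False

    def contains(self, d: float, tol: float = BOUND_TOL) -> bool:
        if self.inert:
            return True
        return self.lower - tol < d < self.upper + tol


def d_bounds(x: SampleConfiguration | Sequence[int]) -> DBounds:
    """Admissible open interval for d(x) keeping all probabilities in [0, 1].

    Lower endpoint ``-sum_{z in II} z`` — the class-II probabilities reach 0
    there, and it always binds before the class-III ceiling constraint.
    Upper endpoint: the smaller of ``sum_{z in II} z * (n / max_i x_i - 1)``
    (the top class-II probability reaches 1) and
    ``min_{i in III} x_i^2 * sum_{z in III} 1/z`` (the smallest class-III
    probability reaches 0).  The two coincide for every sample type with
    n <= 4 and whenever class III has a single member; for richer samples
    (e.g. (3, 2, 1, 0) at n = 6) the class-III constraint is tighter.
    """
    part = classify(x)
    if not part.class_II:
        return DBounds(float("-inf"), float("inf"), inert=True)
    n = sum(part.x)
    s = part.sum_II
    xmax = max(part.x)
    upper = (s * n) / xmax - s
    inv_sum = math.fsum(1.0 / part.x[i] for i in part.class_III)
    for i in part.class_III:
        upper = min(upper, part.x[i] ** 2 * inv_sum)
    return DBounds(float(-s), upper)


def uniform_d_lower_bound(n: int, m: int) -> float:
    """Tightest lower bound for a single constant coefficient d(x) = D.

    The maximum (least negative) of the per-configuration lower bounds over
    all configurations with nonempty class II: any constant D above this is
    admissible at every sample configuration.
    """
    if n < 2 or m < 2:
        raise ValueError(f"need n >= 2 and m >= 2, got n={n}, m={m}")
    best = float("-inf")
    for x in enumerate_configurations(n, m):
        b = d_bounds(x)
        if not b.inert:
            best = max(best, b.lower)
    return best


class ClassificationScheme(ConformityScheme):
    """Scheme built from a scalar coefficient d(x) per unordered sample type.

    ``d`` may be a constant, a mapping keyed by sorted-descending count
    tuples, or a callable on configurations (which must be permutation
    invariant).  Coefficients are ``D_i(x) = g_i(x) * d(x)``.
    """

    def __init__(
        self,
        n: int,
        m: int,
        d: float | Mapping[tuple[int, ...], float] | Callable[[SampleConfiguration], float],
        description: str = "classification scheme",
        *,
        check_bounds: bool = True,
    ):
        super().__init__(n, m, description)
        self._d = d
        self._coeff_cache: dict[tuple[int, ...], np.ndarray] = {}
        if check_bounds:
            self._check_admissibility()

    def d_value(self, x: SampleConfiguration | Sequence[int]) -> float:
        x = x if isinstance(x, SampleConfiguration) else SampleConfiguration(x)
        if callable(self._d):
            return float(self._d(x))
        if isinstance(self._d, Mapping):
            key = x.sorted_type()
            try:
                return float(self._d[key])
            except KeyError:
                raise KeyError(
                    f"no d(x) entry for sample type {key} in {self.description}"
                )
        return float(self._d)

    def _check_admissibility(self) -> None:
        for x in self.configurations():
            b = d_bounds(x)
            if b.inert:
                continue
            d = self.d_value(x)
            if not (b.lower - BOUND_TOL < d < b.upper + BOUND_TOL):
                raise SchemeBoundError(
                    f"d({tuple(x)}) = {d} outside admissible interval "
                    f"({b.lower}, {b.upper})"
                )
            if d - b.lower <= BOUND_WARN or b.upper - d <= BOUND_WARN:
                warnings.warn(
                    f"d({tuple(x)}) = {d} is at or within {BOUND_WARN} of an "
                    f"endpoint of its open admissibility interval "
                    f"({b.lower}, {b.upper}); some adoption probability is "
                    "numerically 0 or 1",
                    stacklevel=3,
                )

    def coefficients(self, x: SampleConfiguration) -> np.ndarray:
        key = tuple(x)
        cached = self._coeff_cache.get(key)
        if cached is None:
            cached = g_weights(key) * self.d_value(key)
            self._coeff_cache[key] = cached
        return cached


def single_coefficient_scheme(D: float, m: int = 3, n: int = 3) -> ConformityScheme:
    """The n = 3 scheme governed by one conformity coefficient D.

    With three role models the only sample types are fixation
    ``(3, 0, ..., 0)``, the unanimous minority ``(1, 1, 1, 0, ...)`` — both
    forced to zero coefficients — and ``(2, 1, 0, ...)`` where the majority
    variant gets ``+D`` and the minority ``-D``.  Admissible for
    ``-2 < D < 1``; ``D > 0`` is conformist, ``D < 0`` anticonformist.
    """
    if n != 3:
        raise ValueError("the single-coefficient scheme is defined for n = 3")
    if m < 2:
        raise ValueError("need at least two variants")
    if not (-2.0 - BOUND_TOL < D < 1.0 + BOUND_TOL):
        raise SchemeBoundError(f"D = {D} outside the admissible interval (-2, 1)")
    return ClassificationScheme(
        3, m, float(D), description=f"single-coefficient (D={D:g})"
    )


def two_coefficient_scheme_n4_m3(D_prime: float, D: float) -> ConformityScheme:
    """The n = 4, m = 3 scheme with two free coefficients.

    Sample type ``(3, 1, 0)`` carries coefficient D' (majority ``+D'``,
    minority ``-D'``); type ``(2, 1, 1)`` carries D (majority ``+D``, the
    two tied minorities ``-D/2`` each, forced by symmetry and the zero
    sum).  Types ``(4, 0, 0)`` and the equal split ``(2, 2, 0)`` are forced
    to zero.  Admissible for ``-3 < D' < 1`` and ``-2 < D < 2``.
    """
    if not (-3.0 - BOUND_TOL < D_prime < 1.0 + BOUND_TOL):
        raise SchemeBoundError(f"D' = {D_prime} outside the admissible interval (-3, 1)")
    if not (-2.0 - BOUND_TOL < D < 2.0 + BOUND_TOL):
        raise SchemeBoundError(f"D = {D} outside the admissible interval (-2, 2)")
    d_map = {
        (4, 0, 0): 0.0,
        (2, 2, 0): 0.0,
        (3, 1, 0): float(D_prime),
        (2, 1, 1): float(D),
    }
    return ClassificationScheme(
        4, 3, d_map,
        description=f"two-coefficient n=4 (D'={D_prime:g}, D={D:g})",
    )


def adoption_probabilities(
    x: SampleConfiguration | Sequence[int], scheme: ConformityScheme
) -> np.ndarray:
    """Offspring adoption probabilities (x_i/n + D_i(x)/n) for each variant.

    Raises :class:`SchemeBoundError` if the scheme's coefficients push any
    probability outside [0, 1] (beyond a 1e-12 float tolerance).
    """
    x = x if isinstance(x, SampleConfiguration) else SampleConfiguration(x)
    if x.n != scheme.n or x.m != scheme.m:
        raise ValueError(
            f"configuration {tuple(x)} does not match scheme (n={scheme.n}, m={scheme.m})"
        )
    D = scheme.coefficients(x)
    counts = np.array(x.counts, dtype=float)
    for i, (xi, Di) in enumerate(zip(x.counts, D)):
        if not (-xi - BOUND_TOL < Di < scheme.n - xi + BOUND_TOL):
            raise SchemeBoundError(
                f"D_{i + 1}({tuple(x)}) = {Di} outside (-{xi}, {scheme.n - xi})"
            )
    probs = (counts + D) / scheme.n
    return np.clip(probs, 0.0, 1.0)


@dataclass
class SchemeViolation:
    """One violated scheme axiom at one configuration."""

    kind: str  # bounds | zero_sum | absent_variant | symmetry | forced_zero
    x: tuple[int, ...]
    detail: str


@dataclass
class ValidationReport:
    violations: list[SchemeViolation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "<valid scheme>"
        lines = [f"{v.kind} at x={v.x}: {v.detail}" for v in self.violations]
        return "<invalid scheme:\n  " + "\n  ".join(lines) + ">"


def validate_scheme(scheme: ConformityScheme, *, tol: float = 1e-9) -> ValidationReport:
    """Check every configuration against the scheme axioms.

    Verifies the open bounds, the zero sum, property P(i) (absent variants
    keep zero coefficients), property P(ii) (full permutation equivariance,
    tested over all permutations of each configuration), and the forced
    zeros at fixation and integer equal-split samples.  Violations are
    collected, not raised.
    """
    from itertools import permutations

    report = ValidationReport()
    n, m = scheme.n, scheme.m
    perms = list(permutations(range(m)))
    for x in scheme.configurations():
        D = np.asarray(scheme.coefficients(x), dtype=float)
        for i, (xi, Di) in enumerate(zip(x.counts, D)):
            if not (-xi - tol < Di < n - xi + tol):
                report.violations.append(
                    SchemeViolation(
                        "bounds", x.counts,
                        f"D_{i + 1} = {Di} outside (-{xi}, {n - xi})",
                    )
                )
        s = math.fsum(D)
        if abs(s) > tol:
            report.violations.append(
                SchemeViolation("zero_sum", x.counts, f"sum(D) = {s}")
            )
        for i, xi in enumerate(x.counts):
            if xi == 0 and D[i] != 0.0:
                report.violations.append(
                    SchemeViolation(
                        "absent_variant", x.counts, f"x_{i + 1}=0 but D_{i + 1}={D[i]}"
                    )
                )
        for perm in perms:
            px = x.permuted(perm)
            pD = np.asarray(scheme.coefficients(px), dtype=float)
            expected = np.array([D[j] for j in perm])
            if not np.allclose(pD, expected, atol=tol, rtol=0.0):
                report.violations.append(
                    SchemeViolation(
                        "symmetry", x.counts,
                        f"D({px.counts}) = {pD.tolist()} != permuted "
                        f"D({x.counts}) = {expected.tolist()}",
                    )
                )
                break
        positive = sorted(c for c in x.counts if c > 0)
        equal_split = len(set(positive)) == 1  # includes fixation (n,0,...,0)
        if equal_split and np.any(D != 0.0):
            report.violations.append(
                SchemeViolation(
                    "forced_zero", x.counts,
                    f"equal-split sample must have D = 0, got {D.tolist()}",
                )
            )
    return report
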