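"""Frequency recursions: one-generation step and trajectory iteration.

The offspring frequency of variant ``A_i`` is the expectation of the
adoption probability over the multinomial distribution of role-model
samples:

    p_i' = p_i + (1/n) * sum_x D_i(x) * C(x) * p_1^{x_1} ... p_m^{x_m}

where ``C(x)`` is the multinomial coefficient.  The sum runs over the full
enumeration of sample configurations — the model is an exact expectation,
not a Monte-Carlo estimate.  Closed forms exist for the single-coefficient
n = 3 scheme and the two-coefficient n = 4, m = 3 scheme and are used as
cross-checks of the general engine.

Numerical notes
---------------
The step is made *exactly* permutation-equivariant: per-configuration
monomials are computed as sorted-factor products and per-variant sums use
``math.fsum`` (correctly rounded, hence order-invariant).  Consequently
variants tied in frequency remain tied bit-for-bit every generation, which
the long-run analysis relies on (ties in the initial maximum determine the
conformist limit exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .configurations import (
    SampleConfiguration,
    as_frequencies,
    multinomial_coefficient,
)
from .schemes import ClassificationScheme, ConformityScheme, classify, SchemeBoundError, d_bounds

__all__ = [
    "step",
    "apply_map",
    "step_exact",
    "step_closed_form_n3",
    "step_closed_form_n4_m3",
    "step_classification",
    "iterate",
    "TrajectoryResult",
    "SimplexDriftError",
]

SIMPLEX_STEP_TOL = 1e-9
NEG_SNAP_TOL = 1e-15


class SimplexDriftError(RuntimeError):
    """The recursion produced a point off the simplex.

    Signals an inadmissible coefficient scheme that slipped through
    validation, never ordinary float noise.
    """


@dataclass
class _SchemeTables:
    """Precomputed enumeration tables for the general engine."""

    X: np.ndarray       # (K, m) integer count matrix
    coeffs: np.ndarray  # (K,) multinomial coefficients
    D: np.ndarray       # (K, m) conformity coefficients
    DC: np.ndarray      # (K, m) D * coeff, the per-term weights


def _tables(scheme: ConformityScheme) -> _SchemeTables:
    cached = getattr(scheme, "_engine_tables", None)
    if cached is not None:
        return cached
    configs = scheme.configurations()
    X = np.array([c.counts for c in configs], dtype=np.int64)
    coeffs = np.array([float(multinomial_coefficient(c)) for c in configs])
    D = np.array([np.asarray(scheme.coefficients(c), dtype=float) for c in configs])
    tables = _SchemeTables(X=X, coeffs=coeffs, D=D, DC=D * coeffs[:, None])
    scheme._engine_tables = tables  # type: ignore[attr-defined]
    return tables


def _monomials(p: np.ndarray, X: np.ndarray) -> np.ndarray:
    """p_1^{x_1} ... p_m^{x_m} per configuration, permutation-stable.

    Factors are sorted before the sequential product so that permuting
    tied entries of p yields bit-identical monomial values.
    """
    F = p[None, :] ** X  # 0.0 ** 0 == 1.0
    F = np.sort(F, axis=1)
    out = F[:, 0].copy()
    for j in range(1, F.shape[1]):
        out *= F[:, j]
    return out


def apply_map(p, scheme: ConformityScheme) -> np.ndarray:
    """Evaluate the polynomial recursion at ``p`` without simplex checks.

    The recursion is a polynomial map of R^m; this evaluates its natural
    extension off the simplex (used for finite-difference Jacobians near
    boundaries).  Use :func:`step` for actual dynamics.
    """
    p = np.asarray(p, dtype=float)
    t = _tables(scheme)
    P = _monomials(p, t.X)
    terms = t.DC * P[:, None]
    incr = np.array([math.fsum(terms[:, i]) for i in range(scheme.m)])
    return p + incr / scheme.n


def step(p, scheme: ConformityScheme) -> np.ndarray:
    """One generation of the recursion at simplex point ``p``.

    Validates the input, snaps float-noise negatives (>= -1e-15) to zero,
    and raises :class:`SimplexDriftError` if the output leaves the simplex
    by more than 1e-9 — which cannot happen for an admissible scheme.
    """
    p = as_frequencies(p, m=scheme.m)
    q = apply_map(p, scheme)
    neg = q < 0.0
    if np.any(neg):
        worst = float(q[neg].min())
        if worst < -NEG_SNAP_TOL:
            raise SimplexDriftError(
                f"negative frequency {worst} after step with {scheme.description}"
            )
        q[neg] = 0.0
    total = math.fsum(q)
    if abs(total - 1.0) > SIMPLEX_STEP_TOL:
        raise SimplexDriftError(
            f"frequencies sum to {total} after step with {scheme.description}"
        )
    return q


def step_exact(p: Sequence, scheme: ConformityScheme) -> list:
    """Exact-rational one-generation step (oracle for small n, m).

    ``p`` entries are converted to :class:`fractions.Fraction` (floats are
    converted exactly).  Coefficients are re-derived in rational arithmetic
    for classification schemes; tabular schemes use exact conversion of
    their float entries.
    """
    pf = [Fraction(v) for v in p]
    if sum(pf) != 1:
        raise ValueError("exact step requires frequencies summing exactly to 1")
    n, m = scheme.n, scheme.m
    incr = [Fraction(0)] * m
    for x in scheme.configurations():
        coeff = multinomial_coefficient(x)
        mono = Fraction(coeff)
        for c, v in zip(x.counts, pf):
            mono *= v**c
        if mono == 0:
            continue
        D = _exact_coefficients(x, scheme)
        for i in range(m):
            incr[i] += D[i] * mono
    return [pf[i] + incr[i] / n for i in range(m)]


def _exact_coefficients(x: SampleConfiguration, scheme: ConformityScheme) -> list:
    if isinstance(scheme, ClassificationScheme):
        d = Fraction(scheme.d_value(x))
        part = classify(x)
        g = [Fraction(0)] * len(x)
        if part.class_II:
            s = sum(part.x[i] for i in part.class_II)
            inv = sum(Fraction(1, part.x[i]) for i in part.class_III)
            for i in part.class_II:
                g[i] = Fraction(part.x[i], s)
            for i in part.class_III:
                g[i] = -Fraction(1, part.x[i]) / inv
        return [gi * d for gi in g]
    return [Fraction(v) for v in scheme.coefficients(x)]


def step_closed_form_n3(p, D: float) -> np.ndarray:
    """Closed form of the n = 3 single-coefficient recursion, any m >= 2.

    ``p_i' = p_i + D p_i (p_i - sum_j p_j^2)``.
    """
    if not (-2.0 < D < 1.0) and D not in (-2.0, 1.0):
        raise SchemeBoundError(f"D = {D} outside the admissible interval (-2, 1)")
    p = as_frequencies(p)
    S = float(p @ p)
    return p + D * p * (p - S)


def step_closed_form_n4_m3(p, D_prime: float, D: float) -> np.ndarray:
    """Closed form of the n = 4, m = 3 two-coefficient recursion.

    For {i, j, k} = {1, 2, 3}:
    ``p_i' = p_i + D' p_i (1 - p_i)(2 p_i - 1)
           + 3 p_i (p_j^2 p_k + p_j p_k^2)(D' - D/2) + 3 D p_i^2 p_j p_k``.
    """
    if not (-3.0 < D_prime < 1.0):
        raise SchemeBoundError(f"D' = {D_prime} outside (-3, 1)")
    if not (-2.0 < D < 2.0):
        raise SchemeBoundError(f"D = {D} outside (-2, 2)")
    p = as_frequencies(p, m=3)
    out = np.empty(3)
    for i in range(3):
        j, k = [a for a in range(3) if a != i]
        pi, pj, pk = p[i], p[j], p[k]
        out[i] = (
            pi
            + D_prime * pi * (1.0 - pi) * (2.0 * pi - 1.0)
            + 3.0 * pi * (pj**2 * pk + pj * pk**2) * (D_prime - 0.5 * D)
            + 3.0 * D * pi**2 * pj * pk
        )
    return out


def step_classification(p, scheme: ClassificationScheme) -> np.ndarray:
    """One step of the scalar-coefficient recursion.

    ``p_i' = p_i + (1/n) sum_x d(x) g_i(x) C(x) p_1^{x_1} ... p_m^{x_m}``
    — identical to :func:`step` with the induced coefficient scheme; this
    entry point re-validates every d(x) against its admissibility interval
    first.
    """
    if not isinstance(scheme, ClassificationScheme):
        raise TypeError("step_classification requires a ClassificationScheme")
    for x in scheme.configurations():
        b = d_bounds(x)
        if not b.contains(scheme.d_value(x)):
            raise SchemeBoundError(
                f"d({tuple(x)}) = {scheme.d_value(x)} outside "
                f"({b.lower}, {b.upper})"
            )
    return step(p, scheme)


@dataclass
class TrajectoryResult:
    """Iterated frequencies with long-run classification.

    ``history`` holds the recorded generations (always a contiguous tail;
    row 0 is generation ``first_recorded``).  ``generations`` is the total
    number of steps applied.
    """

    history: np.ndarray
    generations: int
    scheme_description: str
    first_recorded: int = 0
    longrun: "object | None" = None  # longrun.LongRunReport when classified
    thinned: np.ndarray | None = None  # every 100th generation when tail-recorded
    meta: dict = field(default_factory=dict)

    @property
    def final(self) -> np.ndarray:
        return self.history[-1]

    @property
    def classification(self) -> str | None:
        return None if self.longrun is None else self.longrun.classification


MAX_FULL_HISTORY = 100_000
TAIL_LENGTH = 10_000


def iterate(
    p0,
    scheme: ConformityScheme,
    generations: int,
    record: str = "auto",
    *,
    classify_longrun: bool = True,
    k_max: int = 64,
) -> TrajectoryResult:
    """Apply the recursion ``generations`` times from ``p0``.

    ``record``: ``"all"`` keeps every generation, ``"tail"`` keeps the last
    10,000 plus every 100th, ``"auto"`` picks ``"all"`` up to 100,000
    generations.  The long-run classification (fixed point / period-k cycle
    / nonconvergent) is attached when the recorded tail is long enough.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if record == "auto":
        record = "all" if generations <= MAX_FULL_HISTORY else "tail"
    if record not in ("all", "tail"):
        raise ValueError(f"unknown record policy {record!r}")

    p = as_frequencies(p0, m=scheme.m).copy()
    keep_all = record == "all"
    tail_len = generations + 1 if keep_all else min(TAIL_LENGTH, generations + 1)
    history = np.empty((generations + 1, scheme.m)) if keep_all else None
    tail: list[np.ndarray] = []
    thinned: list[np.ndarray] = []
    if keep_all:
        history[0] = p
    else:
        tail.append(p.copy())
        thinned.append(p.copy())

    for t in range(1, generations + 1):
        try:
            p = step(p, scheme)
        except SimplexDriftError as err:
            raise SimplexDriftError(f"at generation {t}: {err}") from err
        if keep_all:
            history[t] = p
        else:
            tail.append(p.copy())
            if len(tail) > tail_len:
                tail.pop(0)
            if t % 100 == 0:
                thinned.append(p.copy())

    if keep_all:
        result = TrajectoryResult(
            history=history,
            generations=generations,
            scheme_description=scheme.description,
            first_recorded=0,
        )
    else:
        result = TrajectoryResult(
            history=np.array(tail),
            generations=generations,
            scheme_description=scheme.description,
            first_recorded=generations - (len(tail) - 1),
            thinned=np.array(thinned),
        )

    if classify_longrun and result.history.shape[0] >= 10 * 2:
        from . import longrun as _longrun

        try:
            result.longrun = _longrun.classify_longrun(result, k_max=k_max)
        except ValueError:
            result.longrun = None
    return result
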