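"""Equilibria of the transmission recursion and their local stability.

For any admissible symmetric scheme the recursion fixes every *symmetric*
point: corners (one variant fixed), boundary equal splits (l variants at
1/l, the rest absent) and the central polymorphism (1/m, ..., 1/m).  The
two-coefficient n = 4, m = 3 scheme additionally admits up to three
asymmetric interior equilibria

    p* = ((-2D' - 3D)/(2D' - 3D), 2D'/(2D' - 3D), 2D'/(2D' - 3D))

and permutations, valid (all coordinates in (0, 1)) exactly when D' and D
have opposite signs with 0 < D' < -(3/2)D or -(3/2)D < D' < 0; these are
always unstable.

Local stability is assessed two ways and cross-checked:

* analytically — the corners are stable iff ``D_1(n-1, 1, 0, ..., 0) > 0``,
  and the central polymorphism is stable iff ``|1 + m/(m-1) * alpha| < 1``
  with the aggregate conformity statistic
  ``alpha = (1/(n m^{n-1})) sum_x D_i(x) C(x) x_i`` (any i, by symmetry);
* numerically — eigenvalues of the finite-difference Jacobian of the map
  restricted to the simplex (the last coordinate is dropped; the map is a
  polynomial, so central differences remain valid at boundary points via
  polynomial extension).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import optimize

from .configurations import as_frequencies, multinomial_coefficient
from .dynamics import apply_map, step
from .schemes import ConformityScheme, SampleConfiguration

__all__ = [
    "EquilibriumReport",
    "CentralStabilityStatistic",
    "symmetric_equilibria",
    "interior_equilibria_n4_m3",
    "alpha_statistic",
    "corner_stability",
    "jacobian",
    "jacobian_eigenvalues",
    "stability_verdict",
    "find_fixed_points",
    "classify_equilibrium_kind",
    "n4_m3_stability_summary",
    "simplex_lattice",
]

MARGINAL_TOL = 1e-9
FIXED_POINT_RESIDUAL = 1e-10
DEDUPE_TOL = 1e-8


@dataclass
class EquilibriumReport:
    """A fixed point of the recursion with its stability assessment."""

    point: np.ndarray
    kind: str  # corner | boundary_equal_split | central | interior_asymmetric
    eigenvalues: np.ndarray
    verdict: str  # stable | unstable | marginal
    residual: float = 0.0
    analytic_checks: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "point": self.point.tolist(),
            "kind": self.kind,
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "spectral_radius": float(np.abs(self.eigenvalues).max())
            if self.eigenvalues.size
            else 0.0,
            "verdict": self.verdict,
            "residual": self.residual,
            "analytic_checks": self.analytic_checks,
        }


@dataclass(frozen=True)
class CentralStabilityStatistic:
    """Aggregate conformity statistic alpha at the central polymorphism.

    The central point (1/m, ..., 1/m) is locally stable iff
    ``|1 + m/(m-1) * alpha| < 1``.
    """

    alpha: float
    m: int

    @property
    def multiplier(self) -> float:
        """The dominant local multiplier 1 + m/(m-1) * alpha."""
        return 1.0 + self.m / (self.m - 1.0) * self.alpha

    @property
    def verdict(self) -> str:
        mod = abs(self.multiplier)
        if abs(mod - 1.0) <= MARGINAL_TOL:
            return "marginal"
        return "stable" if mod < 1.0 else "unstable"


def symmetric_equilibria(n: int, m: int) -> list[np.ndarray]:
    """All symmetric fixed points: l variants at 1/l, the rest at 0.

    Every nonempty support set of {1, ..., m} gives one point, 2^m - 1 in
    all; each is fixed under any admissible symmetric scheme (n plays no
    role in the catalogue itself).
    """
    if m < 1:
        raise ValueError("need m >= 1")
    points = []
    for l in range(1, m + 1):
        for support in combinations(range(m), l):
            p = np.zeros(m)
            p[list(support)] = 1.0 / l
            points.append(p)
    return points


def interior_equilibria_n4_m3(
    D_prime: float, D: float
) -> list[tuple[np.ndarray, bool]]:
    """The up-to-three asymmetric interior equilibria of the n=4, m=3 scheme.

    Returns ``(point, valid)`` pairs, ``valid`` meaning every coordinate
    lies strictly inside (0, 1).  A vanishing denominator ``2D' - 3D``
    yields an empty list (the equilibria escape to infinity).
    """
    den = 2.0 * D_prime - 3.0 * D
    if den == 0.0:
        return []
    a = (-2.0 * D_prime - 3.0 * D) / den
    b = 2.0 * D_prime / den
    valid = 0.0 < a < 1.0 and 0.0 < b < 1.0
    pts = [
        np.array([a, b, b]),
        np.array([b, a, b]),
        np.array([b, b, a]),
    ]
    return [(p, valid) for p in pts]


def alpha_statistic(scheme: ConformityScheme, *, tol: float = 1e-9) -> CentralStabilityStatistic:
    """Compute alpha by full enumeration over sample configurations.

    ``alpha = (1/(n m^{n-1})) sum_x D_i(x) C(x) x_i`` — the same for every
    ``i`` when the scheme is symmetric; asymmetry (differing per-variant
    values) raises.
    """
    n, m = scheme.n, scheme.m
    sums = np.zeros(m)
    for x in scheme.configurations():
        D = np.asarray(scheme.coefficients(x), dtype=float)
        coeff = multinomial_coefficient(x)
        sums += D * coeff * np.array(x.counts, dtype=float)
    alphas = sums / (n * float(m) ** (n - 1))
    if np.max(alphas) - np.min(alphas) > tol:
        raise ValueError(
            f"scheme is not symmetric: per-variant alpha values {alphas.tolist()}"
        )
    return CentralStabilityStatistic(alpha=float(alphas[0]), m=m)


def corner_stability(scheme: ConformityScheme) -> str:
    """Stability of the m corner equilibria from the near-fixation sample.

    All corners are locally stable iff ``D_1(x) > 0`` at
    ``x = (n-1, 1, 0, ..., 0)`` — a slightly perturbed fixation sample must
    push back toward fixation.
    """
    counts = [scheme.n - 1, 1] + [0] * (scheme.m - 2)
    D1 = float(scheme.coefficients(SampleConfiguration(counts))[0])
    if abs(D1) <= MARGINAL_TOL:
        return "marginal"
    return "stable" if D1 > 0.0 else "unstable"


def _embed(q: np.ndarray) -> np.ndarray:
    """Simplex coordinates (first m-1 frequencies) -> full vector."""
    return np.concatenate([q, [1.0 - q.sum()]])


def jacobian(p, scheme: ConformityScheme, h: float = 1e-6) -> np.ndarray:
    """(m-1) x (m-1) Jacobian of the map in simplex coordinates at ``p``.

    Central finite differences of the polynomial extension of the map; the
    last frequency is eliminated via ``p_m = 1 - sum of the rest``, which
    removes the spurious unit eigenvalue along the constraint direction.
    """
    p = as_frequencies(p, m=scheme.m)
    m = scheme.m
    q0 = p[: m - 1].copy()
    J = np.empty((m - 1, m - 1))
    for j in range(m - 1):
        qp, qm = q0.copy(), q0.copy()
        qp[j] += h
        qm[j] -= h
        fp = apply_map(_embed(qp), scheme)[: m - 1]
        fm = apply_map(_embed(qm), scheme)[: m - 1]
        J[:, j] = (fp - fm) / (2.0 * h)
    return J


def jacobian_eigenvalues(p, scheme: ConformityScheme, h: float = 1e-6) -> np.ndarray:
    return np.linalg.eigvals(jacobian(p, scheme, h=h))


def stability_verdict(eigenvalues: np.ndarray, *, tol: float = MARGINAL_TOL) -> str:
    """stable / unstable / marginal from eigenvalue moduli of the local map."""
    moduli = np.abs(np.asarray(eigenvalues))
    if moduli.size == 0:
        return "marginal"
    if np.any(np.abs(moduli - 1.0) <= tol):
        return "marginal"
    return "stable" if np.all(moduli < 1.0) else "unstable"


def classify_equilibrium_kind(p: np.ndarray, *, tol: float = 1e-6) -> str:
    """corner / boundary_equal_split / central / interior_asymmetric."""
    p = np.asarray(p, dtype=float)
    m = p.shape[0]
    support = p > tol
    l = int(support.sum())
    if l == 1:
        return "corner"
    equal_split = np.allclose(p[support], 1.0 / l, atol=tol)
    if equal_split:
        return "central" if l == m else "boundary_equal_split"
    return "interior_asymmetric"


def simplex_lattice(m: int, spacing: float = 0.05) -> list[np.ndarray]:
    """Triangular lattice of simplex points with the given spacing."""
    k = int(round(1.0 / spacing))
    points = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            points.append(np.array(prefix + [remaining], dtype=float) / k)
            return
        for c in range(remaining + 1):
            rec(prefix + [c], remaining - c, slots - 1)

    rec([], k, m)
    return points


def find_fixed_points(
    scheme: ConformityScheme,
    seeds: list | None = None,
    *,
    dedupe_tol: float = DEDUPE_TOL,
    residual_tol: float = FIXED_POINT_RESIDUAL,
) -> list[EquilibriumReport]:
    """Locate fixed points of the recursion by root finding from seeds.

    Default seeds: the symmetric catalogue plus a triangular lattice
    (spacing 0.05 for m = 3, 0.1 for larger m).  Each converged root is
    kept when it lies on the simplex and has step residual below
    ``residual_tol``; duplicates within ``dedupe_tol`` are merged.  Every
    survivor is reported with its Jacobian eigenvalues and verdict.
    """
    m = scheme.m
    if seeds is None:
        spacing = 0.05 if m <= 3 else 0.1
        seeds = symmetric_equilibria(scheme.n, m) + simplex_lattice(m, spacing)

    def residual(q: np.ndarray) -> np.ndarray:
        return apply_map(_embed(q), scheme)[: m - 1] - q

    found: list[np.ndarray] = []
    for seed in seeds:
        p0 = np.asarray(seed, dtype=float)
        sol = optimize.root(residual, p0[: m - 1], method="hybr", tol=1e-13)
        if not sol.success:
            continue
        q = sol.x
        p = _embed(q)
        if np.any(p < -1e-9) or np.any(p > 1.0 + 1e-9):
            continue
        p = np.clip(p, 0.0, 1.0)
        p /= p.sum()
        res = float(np.abs(step(p, scheme) - p).max())
        if res > residual_tol:
            continue
        if any(np.abs(p - other).max() < dedupe_tol for other in found):
            continue
        found.append(p)

    reports = []
    for p in sorted(found, key=lambda v: tuple(np.round(-v, 12))):
        eigs = jacobian_eigenvalues(p, scheme)
        reports.append(
            EquilibriumReport(
                point=p,
                kind=classify_equilibrium_kind(p),
                eigenvalues=eigs,
                verdict=stability_verdict(eigs),
                residual=float(np.abs(step(p, scheme) - p).max()),
            )
        )
    return reports


def n4_m3_stability_summary(D_prime: float, D: float) -> dict:
    """Analytic stability portrait of the two-coefficient n=4, m=3 scheme.

    The two discriminants ``2D' + 3D`` (existence of the asymmetric
    interior equilibria when D' < 0) and ``4D' + 3D`` (sign of the central
    multiplier gap) determine the regime:

    * corners stable iff D' > 0;
    * boundary equal splits (0, 1/2, 1/2) stable iff -(3/2) D < D' < 0;
    * central point (1/3, 1/3, 1/3) stable iff D' < -(3/4) D;
    * the asymmetric interior equilibria, when valid, are always unstable.
    """
    interior = interior_equilibria_n4_m3(D_prime, D)
    interior_valid = bool(interior) and interior[0][1]
    return {
        "discriminant_2Dp_3D": 2.0 * D_prime + 3.0 * D,
        "discriminant_4Dp_3D": 4.0 * D_prime + 3.0 * D,
        "corners": "stable" if D_prime > 0 else ("marginal" if D_prime == 0 else "unstable"),
        "boundary_equal_split": "stable"
        if (-1.5 * D < D_prime < 0.0)
        else "unstable",
        "central": "stable" if D_prime < -0.75 * D else "unstable",
        "interior_asymmetric_exist": interior_valid,
        "interior_asymmetric": "unstable" if interior_valid else None,
    }
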