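"""Long-run classification of trajectories: convergence, cycles, chaos.

Under purely conformist transmission (every scalar coefficient d(x) > 0)
the recursion converges globally: the l variants that start at the maximum
frequency end at 1/l each and all others are lost.  Anticonformity can
instead sustain exact period-k cycles or aperiodic (chaotic) fluctuation —
for example with n = 15 role models and m = 3 variants, a constant
d(x) = -5.9 produces an exact two-generation cycle, while pushing each
d(x) near its admissibility floor produces chaotic fluctuations around the
central polymorphism.

"Exact cycle" here means machine-precision periodicity of the deterministic
map (sup-norm tolerance 1e-9), and "chaotic" is a numerical diagnostic — a
positive divergence-rate estimate on a nonconvergent run — not a proof.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .configurations import as_frequencies
from .dynamics import TrajectoryResult, apply_map, step
from .schemes import ClassificationScheme, ConformityScheme, d_bounds

__all__ = [
    "LongRunReport",
    "classify_longrun",
    "ergodic_mean",
    "max_frequency_limit",
    "sensitivity_diagnostic",
    "is_strictly_conformist",
]

FIXED_POINT_TOL = 1e-10
CYCLE_TOL = 1e-9


@dataclass
class LongRunReport:
    """Outcome of the asymptotic classification of one trajectory."""

    classification: str  # "fixed_point" | "cycle" | "nonconvergent"
    period: int | None = None
    cycle_points: list[np.ndarray] = field(default_factory=list)
    fixed_point: np.ndarray | None = None
    ergodic_mean: np.ndarray | None = None
    divergence_rate: float | None = None

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "period": self.period,
            "cycle_points": [pt.tolist() for pt in self.cycle_points],
            "fixed_point": None if self.fixed_point is None else self.fixed_point.tolist(),
            "ergodic_mean": None if self.ergodic_mean is None else self.ergodic_mean.tolist(),
            "divergence_rate": self.divergence_rate,
        }


def _tail(traj: TrajectoryResult | np.ndarray) -> np.ndarray:
    if isinstance(traj, TrajectoryResult):
        return traj.history
    return np.asarray(traj, dtype=float)


def classify_longrun(traj: TrajectoryResult | np.ndarray, k_max: int = 64) -> LongRunReport:
    """Classify the asymptotic behaviour of a recorded trajectory tail.

    ``fixed_point`` if consecutive generations differ by less than 1e-10 in
    sup norm over the last 100 generations; otherwise ``cycle(k)`` for the
    smallest period ``2 <= k <= k_max`` with ``|p_{t+k} - p_t|_inf < 1e-9``
    over the last ``10 k`` generations; otherwise ``nonconvergent``.
    """
    hist = _tail(traj)
    T = hist.shape[0]
    if T < 10 * 2:
        raise ValueError(f"trajectory tail of {T} generations is too short to classify")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    span = min(100, T - 1)
    diffs = np.abs(hist[-span:] - hist[-span - 1:-1]).max()
    if diffs < FIXED_POINT_TOL:
        return LongRunReport(
            classification="fixed_point",
            period=1,
            fixed_point=hist[-1].copy(),
            ergodic_mean=hist[-1].copy(),
        )

    for k in range(2, k_max + 1):
        need = 10 * k
        if need + k > T:
            break
        seg = hist[-(need + k):]
        if np.abs(seg[k:] - seg[:-k]).max() < CYCLE_TOL:
            # phases ordered so the last point is the final generation
            points = [hist[T - k + j].copy() for j in range(k)]
            return LongRunReport(
                classification="cycle",
                period=k,
                cycle_points=points,
                ergodic_mean=np.mean(np.array(points), axis=0),
            )

    window = min(T, 5000)
    return LongRunReport(
        classification="nonconvergent",
        ergodic_mean=hist[-window:].mean(axis=0),
    )


def ergodic_mean(traj: TrajectoryResult | np.ndarray, window: int) -> np.ndarray:
    """Componentwise mean frequency over the last ``window`` generations."""
    hist = _tail(traj)
    if window < 1 or window > hist.shape[0]:
        raise ValueError(
            f"window {window} outside the recorded trajectory of {hist.shape[0]} generations"
        )
    return hist[-window:].mean(axis=0)


def is_strictly_conformist(scheme: ConformityScheme) -> bool:
    """True when every non-inert sample configuration has d(x) > 0."""
    if isinstance(scheme, ClassificationScheme):
        for x in scheme.configurations():
            if d_bounds(x).inert:
                continue
            if scheme.d_value(x) <= 0.0:
                return False
        return True
    # generic scheme: conformist iff the above-average variants always gain
    for x in scheme.configurations():
        if d_bounds(x).inert:
            continue
        D = np.asarray(scheme.coefficients(x), dtype=float)
        counts = np.array(x.counts)
        avg = x.n / x.r
        above = (counts > avg) & (counts < x.n)
        if np.any(D[above] <= 0.0):
            return False
    return True


def max_frequency_limit(p0, scheme: ConformityScheme) -> np.ndarray:
    """Predicted conformist limit from the initial maximum-frequency set.

    For strictly conformist schemes the recursion converges globally: if
    ``l`` variants share the initial maximum frequency, they end at ``1/l``
    each and every other variant is lost.  Ties are detected by exact float
    equality (the symmetry of the map preserves exact ties every
    generation).
    """
    if not is_strictly_conformist(scheme):
        raise ValueError(
            "max_frequency_limit applies only to strictly conformist schemes "
            "(every effective d(x) > 0)"
        )
    p = as_frequencies(p0, m=scheme.m)
    pmax = p.max()
    winners = p == pmax
    l = int(winners.sum())
    limit = np.where(winners, 1.0 / l, 0.0)
    return limit


def sensitivity_diagnostic(
    p0,
    scheme: ConformityScheme,
    generations: int = 2000,
    delta: float = 1e-9,
    *,
    discard: int | None = None,
) -> float:
    """Divergence-rate estimate (largest-Lyapunov style) along a trajectory.

    Runs a twin trajectory displaced by ``delta`` (within the simplex) and
    renormalizes the separation every generation; returns the mean log
    growth rate of the separation after discarding a transient (first half
    by default).  Positive rates label a nonconvergent run chaotic;
    negative rates indicate contraction (stable fixed point or cycle).
    """
    if generations < 10:
        raise ValueError("need at least 10 generations for the diagnostic")
    if discard is None:
        discard = generations // 2
    p = as_frequencies(p0, m=scheme.m).copy()
    # tangent-like displacement inside the simplex (zero-sum)
    v = np.zeros(scheme.m)
    v[0], v[-1] = 1.0, -1.0
    v /= np.linalg.norm(v)
    q = p + delta * v

    logs = []
    for t in range(generations):
        p = step(p, scheme)
        q = apply_map(q, scheme)
        sep = q - p
        # keep the perturbation in the simplex tangent space (zero sum);
        # the unit-sum direction is an artifact of the polynomial extension
        sep -= sep.mean()
        dist = float(np.linalg.norm(sep))
        if dist == 0.0:
            # exactly merged: renormalize along the original direction
            sep = delta * v
            dist = delta
            logs.append(-math.inf)
        elif t >= discard:
            logs.append(math.log(dist / delta))
        q = p + sep * (delta / dist)

    finite = [x for x in logs if math.isfinite(x)]
    if not finite:
        return -math.inf
    return float(np.mean(finite))
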