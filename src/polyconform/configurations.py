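"""Role-model sample configurations and their multinomial probabilities.

Each offspring observes ``n`` role models drawn at random from a population
in which a cultural trait has ``m`` discrete variants.  The observed sample
is summarised by a *configuration* ``x = (x_1, ..., x_m)``: the count of
role models carrying each variant.  Configurations are ordered compositions
of ``n`` into ``m`` non-negative parts; there are ``C(m - 1 + n, n)`` of
them.  Under random sampling the probability of observing ``x`` when the
population frequencies are ``p`` is the multinomial mass
``n!/(x_1! ... x_m!) * p_1^{x_1} ... p_m^{x_m}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SampleConfiguration",
    "FrequencyVector",
    "enumerate_configurations",
    "n_configurations",
    "multinomial_coefficient",
    "multinomial_probability",
]

SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class SampleConfiguration:
    """Counts of each variant among the ``n`` sampled role models.

    Immutable and hashable by value so configurations can key lookup
    tables (coefficient maps, probability caches).
    """

    counts: tuple[int, ...]

    def __init__(self, counts: Sequence[int]):
        counts = tuple(int(c) for c in counts)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in configuration {counts}")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        """Number of role models in the sample."""
        return sum(self.counts)

    @property
    def m(self) -> int:
        """Number of variant slots (including absent variants)."""
        return len(self.counts)

    @property
    def r(self) -> int:
        """Number of variants present in the sample (nonzero counts)."""
        return sum(1 for c in self.counts if c > 0)

    def sorted_type(self) -> tuple[int, ...]:
        """Counts sorted descending: the unordered type of this sample."""
        return tuple(sorted(self.counts, reverse=True))

    def permuted(self, perm: Sequence[int]) -> "SampleConfiguration":
        """Configuration with entry ``j`` taken from ``counts[perm[j]]``."""
        return SampleConfiguration(tuple(self.counts[k] for k in perm))

    def __iter__(self) -> Iterator[int]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __getitem__(self, i):
        return self.counts[i]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"x{self.counts}"


class FrequencyVector:
    """Point on the (m-1)-simplex: population frequencies of the m variants.

    Thin wrapper over a read-only float array; validates non-negativity and
    unit sum on construction.  Most numerical routines accept any array-like
    and convert through :func:`as_frequencies`.
    """

    __slots__ = ("freqs",)

    def __init__(self, freqs: Sequence[float], *, tol: float = 1e-9):
        arr = np.asarray(freqs, dtype=float).copy()
        if arr.ndim != 1:
            raise ValueError("frequency vector must be one-dimensional")
        if np.any(arr < -tol):
            raise ValueError(f"negative frequency in {arr!r}")
        np.clip(arr, 0.0, None, out=arr)
        if abs(float(arr.sum()) - 1.0) > tol:
            raise ValueError(f"frequencies sum to {arr.sum()!r}, not 1")
        arr.flags.writeable = False
        self.freqs = arr

    @property
    def m(self) -> int:
        return self.freqs.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.freqs, dtype=dtype)

    def __iter__(self):
        return iter(self.freqs)

    def __len__(self) -> int:
        return self.freqs.shape[0]

    def __getitem__(self, i):
        return self.freqs[i]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"p({', '.join(format(v, '.6g') for v in self.freqs)})"


def as_frequencies(p, m: int | None = None, *, tol: float = 1e-9) -> np.ndarray:
    """Validate ``p`` as a simplex point and return it as a float array."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("frequency vector must be one-dimensional")
    if m is not None and arr.shape[0] != m:
        raise ValueError(f"expected {m} frequencies, got {arr.shape[0]}")
    if np.any(arr < -tol):
        raise ValueError(f"negative frequency in {arr!r}")
    if abs(float(arr.sum()) - 1.0) > tol:
        raise ValueError(f"frequencies sum to {arr.sum()!r}, not 1")
    return arr


def n_configurations(n: int, m: int) -> int:
    """Number of role-model sample configurations: C(m - 1 + n, n)."""
    return math.comb(m - 1 + n, n)


def enumerate_configurations(n: int, m: int) -> list[SampleConfiguration]:
    """All ordered compositions of ``n`` into ``m`` non-negative parts.

    Deterministic lexicographic-descending order on the count tuples, so
    the first configuration is ``(n, 0, ..., 0)`` and the last is
    ``(0, ..., 0, n)``.  The length equals ``C(m - 1 + n, n)``.
    """
    if n < 1 or m < 1:
        raise ValueError(f"n and m must be positive, got n={n}, m={m}")

    out: list[SampleConfiguration] = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            out.append(SampleConfiguration(prefix + [remaining]))
            return
        for c in range(remaining, -1, -1):
            rec(prefix + [c], remaining - c, slots - 1)

    rec([], n, m)
    return out


def multinomial_coefficient(x: SampleConfiguration | Sequence[int]) -> int:
    """Exact integer multinomial coefficient n! / (x_1! ... x_m!)."""
    counts = tuple(x)
    n = sum(counts)
    num = math.factorial(n)
    for c in counts:
        num //= math.factorial(c)
    return num


def multinomial_probability(
    x: SampleConfiguration | Sequence[int],
    p,
    *,
    exact: bool = False,
):
    """Probability of sample configuration ``x`` at population frequencies ``p``.

    ``n!/(x_1!...x_m!) * prod_i p_i^{x_i}`` with the convention ``0**0 = 1``
    (absent variants with zero count contribute a unit factor).

    With ``exact=True`` and rational ``p`` entries, the computation is done
    in :class:`fractions.Fraction` arithmetic and returns a ``Fraction`` —
    used as an oracle in tests and for exact-rational iteration.
    """
    counts = tuple(x)
    if exact:
        pf = [Fraction(v) for v in p]
        if len(pf) != len(counts):
            raise ValueError("configuration and frequency vector differ in length")
        val = Fraction(multinomial_coefficient(counts))
        for c, v in zip(counts, pf):
            val *= v**c
        return val

    arr = as_frequencies(p, m=len(counts))
    prob = float(multinomial_coefficient(counts))
    for c, v in zip(counts, arr):
        prob *= float(v) ** c  # 0.0 ** 0 == 1.0
    return prob
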