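"""Shared fixtures: seeded random schemes and simplex points."""

from __future__ import annotations

import numpy as np
import pytest

from polyconform import ClassificationScheme
from polyconform.configurations import enumerate_configurations
from polyconform.schemes import d_bounds


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220919)


def random_simplex(rng: np.random.Generator, m: int, interior: bool = False) -> np.ndarray:
    p = rng.dirichlet(np.ones(m))
    if interior:
        p = 0.98 * p + 0.02 / m  # bound away from the boundary
        p /= p.sum()
    return p


def random_classification_scheme(
    rng: np.random.Generator,
    n: int,
    m: int,
    *,
    conformist: bool | None = None,
    margin: float = 0.05,
) -> ClassificationScheme:
    """Random admissible scheme: one d(x) per unordered sample type.

    Each d is drawn uniformly within the open admissibility interval,
    shrunk by ``margin`` on both sides.  ``conformist=True`` restricts to
    positive values, ``False`` to negative ones.
    """
    table: dict[tuple[int, ...], float] = {}
    for x in enumerate_configurations(n, m):
        key = tuple(sorted(x.counts, reverse=True))
        if key in table:
            continue
        b = d_bounds(x)
        if b.inert:
            table[key] = 0.0
            continue
        lo, hi = b.lower, b.upper
        if conformist is True:
            lo = 0.0
        elif conformist is False:
            hi = 0.0
        u = rng.uniform(margin, 1.0 - margin)
        table[key] = lo + u * (hi - lo)
    return ClassificationScheme(n, m, table, description=f"random table n={n} m={m}")
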