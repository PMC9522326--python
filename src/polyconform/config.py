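"""Run configuration, scheme specification parsing, and result serialization.

A run is described by a flat key-value config (TOML or JSON) or by CLI
flags.  Scheme specifications come in four kinds:

* ``single`` — the n = 3 single-coefficient scheme; parameter ``D``.
* ``n4m3`` — the two-coefficient n = 4, m = 3 scheme; ``D_prime`` and ``D``.
* ``classification`` — scalar d(x) per unordered sample type; either a
  constant ``d`` or a ``d_table`` keyed by sorted-descending count tuples
  written as comma-joined strings (e.g. ``"4,1,0"``), or the string
  ``"lower_bound_plus"`` with an ``offset`` to place every d(x) relative to
  its admissibility floor.
* ``explicit`` — a full table of coefficient vectors per configuration.

Every output embeds the fully resolved configuration for provenance.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import __version__
from .schemes import (
    ClassificationScheme,
    ConformityScheme,
    TabularScheme,
    d_bounds,
    single_coefficient_scheme,
    two_coefficient_scheme_n4_m3,
)

__all__ = [
    "RunConfig",
    "load_config",
    "scheme_from_spec",
    "random_simplex_point",
    "write_trajectory_csv",
    "write_summary_json",
]


def random_simplex_point(m: int, seed: int | np.random.Generator) -> np.ndarray:
    """Symmetric Dirichlet(1) draw on the (m-1)-simplex, seed-deterministic."""
    if m < 2:
        raise ValueError("need m >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.dirichlet(np.ones(m))


def _type_key(key: str | Sequence[int]) -> tuple[int, ...]:
    if isinstance(key, str):
        parts = key.replace("(", "").replace(")", "").split(",")
        key = [int(s.strip()) for s in parts if s.strip()]
    return tuple(sorted((int(c) for c in key), reverse=True))


def scheme_from_spec(spec: dict[str, Any]) -> ConformityScheme:
    """Build a conformity scheme from a flat specification mapping."""
    kind = spec.get("kind")
    if kind == "single":
        return single_coefficient_scheme(float(spec["D"]), m=int(spec.get("m", 3)))
    if kind == "n4m3":
        return two_coefficient_scheme_n4_m3(float(spec["D_prime"]), float(spec["D"]))
    if kind == "classification":
        n, m = int(spec["n"]), int(spec["m"])
        if "d_table" in spec:
            table = {_type_key(k): float(v) for k, v in spec["d_table"].items()}
            return ClassificationScheme(n, m, table, description=f"classification table n={n} m={m}")
        d = spec.get("d")
        if d == "lower_bound_plus":
            offset = float(spec.get("offset", 0.1))
            return lower_bound_plus_scheme(n, m, offset)
        return ClassificationScheme(
            n, m, float(d), description=f"classification d={float(d):g} n={n} m={m}"
        )
    if kind == "explicit":
        n, m = int(spec["n"]), int(spec["m"])
        table = {
            tuple(int(c) for c in str(k).replace("(", "").replace(")", "").split(",")):
                [float(v) for v in vec]
            for k, vec in spec["table"].items()
        }
        return TabularScheme(n, m, table, description=f"explicit table n={n} m={m}")
    raise ValueError(f"unknown scheme kind {kind!r}")


def lower_bound_plus_scheme(n: int, m: int, offset: float = 0.1) -> ClassificationScheme:
    """Classification scheme with each d(x) at its admissibility floor + offset.

    Strong state-dependent anticonformity: every above-average variant is
    pushed down as hard as the probability constraints allow (up to the
    offset).  Inert configurations (empty class II) get d = 0.
    """
    from .configurations import enumerate_configurations

    table: dict[tuple[int, ...], float] = {}
    for x in enumerate_configurations(n, m):
        key = x.sorted_type()
        if key in table:
            continue
        b = d_bounds(x)
        table[key] = 0.0 if b.inert else b.lower + offset
    return ClassificationScheme(
        n, m, table, description=f"lower-bound+{offset:g} anticonformity n={n} m={m}"
    )


@dataclass
class RunConfig:
    """Fully resolved simulation run: scheme, start, length, outputs."""

    scheme: dict[str, Any]
    generations: int
    p0: list[float] | None = None  # None => Dirichlet(1) draw from seed
    seed: int | None = None
    record: str = "auto"
    trajectory_csv: str | None = None
    summary_json: str | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def build_scheme(self) -> ConformityScheme:
        return scheme_from_spec(self.scheme)

    def initial_point(self, m: int) -> np.ndarray:
        if self.p0 is not None:
            return np.asarray(self.p0, dtype=float)
        if self.seed is None:
            raise ValueError("random p0 requested but no seed given")
        return random_simplex_point(m, self.seed)

    def to_dict(self) -> dict[str, Any]:
        return {
            "scheme": self.scheme,
            "generations": self.generations,
            "p0": self.p0,
            "seed": self.seed,
            "record": self.record,
            "version": __version__,
        }


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML or JSON file (chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(path.read_text())
    elif path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use .toml or .json)")
    known = {"scheme", "generations", "p0", "seed", "record", "trajectory_csv", "summary_json"}
    meta = {k: v for k, v in data.items() if k not in known}
    return RunConfig(
        scheme=dict(data["scheme"]),
        generations=int(data["generations"]),
        p0=list(data["p0"]) if data.get("p0") is not None else None,
        seed=data.get("seed"),
        record=data.get("record", "auto"),
        trajectory_csv=data.get("trajectory_csv"),
        summary_json=data.get("summary_json"),
        meta=meta,
    )


def write_trajectory_csv(path: str | Path, history: np.ndarray, first_generation: int = 0) -> None:
    """Write generations as CSV rows: generation, p_1, ..., p_m.

    Floats carry 17 significant digits so rows round-trip bit-faithfully.
    """
    history = np.asarray(history, dtype=float)
    m = history.shape[1]
    with open(path, "w") as fh:
        fh.write("generation," + ",".join(f"p_{i + 1}" for i in range(m)) + "\n")
        for t, row in enumerate(history):
            fh.write(
                f"{first_generation + t},"
                + ",".join(format(v, ".17g") for v in row)
                + "\n"
            )


def write_summary_json(path: str | Path, payload: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
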