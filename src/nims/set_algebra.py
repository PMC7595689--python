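"""Filtering of node-level modules and the exact multi-set intersection test.

Duplicated member sets are collapsed and nested ones removed, leaving an
antichain of non-redundant modules. Every combination of two or more
modules is then tested for excess overlap under the null model in which
each module is an independent uniform random subset of its observed size
drawn from the node universe. The null distribution of the intersection
size is exact, obtained by chaining hypergeometric draws: the running
intersection of size ``s`` meets the next random set of size ``m`` in
``Hypergeometric(universe, s, m)`` elements.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .local_modules import NodeModule

__all__ = [
    "ModuleSetCollection",
    "IntersectionRecord",
    "drop_duplicates",
    "drop_nested",
    "is_trivially_integrated",
    "intersection_pmf",
    "supertest",
    "write_intersections_tsv",
]


@dataclass(frozen=True)
class ModuleSetCollection:
    """A list of non-redundant node-level modules over a fixed node universe."""

    modules: tuple[NodeModule, ...]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        for mod in self.modules:
            if len(mod.members) > self.universe_size:
                raise ValueError(
                    f"module {mod.focal!r} is larger than the universe"
                )

    def labels(self) -> tuple[str, ...]:
        return tuple(m.focal for m in self.modules)

    def by_label(self, label: str) -> NodeModule:
        for m in self.modules:
            if m.focal == label:
                return m
        raise KeyError(label)


@dataclass(frozen=True)
class IntersectionRecord:
    """Observed vs. expected overlap for one combination of modules."""

    combo: tuple[str, ...]
    observed: int
    expected: float
    fold_enrichment: float
    p_raw: float
    p_bonferroni: float
    significant: bool

    @property
    def degree(self) -> int:
        return len(self.combo)


# ---------------------------------------------------------------------------
# Steps 2-3: redundancy filters
# ---------------------------------------------------------------------------

def drop_duplicates(modules: Sequence[NodeModule]) -> list[NodeModule]:
    """Keep exactly one representative per distinct member set.

    The representative is the module whose focal label sorts first; output
    order otherwise preserves first appearance of each member set.
    """
    groups: dict[frozenset[str], NodeModule] = {}
    order: list[frozenset[str]] = []
    for mod in modules:
        key = frozenset(mod.members)
        if key not in groups:
            groups[key] = mod
            order.append(key)
        elif mod.focal < groups[key].focal:
            groups[key] = mod
    return [groups[key] for key in order]


def drop_nested(modules: Sequence[NodeModule]) -> list[NodeModule]:
    """Remove every module strictly contained in another module's member set.

    Assumes duplicates were already removed; the result is an antichain
    under set inclusion.
    """
    keep = []
    for mod in modules:
        nested = any(
            mod.members < other.members for other in modules if other is not mod
        )
        if not nested:
            keep.append(mod)
    return keep


def is_trivially_integrated(collection: ModuleSetCollection) -> bool:
    """True when filtering left a single module: the network is fully
    integrated and has no modular structure to analyze further."""
    return len(collection.modules) == 1


# ---------------------------------------------------------------------------
# Step 4: exact intersection test
# ---------------------------------------------------------------------------

def intersection_pmf(universe_size: int, sizes: Sequence[int]) -> np.ndarray:
    """Exact null pmf of the intersection size of independent uniform random
    subsets of the given sizes, as a vector over 0..min(sizes).

    Computed by chained convolution: conditioned on the running intersection
    having size ``s``, the next subset of size ``m`` hits it in
    ``Hypergeometric(universe_size, s, m)`` elements.
    """
    sizes = list(sizes)
    if len(sizes) < 2:
        raise ValueError("need at least 2 set sizes")
    for m in sizes:
        if not (0 <= m <= universe_size):
            raise ValueError(f"set size {m} exceeds the universe ({universe_size})")
    cap = min(sizes)
    pmf = np.zeros(sizes[0] + 1)
    pmf[sizes[0]] = 1.0
    for m in sizes[1:]:
        new = np.zeros(min(len(pmf) - 1, m) + 1)
        support = np.arange(len(new))
        for s, p in enumerate(pmf):
            if p == 0.0:
                continue
            new += p * hypergeom.pmf(support, universe_size, s, m)
        pmf = new
    out = np.zeros(cap + 1)
    out[: len(pmf)] = pmf[: cap + 1]
    total = out.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise AssertionError(f"pmf does not sum to 1 (got {total})")
    return out / total


def expected_intersection(universe_size: int, sizes: Sequence[int]) -> float:
    """Null mean intersection size: ``N * prod(m_i / N)``."""
    out = float(universe_size)
    for m in sizes:
        out *= m / universe_size
    return out


def supertest(collection: ModuleSetCollection, alpha: float = 0.05) -> list[IntersectionRecord]:
    """Exact enrichment test of every combination of >= 2 modules.

    Returns ``2**k - k - 1`` records for ``k`` modules. ``p_raw`` is the
    upper tail ``P(X >= observed)`` of :func:`intersection_pmf`; the
    Bonferroni factor is the number of tested combinations.
    """
    mods = collection.modules
    if len(mods) < 2:
        raise ValueError("need at least 2 non-redundant modules to test overlaps")
    n = collection.universe_size
    combos: list[tuple[NodeModule, ...]] = []
    for r in range(2, len(mods) + 1):
        combos.extend(combinations(mods, r))
    n_tests = len(combos)
    records = []
    for combo in combos:
        sizes = [len(m.members) for m in combo]
        inter = frozenset.intersection(*(frozenset(m.members) for m in combo))
        observed = len(inter)
        pmf = intersection_pmf(n, sizes)
        p_raw = float(pmf[observed:].sum())
        p_raw = min(max(p_raw, 0.0), 1.0)
        exp = expected_intersection(n, sizes)
        records.append(
            IntersectionRecord(
                combo=tuple(m.focal for m in combo),
                observed=observed,
                expected=exp,
                fold_enrichment=observed / exp if exp > 0 else math.inf,
                p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * n_tests),
                significant=min(1.0, p_raw * n_tests) <= alpha,
            )
        )
    return records


def write_intersections_tsv(records: Iterable[IntersectionRecord], path: str | Path) -> None:
    """Export the intersection table (tabular twin of the bar-chart view)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["combo", "degree", "observed", "expected", "fold_enrichment",
             "p_raw", "p_bonferroni", "significant"]
        )
        for r in records:
            w.writerow(
                ["+".join(r.combo), r.degree, r.observed, f"{r.expected:.6g}",
                 f"{r.fold_enrichment:.6g}", f"{r.p_raw:.6g}",
                 f"{r.p_bonferroni:.6g}", str(r.significant).lower()]
            )
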