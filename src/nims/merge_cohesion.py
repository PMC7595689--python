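"""Merge selection, cover construction, cohesion testing, and the pipeline.

Step 5 turns the intersection table into a merge plan: Bonferroni-significant
combinations are ranked by larger observed overlap, then smaller corrected
p-value, then fewer constituent modules, and committed greedily so that no
module joins two merges. A significant superset of an accepted merge that
shrinks the overlap is explicitly rejected (the informed-decision rule).

Step 6 checks each final cover against the definition of a module — more
links inside than outside — with a paired one-sided Wilcoxon signed-rank
test over per-node (in_links, out_links) pairs: zero differences dropped,
midranks on ties, exact null distribution when tie-free and n < 50,
otherwise a normal approximation with continuity and tie corrections.
Every network node contributes one pair, counted relative to its own side
of the cover boundary (cover members: links into the cover vs. out of it;
non-members: links into the complement vs. into the cover), so a clean
module pushes every node's difference positive. The pairing is pluggable.
"""

from __future__ import annotations

import csv
import json
import math
import time
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .network_model import AnatomicalNetwork, DegreeSplit, degree_split, validate_network
from .local_modules import (
    NodeModule,
    SpinglassConfig,
    all_local_modules,
    local_module,
    LocalModuleFn,
)
from .set_algebra import (
    IntersectionRecord,
    ModuleSetCollection,
    drop_duplicates,
    drop_nested,
    is_trivially_integrated,
    supertest,
)

__all__ = [
    "MergePlan",
    "MergeRationale",
    "Cover",
    "CohesionResult",
    "NimsReport",
    "signed_rank_test",
    "own_group_pairing",
    "cover_reference_pairing",
    "select_merges",
    "build_covers",
    "cohesion_test",
    "run_nims",
]

logger = logging.getLogger("nims")


@dataclass(frozen=True)
class MergeRationale:
    combo: tuple[str, ...]
    observed: int
    p_bonferroni: float
    overlap_fraction: dict[str, float]  # per constituent: observed / module size


@dataclass(frozen=True)
class MergePlan:
    merges: tuple[tuple[str, ...], ...]
    rationale: tuple[MergeRationale, ...]
    rejected: tuple[tuple[tuple[str, ...], str], ...]  # (combo, reason)


@dataclass(frozen=True)
class Cover:
    """A final module: the union of one merge group, or a surviving
    unmerged node-level module. Covers may share nodes."""

    label: str
    members: frozenset[str]
    constituents: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cover cannot be empty")


@dataclass(frozen=True)
class CohesionResult:
    cover: str
    W: float
    p: float
    n_used: int
    splits: tuple[DegreeSplit, ...]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (one-sided, greater)
# ---------------------------------------------------------------------------

def _exact_rank_sum_sf(w: float, n: int) -> float:
    """P(W >= w) for the tie-free null rank-sum over n pairs, by the
    classic counting recursion over ranks 1..n."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    lo = int(math.ceil(w - 1e-9))
    return float(counts[lo:].sum() / 2.0**n)


def signed_rank_test(differences: Sequence[float]) -> tuple[float, float, int]:
    """One-sided (greater) paired Wilcoxon signed-rank test.

    Zeros are dropped; absolute differences are mid-ranked; ``W`` is the sum
    of ranks of positive differences. Exact p-value when the remaining
    absolute differences are tie-free and fewer than 50; otherwise a normal
    approximation with continuity correction and the tie-adjusted variance.

    Returns ``(W, p, n_used)``.
    """
    d = np.asarray([x for x in differences if x != 0], dtype=float)
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    if not has_ties and n < 50:
        p = _exact_rank_sum_sf(w, n)
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            ((tie_counts**3 - tie_counts).sum()) / 48.0
        )
        if var <= 0:
            raise ValueError("zero variance; the test is undefined")
        z = (w - mu - 0.5) / math.sqrt(var)
        p = float(norm.sf(z))
    return w, min(max(p, 0.0), 1.0), n


PairingFn = Callable[[AnatomicalNetwork, "Cover"], list[DegreeSplit]]


def own_group_pairing(net: AnatomicalNetwork, cover: Cover) -> list[DegreeSplit]:
    """One pair per network node, relative to its own side of the cover:
    for members, ``in_links`` counts links into the cover; for non-members,
    links into the complement. A well-separated module makes every node's
    difference positive."""
    splits = []
    for s in degree_split(net, cover.members):
        if s.node in cover.members:
            splits.append(s)
        else:
            splits.append(
                DegreeSplit(node=s.node, in_links=s.out_links, out_links=s.in_links)
            )
    return splits


def cover_reference_pairing(net: AnatomicalNetwork, cover: Cover) -> list[DegreeSplit]:
    """One pair per network node, always counting links toward the cover as
    ``in_links`` (plain :func:`degree_split`). Under this convention
    non-members of a good module contribute negative differences."""
    return degree_split(net, cover.members)


def cohesion_test(
    net: AnatomicalNetwork,
    cover: Cover,
    pairing: PairingFn = own_group_pairing,
) -> CohesionResult:
    """Test whether a cover has more links inside than outside.

    Pairs (in_links, out_links) are formed over ALL network nodes, by
    default relative to each node's own side of the cover boundary
    (:func:`own_group_pairing`); the pairing is pluggable so alternative
    per-node conventions can be swapped in without touching the test.
    """
    unknown = set(cover.members) - set(net.nodes)
    if unknown:
        raise ValueError(f"cover members not in network: {sorted(unknown)}")
    splits = pairing(net, cover)
    w, p, n_used = signed_rank_test([s.difference for s in splits])
    return CohesionResult(cover=cover.label, W=w, p=p, n_used=n_used, splits=tuple(splits))


# ---------------------------------------------------------------------------
# Step 5: merge selection
# ---------------------------------------------------------------------------

DecideFn = Callable[[IntersectionRecord], bool]


def select_merges(
    records: Sequence[IntersectionRecord],
    collection: ModuleSetCollection,
    alpha: float = 0.05,
    decide: DecideFn | None = None,
) -> MergePlan:
    """Greedy selection of statistically supported merges.

    Candidates are the Bonferroni-significant combinations, ranked by larger
    observed overlap, then smaller corrected p-value, then fewer modules.
    A candidate is committed only when none of its modules is already part
    of an accepted merge. ``decide`` (interactive use) is called with each
    otherwise-acceptable candidate and may veto it; by default all are taken.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    sizes = {m.focal: len(m.members) for m in collection.modules}
    candidates = [r for r in records if r.p_bonferroni <= alpha]
    candidates.sort(key=lambda r: (-r.observed, r.p_bonferroni, len(r.combo)))
    committed: set[str] = set()
    merges: list[tuple[str, ...]] = []
    rationale: list[MergeRationale] = []
    rejected: list[tuple[tuple[str, ...], str]] = []
    for rec in candidates:
        if any(lab in committed for lab in rec.combo):
            swallowed = [m for m in merges if set(m) < set(rec.combo)]
            if swallowed and rec.observed < max(
                r.observed for r in records if r.combo in swallowed
            ):
                reason = "overlap-reducing superset"
            else:
                reason = "constituent already merged"
            rejected.append((rec.combo, reason))
            continue
        if decide is not None and not decide(rec):
            rejected.append((rec.combo, "declined by user"))
            continue
        merges.append(rec.combo)
        committed.update(rec.combo)
        rationale.append(
            MergeRationale(
                combo=rec.combo,
                observed=rec.observed,
                p_bonferroni=rec.p_bonferroni,
                overlap_fraction={
                    lab: rec.observed / sizes[lab] for lab in rec.combo
                },
            )
        )
    return MergePlan(
        merges=tuple(merges), rationale=tuple(rationale), rejected=tuple(rejected)
    )


def build_covers(collection: ModuleSetCollection, plan: MergePlan) -> list[Cover]:
    """One cover per merge group (members = union of the merged modules)
    plus one cover per unmerged module."""
    labels = set(collection.labels())
    for group in plan.merges:
        dangling = set(group) - labels
        if dangling:
            raise ValueError(f"merge plan references unknown modules: {sorted(dangling)}")
    merged: set[str] = {lab for group in plan.merges for lab in group}
    covers = []
    for group in plan.merges:
        members = frozenset().union(
            *(collection.by_label(lab).members for lab in group)
        )
        covers.append(
            Cover(label="+".join(sorted(group)), members=members, constituents=tuple(group))
        )
    for mod in collection.modules:
        if mod.focal not in merged:
            covers.append(
                Cover(label=mod.focal, members=frozenset(mod.members), constituents=(mod.focal,))
            )
    return covers


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class NimsReport:
    """Full record of one pipeline run."""

    n_nodes: int
    n_edges: int
    seed: int
    config: SpinglassConfig
    alpha: float
    raw_modules: list[NodeModule]
    modules: list[NodeModule]
    trivially_integrated: bool
    intersections: list[IntersectionRecord]
    plan: MergePlan | None
    covers: list[Cover]
    cohesion: list[CohesionResult]
    uncovered_nodes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def module_dict(m: NodeModule) -> dict:
            return {
                "focal": m.focal,
                "members": sorted(m.members),
                "score": m.score,
                "agreement": m.agreement,
            }

        return {
            "network": {"n_nodes": self.n_nodes, "n_edges": self.n_edges},
            "seed": self.seed,
            "config": asdict(self.config),
            "alpha": self.alpha,
            "node_level_modules": {
                "raw": [module_dict(m) for m in self.raw_modules],
                "non_redundant": [module_dict(m) for m in self.modules],
            },
            "trivially_integrated": self.trivially_integrated,
            "intersections": [
                {
                    "combo": list(r.combo),
                    "degree": r.degree,
                    "observed": r.observed,
                    "expected": r.expected,
                    "fold_enrichment": r.fold_enrichment,
                    "p_raw": r.p_raw,
                    "p_bonferroni": r.p_bonferroni,
                    "significant": r.significant,
                }
                for r in self.intersections
            ],
            "merge_plan": None
            if self.plan is None
            else {
                "merges": [list(g) for g in self.plan.merges],
                "rationale": [
                    {
                        "combo": list(r.combo),
                        "observed": r.observed,
                        "p_bonferroni": r.p_bonferroni,
                        "overlap_fraction": r.overlap_fraction,
                    }
                    for r in self.plan.rationale
                ],
                "rejected": [
                    {"combo": list(c), "reason": reason}
                    for c, reason in self.plan.rejected
                ],
            },
            "covers": [
                {
                    "label": c.label,
                    "members": sorted(c.members),
                    "constituents": list(c.constituents),
                }
                for c in self.covers
            ],
            "cohesion": [
                {"cover": r.cover, "W": r.W, "p": r.p, "n_used": r.n_used}
                for r in self.cohesion
            ],
            "uncovered_nodes": sorted(self.uncovered_nodes),
            "warnings": list(self.warnings),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def run_nims(
    net: AnatomicalNetwork,
    config: SpinglassConfig | None = None,
    alpha: float = 0.05,
    decide: DecideFn | None = None,
    detector: LocalModuleFn = local_module,
) -> NimsReport:
    """Execute the six-step pipeline.

    1. one local module per node; 2-3. drop duplicated and nested member
    sets (stop if a single module remains: fully integrated network);
    4. exact intersection test over all multi-module combinations;
    5. informed merge selection; 6. Wilcoxon cohesion test per final cover.
    Deterministic given ``config.seed``.
    """
    config = config or SpinglassConfig()
    report_warnings: list[str] = []
    vr = validate_network(net)
    report_warnings.extend(vr.warnings)

    t0 = time.perf_counter()
    raw = all_local_modules(net, config, detector=detector)
    logger.info("step 1: %d node-level modules (%.2fs)", len(raw), time.perf_counter() - t0)

    filtered = drop_nested(drop_duplicates(raw))
    collection = ModuleSetCollection(modules=tuple(filtered), universe_size=net.n_nodes)
    logger.info("steps 2-3: %d non-redundant modules", len(filtered))

    if is_trivially_integrated(collection):
        logger.info("single module after filtering: fully integrated network")
        return NimsReport(
            n_nodes=net.n_nodes,
            n_edges=net.n_edges,
            seed=config.seed,
            config=config,
            alpha=alpha,
            raw_modules=raw,
            modules=filtered,
            trivially_integrated=True,
            intersections=[],
            plan=None,
            covers=[],
            cohesion=[],
            uncovered_nodes=[],
            warnings=report_warnings,
        )

    records = supertest(collection, alpha=alpha)
    logger.info("step 4: %d combinations tested", len(records))

    plan = select_merges(records, collection, alpha=alpha, decide=decide)
    logger.info(
        "step 5: %d merges accepted, %d rejected", len(plan.merges), len(plan.rejected)
    )

    covers = build_covers(collection, plan)
    cohesion = []
    for cover in covers:
        try:
            cohesion.append(cohesion_test(net, cover))
        except ValueError as exc:
            report_warnings.append(f"cohesion test undefined for cover {cover.label!r}: {exc}")
    logger.info("step 6: cohesion tested on %d covers", len(covers))

    covered = set().union(*(c.members for c in covers)) if covers else set()
    uncovered = [n for n in net.nodes if n not in covered]
    if uncovered:
        report_warnings.append(f"nodes in no cover: {', '.join(sorted(uncovered))}")

    return NimsReport(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        seed=config.seed,
        config=config,
        alpha=alpha,
        raw_modules=raw,
        modules=filtered,
        trivially_integrated=False,
        intersections=records,
        plan=plan,
        covers=covers,
        cohesion=cohesion,
        uncovered_nodes=uncovered,
        warnings=report_warnings,
    )


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------

def write_covers_tsv(covers: Iterable[Cover], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["cover", "size", "constituents", "members"])
        for c in covers:
            w.writerow(
                [c.label, len(c.members), "+".join(c.constituents), ",".join(sorted(c.members))]
            )


def write_cohesion_tsv(results: Iterable[CohesionResult], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["cover", "W", "p", "n_used"])
        for r in results:
            w.writerow([r.cover, f"{r.W:g}", f"{r.p:.6g}", r.n_used])
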