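"""Generators for small test networks with the structure the pipeline assumes.

Provides planted overlapping-module networks (optionally mirrored into
bilaterally symmetric L/R halves joined by midline nodes), single-edge
perturbations emulating intraspecific variation, the Zachary karate club
benchmark, and reconstructions of the 21-bone adult human skull suture
network from standard anatomy.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .network_model import AnatomicalNetwork, write_network

__all__ = [
    "PlantedSpec",
    "planted_network",
    "perturb",
    "karate_fixture",
    "human_skull_type",
    "human_skull_variant",
    "export_fixture",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted overlapping-module network.

    Adjacent modules in the chain share ``overlap`` nodes. With
    ``bilateral`` set, the sampled network is mirrored into L/R halves;
    the shared (overlap) nodes become unpaired midline nodes connected
    identically to both sides, so the L<->R relabeling is an exact graph
    automorphism.
    """

    module_sizes: tuple[int, ...]
    p_in: float = 1.0
    p_out: float = 0.0
    overlap: int = 0
    bilateral: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.module_sizes or any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.overlap < 0 or (
            len(self.module_sizes) > 1 and self.overlap >= min(self.module_sizes)
        ):
            raise ValueError("overlap must be smaller than the smallest module")


def _rng(seed: int, stream: str) -> np.random.Generator:
    # independent stream per operation, so adding fixtures never shifts others
    ss = np.random.SeedSequence([seed, int.from_bytes(stream.encode(), "big") % (2**63)])
    return np.random.default_rng(ss)


def planted_network(spec: PlantedSpec) -> tuple[AnatomicalNetwork, dict[str, set[str]]]:
    """Sample a network with planted (possibly overlapping) modules.

    Returns the network and the ground-truth map ``module label -> node set``.
    Edges are independent Bernoulli draws: probability ``p_in`` for pairs
    sharing at least one module, ``p_out`` otherwise.
    """
    rng = _rng(spec.seed, "planted")
    modules: list[list[str]] = []
    node_order: list[str] = []
    counter = 0
    prev_tail: list[str] = []
    for mi, size in enumerate(spec.module_sizes):
        fresh_needed = size - (len(prev_tail) if mi > 0 else 0)
        fresh = [f"n{counter + j:02d}" for j in range(fresh_needed)]
        counter += fresh_needed
        members = (prev_tail + fresh) if mi > 0 else fresh
        modules.append(members)
        node_order.extend(fresh)
        prev_tail = members[-spec.overlap:] if spec.overlap else []

    membership: dict[str, set[int]] = {n: set() for n in node_order}
    for mi, members in enumerate(modules):
        for n in members:
            membership[n].add(mi)

    edges = []
    for i, a in enumerate(node_order):
        for b in node_order[i + 1:]:
            p = spec.p_in if membership[a] & membership[b] else spec.p_out
            if p > 0 and rng.random() < p:
                edges.append((a, b))

    if not spec.bilateral:
        net = AnatomicalNetwork(nodes=node_order, edges=edges)
        truth = {f"M{mi}": set(members) for mi, members in enumerate(modules)}
        return net, truth

    midline = {n for n in node_order if len(membership[n]) > 1}

    def sided(n: str, s: str) -> str:
        return n if n in midline else f"{n}{s}"

    nodes, side = [], {}
    for n in node_order:
        if n in midline:
            nodes.append(n)
            side[n] = "U"
        else:
            nodes.extend([f"{n}L", f"{n}R"])
            side[f"{n}L"] = "L"
            side[f"{n}R"] = "R"
    mirrored = set()
    for a, b in edges:
        if a in midline and b in midline:
            mirrored.add((a, b))
        else:
            for s in ("L", "R"):
                mirrored.add((sided(a, s), sided(b, s)))
    net = AnatomicalNetwork(nodes=nodes, edges=sorted(mirrored), laterality=side)
    truth = {
        f"M{mi}": {sided(n, s) for n in members for s in ("L", "R")}
        for mi, members in enumerate(modules)
    }
    return net, truth


def perturb(
    net: AnatomicalNetwork,
    n_rewires: int = 0,
    add_node: str | None = None,
    attach: tuple[str, ...] = (),
    seed: int = 0,
) -> AnatomicalNetwork:
    """Minimal intraspecific-variation edits: degree-perturbing single-edge
    swaps (remove one edge, add one currently absent edge) and an optional
    extra node with explicit attachments. The result stays simple."""
    if n_rewires > net.n_edges:
        raise ValueError("cannot rewire more edges than the network has")
    rng = _rng(seed, "perturb")
    nodes = list(net.nodes)
    edges = set(net.edges)
    all_pairs = {
        (a, b) for i, a in enumerate(sorted(nodes)) for b in sorted(nodes)[i + 1:]
    }
    for _ in range(n_rewires):
        if not edges:
            raise ValueError("no edge available for a swap")
        drop = sorted(edges)[rng.integers(len(edges))]
        edges.discard(drop)
        # re-adding the removed edge would undo the swap; on a complete
        # graph the swap degenerates to a removal (triangle -> path)
        absent = sorted(all_pairs - edges - {drop})
        if absent:
            edges.add(absent[rng.integers(len(absent))])
    laterality = dict(net.laterality)
    if add_node is not None:
        if add_node in nodes:
            raise ValueError(f"node {add_node!r} already exists")
        unknown = set(attach) - set(nodes)
        if unknown:
            raise ValueError(f"attachment targets not in network: {sorted(unknown)}")
        nodes.append(add_node)
        for t in attach:
            edges.add(tuple(sorted((add_node, t))))
    return AnatomicalNetwork(nodes=nodes, edges=sorted(edges), laterality=laterality)


def _load_packaged_edgelist(name: str) -> list[tuple[str, str]]:
    text = (resources.files("nims") / "data" / name).read_text(encoding="utf-8")
    out = []
    for row in csv.reader(text.splitlines()):
        if row:
            out.append((row[0].strip(), row[1].strip()))
    return out


def karate_fixture() -> AnatomicalNetwork:
    """The canonical 34-node, 78-edge Zachary karate club benchmark,
    bundled as a data file (no download)."""
    edges = _load_packaged_edgelist("karate.csv")
    nodes = sorted({n for e in edges for n in e}, key=int)
    return AnatomicalNetwork(nodes=nodes, edges=edges)


def _skull_laterality(nodes: list[str]) -> dict[str, str]:
    return {
        n: ("L" if n.endswith("_L") else "R" if n.endswith("_R") else "U")
        for n in nodes
    }


def human_skull_type() -> AnatomicalNetwork:
    """Reconstruction of the 'type' adult human skull suture network.

    21 bones of the cranium (mandible and ossicles excluded), one edge per
    standard articulation between them, with the sphenoparietal (pterion)
    contact on both sides. Assembled from standard gross-anatomy
    articulation tables, not from any specific published data file.
    """
    edges = _load_packaged_edgelist("human_skull_type.csv")
    nodes = sorted({n for e in edges for n in e})
    return AnatomicalNetwork(
        nodes=nodes, edges=edges, laterality=_skull_laterality(nodes)
    )


def human_skull_variant() -> AnatomicalNetwork:
    """The type human skull with two natural intraspecific variations:
    an extra Wormian bone between the left parietal and the occipital, and
    an asymmetric pterion (left keeps the parietal-sphenoid contact; on the
    right the temporal meets the frontal instead)."""
    base = human_skull_type()
    edges = set(base.edges)
    edges.discard(tuple(sorted(("Parietal_R", "Sphenoid"))))
    edges.add(tuple(sorted(("Temporal_R", "Frontal"))))
    nodes = list(base.nodes) + ["Wormian"]
    edges.add(tuple(sorted(("Wormian", "Parietal_L"))))
    edges.add(tuple(sorted(("Wormian", "Occipital"))))
    lat = dict(base.laterality)
    lat["Wormian"] = "U"
    return AnatomicalNetwork(nodes=nodes, edges=sorted(edges), laterality=lat)


def export_fixture(
    net: AnatomicalNetwork,
    truth: dict[str, set[str]],
    directory: str | Path,
    name: str,
) -> tuple[Path, Path]:
    """Write a fixture as GraphML plus a ground-truth JSON (module map and
    pairwise overlaps) for golden tests."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gpath = directory / f"{name}.graphml"
    jpath = directory / f"{name}.truth.json"
    write_network(net, gpath, format="graphml")
    labels = sorted(truth)
    overlaps = {
        f"{a}&{b}": sorted(truth[a] & truth[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
        if truth[a] & truth[b]
    }
    jpath.write_text(
        json.dumps(
            {"modules": {k: sorted(v) for k, v in truth.items()}, "overlaps": overlaps},
            indent=2,
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    return gpath, jpath
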