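"""Three-step causal-skeleton discovery.

Step 1 builds an undirected graph in which each edge is a channel whose
capacity differs significantly from zero (permutation test, both
orientations, OR-rule).  Step 2 prunes edges that are explained by a
single mediator: for an edge X-Z and common neighbor Y, the composed
tensor of the path {X}{Y}{Z} is compared cellwise against the Jeffreys
band of the directly estimated tensor, in both traversal directions.
Step 3 handles edges whose association could arise from *several*
indirect paths: the capacity of each indirect path is bootstrap-tested,
and when two or more carry capacity the interior vertices are merged into
a joint mediator set S and the direct tensor is compared against the
composed {X}{S}{Z} tensor.  The output of the third step is the final
causal skeleton.

An exact population-oracle variant (:func:`discover_skeleton_oracle`)
replaces estimated tensors with population tensors and the confidence-band
verdict with exact equality; it is used to validate the pipeline logic
independently of sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .channel import (
    DiscreteDataset,
    StochasticTensor,
    compose_path_tensor,
    estimate_tensor,
    joint_name,
    joint_variable,
    tensor_equal_within_ci,
)
from .config import RunConfig
from .errors import CapskelError, MediatorAlphabetError, UnknownVariableError
from .information import capacities
from .stats import edge_capacity_test_pair, path_capacity_test

STATUS_DIRECT = "direct"
STATUS_PRUNED_BIVARIATE = "pruned_bivariate"
STATUS_PRUNED_MULTIVARIATE = "pruned_multivariate"

_PRUNED = (STATUS_PRUNED_BIVARIATE, STATUS_PRUNED_MULTIVARIATE)


@dataclass(frozen=True)
class Path:
    """A simple path, stored as its ordered vertex labels."""

    vertices: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise CapskelError("a path must not repeat a vertex")
        if len(self.vertices) < 2:
            raise CapskelError("a path needs at least two vertices")

    @property
    def interior(self) -> tuple[str, ...]:
        """The mediators: every vertex except the two endpoints."""
        return self.vertices[1:-1]

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.vertices, self.vertices[1:]))

    def __str__(self) -> str:
        return "".join("{" + v + "}" for v in self.vertices)


class SkeletonGraph:
    """Undirected graph whose edges carry capacity, significance and
    pruning status.

    Edges keep their attributes after pruning (status records *why* an
    edge is not part of the final skeleton); a pair that never gained an
    edge is simply absent.
    """

    def __init__(self, vertices: Sequence[str]) -> None:
        self._g = nx.Graph()
        self._g.add_nodes_from(vertices)

    @property
    def vertices(self) -> list[str]:
        return sorted(self._g.nodes)

    def add_edge(
        self, u: str, v: str, capacity: float, p_value: float | None
    ) -> None:
        if u == v:
            raise CapskelError("self-loops are not allowed")
        self._g.add_edge(
            u, v, capacity=capacity, p_value=p_value,
            status=STATUS_DIRECT, pruned_by=None,
        )

    def has_edge(self, u: str, v: str, statuses: tuple[str, ...] | None = None) -> bool:
        if not self._g.has_edge(u, v):
            return False
        if statuses is None:
            return True
        return self._g.edges[u, v]["status"] in statuses

    def status(self, u: str, v: str) -> str | None:
        if not self._g.has_edge(u, v):
            return None
        return self._g.edges[u, v]["status"]

    def set_status(
        self, u: str, v: str, status: str, pruned_by: Path | None = None
    ) -> None:
        if not self._g.has_edge(u, v):
            raise CapskelError(f"no edge between {u!r} and {v!r}")
        self._g.edges[u, v]["status"] = status
        self._g.edges[u, v]["pruned_by"] = pruned_by

    def edge_attrs(self, u: str, v: str) -> dict:
        return dict(self._g.edges[u, v])

    def edges(self, statuses: tuple[str, ...] | None = None) -> list[tuple[str, str, dict]]:
        out = []
        for u, v, attrs in self._g.edges(data=True):
            if statuses is None or attrs["status"] in statuses:
                a, b = sorted((u, v))
                out.append((a, b, dict(attrs)))
        out.sort(key=lambda e: (e[0], e[1]))
        return out

    def surviving_edges(self) -> list[tuple[str, str]]:
        """Edges of the current skeleton (status ``direct``)."""
        return [(u, v) for u, v, _ in self.edges((STATUS_DIRECT,))]

    def edge_set(self, statuses: tuple[str, ...] = (STATUS_DIRECT,)) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v, _ in self.edges(statuses)}

    def neighbors(
        self, v: str, statuses: tuple[str, ...] | None = None
    ) -> list[str]:
        out = []
        for u in self._g.neighbors(v):
            if statuses is None or self._g.edges[v, u]["status"] in statuses:
                out.append(u)
        return sorted(out)

    def subgraph(self, statuses: tuple[str, ...] = (STATUS_DIRECT,)) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes)
        for u, v, attrs in self._g.edges(data=True):
            if attrs["status"] in statuses:
                g.add_edge(u, v)
        return g

    def copy(self) -> "SkeletonGraph":
        new = SkeletonGraph(self.vertices)
        new._g = self._g.copy()
        return new

    def to_records(self) -> list[dict]:
        records = []
        for u, v, attrs in self.edges():
            records.append(
                {
                    "vertex1": u,
                    "vertex2": v,
                    "capacity": attrs["capacity"],
                    "p_value": attrs["p_value"],
                    "status": attrs["status"],
                    "pruned_by": (
                        list(attrs["pruned_by"].vertices)
                        if attrs["pruned_by"] is not None
                        else None
                    ),
                }
            )
        return records


def _derive_seed(*keys: int) -> int:
    """Deterministic child seed (< 2**31) from integer keys."""
    ss = np.random.SeedSequence(list(keys))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# step 1


def step1_capacity_graph(
    data: DiscreteDataset, config: RunConfig | None = None
) -> tuple[SkeletonGraph, dict[tuple[str, str], StochasticTensor], list[dict]]:
    """Detect every pair whose channel carries significant capacity.

    Both orientations of each unordered pair are permutation-tested
    against a shared null; the edge is present when at least one
    orientation is significant (capacity can be easier to detect in one
    direction at finite n, and the skeleton is undirected).  Returns the
    graph, a cache of the estimated tensors for both orientations of every
    pair, and the per-pair test records.
    """
    config = config or RunConfig()
    names = sorted(data.variable_names)
    if len(names) < 2:
        raise CapskelError("skeleton discovery needs at least two variables")
    pairs = list(combinations(names, 2))
    alpha_eff = (
        config.alpha / len(pairs) if config.bonferroni else config.alpha
    )
    graph = SkeletonGraph(names)
    cache: dict[tuple[str, str], StochasticTensor] = {}
    records = []
    for k, (u, v) in enumerate(pairs):
        seed_k = _derive_seed(config.seed, 1, k)
        v12, v21, t12, t21 = edge_capacity_test_pair(
            data,
            u,
            v,
            alpha=alpha_eff,
            n_permutations=config.n_permutations,
            seed=seed_k,
            ba_tolerance=config.ba_tolerance,
            ba_max_iterations=config.ba_max_iterations,
        )
        if t12 is not None:
            cache[(u, v)] = t12
            cache[(v, u)] = t21
        significant = v12.significant or v21.significant
        if significant:
            best = v12 if (v12.p_value or 1.0) <= (v21.p_value or 1.0) else v21
            graph.add_edge(u, v, capacity=best.statistic, p_value=best.p_value)
        records.append(
            {
                "pair": [u, v],
                "seed": seed_k,
                "capacity_fwd": v12.statistic,
                "capacity_bwd": v21.statistic,
                "p_value_fwd": v12.p_value,
                "p_value_bwd": v21.p_value,
                "degenerate": v12.degenerate,
                "edge": significant,
            }
        )
    return graph, cache, records


# ---------------------------------------------------------------------------
# path enumeration


def enumerate_indirect_paths(
    graph: SkeletonGraph,
    endpoint1: str,
    endpoint2: str,
    max_length: int,
    statuses: tuple[str, ...] = (STATUS_DIRECT,),
) -> list[Path]:
    """All simple indirect paths between two endpoints.

    Paths run through edges with the given statuses (by default the
    currently surviving skeleton), have 2..``max_length`` edges, exclude
    the direct edge itself, and are returned in lexicographic order of
    their vertex sequences.
    """
    if endpoint1 not in graph.vertices:
        raise UnknownVariableError(f"unknown endpoint {endpoint1!r}")
    if endpoint2 not in graph.vertices:
        raise UnknownVariableError(f"unknown endpoint {endpoint2!r}")
    g = graph.subgraph(statuses)
    paths = []
    for p in nx.all_simple_paths(g, endpoint1, endpoint2, cutoff=max_length):
        if len(p) >= 3:
            paths.append(Path(tuple(p)))
    paths.sort(key=lambda p: p.vertices)
    return paths


# ---------------------------------------------------------------------------
# step 2


def _both_orientations_equal(
    cache: Mapping[tuple[str, str], StochasticTensor],
    x: str,
    z: str,
    mediator: str,
) -> bool:
    fwd = tensor_equal_within_ci(
        cache[(x, z)],
        compose_path_tensor([cache[(x, mediator)], cache[(mediator, z)]]),
    )
    if not fwd.equal:
        return False
    bwd = tensor_equal_within_ci(
        cache[(z, x)],
        compose_path_tensor([cache[(z, mediator)], cache[(mediator, x)]]),
    )
    return bwd.equal


def step2_bivariate_prune(
    graph: SkeletonGraph,
    tensor_cache: Mapping[tuple[str, str], StochasticTensor],
    config: RunConfig | None = None,
) -> tuple[SkeletonGraph, list[dict]]:
    """Prune edges explained by a single mediator.

    One synchronous pass over the step-1 graph: for every edge (X, Z) and
    every common neighbor Y, the composed tensor of {X}{Y}{Z} is compared
    against the Jeffreys band of the direct tensor, and likewise for the
    reversed traversal {Z}{Y}{X}; the edge is pruned iff both directions
    agree for some mediator.  Decisions are computed against the snapshot
    and applied together, which makes the pass order-independent.  With
    ``iterate_prune`` the pass is repeated on the surviving graph until a
    fixed point.
    """
    config = config or RunConfig()
    current = graph
    records: list[dict] = []
    while True:
        decisions = []
        for u, v, _ in current.edges((STATUS_DIRECT,)):
            mediators = sorted(
                set(current.neighbors(u, (STATUS_DIRECT,)))
                & set(current.neighbors(v, (STATUS_DIRECT,)))
            )
            for y in mediators:
                if _both_orientations_equal(tensor_cache, u, v, y):
                    decisions.append((u, v, y))
                    records.append(
                        {"edge": [u, v], "mediator": y, "pruned": True}
                    )
                    break
        result = current.copy()
        for u, v, y in decisions:
            result.set_status(
                u, v, STATUS_PRUNED_BIVARIATE, pruned_by=Path((u, y, v))
            )
        if not config.iterate_prune or not decisions:
            return result, records
        current = result


# ---------------------------------------------------------------------------
# step 3


def _mediator_set_tensors(
    data: DiscreteDataset,
    x: str,
    z: str,
    members: Sequence[str],
    config: RunConfig,
) -> tuple[StochasticTensor, StochasticTensor, StochasticTensor, StochasticTensor]:
    """Estimated tensors {X}{S}, {S}{Z}, {Z}{S}, {S}{X} for a mediator set."""
    augmented = joint_variable(data, list(members))
    s = joint_name(list(members))
    k = len(augmented.alphabet(s))
    if k > config.mediator_alphabet_cap:
        raise MediatorAlphabetError(
            f"joint mediator {s} has {k} observed symbols, above the cap of "
            f"{config.mediator_alphabet_cap}; rows would be too thin to test"
        )
    t_xs = estimate_tensor(augmented, x, s, alpha=config.alpha)
    t_sz = estimate_tensor(augmented, s, z, alpha=config.alpha)
    t_zs = estimate_tensor(augmented, z, s, alpha=config.alpha)
    t_sx = estimate_tensor(augmented, s, x, alpha=config.alpha)
    return t_xs, t_sz, t_zs, t_sx


def _mediator_set_equal(
    data: DiscreteDataset,
    cache: Mapping[tuple[str, str], StochasticTensor],
    x: str,
    z: str,
    members: Sequence[str],
    config: RunConfig,
) -> bool:
    t_xs, t_sz, t_zs, t_sx = _mediator_set_tensors(data, x, z, members, config)
    fwd = tensor_equal_within_ci(
        cache[(x, z)], compose_path_tensor([t_xs, t_sz])
    )
    if not fwd.equal:
        return False
    bwd = tensor_equal_within_ci(
        cache[(z, x)], compose_path_tensor([t_zs, t_sx])
    )
    return bwd.equal


def step3_multivariate_prune(
    graph: SkeletonGraph,
    data: DiscreteDataset,
    tensor_cache: Mapping[tuple[str, str], StochasticTensor],
    config: RunConfig | None = None,
) -> tuple[SkeletonGraph, list[dict]]:
    """Prune edges whose association is carried by several indirect paths.

    For each surviving edge (X, Z) joined by at least two indirect paths
    in the current skeleton, every path's capacity is bootstrap-tested.
    With two or more significant paths the interiors are merged into a
    mediator set S and the direct tensor is compared against the composed
    {X}{S}{Z} tensor (both orientations).  With exactly one significant
    path the step-2 verdict is kept after re-checking that single path
    (bivariately for a lone mediator, via the mediator set otherwise) -
    a conservative re-check, flagged in the records.
    """
    config = config or RunConfig()
    result = graph.copy()
    records: list[dict] = []
    candidates = []
    for u, v, _ in graph.edges((STATUS_DIRECT,)):
        paths = enumerate_indirect_paths(graph, u, v, config.max_path_length)
        if len(paths) >= 2:
            candidates.append((u, v, paths))
    for c_idx, (u, v, paths) in enumerate(candidates):
        path_records = []
        significant_paths = []
        for p_idx, path in enumerate(paths):
            tensors = [tensor_cache[e] for e in path.edges]
            verdict = path_capacity_test(
                tensors,
                confidence=1.0 - config.alpha,
                n_bootstrap=config.n_bootstrap,
                seed=_derive_seed(config.seed, 3, c_idx, p_idx),
                epsilon=config.capacity_epsilon,
                ba_tolerance=config.ba_tolerance,
                ba_max_iterations=config.ba_max_iterations,
            )
            if verdict.significant:
                significant_paths.append(path)
            path_records.append(
                {
                    "path": list(path.vertices),
                    "capacity": verdict.statistic,
                    "significant": verdict.significant,
                    "seed": verdict.seed,
                }
            )
        pruned = False
        mediator_set: list[str] = []
        recheck = False
        if len(significant_paths) >= 2:
            mediator_set = sorted(
                {m for p in significant_paths for m in p.interior}
            )
            if _mediator_set_equal(data, tensor_cache, u, v, mediator_set, config):
                pruned = True
        elif len(significant_paths) == 1:
            # conservative single-path re-check of the step-2 verdict
            recheck = True
            (path,) = significant_paths
            if len(path.interior) == 1:
                pruned = _both_orientations_equal(
                    tensor_cache, u, v, path.interior[0]
                )
            else:
                mediator_set = list(path.interior)
                pruned = _mediator_set_equal(
                    data, tensor_cache, u, v, mediator_set, config
                )
        if pruned:
            by = Path((u, *mediator_set, v)) if mediator_set else significant_paths[0]
            result.set_status(u, v, STATUS_PRUNED_MULTIVARIATE, pruned_by=by)
        records.append(
            {
                "edge": [u, v],
                "paths": path_records,
                "n_significant": len(significant_paths),
                "mediator_set": mediator_set,
                "single_path_recheck": recheck,
                "pruned": pruned,
            }
        )
    return result, records


# ---------------------------------------------------------------------------
# full pipeline


def discover_skeleton(
    data: DiscreteDataset, config: RunConfig | None = None
) -> tuple[SkeletonGraph, dict]:
    """Run the three discovery steps and return the final skeleton.

    The report records every test, tensor comparison, seed and decision,
    so a run is fully reproducible from it.
    """
    config = config or RunConfig()
    g1, cache, rec1 = step1_capacity_graph(data, config)
    g2, rec2 = step2_bivariate_prune(g1, cache, config)
    g3, rec3 = step3_multivariate_prune(g2, data, cache, config)
    tensors = {}
    for u, v, _ in g1.edges():
        for a, b in ((u, v), (v, u)):
            t = cache[(a, b)]
            tensors[f"{a}->{b}"] = {
                "input_alphabet": list(t.input_alphabet.symbols),
                "output_alphabet": list(t.output_alphabet.symbols),
                "probs": t.probs.tolist(),
                "counts": None if t.counts is None else t.counts.tolist(),
            }
    report = {
        "config": config.to_dict(),
        "n_samples": data.n_samples,
        "variables": sorted(data.variable_names),
        "step1": rec1,
        "step2": rec2,
        "step3": rec3,
        "edges": g3.to_records(),
        "tensors": tensors,
    }
    return g3, report


# ---------------------------------------------------------------------------
# population-oracle mode


def discover_skeleton_oracle(
    net,
    capacity_floor: float = 1e-6,
    atol: float = 1e-9,
    max_path_length: int = 4,
    ba_tolerance: float = 1e-6,
) -> SkeletonGraph:
    """Three-step discovery on the exact population distribution.

    Estimated tensors are replaced by population tensors, the permutation
    test by ``capacity > capacity_floor``, and the confidence-band verdict
    by exact cellwise equality (``atol``).  With exact inputs the pipeline
    must recover the ground-truth skeleton exactly; this is the oracle the
    finite-sample pipeline is validated against.
    """
    from . import synthetic  # local import to avoid a cycle

    names = sorted(net.nodes)
    joint = synthetic.population_joint_array(net)
    cache: dict[tuple[str, str], StochasticTensor] = {}
    graph = SkeletonGraph(names)
    for u, v in combinations(names, 2):
        t_uv = synthetic.population_tensor(net, u, v, joint=joint)
        t_vu = synthetic.population_tensor(net, v, u, joint=joint)
        cache[(u, v)] = t_uv
        cache[(v, u)] = t_vu
        cap = float(capacities(t_uv.probs[None], ba_tolerance)[0])
        if cap > capacity_floor:
            graph.add_edge(u, v, capacity=cap, p_value=None)

    def equal(direct: StochasticTensor, cand: StochasticTensor) -> bool:
        return bool(np.allclose(direct.probs, cand.probs, atol=atol, rtol=0.0))

    def pair_equal(x: str, z: str, mediators: Sequence[str]) -> bool:
        if len(mediators) == 1:
            y = mediators[0]
            t_xs, t_sz = cache[(x, y)], cache[(y, z)]
            t_zs, t_sx = cache[(z, y)], cache[(y, x)]
        else:
            t_xs = synthetic.population_tensor(net, x, list(mediators), joint=joint)
            t_sz = synthetic.population_tensor(net, list(mediators), z, joint=joint)
            t_zs = synthetic.population_tensor(net, z, list(mediators), joint=joint)
            t_sx = synthetic.population_tensor(net, list(mediators), x, joint=joint)
        return equal(
            cache[(x, z)], compose_path_tensor([t_xs, t_sz])
        ) and equal(cache[(z, x)], compose_path_tensor([t_zs, t_sx]))

    # step 2
    decisions = []
    for u, v, _ in graph.edges((STATUS_DIRECT,)):
        mediators = sorted(
            set(graph.neighbors(u, (STATUS_DIRECT,)))
            & set(graph.neighbors(v, (STATUS_DIRECT,)))
        )
        for y in mediators:
            if pair_equal(u, v, [y]):
                decisions.append((u, v, y))
                break
    g2 = graph.copy()
    for u, v, y in decisions:
        g2.set_status(u, v, STATUS_PRUNED_BIVARIATE, pruned_by=Path((u, y, v)))

    # step 3
    g3 = g2.copy()
    for u, v, _ in g2.edges((STATUS_DIRECT,)):
        paths = enumerate_indirect_paths(g2, u, v, max_path_length)
        if len(paths) < 2:
            continue
        significant = []
        for path in paths:
            composed = compose_path_tensor([cache[e] for e in path.edges])
            if float(capacities(composed.probs[None], ba_tolerance)[0]) > capacity_floor:
                significant.append(path)
        pruned = False
        mediator_set: list[str] = []
        if len(significant) >= 2:
            mediator_set = sorted({m for p in significant for m in p.interior})
            pruned = pair_equal(u, v, mediator_set)
        elif len(significant) == 1:
            mediator_set = list(significant[0].interior)
            pruned = pair_equal(u, v, mediator_set)
        if pruned:
            g3.set_status(
                u,
                v,
                STATUS_PRUNED_MULTIVARIATE,
                pruned_by=Path((u, *mediator_set, v)),
            )
    return g3
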