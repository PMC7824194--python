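"""Ground-truthed discrete Bayesian networks for simulation and oracles.

The generator plays two roles: it produces finite samples by ancestral
sampling (the data every stage of the pipeline is exercised on), and it
exposes the *exact* population distribution by full joint enumeration,
which serves as the independent oracle for population-level identities
(chain composition, the data processing inequality, fork symmetry, and
oracle-mode skeleton recovery).

The ``lucas_like`` fixture is a 12-binary-node network whose skeleton
matches the published LUCAS ground truth ("LUng CAncer Simple set": a toy
benchmark of 12 binary variables around smoking and lung cancer, including
one isolated variable).  The generating conditional probability tables of
the original benchmark are not public, so this module ships its own; only
the *skeleton*, not the distribution, emulates the benchmark.  Every true
edge of every shipped fixture is guaranteed a population channel capacity
of at least 0.05 bits (a faithfulness guard, checked in the test suite via
:func:`population_tensor` plus Blahut-Arimoto).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .channel import (
    JOINT_SEP,
    AlphabetMap,
    DiscreteDataset,
    JointDistribution,
    StochasticTensor,
)
from .errors import CapskelError

#: Refuse full joint enumeration above this many states.
DEFAULT_STATE_CAP = 2**20

_BINARY = AlphabetMap(("0", "1"))


@dataclass(frozen=True)
class BayesNet:
    """A DAG with per-node conditional probability tables.

    ``cpts[node]`` has shape ``(*parent_cardinalities, K_node)`` with parent
    axes in the order of ``parents[node]``; every row sums to 1 and a row
    exists for every parent configuration.
    """

    nodes: tuple[str, ...]
    parents: Mapping[str, tuple[str, ...]]
    cpts: Mapping[str, np.ndarray]
    node_alphabets: Mapping[str, AlphabetMap]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise CapskelError("node labels must be unique")
        dag = nx.DiGraph()
        dag.add_nodes_from(self.nodes)
        for node in self.nodes:
            for p in self.parents.get(node, ()):
                if p not in self.node_alphabets:
                    raise CapskelError(f"unknown parent {p!r} of {node!r}")
                dag.add_edge(p, node)
        if not nx.is_directed_acyclic_graph(dag):
            raise CapskelError("parent structure must be acyclic")
        for node in self.nodes:
            cpt = np.asarray(self.cpts[node], dtype=float)
            expected = tuple(
                len(self.node_alphabets[p]) for p in self.parents.get(node, ())
            ) + (len(self.node_alphabets[node]),)
            if cpt.shape != expected:
                raise CapskelError(
                    f"CPT of {node!r} has shape {cpt.shape}, expected {expected}"
                )
            if np.any(cpt < 0) or np.max(np.abs(cpt.sum(axis=-1) - 1.0)) > 1e-12:
                raise CapskelError(
                    f"every CPT row of {node!r} must sum to 1"
                )

    @property
    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node in self.nodes:
            for p in self.parents.get(node, ()):
                g.add_edge(p, node)
        return g

    def skeleton_edges(self) -> set[frozenset[str]]:
        """The undirected ground-truth skeleton as a set of vertex pairs."""
        return {
            frozenset((p, node))
            for node in self.nodes
            for p in self.parents.get(node, ())
        }

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "parents": {n: list(self.parents.get(n, ())) for n in self.nodes},
            "alphabets": {
                n: list(self.node_alphabets[n].symbols) for n in self.nodes
            },
            "cpts": {n: np.asarray(self.cpts[n]).tolist() for n in self.nodes},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "BayesNet":
        return cls(
            nodes=tuple(d["nodes"]),
            parents={n: tuple(v) for n, v in d["parents"].items()},
            cpts={n: np.asarray(v, dtype=float) for n, v in d["cpts"].items()},
            node_alphabets={
                n: AlphabetMap(tuple(v)) for n, v in d["alphabets"].items()
            },
        )

    @classmethod
    def from_json(cls, s: str) -> "BayesNet":
        return cls.from_dict(json.loads(s))


def sample(net: BayesNet, n_samples: int, seed: int) -> DiscreteDataset:
    """Ancestral sampling in topological order; seed-deterministic.

    Columns of the returned dataset are in lexicographic node order.
    """
    if n_samples < 1:
        raise CapskelError("n_samples must be at least 1")
    rng = np.random.default_rng(int(seed))
    codes: dict[str, np.ndarray] = {}
    for node in nx.lexicographical_topological_sort(net.dag):
        cpt = np.asarray(net.cpts[node], dtype=float)
        pars = net.parents.get(node, ())
        if pars:
            rows = cpt[tuple(codes[p] for p in pars)]
        else:
            rows = np.broadcast_to(cpt, (n_samples, cpt.shape[-1]))
        u = rng.random(n_samples)
        cum = np.cumsum(rows, axis=1)
        codes[node] = np.minimum(
            (u[:, None] > cum).sum(axis=1), cpt.shape[-1] - 1
        )
    columns = {}
    for node in sorted(net.nodes):
        symbols = np.asarray(net.node_alphabets[node].symbols, dtype=object)
        columns[node] = symbols[codes[node]]
    return DiscreteDataset.from_dict(columns)


def population_joint_array(
    net: BayesNet, state_cap: int = DEFAULT_STATE_CAP
) -> np.ndarray:
    """Exact joint probability over all nodes, axes in ``net.nodes`` order."""
    cards = [len(net.node_alphabets[n]) for n in net.nodes]
    n_states = int(np.prod(cards))
    if n_states > state_cap:
        raise CapskelError(
            f"joint enumeration over {n_states} states exceeds the cap "
            f"({state_cap})"
        )
    idx = {n: i for i, n in enumerate(net.nodes)}
    joint = np.ones(cards)
    for node in net.nodes:
        cpt = np.asarray(net.cpts[node], dtype=float)
        axes = [idx[p] for p in net.parents.get(node, ())] + [idx[node]]
        order = np.argsort(axes)
        cpt_t = np.transpose(cpt, order)
        shape = [1] * len(cards)
        for ax, k in zip([axes[i] for i in order], cpt_t.shape):
            shape[ax] = k
        joint = joint * cpt_t.reshape(shape)
    return joint


def _group_marginal(
    net: BayesNet,
    joint: np.ndarray,
    variables: Sequence[str],
) -> tuple[np.ndarray, list[tuple[str, ...]]]:
    """Marginal over a variable group, flattened in lexicographic
    tuple order, together with the symbol tuples of positive-probability
    configurations."""
    idx = {n: i for i, n in enumerate(net.nodes)}
    axes = [idx[v] for v in variables]
    keep = sorted(axes)
    marg = joint.sum(axis=tuple(i for i in range(joint.ndim) if i not in keep))
    # reorder axes to the requested variable order
    marg = np.transpose(marg, [keep.index(a) for a in axes])
    flat = marg.reshape(-1)
    grids = np.meshgrid(
        *[np.arange(len(net.node_alphabets[v])) for v in variables],
        indexing="ij",
    )
    combos = np.stack([g.reshape(-1) for g in grids], axis=1)
    tuples = [
        tuple(
            net.node_alphabets[v].symbols[c]
            for v, c in zip(variables, row)
        )
        for row in combos
    ]
    return flat, tuples


def population_marginal(
    net: BayesNet,
    variables: str | Sequence[str],
    state_cap: int = DEFAULT_STATE_CAP,
    joint: np.ndarray | None = None,
) -> np.ndarray:
    """Exact marginal probability vector of a variable (or group)."""
    names = [variables] if isinstance(variables, str) else list(variables)
    if joint is None:
        joint = population_joint_array(net, state_cap)
    flat, _ = _group_marginal(net, joint, names)
    return flat


def population_tensor(
    net: BayesNet,
    input_vars: str | Sequence[str],
    output_vars: str | Sequence[str],
    state_cap: int = DEFAULT_STATE_CAP,
    joint: np.ndarray | None = None,
) -> StochasticTensor:
    """Exact channel ``p(output | input)`` by full joint enumeration.

    Either terminal may be a set of variables, in which case its alphabet
    consists of the positive-probability symbol tuples (joined with the
    same separator as :func:`capskel.channel.joint_variable`), in
    lexicographic order.  The tensor carries no counts or bounds.
    """
    in_names = [input_vars] if isinstance(input_vars, str) else list(input_vars)
    out_names = (
        [output_vars] if isinstance(output_vars, str) else list(output_vars)
    )
    if set(in_names) & set(out_names):
        raise CapskelError("input and output variables must be distinct")
    if joint is None:
        joint = population_joint_array(net, state_cap)
    flat, tuples = _group_marginal(net, joint, in_names + out_names)
    k_out = int(
        np.prod([len(net.node_alphabets[v]) for v in out_names])
    )
    table = flat.reshape(-1, k_out)
    in_tuples = [t[: len(in_names)] for t in tuples[::k_out]]
    out_tuples = [t[len(in_names):] for t in tuples[:k_out]]
    row_keep = np.flatnonzero(table.sum(axis=1) > 0)
    col_keep = np.flatnonzero(table.sum(axis=0) > 0)
    table = table[np.ix_(row_keep, col_keep)]
    in_symbols = tuple(JOINT_SEP.join(in_tuples[i]) for i in row_keep)
    out_symbols = tuple(JOINT_SEP.join(out_tuples[j]) for j in col_keep)
    probs = table / table.sum(axis=1, keepdims=True)
    return StochasticTensor(
        input_alphabet=AlphabetMap(in_symbols),
        output_alphabet=AlphabetMap(out_symbols),
        probs=probs,
    )


def population_pair_joint(
    net: BayesNet, var1: str, var2: str, state_cap: int = DEFAULT_STATE_CAP
) -> JointDistribution:
    """Exact joint distribution of a pair of single variables."""
    joint = population_joint_array(net, state_cap)
    flat, _ = _group_marginal(net, joint, [var1, var2])
    probs = flat.reshape(
        len(net.node_alphabets[var1]), len(net.node_alphabets[var2])
    )
    return JointDistribution(
        net.node_alphabets[var1], net.node_alphabets[var2], probs
    )


# ---------------------------------------------------------------------------
# fixtures


def _check_noise(noise: float) -> None:
    if not 0.0 < noise < 0.5:
        raise CapskelError("noise must lie in the open interval (0, 0.5)")


def _binary_net(
    parents: Mapping[str, tuple[str, ...]],
    p_one: Mapping[str, np.ndarray],
) -> BayesNet:
    """Binary network from per-node arrays of p(node = 1 | parent combo)."""
    nodes = tuple(parents)
    cpts = {}
    for node in nodes:
        p1 = np.asarray(p_one[node], dtype=float)
        cpts[node] = np.stack([1.0 - p1, p1], axis=-1)
    return BayesNet(
        nodes=nodes,
        parents={n: tuple(v) for n, v in parents.items()},
        cpts=cpts,
        node_alphabets={n: _BINARY for n in nodes},
    )


def chain(noise: float = 0.1) -> BayesNet:
    """X -> Y -> Z with binary symmetric links of the given flip probability."""
    _check_noise(noise)
    return _binary_net(
        {"X": (), "Y": ("X",), "Z": ("Y",)},
        {
            "X": np.array(0.5),
            "Y": np.array([noise, 1.0 - noise]),
            "Z": np.array([noise, 1.0 - noise]),
        },
    )


def fork(noise: float = 0.1) -> BayesNet:
    """Y <- X -> Z with binary symmetric links."""
    _check_noise(noise)
    return _binary_net(
        {"X": (), "Y": ("X",), "Z": ("X",)},
        {
            "X": np.array(0.5),
            "Y": np.array([noise, 1.0 - noise]),
            "Z": np.array([noise, 1.0 - noise]),
        },
    )


def collider(noise: float = 0.1) -> BayesNet:
    """X -> Y <- Z; the two causes are marginally independent.

    ``p(Y=1 | x, z)`` is ``noise`` when both causes are absent, ``1 -
    noise`` when both are present, and 1/2 otherwise, so each cause-collider
    edge carries capacity while X and Z stay independent.
    """
    _check_noise(noise)
    return _binary_net(
        {"X": (), "Z": (), "Y": ("X", "Z")},
        {
            "X": np.array(0.5),
            "Z": np.array(0.5),
            "Y": np.array([[noise, 0.5], [0.5, 1.0 - noise]]),
        },
    )


def diamond(noise: float = 0.1) -> BayesNet:
    """X -> U -> Z and X -> V -> Z with no direct X -> Z mechanism.

    The association between X and Z is carried by *two* indirect paths, so
    neither single-mediator composition reproduces the end-to-end tensor -
    the configuration that forces the multivariate pruning step.
    """
    _check_noise(noise)
    return _binary_net(
        {"X": (), "U": ("X",), "V": ("X",), "Z": ("U", "V")},
        {
            "X": np.array(0.5),
            "U": np.array([noise, 1.0 - noise]),
            "V": np.array([noise, 1.0 - noise]),
            "Z": np.array([[noise, 0.5], [0.5, 1.0 - noise]]),
        },
    )


#: Node labels of the LUCAS-like network.
LUCAS_NODES = (
    "Allergy",
    "Anxiety",
    "AttentionDisorder",
    "BornEvenDay",
    "CarAccident",
    "Coughing",
    "Fatigue",
    "Genetics",
    "LungCancer",
    "PeerPressure",
    "Smoking",
    "YellowFingers",
)


def lucas_like() -> BayesNet:
    """12-binary-node network with the published LUCAS skeleton.

    Structure: Anxiety and PeerPressure drive Smoking; Smoking drives
    YellowFingers and (with Genetics) LungCancer; Genetics also drives
    AttentionDisorder; Allergy and LungCancer drive Coughing; LungCancer
    and Coughing drive Fatigue; AttentionDisorder and Fatigue drive
    CarAccident; BornEvenDay is isolated.  The tables are this package's
    own (the benchmark's generating distribution is not public) and give
    every true edge a population capacity comfortably above 0.05 bits.
    """
    return _binary_net(
        {
            "Anxiety": (),
            "PeerPressure": (),
            "Genetics": (),
            "Allergy": (),
            "BornEvenDay": (),
            "Smoking": ("Anxiety", "PeerPressure"),
            "YellowFingers": ("Smoking",),
            "LungCancer": ("Smoking", "Genetics"),
            "AttentionDisorder": ("Genetics",),
            "Coughing": ("Allergy", "LungCancer"),
            "Fatigue": ("LungCancer", "Coughing"),
            "CarAccident": ("AttentionDisorder", "Fatigue"),
        },
        {
            "Anxiety": np.array(0.4),
            "PeerPressure": np.array(0.3),
            "Genetics": np.array(0.3),
            "Allergy": np.array(0.3),
            "BornEvenDay": np.array(0.5),
            "Smoking": np.array([[0.2, 0.65], [0.65, 0.9]]),
            "YellowFingers": np.array([0.15, 0.85]),
            "LungCancer": np.array([[0.05, 0.55], [0.55, 0.9]]),
            "AttentionDisorder": np.array([0.15, 0.8]),
            "Coughing": np.array([[0.1, 0.75], [0.6, 0.95]]),
            "Fatigue": np.array([[0.15, 0.6], [0.6, 0.9]]),
            "CarAccident": np.array([[0.1, 0.5], [0.5, 0.85]]),
        },
    )


def fixtures(noise: float = 0.1) -> dict[str, BayesNet]:
    """The named fixture collection used throughout the test suite."""
    return {
        "chain": chain(noise),
        "fork": fork(noise),
        "collider": collider(noise),
        "diamond": diamond(noise),
        "lucas_like": lucas_like(),
    }
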