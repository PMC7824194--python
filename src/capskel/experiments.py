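"""Reference experiments on the shipped fixtures.

These runners back both the acceptance checks of the test suite and the
reproduction script: closed-form capacity checks, exact population
identities (chain composition, DPI, fork symmetry), test calibration, and
skeleton-recovery rates on the chain/fork/collider/diamond and LUCAS-like
networks.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

import numpy as np

from . import synthetic as syn
from .channel import (
    AlphabetMap,
    DiscreteDataset,
    StochasticTensor,
    compose_path_tensor,
    reverse_tensor,
)
from .config import RunConfig
from .information import blahut_arimoto, dpi_gap, mutual_information, path_information
from .skeleton import discover_skeleton, discover_skeleton_oracle
from .stats import edge_capacity_test

_BINARY = AlphabetMap(("0", "1"))


def _random_channel(rng: np.random.Generator, k_in: int, k_out: int) -> StochasticTensor:
    m = rng.gamma(1.0, 1.0, size=(k_in, k_out)) + 1e-3
    return StochasticTensor(
        AlphabetMap(tuple(str(i) for i in range(k_in))),
        AlphabetMap(tuple(str(i) for i in range(k_out))),
        m / m.sum(axis=1, keepdims=True),
    )


def bsc_capacity_max_error(flips=(0.01, 0.05, 0.1, 0.2, 0.3, 0.45)) -> float:
    """Largest |Blahut-Arimoto - closed form| over a BSC grid, in bits."""
    worst = 0.0
    for p in flips:
        t = StochasticTensor(
            _BINARY, _BINARY, np.array([[1 - p, p], [p, 1 - p]])
        )
        closed = 1.0 + p * np.log2(p) + (1 - p) * np.log2(1 - p)
        worst = max(
            worst, abs(blahut_arimoto(t, tolerance=1e-9).capacity - closed)
        )
    return worst


def chain_identity_errors(noise: float = 0.1) -> tuple[float, float]:
    """(tensor composition error, path-information-vs-MI error) on the
    population chain."""
    net = syn.chain(noise)
    a = syn.population_tensor(net, "X", "Y")
    b = syn.population_tensor(net, "Y", "Z")
    c = syn.population_tensor(net, "X", "Z")
    tensor_err = float(np.abs(c.probs - a.probs @ b.probs).max())
    px = syn.population_marginal(net, "X")
    info_err = abs(
        path_information(px, c)
        - mutual_information(syn.population_pair_joint(net, "X", "Z"))
    )
    return tensor_err, info_err


def dpi_min_gap(n_chains: int, seed: int) -> float:
    """Smallest DPI slack over random population chains (alphabets 2-4)."""
    rng = np.random.default_rng(seed)
    worst = np.inf
    for _ in range(n_chains):
        k = [int(rng.integers(2, 5)) for _ in range(3)]
        a = _random_channel(rng, k[0], k[1])
        b = StochasticTensor(
            a.output_alphabet,
            AlphabetMap(tuple(str(i) for i in range(k[2]))),
            _random_channel(rng, k[1], k[2]).probs,
        )
        px = rng.dirichlet(np.ones(k[0]))
        worst = min(worst, dpi_gap(a, b, px))
    return float(worst)


def fork_symmetry_max_diff(n_forks: int, seed: int) -> float:
    """Largest |I({Y}{X}{Z}) - I({Z}{X}{Y})| over random population forks."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_forks):
        k = [int(rng.integers(2, 4)) for _ in range(3)]
        a = _random_channel(rng, k[0], k[1])  # X -> Y
        c = StochasticTensor(
            a.input_alphabet,
            AlphabetMap(tuple(str(i) for i in range(k[2]))),
            _random_channel(rng, k[0], k[2]).probs,
        )  # X -> Z
        px = rng.dirichlet(np.ones(k[0])) + 1e-3
        px = px / px.sum()
        py, pz = px @ a.probs, px @ c.probs
        fwd = path_information(py, compose_path_tensor([reverse_tensor(a, px), c]))
        bwd = path_information(pz, compose_path_tensor([reverse_tensor(c, px), a]))
        worst = max(worst, abs(fwd - bwd))
    return worst


def edge_test_false_positive_rate(
    n_reps: int, n_samples: int, alpha: float, seed: int
) -> float:
    """Rejection rate of the edge test on independent binary pairs."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_reps):
        x = rng.integers(0, 2, size=n_samples)
        y = rng.integers(0, 2, size=n_samples)
        ds = DiscreteDataset.from_dict(
            {"X": [str(v) for v in x], "Y": [str(v) for v in y]}
        )
        test_seed = int(rng.integers(0, 2**31 - 1))
        if edge_capacity_test(ds, "X", "Y", alpha=alpha, seed=test_seed).significant:
            hits += 1
    return hits / n_reps


def triad_recovery_rate(
    fixture: str, n_seeds: int, n_samples: int = 2000, base_seed: int = 0,
    noise: float = 0.1,
) -> float:
    """Fraction of seeds on which the exact true skeleton is recovered."""
    net = syn.fixtures(noise)[fixture]
    ok = 0
    for s in range(n_seeds):
        seed = base_seed + s
        data = syn.sample(net, n_samples, seed)
        graph, _ = discover_skeleton(data, RunConfig(seed=seed))
        ok += graph.edge_set() == net.skeleton_edges()
    return ok / n_seeds


def diamond_pruning_rates(
    n_seeds: int, n_samples: int = 2000, base_seed: int = 0, noise: float = 0.1
) -> dict:
    """Spurious-edge handling on the diamond: is X-Z absent or pruned, and
    does the multivariate step engage whenever step 1 creates the edge?"""
    net = syn.diamond(noise)
    gone = created = engaged = 0
    for s in range(n_seeds):
        seed = base_seed + s
        data = syn.sample(net, n_samples, seed)
        graph, report = discover_skeleton(data, RunConfig(seed=seed))
        status = graph.status("X", "Z")
        if status != "direct":
            gone += 1
        if status is not None:  # step 1 created the edge
            created += 1
            rec = [r for r in report["step3"] if set(r["edge"]) == {"X", "Z"}]
            if rec and rec[0]["n_significant"] >= 2:
                engaged += 1
    return {
        "absent_or_pruned_rate": gone / n_seeds,
        "edges_created": created,
        "step3_engaged": engaged,
    }


def lucas_recovery(
    n_seeds: int, n_samples: int = 2000, base_seed: int = 0
) -> dict:
    """End-to-end recovery on the LUCAS-like network."""
    net = syn.lucas_like()
    truth = net.skeleton_edges()
    exact = only_lcfat = 0
    for s in range(n_seeds):
        seed = base_seed + s
        data = syn.sample(net, n_samples, seed)
        graph, report = discover_skeleton(data, RunConfig(seed=seed))
        exact += graph.edge_set() == truth
        evaluated = sorted(tuple(r["edge"]) for r in report["step3"])
        only_lcfat += evaluated == [("Fatigue", "LungCancer")]
    return {
        "exact_rate": exact / n_seeds,
        "only_lucas_pair_in_step3": only_lcfat,
        "n_seeds": n_seeds,
    }


def oracle_mismatch_count() -> int:
    """Total edge errors of oracle-mode discovery over all fixtures."""
    errors = 0
    for net in syn.fixtures(0.1).values():
        got = discover_skeleton_oracle(net).edge_set()
        errors += len(got ^ net.skeleton_edges())
    return errors
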