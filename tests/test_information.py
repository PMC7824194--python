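"""Mutual information, path information, capacity, and the DPI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capskel import (
    AlphabetMap,
    JointDistribution,
    StochasticTensor,
    blahut_arimoto,
    compose_path_tensor,
    dpi_gap,
    mutual_information,
    path_information,
    reverse_tensor,
)
from capskel.errors import AlphabetMismatchError, CapskelError
from capskel.information import capacities
from capskel import synthetic as syn

from conftest import BINARY, binary_tensor, random_stochastic


def h2(p: float) -> float:
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def binary_joint(m) -> JointDistribution:
    return JointDistribution(BINARY, BINARY, np.asarray(m, dtype=float))


# ---------------------------------------------------------------------------
# mutual information


def test_mi_independence_and_identity():
    assert mutual_information(binary_joint([[0.25, 0.25], [0.25, 0.25]])) == 0.0
    assert mutual_information(binary_joint([[0.5, 0.0], [0.0, 0.5]])) == pytest.approx(1.0)


def test_mi_four_term_example():
    # direct summation: 2*0.4*log2(1.6) + 2*0.1*log2(0.4)
    expected = 2 * 0.4 * np.log2(1.6) + 2 * 0.1 * np.log2(0.4)
    assert mutual_information(binary_joint([[0.4, 0.1], [0.1, 0.4]])) == pytest.approx(
        expected, abs=1e-12
    )
    assert expected == pytest.approx(0.2781, abs=5e-5)


def test_mi_zero_iff_factorized(rng):
    for _ in range(50):
        px = rng.dirichlet(np.ones(3))
        pz = rng.dirichlet(np.ones(2))
        j = JointDistribution(
            AlphabetMap(("a", "b", "c")), BINARY, np.outer(px, pz)
        )
        assert mutual_information(j) == pytest.approx(0.0, abs=1e-12)


def test_unnormalized_joint_is_rejected():
    with pytest.raises(CapskelError):
        JointDistribution(BINARY, BINARY, np.array([[0.5, 0.2], [0.2, 0.2]]))


# ---------------------------------------------------------------------------
# path information


def test_path_information_equals_population_mi_on_chain(chain_net):
    px = syn.population_marginal(chain_net, "X")
    t = syn.population_tensor(chain_net, "X", "Z")
    j = syn.population_pair_joint(chain_net, "X", "Z")
    assert path_information(px, t) == pytest.approx(
        mutual_information(j), abs=1e-12
    )


def test_path_information_identical_rows_is_zero():
    t = binary_tensor([[0.3, 0.7], [0.3, 0.7]])
    assert path_information(np.array([0.2, 0.8]), t) == pytest.approx(0.0, abs=1e-12)


def test_path_information_composed_example():
    a = binary_tensor([[0.9, 0.1], [0.2, 0.8]])
    b = binary_tensor([[0.7, 0.3], [0.4, 0.6]])
    c = compose_path_tensor([a, b])
    # direct summation over the induced joint p(x,z) = px * C[x,z]
    px = np.array([0.5, 0.5])
    joint = px[:, None] * c.probs
    pz = joint.sum(axis=0)
    expected = float(
        (joint * np.log2(joint / (px[:, None] * pz[None, :]))).sum()
    )
    assert path_information(px, c) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.0326, abs=5e-5)


# ---------------------------------------------------------------------------
# Blahut-Arimoto


def test_capacity_noiseless_binary_channel():
    res = blahut_arimoto(binary_tensor(np.eye(2)))
    assert res.capacity == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(res.optimal_input, [0.5, 0.5], atol=1e-6)
    assert res.converged


def test_capacity_identical_rows_is_zero():
    res = blahut_arimoto(binary_tensor([[0.4, 0.6], [0.4, 0.6]]))
    assert res.capacity == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("p", [0.01, 0.05, 0.1, 0.2, 0.3, 0.45])
def test_capacity_bsc_closed_form(p):
    t = binary_tensor([[1 - p, p], [p, 1 - p]])
    res = blahut_arimoto(t, tolerance=1e-9)
    assert res.capacity == pytest.approx(1 - h2(p), abs=1e-6)


def test_capacity_upper_bounds_any_fixed_input_mi(rng):
    # capacity is a maximum over input distributions
    for _ in range(20):
        k_in, k_out = int(rng.integers(2, 4)), int(rng.integers(2, 4))
        probs = random_stochastic(rng, k_in, k_out)
        t = StochasticTensor(
            AlphabetMap(tuple(str(i) for i in range(k_in))),
            AlphabetMap(tuple(str(i) for i in range(k_out))),
            probs,
        )
        cap = blahut_arimoto(t, tolerance=1e-9).capacity
        assert cap <= np.log2(min(k_in, k_out)) + 1e-9
        for _ in range(50):
            px = rng.dirichlet(np.ones(k_in))
            assert cap + 1e-7 >= path_information(px, t)


def test_batch_capacities_match_single(rng):
    mats = np.stack([random_stochastic(rng, 3, 3) for _ in range(20)])
    batch = capacities(mats, tolerance=1e-9)
    alph = AlphabetMap(("0", "1", "2"))
    for i in range(20):
        single = blahut_arimoto(
            StochasticTensor(alph, alph, mats[i]), tolerance=1e-9
        ).capacity
        assert batch[i] == pytest.approx(single, abs=1e-8)


def test_blahut_arimoto_input_validation():
    t = binary_tensor([[0.9, 0.1], [0.2, 0.8]])
    with pytest.raises(CapskelError):
        blahut_arimoto(t, tolerance=0.0)
    with pytest.raises(CapskelError):
        capacities(np.array([[[0.9, 0.2], [0.1, 0.8]]]))  # rows don't sum to 1


# ---------------------------------------------------------------------------
# data processing inequality


def test_dpi_gap_identity_first_link():
    ident = binary_tensor(np.eye(2))
    b = binary_tensor([[0.8, 0.2], [0.3, 0.7]])
    # noiseless first link: I(X;Z) = I(Y;Z) and the gap closes
    assert dpi_gap(ident, b, np.array([0.5, 0.5])) == pytest.approx(0.0, abs=1e-12)


def test_dpi_gap_strictly_positive_for_noisy_links():
    a = binary_tensor([[0.9, 0.1], [0.2, 0.8]])
    b = binary_tensor([[0.7, 0.3], [0.4, 0.6]])
    assert dpi_gap(a, b, np.array([0.5, 0.5])) > 0.01


def test_dpi_gap_nonnegative_random_sweep(rng):
    for _ in range(1000):
        k = [int(rng.integers(2, 5)) for _ in range(3)]
        a = StochasticTensor(
            AlphabetMap(tuple(str(i) for i in range(k[0]))),
            AlphabetMap(tuple(str(i) for i in range(k[1]))),
            random_stochastic(rng, k[0], k[1]),
        )
        b = StochasticTensor(
            a.output_alphabet,
            AlphabetMap(tuple(str(i) for i in range(k[2]))),
            random_stochastic(rng, k[1], k[2]),
        )
        px = rng.dirichlet(np.ones(k[0]))
        assert dpi_gap(a, b, px) >= -1e-12


def test_composed_capacity_bounded_by_links(rng):
    for _ in range(50):
        a = binary_tensor(random_stochastic(rng, 2, 2))
        b = binary_tensor(random_stochastic(rng, 2, 2))
        c = compose_path_tensor([a, b])
        cap_c = blahut_arimoto(c, tolerance=1e-9).capacity
        cap_a = blahut_arimoto(a, tolerance=1e-9).capacity
        cap_b = blahut_arimoto(b, tolerance=1e-9).capacity
        assert cap_c <= min(cap_a, cap_b) + 1e-7


# ---------------------------------------------------------------------------
# fork symmetry


def test_fork_symmetry_random_population_forks(rng):
    # fork Y <- X -> Z: path information of {Y}{X}{Z} equals {Z}{X}{Y}
    for _ in range(100):
        k = [int(rng.integers(2, 4)) for _ in range(3)]
        a = StochasticTensor(  # X -> Y
            AlphabetMap(tuple(str(i) for i in range(k[0]))),
            AlphabetMap(tuple(str(i) for i in range(k[1]))),
            random_stochastic(rng, k[0], k[1]),
        )
        c = StochasticTensor(  # X -> Z
            a.input_alphabet,
            AlphabetMap(tuple(str(i) for i in range(k[2]))),
            random_stochastic(rng, k[0], k[2]),
        )
        px = rng.dirichlet(np.ones(k[0])) + 1e-3
        px = px / px.sum()
        py = px @ a.probs
        pz = px @ c.probs
        a_dag = reverse_tensor(a, px)  # {Y}{X}
        c_dag = reverse_tensor(c, px)  # {Z}{X}
        fwd = path_information(py, compose_path_tensor([a_dag, c]))
        bwd = path_information(pz, compose_path_tensor([c_dag, a]))
        assert fwd == pytest.approx(bwd, abs=1e-12)


def test_dpi_gap_alphabet_mismatch():
    a = binary_tensor([[0.9, 0.1], [0.2, 0.8]])
    wide = StochasticTensor(
        AlphabetMap(("0", "1", "2")),
        BINARY,
        random_stochastic(np.random.default_rng(0), 3, 2),
    )
    with pytest.raises(AlphabetMismatchError):
        dpi_gap(a, wide, np.array([0.5, 0.5]))
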