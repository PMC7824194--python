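"""Tensor estimation and channel algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from capskel import (
    AlphabetMap,
    DiscreteDataset,
    StochasticTensor,
    compose_path_tensor,
    estimate_joint,
    estimate_tensor,
    joint_variable,
    reverse_tensor,
    tensor_equal_within_ci,
)
from capskel.channel import joint_name, tensor_from_counts
from capskel.errors import (
    AlphabetMismatchError,
    CapskelError,
    DegenerateInputError,
    MissingConfidenceError,
    UnknownVariableError,
)

from conftest import BINARY, binary_tensor, random_stochastic


# ---------------------------------------------------------------------------
# AlphabetMap / DiscreteDataset


def test_alphabet_is_lexicographic_bijection():
    a = AlphabetMap.from_values(["b", "a", "c", "a"])
    assert a.symbols == ("a", "b", "c")
    assert [a.index_of(s) for s in a.symbols] == [0, 1, 2]
    with pytest.raises(CapskelError):
        a.index_of("z")
    with pytest.raises(CapskelError):
        AlphabetMap(("b", "a"))  # not sorted


def test_dataset_requires_unique_names_and_samples():
    import pandas as pd

    with pytest.raises(CapskelError):
        DiscreteDataset(pd.DataFrame(columns=["X"]))
    df = pd.DataFrame([["0", "1"]], columns=["X", "X"])
    with pytest.raises(CapskelError):
        DiscreteDataset(df)


def test_pairwise_deletion_drops_incomplete_rows():
    ds = DiscreteDataset.from_dict(
        {"X": ["0", "1", None, "1"], "Y": ["0", None, "1", "1"]}
    )
    cx, cy = ds.pair_codes("X", "Y")
    assert len(cx) == 2  # rows 0 and 3 survive
    assert ds.n_samples == 4  # rows themselves are retained


# ---------------------------------------------------------------------------
# estimate_tensor


def test_identical_copy_gives_jeffreys_smoothed_diagonal():
    # 50 samples of each input symbol, output identical to input:
    # diagonal = (50 + 1/2) / (50 + 1) per the add-1/2 smoothing rule
    vals = ["0"] * 50 + ["1"] * 50
    ds = DiscreteDataset.from_dict({"X": vals, "Y": list(vals)})
    t = estimate_tensor(ds, "X", "Y")
    expected = 50.5 / 51.0
    assert t.probs[0, 0] == pytest.approx(expected, abs=1e-12)
    assert t.probs[1, 1] == pytest.approx(expected, abs=1e-12)
    assert t.probs[0, 1] == pytest.approx(1 - expected, abs=1e-12)


def test_single_symbol_input_yields_smoothed_output_marginal():
    ds = DiscreteDataset.from_dict(
        {"X": ["a"] * 10, "Y": ["0"] * 7 + ["1"] * 3}
    )
    t = estimate_tensor(ds, "X", "Y")
    assert t.probs.shape == (1, 2)
    assert t.probs[0, 0] == pytest.approx(7.5 / 11.0)


def test_count_table_oracle():
    # {(a,a):30, (a,b):10, (b,a):5, (b,b):55} recomputed by brute force
    counts = np.array([[30.0, 10.0], [5.0, 55.0]])
    ab = AlphabetMap(("a", "b"))
    t = tensor_from_counts(counts, ab, ab, alpha=0.05)
    for i in range(2):
        n_row = counts[i].sum()
        for j in range(2):
            c = counts[i, j]
            assert t.probs[i, j] == pytest.approx(
                (c + 0.5) / (n_row + 1.0), abs=1e-14
            )
            a_par, b_par = c + 0.5, n_row - c + 0.5
            assert t.ci_low[i, j] == pytest.approx(
                beta_dist.ppf(0.025, a_par, b_par), abs=1e-12
            )
            assert t.ci_high[i, j] == pytest.approx(
                beta_dist.ppf(0.975, a_par, b_par), abs=1e-12
            )
    assert np.all(t.ci_low <= t.probs) and np.all(t.probs <= t.ci_high)


def test_estimate_tensor_errors():
    ds = DiscreteDataset.from_dict({"X": ["0", "1"], "Y": ["0", "1"]})
    with pytest.raises(CapskelError):
        estimate_tensor(ds, "X", "X")
    with pytest.raises(UnknownVariableError):
        estimate_tensor(ds, "X", "Q")
    # an input symbol whose only rows are incomplete in the pair
    ds2 = DiscreteDataset.from_dict(
        {"X": ["0", "1", "1"], "Y": [None, "0", "1"]}
    )
    with pytest.raises(DegenerateInputError):
        estimate_tensor(ds2, "X", "Y")


# ---------------------------------------------------------------------------
# estimate_joint


def test_joint_examples_and_tally(rng):
    ds = DiscreteDataset.from_dict(
        {"X": ["a", "a", "b", "b"], "Y": ["a", "b", "a", "b"]}
    )
    j = estimate_joint(ds, "X", "Y")
    assert np.allclose(j.probs, 0.25)

    ds_const = DiscreteDataset.from_dict({"X": ["a"] * 5, "Y": ["b"] * 5})
    assert estimate_joint(ds_const, "X", "Y").probs[0, 0] == 1.0

    # 100 random samples vs an independent tally
    xs = rng.integers(0, 3, size=100)
    ys = rng.integers(0, 2, size=100)
    ds_r = DiscreteDataset.from_dict(
        {"X": [str(v) for v in xs], "Y": [str(v) for v in ys]}
    )
    j = estimate_joint(ds_r, "X", "Y")
    for a in range(3):
        for b in range(2):
            assert j.probs[a, b] == pytest.approx(
                np.sum((xs == a) & (ys == b)) / 100.0
            )


# ---------------------------------------------------------------------------
# reverse_tensor


def test_reverse_hand_example():
    a = binary_tensor([[0.9, 0.1], [0.2, 0.8]])
    rev = reverse_tensor(a, np.array([0.5, 0.5]))
    assert np.allclose(
        rev.probs, [[0.5 * 0.9 / 0.55, 0.5 * 0.2 / 0.55],
                    [0.5 * 0.1 / 0.45, 0.5 * 0.8 / 0.45]]
    )
    assert np.round(rev.probs, 4).tolist() == [
        [0.8182, 0.1818],
        [0.1111, 0.8889],
    ]


def test_reverse_symmetric_doubly_stochastic_is_transpose():
    a = binary_tensor([[0.7, 0.3], [0.3, 0.7]])
    rev = reverse_tensor(a, np.array([0.5, 0.5]))
    assert np.allclose(rev.probs, a.probs.T)


def test_reverse_round_trip_recovers_marginal(rng):
    for _ in range(100):
        k_in = int(rng.integers(2, 5))
        k_out = int(rng.integers(2, 5))
        probs = random_stochastic(rng, k_in, k_out)
        t = StochasticTensor(
            AlphabetMap(tuple(str(i) for i in range(k_in))),
            AlphabetMap(tuple(str(i) for i in range(k_out))),
            probs,
        )
        px = rng.dirichlet(np.ones(k_in)) + 1e-3
        px = px / px.sum()
        rev = reverse_tensor(t, px)
        py = px @ t.probs
        assert np.allclose(py @ rev.probs, px, atol=1e-12)
        # double reversal returns the original tensor
        back = reverse_tensor(rev, py)
        assert np.allclose(back.probs, t.probs, atol=1e-10)


def test_reverse_is_not_matrix_inverse():
    a = binary_tensor([[0.8, 0.2], [0.3, 0.7]])
    rev = reverse_tensor(a, np.array([0.6, 0.4]))
    assert not np.allclose(rev.probs @ a.probs, np.eye(2), atol=1e-3)


def test_reverse_rejects_bad_marginals():
    a = binary_tensor([[0.9, 0.1], [0.2, 0.8]])
    with pytest.raises(CapskelError):
        reverse_tensor(a, np.array([1.0, 0.0]))  # not strictly positive
    with pytest.raises(AlphabetMismatchError):
        reverse_tensor(a, np.array([0.3, 0.3, 0.4]))


# ---------------------------------------------------------------------------
# compose_path_tensor


def test_compose_hand_product_and_identity():
    a = binary_tensor([[0.9, 0.1], [0.2, 0.8]])
    b = binary_tensor([[0.7, 0.3], [0.4, 0.6]])
    c = compose_path_tensor([a, b])
    assert np.allclose(c.probs, [[0.67, 0.33], [0.46, 0.54]], atol=1e-12)
    ident = binary_tensor(np.eye(2))
    assert np.allclose(compose_path_tensor([a, ident]).probs, a.probs)
    with pytest.raises(CapskelError):
        compose_path_tensor([])


def test_compose_alphabet_mismatch():
    a = binary_tensor([[0.9, 0.1], [0.2, 0.8]])
    wide = StochasticTensor(
        AlphabetMap(("0", "1", "2")), BINARY, random_stochastic(
            np.random.default_rng(0), 3, 2
        )
    )
    with pytest.raises(AlphabetMismatchError):
        compose_path_tensor([a, wide])


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1), st.integers(2, 5))
def test_composition_preserves_row_stochasticity(seed, depth):
    r = np.random.default_rng(seed)
    sizes = [int(r.integers(2, 5)) for _ in range(depth + 1)]
    tensors = [
        StochasticTensor(
            AlphabetMap(tuple(str(i) for i in range(sizes[k]))),
            AlphabetMap(tuple(str(i) for i in range(sizes[k + 1]))),
            random_stochastic(r, sizes[k], sizes[k + 1]),
        )
        for k in range(depth)
    ]
    c = compose_path_tensor(tensors)
    assert np.allclose(c.probs.sum(axis=1), 1.0, atol=1e-12)


def test_composition_is_associative(rng):
    mats = [random_stochastic(rng, 2, 2) for _ in range(3)]
    ts = [binary_tensor(m) for m in mats]
    left = compose_path_tensor([compose_path_tensor(ts[:2]), ts[2]])
    right = compose_path_tensor([ts[0], compose_path_tensor(ts[1:])])
    assert np.allclose(left.probs, right.probs, atol=1e-12)


# ---------------------------------------------------------------------------
# joint_variable


def test_joint_variable_singleton_matches_member():
    ds = DiscreteDataset.from_dict({"X": ["0", "1"], "Y": ["1", "0"]})
    out = joint_variable(ds, ["Y"])
    name = joint_name(["Y"])
    assert out.codes(name).tolist() == out.codes("Y").tolist()


def test_joint_variable_observed_tuples_only():
    full = DiscreteDataset.from_dict(
        {"A": ["0", "0", "1", "1"], "B": ["0", "1", "0", "1"]}
    )
    assert len(joint_variable(full, ["A", "B"]).alphabet(joint_name(["A", "B"]))) == 4
    partial = DiscreteDataset.from_dict(
        {"A": ["0", "0", "1"], "B": ["0", "1", "0"]}
    )
    assert len(joint_variable(partial, ["A", "B"]).alphabet(joint_name(["A", "B"]))) == 3


def test_joint_variable_errors():
    ds = DiscreteDataset.from_dict({"X": ["0"], "Y": ["1"]})
    with pytest.raises(UnknownVariableError):
        joint_variable(ds, ["Q"])
    with pytest.raises(CapskelError):
        joint_variable(ds, ["X", "X"])
    with pytest.raises(CapskelError):
        joint_variable(ds, [])


# ---------------------------------------------------------------------------
# tensor_equal_within_ci


def test_point_estimate_inside_own_band():
    vals = ["0"] * 60 + ["1"] * 40
    ds = DiscreteDataset.from_dict({"X": vals, "Y": list(reversed(vals))})
    direct = estimate_tensor(ds, "X", "Y")
    cand = StochasticTensor(BINARY, BINARY, direct.probs.copy())
    assert tensor_equal_within_ci(direct, cand).equal


def test_violating_cell_is_reported():
    vals = ["0"] * 60 + ["1"] * 40
    ds = DiscreteDataset.from_dict({"X": vals, "Y": list(vals)})
    direct = estimate_tensor(ds, "X", "Y")
    bad = direct.probs.copy()
    bad[0] = [0.5, 0.5]  # far outside the near-diagonal band
    cmp = tensor_equal_within_ci(
        direct, StochasticTensor(BINARY, BINARY, bad)
    )
    assert not cmp.equal
    cells = {(v.input_symbol, v.output_symbol) for v in cmp.violations}
    assert ("0", "0") in cells
    assert all(v.margin > 0 for v in cmp.violations)


def test_equal_within_ci_requires_bounds_and_alphabets():
    direct = binary_tensor([[0.9, 0.1], [0.1, 0.9]])  # no CIs
    with pytest.raises(MissingConfidenceError):
        tensor_equal_within_ci(direct, direct)
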