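"""Significance decisions for channel capacities.

Edges enter the skeleton only when their capacity differs significantly
from zero.  Two decision rules are used:

* **Direct edges** - a permutation test.  The plug-in capacity of an
  estimated tensor is positively biased (smoothing alone yields capacities
  of order 1/n), so interval-based rules would be anti-conservative; the
  permutation null, obtained by breaking the sample pairing, is exactly
  calibrated.
* **Composed paths** - a Dirichlet-posterior bootstrap.  A composed tensor
  has no direct counts to permute, so each constituent tensor's rows are
  redrawn from their Dirichlet(counts + 1/2) posterior, the replicates are
  composed, and the path is called significant when the lower quantile of
  the bootstrap capacities clears a small epsilon floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .channel import (
    DiscreteDataset,
    StochasticTensor,
    pair_counts,
    tensor_from_counts,
)
from .errors import AlphabetMismatchError, CapskelError, MissingCountsError
from .information import capacities


@dataclass(frozen=True)
class SignificanceVerdict:
    """Decision about a capacity differing from zero.

    ``p_value`` is present for the permutation mode only; ``threshold`` is
    the null (1 - alpha) capacity quantile for permutation tests and the
    epsilon floor for bootstrap tests.  ``degenerate`` flags a variable
    observed with a single symbol, which can never gain an edge.
    """

    statistic: float
    threshold: float
    significant: bool
    replicates: int
    seed: int
    p_value: float | None = None
    degenerate: bool = False
    mode: str = "permutation"


def _permuted_count_tables(
    ci: np.ndarray,
    co: np.ndarray,
    k_in: int,
    k_out: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Count tables after re-pairing the columns ``n_permutations`` times."""
    tables = np.empty((n_permutations, k_in, k_out))
    for b in range(n_permutations):
        perm = rng.permutation(co)
        flat = np.bincount(ci * k_out + perm, minlength=k_in * k_out)
        tables[b] = flat.reshape(k_in, k_out)
    return tables


def _smoothed(tables: np.ndarray) -> np.ndarray:
    """Jeffreys add-1/2 smoothed channels for a stack of count tables."""
    k_out = tables.shape[2]
    totals = tables.sum(axis=2, keepdims=True)
    return (tables + 0.5) / (totals + k_out / 2.0)


def edge_capacity_test_pair(
    data: DiscreteDataset,
    var1: str,
    var2: str,
    alpha: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
    ba_tolerance: float = 1e-6,
    ba_max_iterations: int = 10_000,
) -> tuple[
    SignificanceVerdict,
    SignificanceVerdict,
    StochasticTensor | None,
    StochasticTensor | None,
]:
    """Test both orientations of an unordered pair against one shared null.

    The same permuted pairings feed both orientations, so the two verdicts
    answer the same question ("is this pairing informative?") from either
    terminal.  Returns the two verdicts plus the estimated tensors
    (``var1 -> var2`` and ``var2 -> var1``; ``None`` when degenerate).
    """
    if n_permutations < 19:
        raise CapskelError("n_permutations must be at least 19")
    ci, co = data.pair_codes(var1, var2)
    if ci.size == 0:
        raise CapskelError(
            f"no complete observations for pair ({var1!r}, {var2!r})"
        )
    k_in = len(data.alphabet(var1))
    k_out = len(data.alphabet(var2))
    seed = int(seed)
    if (
        np.unique(ci).size < 2
        or np.unique(co).size < 2
    ):
        verdict = SignificanceVerdict(
            statistic=0.0,
            threshold=0.0,
            significant=False,
            replicates=n_permutations,
            seed=seed,
            p_value=1.0,
            degenerate=True,
        )
        return verdict, verdict, None, None

    counts = np.bincount(ci * k_out + co, minlength=k_in * k_out)
    counts = counts.reshape(k_in, k_out).astype(float)
    t12 = tensor_from_counts(
        counts, data.alphabet(var1), data.alphabet(var2), alpha
    )
    t21 = tensor_from_counts(
        counts.T, data.alphabet(var2), data.alphabet(var1), alpha
    )
    stat12 = float(
        capacities(t12.probs[None], ba_tolerance, ba_max_iterations)[0]
    )
    stat21 = float(
        capacities(t21.probs[None], ba_tolerance, ba_max_iterations)[0]
    )

    rng = np.random.default_rng(seed)
    tables = _permuted_count_tables(ci, co, k_in, k_out, n_permutations, rng)
    null12 = capacities(_smoothed(tables), ba_tolerance, ba_max_iterations)
    null21 = capacities(
        _smoothed(tables.transpose(0, 2, 1)), ba_tolerance, ba_max_iterations
    )

    def _verdict(stat: float, null: np.ndarray) -> SignificanceVerdict:
        p = (1.0 + float((null >= stat - 1e-12).sum())) / (
            1.0 + n_permutations
        )
        return SignificanceVerdict(
            statistic=stat,
            threshold=float(np.quantile(null, 1.0 - alpha)),
            significant=p <= alpha,
            replicates=n_permutations,
            seed=seed,
            p_value=p,
        )

    return _verdict(stat12, null12), _verdict(stat21, null21), t12, t21


def edge_capacity_test(
    data: DiscreteDataset,
    var1: str,
    var2: str,
    alpha: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
    ba_tolerance: float = 1e-6,
    ba_max_iterations: int = 10_000,
) -> SignificanceVerdict:
    """Permutation test of the capacity of the channel ``var1 -> var2``.

    The statistic is the Blahut-Arimoto capacity of the smoothed tensor;
    the null re-estimates it after permuting ``var2``'s column (breaking
    the pairing) ``n_permutations`` times; the p-value is
    ``(1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    verdict, _, _, _ = edge_capacity_test_pair(
        data,
        var1,
        var2,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
        ba_tolerance=ba_tolerance,
        ba_max_iterations=ba_max_iterations,
    )
    return verdict


def path_capacity_test(
    constituent_tensors: Sequence[StochasticTensor],
    confidence: float = 0.95,
    n_bootstrap: int = 200,
    seed: int = 0,
    epsilon: float = 1e-3,
    ba_tolerance: float = 1e-6,
    ba_max_iterations: int = 10_000,
) -> SignificanceVerdict:
    """Bootstrap test: does a composed path carry nonzero capacity?

    Each replicate redraws every constituent tensor's rows from
    ``Dirichlet(counts + 1/2)``, composes the replicates along the path,
    and records the capacity.  The path is significant iff the empirical
    ``1 - confidence`` quantile of those capacities exceeds the epsilon
    floor (default 1e-3 bits; plug-in capacities of order 1/n arise from
    smoothing alone).
    """
    if len(constituent_tensors) == 0:
        raise CapskelError("a path needs at least one constituent tensor")
    if n_bootstrap < 50:
        raise CapskelError("n_bootstrap must be at least 50")
    if not 0.0 < confidence < 1.0:
        raise CapskelError("confidence must lie in (0, 1)")
    for t in constituent_tensors:
        if not t.has_counts:
            raise MissingCountsError(
                "every constituent tensor must carry raw counts"
            )
    for left, right in zip(constituent_tensors, constituent_tensors[1:]):
        if left.output_alphabet.symbols != right.input_alphabet.symbols:
            raise AlphabetMismatchError("constituent tensors not composable")

    seed = int(seed)
    point = constituent_tensors[0].probs
    for t in constituent_tensors[1:]:
        point = point @ t.probs
    statistic = float(
        capacities(point[None], ba_tolerance, ba_max_iterations)[0]
    )

    rng = np.random.default_rng(seed)
    composed = None
    for t in constituent_tensors:
        alphas = np.asarray(t.counts, dtype=float) + 0.5
        draws = rng.gamma(shape=alphas, scale=1.0,
                          size=(n_bootstrap,) + alphas.shape)
        draws = draws / draws.sum(axis=2, keepdims=True)
        composed = draws if composed is None else composed @ draws
    caps = capacities(composed, ba_tolerance, ba_max_iterations)
    lower = float(np.quantile(caps, 1.0 - confidence))
    return SignificanceVerdict(
        statistic=statistic,
        threshold=epsilon,
        significant=lower > epsilon,
        replicates=n_bootstrap,
        seed=seed,
        p_value=None,
        mode="bootstrap",
    )
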