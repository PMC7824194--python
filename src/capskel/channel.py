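"""Discrete memoryless channels as stochastic tensors.

Every association between two categorical variables is modelled as a
communication channel: a row-stochastic transition matrix ``A`` with
``A[x, y] = p(y | x)`` that maps an input probability mass function to an
output one via ``p_y = sum_x p_x A[x, y]``.  Because the matrix transforms
properly under re-orderings of the alphabets it is referred to throughout as
a *stochastic tensor*.

This module provides

* the in-memory containers (:class:`AlphabetMap`, :class:`DiscreteDataset`,
  :class:`StochasticTensor`, :class:`JointDistribution`);
* estimation of tensors and joints from data, with Jeffreys (Beta(1/2,1/2))
  smoothing and per-cell Jeffreys credible bounds;
* the channel algebra used by skeleton discovery: Bayes reversal of a
  channel (the "dagger" tensor for traversing a path backwards), chain
  composition (matrix product of the constituent tensors), joint mediator
  variables, and the cellwise confidence-interval equality verdict that
  decides whether a direct association is explained by an indirect path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .errors import (
    AlphabetMismatchError,
    CapskelError,
    DegenerateInputError,
    MissingConfidenceError,
    UnknownVariableError,
)

#: Separator used to build the symbol of a joint (tuple-valued) variable.
#: The ASCII unit separator sorts below every printable character, so
#: lexicographic order on joined strings equals lexicographic order on the
#: underlying tuples for printable source symbols.
JOINT_SEP = "\x1f"

_ROW_SUM_ATOL = 1e-12


@dataclass(frozen=True)
class AlphabetMap:
    """Ordered alphabet of a categorical variable.

    The ordering is the lexicographic order of the labels' string forms and
    is fixed for the whole run; ``index_of`` is the bijection onto
    ``0..K-1`` implied by that ordering.
    """

    symbols: tuple[str, ...]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise CapskelError("alphabet must contain at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise CapskelError("alphabet symbols must be unique")
        if list(self.symbols) != sorted(self.symbols):
            raise CapskelError("alphabet symbols must be in lexicographic order")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    @classmethod
    def from_values(cls, values: Iterable[str]) -> "AlphabetMap":
        """Build the alphabet of the distinct values, lexicographically."""
        return cls(tuple(sorted(set(map(str, values)))))

    def index_of(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise CapskelError(f"symbol {symbol!r} not in alphabet") from None

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)


class DiscreteDataset:
    """An ``n_samples x n_vars`` table of categorical observations.

    Values are kept as strings (categorical symbols); missing entries are
    ``None``/``NaN`` and are dropped pairwise by the estimators.  Each
    variable carries an :class:`AlphabetMap` over its observed symbols.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        alphabets: Mapping[str, AlphabetMap] | None = None,
    ) -> None:
        if frame.shape[0] < 1:
            raise CapskelError("dataset needs at least one sample")
        names = [str(c) for c in frame.columns]
        if len(set(names)) != len(names):
            raise CapskelError("variable names must be unique")
        # normalize to string values, preserving missingness
        values = frame.astype("object").where(frame.notna(), None)
        values.columns = names
        for c in names:
            col = values[c]
            values[c] = col.map(lambda v: None if v is None else str(v))
        self._frame = values
        self._alphabets: dict[str, AlphabetMap] = {}
        self._codes: dict[str, np.ndarray] = {}
        for c in names:
            observed = [v for v in values[c] if v is not None]
            if alphabets is not None and c in alphabets:
                alph = alphabets[c]
                bad = set(observed) - set(alph.symbols)
                if bad:
                    raise CapskelError(
                        f"values {sorted(bad)} of variable {c!r} are not in "
                        "its declared alphabet"
                    )
            else:
                if not observed:
                    raise CapskelError(
                        f"variable {c!r} has no observed values"
                    )
                alph = AlphabetMap.from_values(observed)
            self._alphabets[c] = alph
            cat = pd.Categorical(values[c], categories=list(alph.symbols))
            self._codes[c] = np.asarray(cat.codes, dtype=np.int64)

    # -- basic accessors ---------------------------------------------------

    @property
    def variable_names(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def n_samples(self) -> int:
        return int(self._frame.shape[0])

    @property
    def n_vars(self) -> int:
        return int(self._frame.shape[1])

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying table (strings; ``None`` marks a missing cell)."""
        return self._frame.copy()

    def alphabet(self, var: str) -> AlphabetMap:
        self._require(var)
        return self._alphabets[var]

    def codes(self, var: str) -> np.ndarray:
        """Integer codes of a column (``-1`` marks a missing value)."""
        self._require(var)
        return self._codes[var]

    def pair_codes(self, var1: str, var2: str) -> tuple[np.ndarray, np.ndarray]:
        """Complete-case integer codes for a pair of variables.

        Rows with a missing value in either column are dropped (pairwise
        deletion), which keeps every estimate bivariate.
        """
        c1, c2 = self.codes(var1), self.codes(var2)
        keep = (c1 >= 0) & (c2 >= 0)
        return c1[keep], c2[keep]

    def _require(self, var: str) -> None:
        if var not in self._frame.columns:
            raise UnknownVariableError(f"unknown variable {var!r}")

    @classmethod
    def from_dict(cls, columns: Mapping[str, Sequence[object]]) -> "DiscreteDataset":
        return cls(pd.DataFrame(dict(columns)))


@dataclass(frozen=True)
class StochasticTensor:
    """Row-stochastic transition matrix ``p(output | input)``.

    ``counts``/``ci_low``/``ci_high``/``row_totals`` are present only for
    tensors estimated directly from data; composed or population-derived
    tensors carry probabilities alone.
    """

    input_alphabet: AlphabetMap
    output_alphabet: AlphabetMap
    probs: np.ndarray
    counts: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    row_totals: np.ndarray | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        expected = (len(self.input_alphabet), len(self.output_alphabet))
        if probs.shape != expected:
            raise CapskelError(
                f"probs shape {probs.shape} does not match alphabets {expected}"
            )
        if np.any(probs < -_ROW_SUM_ATOL) or np.any(probs > 1 + 1e-9):
            raise CapskelError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(probs.sum(axis=1) - 1.0)) > 1e-9:
            raise CapskelError("every row of a stochastic tensor must sum to 1")

    @property
    def has_counts(self) -> bool:
        return self.counts is not None

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class JointDistribution:
    """Joint probability matrix over a variable pair."""

    row_alphabet: AlphabetMap
    col_alphabet: AlphabetMap
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        expected = (len(self.row_alphabet), len(self.col_alphabet))
        if probs.shape != expected:
            raise CapskelError(
                f"joint shape {probs.shape} does not match alphabets {expected}"
            )
        if np.any(probs < 0):
            raise CapskelError("joint probabilities must be nonnegative")
        if abs(float(probs.sum()) - 1.0) > 1e-9:
            raise CapskelError("joint distribution must sum to 1")

    def row_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def col_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=0)


# ---------------------------------------------------------------------------
# estimation


def tensor_from_counts(
    counts: np.ndarray,
    input_alphabet: AlphabetMap,
    output_alphabet: AlphabetMap,
    alpha: float = 0.05,
) -> StochasticTensor:
    """Smoothed tensor plus Jeffreys bounds from a co-occurrence table.

    Cell estimates use Dirichlet--Jeffreys add-1/2 smoothing,
    ``(count(x,y) + 1/2) / (count(x) + K_out/2)``, which keeps every tensor
    strictly positive (the channels of interest are noisy).  The 95% bounds
    per cell are the ``alpha/2`` and ``1 - alpha/2`` quantiles of
    ``Beta(count(x,y) + 1/2, count(x) - count(x,y) + 1/2)``, i.e., the
    Jeffreys interval for each cell against its complement.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(input_alphabet), len(output_alphabet)):
        raise CapskelError("count table shape does not match alphabets")
    if np.any(counts < 0):
        raise CapskelError("counts must be nonnegative")
    row_totals = counts.sum(axis=1)
    if np.any(row_totals == 0):
        missing = [
            input_alphabet.symbols[i]
            for i in np.flatnonzero(row_totals == 0)
        ]
        raise DegenerateInputError(
            f"input symbols {missing} have no complete observations"
        )
    k_out = len(output_alphabet)
    probs = (counts + 0.5) / (row_totals[:, None] + k_out / 2.0)
    a = counts + 0.5
    b = (row_totals[:, None] - counts) + 0.5
    ci_low = beta_dist.ppf(alpha / 2.0, a, b)
    ci_high = beta_dist.ppf(1.0 - alpha / 2.0, a, b)
    return StochasticTensor(
        input_alphabet=input_alphabet,
        output_alphabet=output_alphabet,
        probs=probs,
        counts=counts,
        ci_low=ci_low,
        ci_high=ci_high,
        row_totals=row_totals,
    )


def pair_counts(
    data: DiscreteDataset, input_var: str, output_var: str
) -> np.ndarray:
    """Complete-case co-occurrence count table for an ordered pair."""
    ci, co = data.pair_codes(input_var, output_var)
    k_in = len(data.alphabet(input_var))
    k_out = len(data.alphabet(output_var))
    flat = np.bincount(ci * k_out + co, minlength=k_in * k_out)
    return flat.reshape(k_in, k_out).astype(float)


def estimate_tensor(
    data: DiscreteDataset,
    input_var: str,
    output_var: str,
    alpha: float = 0.05,
) -> StochasticTensor:
    """Estimate the channel ``input_var -> output_var`` from data.

    See :func:`tensor_from_counts` for the smoothing and interval rules.
    Raises :class:`DegenerateInputError` when an input symbol has no
    complete observation, and refuses ``input_var == output_var``.
    """
    if input_var == output_var:
        raise CapskelError("input and output variable must differ")
    counts = pair_counts(data, input_var, output_var)
    return tensor_from_counts(
        counts, data.alphabet(input_var), data.alphabet(output_var), alpha
    )


def estimate_joint(
    data: DiscreteDataset, var1: str, var2: str
) -> JointDistribution:
    """Empirical (unsmoothed) joint distribution of a variable pair."""
    ci, co = data.pair_codes(var1, var2)
    if ci.size == 0:
        raise CapskelError(
            f"no complete observations for pair ({var1!r}, {var2!r})"
        )
    k1, k2 = len(data.alphabet(var1)), len(data.alphabet(var2))
    flat = np.bincount(ci * k2 + co, minlength=k1 * k2).astype(float)
    probs = flat.reshape(k1, k2) / ci.size
    return JointDistribution(data.alphabet(var1), data.alphabet(var2), probs)


# ---------------------------------------------------------------------------
# channel algebra


def reverse_tensor(
    t: StochasticTensor, input_marginal: np.ndarray
) -> StochasticTensor:
    """Bayes-invert a channel to traverse the path backwards.

    Given ``A[x, y] = p(y | x)`` and a strictly positive input marginal
    ``p_x``, returns the dagger tensor ``A‡[y, x] = p_x A[x, y] / p_y`` with
    ``p_y = sum_x p_x A[x, y]``.  The pair satisfies
    ``p_x = sum_y p_y A‡[y, x]``.  Note ``A‡`` is *not* the matrix inverse
    of ``A``: the inverse of a stochastic matrix is in general not
    stochastic and so does not represent a channel.
    """
    px = np.asarray(input_marginal, dtype=float)
    if px.shape != (len(t.input_alphabet),):
        raise AlphabetMismatchError(
            "input marginal length does not match the tensor's input alphabet"
        )
    if np.any(px <= 0):
        raise CapskelError("input marginal must be strictly positive")
    if abs(float(px.sum()) - 1.0) > 1e-9:
        raise CapskelError("input marginal must sum to 1")
    py = px @ t.probs
    if np.any(py <= 0):
        raise CapskelError(
            "reverse tensor undefined: an output symbol has zero marginal"
        )
    rev = (px[:, None] * t.probs).T / py[:, None]
    return StochasticTensor(
        input_alphabet=t.output_alphabet,
        output_alphabet=t.input_alphabet,
        probs=rev,
    )


def compose_path_tensor(
    tensors: Sequence[StochasticTensor],
) -> StochasticTensor:
    """Tensor of a multi-hop path: the matrix product of its links.

    For a chain X -> Y -> Z with link tensors A and B the end-to-end tensor
    is ``C = A @ B``; the same identity composes longer paths hop by hop.
    Composed tensors carry no counts or confidence bounds - their sampling
    uncertainty is handled by the bootstrap in :mod:`capskel.stats`.
    """
    if len(tensors) == 0:
        raise CapskelError("cannot compose an empty list of tensors")
    for left, right in zip(tensors, tensors[1:]):
        if left.output_alphabet.symbols != right.input_alphabet.symbols:
            raise AlphabetMismatchError(
                "output alphabet of one link must equal the input alphabet "
                "of the next"
            )
    probs = reduce(np.matmul, (t.probs for t in tensors))
    # guard against accumulated round-off in long products
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return StochasticTensor(
        input_alphabet=tensors[0].input_alphabet,
        output_alphabet=tensors[-1].output_alphabet,
        probs=probs,
    )


def joint_name(member_vars: Sequence[str]) -> str:
    """Deterministic label of the derived joint variable for a mediator set."""
    return "(" + "+".join(member_vars) + ")"


def joint_variable(
    data: DiscreteDataset, member_vars: Sequence[str]
) -> DiscreteDataset:
    """Add a derived variable whose symbols are tuples of member symbols.

    A mediator on a path may be a *set* of variables; the set is treated as
    one channel terminal by forming the tuple-valued joint variable.  Its
    alphabet is the lexicographically ordered set of observed tuples (not
    the full product space).  A sample missing any member is missing in the
    joint variable.  The original columns are untouched.
    """
    if len(member_vars) == 0:
        raise CapskelError("a joint variable needs at least one member")
    if len(set(member_vars)) != len(member_vars):
        raise CapskelError("joint variable members must be distinct")
    for m in member_vars:
        if m not in data.variable_names:
            raise UnknownVariableError(f"unknown member variable {m!r}")
    name = joint_name(member_vars)
    if name in data.variable_names:
        raise CapskelError(f"derived variable name {name!r} already exists")
    frame = data.frame
    cols = [frame[m] for m in member_vars]
    joined = []
    for row in zip(*cols):
        joined.append(None if any(v is None for v in row) else JOINT_SEP.join(row))
    frame[name] = joined
    return DiscreteDataset(frame)


@dataclass(frozen=True)
class CellViolation:
    """One cell of a candidate tensor that falls outside the direct
    tensor's confidence band."""

    input_symbol: str
    output_symbol: str
    value: float
    ci_low: float
    ci_high: float
    margin: float


@dataclass(frozen=True)
class TensorComparison:
    """Verdict of a cellwise confidence-band equality test."""

    equal: bool
    violations: tuple[CellViolation, ...]


def tensor_equal_within_ci(
    direct: StochasticTensor, candidate: StochasticTensor
) -> TensorComparison:
    """Does a candidate (e.g., composed) tensor agree with a direct one?

    The verdict is TRUE iff *every* cell of ``candidate.probs`` lies inside
    the corresponding Jeffreys band ``[ci_low, ci_high]`` of the directly
    estimated tensor.  When the association between the endpoints is fully
    explained by an indirect path, the composed tensor of that path is a
    consistent estimate of the direct one and should sit inside the band;
    a genuinely direct mechanism pushes cells outside it.
    """
    if (
        direct.input_alphabet.symbols != candidate.input_alphabet.symbols
        or direct.output_alphabet.symbols != candidate.output_alphabet.symbols
    ):
        raise AlphabetMismatchError(
            "direct and candidate tensors must share both alphabets"
        )
    if not direct.has_ci:
        raise MissingConfidenceError(
            "the direct tensor carries no confidence bounds"
        )
    lo, hi = direct.ci_low, direct.ci_high
    violations = []
    for i, s_in in enumerate(direct.input_alphabet.symbols):
        for j, s_out in enumerate(direct.output_alphabet.symbols):
            v = float(candidate.probs[i, j])
            if v < lo[i, j] or v > hi[i, j]:
                margin = max(lo[i, j] - v, v - hi[i, j])
                violations.append(
                    CellViolation(
                        input_symbol=s_in,
                        output_symbol=s_out,
                        value=v,
                        ci_low=float(lo[i, j]),
                        ci_high=float(hi[i, j]),
                        margin=float(margin),
                    )
                )
    return TensorComparison(equal=not violations, violations=tuple(violations))
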