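"""Information measures on channels: mutual information, path information,
and channel capacity via Blahut-Arimoto.

All quantities are in bits (log base 2).  Capacity is the maximum mutual
information between channel input and output over input distributions; it
is zero iff all rows of the transition matrix are identical, which is the
operational criterion for "no information can flow across this edge".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel import JointDistribution, StochasticTensor
from .errors import AlphabetMismatchError, CapskelError

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CapacityResult:
    """Outcome of a Blahut-Arimoto run.

    ``capacity`` is the lower capacity bound at termination; when
    ``converged`` is set it is within the requested tolerance of the true
    maximum because the algorithm maintains a monotone upper/lower bound
    pair.
    """

    capacity: float
    optimal_input: np.ndarray
    iterations: int
    converged: bool


def _mi_bits(joint: np.ndarray) -> float:
    """Mutual information of a joint probability matrix, in bits.

    ``0 * log(0/q)`` terms are treated as 0.
    """
    px = joint.sum(axis=1)
    pz = joint.sum(axis=0)
    mask = joint > 0
    outer = px[:, None] * pz[None, :]
    terms = joint[mask] * np.log2(joint[mask] / outer[mask])
    return max(float(terms.sum()), 0.0)


def mutual_information(joint: JointDistribution) -> float:
    """I(X;Z) of a joint distribution, in bits.

    Equals ``sum_{x,z} p(x,z) log2[ p(x,z) / (p(x) p(z)) ]``; nonnegative,
    and zero iff the joint factorizes.
    """
    if abs(float(joint.probs.sum()) - 1.0) > 1e-9:
        raise CapskelError("joint distribution is not normalized")
    return _mi_bits(joint.probs)


def path_information(
    input_marginal: np.ndarray, path_tensor: StochasticTensor
) -> float:
    """Mutual information between the endpoints of a path, in bits.

    The path tensor (the composed transition matrix of the path's links)
    and the input marginal induce the endpoint joint
    ``p(x,z) = p_x T[x,z]`` and output marginal ``p_z``; the value is the
    mutual information of that induced joint.  For a three-variable chain
    X -> Y -> Z this equals I(X;Z) of the population joint.
    """
    px = np.asarray(input_marginal, dtype=float)
    if px.shape != (len(path_tensor.input_alphabet),):
        raise AlphabetMismatchError(
            "marginal length does not match the path tensor's input alphabet"
        )
    if np.any(px < 0) or abs(float(px.sum()) - 1.0) > 1e-9:
        raise CapskelError("input marginal must be a probability vector")
    joint = px[:, None] * path_tensor.probs
    return _mi_bits(joint)


def blahut_arimoto(
    t: StochasticTensor,
    tolerance: float = 1e-9,
    max_iterations: int = 10_000,
) -> CapacityResult:
    """Channel capacity of a transition matrix, in bits.

    Standard alternating maximization starting from the uniform input
    distribution.  Each iteration computes the per-input divergences
    ``D(x) = D(P[x, .] || q)`` against the current output distribution
    ``q``; ``sum_x r(x) D(x)`` is a lower bound on capacity and
    ``max_x D(x)`` an upper bound, and the iteration stops when their gap
    drops below ``tolerance`` (bits) or after ``max_iterations``.
    """
    if tolerance <= 0:
        raise CapskelError("tolerance must be positive")
    caps, inputs, iters, conv = _blahut_arimoto_batch(
        t.probs[None, :, :], tolerance, max_iterations
    )
    return CapacityResult(
        capacity=float(caps[0]),
        optimal_input=inputs[0],
        iterations=int(iters),
        converged=bool(conv[0]),
    )


def _blahut_arimoto_batch(
    probs: np.ndarray, tolerance: float, max_iterations: int
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Run Blahut-Arimoto on a stack of channels simultaneously.

    ``probs`` has shape ``(B, K_in, K_out)``; returns capacities (bits),
    optimal inputs, the iteration count, and per-channel convergence flags.
    Used for permutation nulls and bootstrap replicates, where hundreds of
    small channels are evaluated at once.
    """
    P = np.asarray(probs, dtype=float)
    if P.ndim != 3:
        raise CapskelError("batch of channels must be a 3-d array")
    if np.any(P < 0) or np.max(np.abs(P.sum(axis=2) - 1.0)) > 1e-9:
        raise CapskelError("every channel must be row-stochastic")
    B, k_in, _ = P.shape
    tol_nats = tolerance * _LN2

    # sum_y P log P per row, with 0 log 0 = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0).sum(axis=2)

    r = np.full((B, k_in), 1.0 / k_in)
    lower = np.zeros(B)
    done = np.zeros(B, dtype=bool)
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        q = np.einsum("bi,bio->bo", r, P)
        with np.errstate(divide="ignore"):
            logq = np.where(q > 0, np.log(q), 0.0)
        # rows reaching a zero-probability output have P[.,y] = 0 there,
        # so the masked log is never multiplied by a positive weight
        d = plogp - np.einsum("bio,bo->bi", P, logq)
        lower = np.einsum("bi,bi->b", r, d)
        upper = d.max(axis=1)
        done = (upper - lower) < tol_nats
        if done.all():
            break
        shift = d - upper[:, None]
        r = r * np.exp(shift)
        r = r / r.sum(axis=1, keepdims=True)
    caps = np.maximum(lower / _LN2, 0.0)
    return caps, r, iterations, done


def capacities(
    probs: np.ndarray,
    tolerance: float = 1e-9,
    max_iterations: int = 10_000,
) -> np.ndarray:
    """Capacities (bits) of a ``(B, K_in, K_out)`` stack of channels."""
    caps, _, _, _ = _blahut_arimoto_batch(probs, tolerance, max_iterations)
    return caps


def _mi_from_channel(px: np.ndarray, probs: np.ndarray) -> float:
    return _mi_bits(px[:, None] * probs)


def dpi_gap(
    a: StochasticTensor,
    b: StochasticTensor,
    input_marginal: np.ndarray,
) -> float:
    """Slack of the data processing inequality along a chain, in bits.

    For X -> Y -> Z with link tensors ``a`` and ``b`` and input marginal
    ``p_x``, returns ``min[I(X;Y), I(Y;Z)] - I(X;Z)``, which is always
    nonnegative; it vanishes when an association is carried by a noiseless
    channel.
    """
    if a.output_alphabet.symbols != b.input_alphabet.symbols:
        raise AlphabetMismatchError("tensors are not composable")
    px = np.asarray(input_marginal, dtype=float)
    if px.shape != (len(a.input_alphabet),):
        raise AlphabetMismatchError(
            "marginal length does not match the first tensor's input alphabet"
        )
    if np.any(px < 0) or abs(float(px.sum()) - 1.0) > 1e-9:
        raise CapskelError("input marginal must be a probability vector")
    i_xy = _mi_from_channel(px, a.probs)
    py = px @ a.probs
    i_yz = _mi_from_channel(py, b.probs)
    i_xz = _mi_from_channel(px, a.probs @ b.probs)
    return min(i_xy, i_yz) - i_xz
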