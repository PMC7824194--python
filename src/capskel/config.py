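"""Run configuration shared by the skeleton pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .errors import CapskelError


@dataclass(frozen=True)
class RunConfig:
    """All tunable knobs of a skeleton-discovery run.

    ``alpha`` is both the edge-test significance level and the complement
    of the tensor confidence level (95% Jeffreys bands by default).
    ``capacity_epsilon`` is the floor (bits) a composed path's bootstrap
    lower bound must clear to count as "capacity larger than zero";
    smoothing alone produces capacities of order 1/n, so exact zero is not
    a usable reference.  ``max_path_length`` caps indirect-path length in
    edges.  ``mediator_alphabet_cap`` bounds the observed symbol count of a
    joint mediator variable; beyond it, rows are too thin to test and the
    run refuses with a diagnostic.  ``iterate_prune`` repeats the bivariate
    pruning pass to a fixed point instead of the default single synchronous
    pass.  ``bonferroni`` divides the edge-test level by the number of
    pairs.
    """

    alpha: float = 0.05
    n_permutations: int = 200
    n_bootstrap: int = 200
    capacity_epsilon: float = 1e-3
    max_path_length: int = 4
    mediator_alphabet_cap: int = 64
    seed: int = 0
    iterate_prune: bool = False
    bonferroni: bool = False
    # Bound-gap tolerance for the capacity iterations inside the pipeline's
    # permutation and bootstrap batches.  The capacity lower bound converges
    # several orders of magnitude faster than the upper/lower gap closes, so
    # a 1e-6-bit certificate already pins the value far below Monte-Carlo
    # resolution; the standalone blahut_arimoto keeps its tighter default.
    ba_tolerance: float = 1e-6
    ba_max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise CapskelError("alpha must lie in (0, 1)")
        for name in ("n_permutations", "n_bootstrap", "max_path_length",
                     "mediator_alphabet_cap", "ba_max_iterations"):
            if getattr(self, name) <= 0:
                raise CapskelError(f"{name} must be positive")
        if self.capacity_epsilon < 0:
            raise CapskelError("capacity_epsilon must be nonnegative")
        if self.ba_tolerance <= 0:
            raise CapskelError("ba_tolerance must be positive")

    def to_dict(self) -> dict:
        return asdict(self)
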