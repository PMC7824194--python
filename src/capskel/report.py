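"""Schema of the JSON run report emitted by ``capskel infer``.

A run is fully reproducible from its report: it embeds the configuration,
every derived seed, the estimated edge tensors, and every test verdict
and pruning decision.  :func:`validate_report` parses a report dict
against the schema and raises on any deviation.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict


class ConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float
    n_permutations: int
    n_bootstrap: int
    capacity_epsilon: float
    max_path_length: int
    mediator_alphabet_cap: int
    seed: int
    iterate_prune: bool
    bonferroni: bool
    ba_tolerance: float
    ba_max_iterations: int


class Step1Record(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pair: list[str]
    seed: int
    capacity_fwd: float
    capacity_bwd: float
    p_value_fwd: float | None
    p_value_bwd: float | None
    degenerate: bool
    edge: bool


class Step2Record(BaseModel):
    model_config = ConfigDict(extra="forbid")

    edge: list[str]
    mediator: str
    pruned: bool


class PathRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    path: list[str]
    capacity: float
    significant: bool
    seed: int


class Step3Record(BaseModel):
    model_config = ConfigDict(extra="forbid")

    edge: list[str]
    paths: list[PathRecord]
    n_significant: int
    mediator_set: list[str]
    single_path_recheck: bool
    pruned: bool


class EdgeRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    vertex1: str
    vertex2: str
    capacity: float
    p_value: float | None
    status: str
    pruned_by: list[str] | None


class TensorRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    input_alphabet: list[str]
    output_alphabet: list[str]
    probs: list[list[float]]
    counts: list[list[float]] | None


class RunReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    config: ConfigModel
    n_samples: int
    variables: list[str]
    step1: list[Step1Record]
    step2: list[Step2Record]
    step3: list[Step3Record]
    edges: list[EdgeRecord]
    tensors: dict[str, TensorRecord]


def validate_report(report: dict) -> RunReport:
    """Parse a report dict against the schema; raises on mismatch."""
    return RunReport.model_validate(report)


def report_json_schema() -> dict:
    """The JSON Schema of the run report."""
    return RunReport.model_json_schema()
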