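"""Run configuration: every under-specified modelling choice as a visible knob.

The YAML config gathers the switches that change what a run computes —
the absorption method, the unregulated-gene convention, the combination-
mining tolerance, screen partitioning and seeds — so that a run can be
reproduced from its config file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    #: 'linear_solve' (exact) or 'power_iteration' (the 99.99% stopping rule)
    absorption_method: str = "linear_solve"
    #: constitutively ON (True) or OFF for genes with no regulators
    unregulated_on: bool = True
    #: max good fraction for a mined combination to classify as "bad"
    bad_tolerance: float = 0.0
    #: Monte-Carlo step cap per run
    mc_step_cap: int = 10_000
    #: screen chunk size (masks per checkpoint chunk)
    screen_chunk_size: int = 65_536
    #: skip the Markov solve for structurally flagged networks
    fast_structural: bool = False
    #: seed for every stochastic component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.absorption_method not in ("linear_solve", "power_iteration"):
            raise ValueError(f"unknown absorption method {self.absorption_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
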