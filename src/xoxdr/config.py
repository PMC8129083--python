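"""Run configuration shared by the CLI and scripted pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Reproducibility and pipeline knobs.

    With a fixed ``seed`` and the exact solver every downstream output is
    bit-for-bit reproducible.  ``sparsity`` is the nonzero probability of
    sparse random-projection columns (None = ``1/sqrt(p)``).
    """

    seed: int = 0
    solver: str = "exact"
    location: str = "median"
    sparsity: float | None = None
    folds: int = 5
    dims: list = field(default_factory=lambda: [1, 2, 3, 5, 10])

    def __post_init__(self):
        if self.solver not in ("exact", "randomized"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.location not in ("mean", "median"):
            raise ValueError(f"unknown location {self.location!r}")
        if self.sparsity is not None and not (0 < self.sparsity <= 1):
            raise ValueError("sparsity must lie in (0, 1]")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML mapping (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
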