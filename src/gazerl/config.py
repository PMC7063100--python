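"""Run configuration: YAML round-trip, seed lists, output layout."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .model_core import ModelSpec

__all__ = ["RunConfig", "load_config", "dump_config", "resolve_seeds"]


class RunConfig(BaseModel):
    """One reproducible run: a model spec, seeds, and output options.

    Seeds may be given either as an explicit ``seeds`` list or as
    ``(seed0, n_seeds)``, which expands to ``seed0 .. seed0 + n_seeds - 1``.
    """

    model_config = ConfigDict(extra="forbid")

    spec: ModelSpec = ModelSpec()
    seeds: Optional[list[int]] = None
    seed0: int = 0
    n_seeds: int = 1
    out_dir: str = "gazerl_out"
    formats: list[str] = ["csv"]
    checkpoints: list[int] = [100, 500, 1000, 2000]

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.seeds is not None and len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be unique")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        for f in self.formats:
            if f not in ("csv", "tsv"):
                raise ValueError(f"unknown output format {f!r} (use csv or tsv)")
        return self

    def resolved_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return list(range(self.seed0, self.seed0 + self.n_seeds))


def resolve_seeds(
    seeds: Optional[Sequence[int]], seed0: int, n_seeds: int
) -> list[int]:
    """Explicit seed list if given, else the contiguous range from seed0."""
    if seeds is not None:
        return [int(s) for s in seeds]
    return list(range(seed0, seed0 + n_seeds))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected; out-of-range parameters raise with the
    offending field named. An empty file yields all defaults.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        bad = ", ".join(
            ".".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ValueError(f"{path}: invalid configuration ({bad})") from err


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration back to YAML (lossless)."""
    data = config.model_dump(mode="json")
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
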