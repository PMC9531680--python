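"""Run configuration: YAML in, validated dataclass out.

Unknown keys and type mismatches are rejected with the offending field
paths; omitted fields receive defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]

_MODULES = ("synth", "patchclass", "vsgd", "seg", "scatnet", "viewbehave",
            "eval")


@dataclass
class RunConfig:
    module: str = "synth"
    seed: int = 0
    device: str = "cpu"
    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.module not in _MODULES:
            raise ValueError(
                f"module: unknown value {self.module!r}; expected one of {_MODULES}")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise TypeError(f"seed: expected integer, got {type(self.seed).__name__}")
        if not isinstance(self.paths, dict):
            raise TypeError(f"paths: expected mapping, got {type(self.paths).__name__}")
        if not isinstance(self.params, dict):
            raise TypeError(f"params: expected mapping, got {type(self.params).__name__}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
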