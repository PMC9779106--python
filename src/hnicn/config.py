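"""Pipeline configuration.

All analysis constants live here and are threaded through the pipeline;
no stage hard-codes them.  Defaults follow the study configuration:
``adj_par=10`` (coverage scale), ``psi=10_000`` (effect damping),
``cse_log_base=2``, connection-type thresholds 20/10/5, and a document
retrieval window of 23 Oct 2019 -- 1 Feb 2022 (inclusive on both ends).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ClassThresholds:
    """Degree cut-points for the four connection types.

    ``full`` iff degree >= full; ``wide-range`` iff wide <= degree < full;
    ``small-range`` iff small <= degree < wide; ``scatter`` otherwise.
    """

    full: int = 20
    wide: int = 10
    small: int = 5

    def __post_init__(self) -> None:
        if not (self.full > self.wide > self.small > 0):
            raise ValueError(
                f"thresholds must be strictly decreasing and positive, "
                f"got full={self.full}, wide={self.wide}, small={self.small}"
            )


@dataclass
class PipelineConfig:
    adj_par: float = 10.0
    psi: float = 10_000.0
    cse_log_base: float = 2.0
    class_thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    window_start: date = date(2019, 10, 23)
    window_end: date = date(2022, 2, 1)
    #: per-column vs global min-max for the mention matrix
    normalization_scope: str = "column"
    top_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adj_par <= 0:
            raise ValueError(f"adj_par must be positive, got {self.adj_par}")
        if self.psi <= 0:
            raise ValueError(f"psi must be positive, got {self.psi}")
        if self.cse_log_base <= 1:
            raise ValueError(f"cse_log_base must exceed 1, got {self.cse_log_base}")
        if self.normalization_scope not in ("column", "global"):
            raise ValueError(
                f"normalization_scope must be 'column' or 'global', "
                f"got {self.normalization_scope!r}"
            )
        if self.window_start > self.window_end:
            raise ValueError("retrieval window start is after its end")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_thresholds"] = dataclasses.asdict(self.class_thresholds)
        d["window_start"] = self.window_start.isoformat()
        d["window_end"] = self.window_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "class_thresholds" in d:
            d["class_thresholds"] = ClassThresholds(**d["class_thresholds"])
        for key in ("window_start", "window_end"):
            if key in d and isinstance(d[key], str):
                d[key] = date.fromisoformat(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
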