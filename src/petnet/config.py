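"""Run configuration: the fixed analysis choices, serializable to JSON."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Analysis settings shared by network build, metrics, and comparison.

    Defaults follow the study conventions this package implements: age and
    sex regressed out, density 0.5 ("density 50"), 1000 permutations,
    20 rewired nulls for sigma, 10 Louvain restarts, q < 0.05.
    """

    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    density: float = 0.5
    n_perm: int = 1000
    n_null_sigma: int = 20
    modularity_restarts: int = 10
    q_threshold: float = 0.05
    seed: int = 0
    weighted_mode: bool = False
    pooled_residualization: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if not 0.0 < self.q_threshold <= 1.0:
            raise ValueError("q_threshold must be in (0, 1]")
        for name in ("n_perm", "n_null_sigma", "modularity_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def config_hash(self) -> str:
        """Short stable digest naming this configuration in output files."""
        canon = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:12]
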