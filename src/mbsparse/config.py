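"""Pipeline configuration and deterministic per-stage seed derivation."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .cvae import CVAEConfig
from .fae import FAEConfig

__all__ = ["PipelineConfig", "derive_seed", "VARIANTS"]

VARIANTS = ("full", "no_fae", "no_cvae", "neither")


def derive_seed(global_seed: int, stage: str, replicate: int = 0) -> int:
    """Stable per-stage seed: sha256 of "seed:stage:replicate", folded to 31 bits.

    Adding stages never perturbs other stages' random streams, and distinct
    (stage, replicate) labels get independent seeds.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}:{replicate}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, seedable from one integer.

    Stage seeds (FAE init/shuffling, CVAE init/shuffling/MC noise, generation
    draws) are derived from ``seed`` by stage name, so two runs with the same
    config are identical and changing one stage's knobs leaves the other
    stages' streams untouched.
    """

    target_library_size: float = 1e6
    normalize_method: str = "log_tss"  # "log_tss" or "none"
    fae: FAEConfig = field(default_factory=FAEConfig)
    cvae: CVAEConfig = field(default_factory=CVAEConfig)
    k: int = 5
    variant: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    def resolve_seeds(self, replicate: int = 0) -> "PipelineConfig":
        """Return a copy with per-stage seeds derived from the global seed."""
        cfg = PipelineConfig.from_dict(self.to_dict())
        cfg.fae.seed = derive_seed(self.seed, "fae", replicate)
        cfg.cvae.seed = derive_seed(self.seed, "cvae", replicate)
        return cfg

    def generation_seed(self, replicate: int = 0) -> int:
        return derive_seed(self.seed, "generate", replicate)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        fae = FAEConfig(**data.pop("fae", {}))
        cvae = CVAEConfig(**data.pop("cvae", {}))
        return cls(fae=fae, cvae=cvae, **data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
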