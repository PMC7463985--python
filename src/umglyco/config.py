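"""Run configuration with documented defaults and YAML round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .imaging import DEFAULT_STAIN_VECTORS

__all__ = ["RunConfig"]


def _default_stains() -> dict:
    return {
        "pas": list(DEFAULT_STAIN_VECTORS.pas),
        "background": list(DEFAULT_STAIN_VECTORS.background),
        "pigment": list(DEFAULT_STAIN_VECTORS.pigment),
    }


@dataclass
class RunConfig:
    """All tunable pipeline parameters.

    Every field has a default; a config file only needs the fields it
    overrides.  ``fish_median_pct`` / ``fish_median_index`` replace the
    cohort-derived FISH medians (e.g. 31.94 / 1.01 to reproduce an
    externally established classification); ``bonferroni_m`` overrides
    the Bonferroni multiplier (default: number of panel genes tested).
    """

    stains: dict = field(default_factory=_default_stains)
    gmin: int = 104
    fish_median_pct: float | None = None
    fish_median_index: float | None = None
    alpha: float = 0.05
    bonferroni_m: int | None = None
    seed: int = 0
    outdir: str = "umglyco_out"
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the analysis parameters, logged for provenance.

        Excludes ``outdir`` and ``paths`` so the same parameters hash the
        same wherever the inputs and outputs live.
        """
        params = {
            k: v for k, v in asdict(self).items() if k not in ("outdir", "paths")
        }
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @property
    def stain_vectors(self):
        from .imaging import StainVectors

        return StainVectors(
            pas=tuple(self.stains["pas"]),
            background=tuple(self.stains["background"]),
            pigment=tuple(self.stains["pigment"]),
        )
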