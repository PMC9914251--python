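"""Run configuration: YAML-backed defaults for every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import Roi

__all__ = ["RunConfig", "load_config", "parse_roi"]


def parse_roi(spec) -> Roi | None:
    """Parse ``slice,row0,row1,col0,col1`` (string or 5-sequence) into a Roi."""
    if spec is None:
        return None
    if isinstance(spec, Roi):
        return spec
    if isinstance(spec, str):
        spec = [int(v) for v in spec.replace(",", " ").split()]
    vals = [int(v) for v in spec]
    if len(vals) != 5:
        raise ValueError("ROI spec must be slice,row0,row1,col0,col1")
    return Roi(*vals)


@dataclass
class RunConfig:
    """Bundle of stage parameter dictionaries plus the RNG seed.

    Sections mirror the CLI subcommands (``thermo``, ``qc``, ``acoustic``,
    ``protocol``, ``simulate``, ...); the seed is recorded in every output
    manifest.  The thermometry coefficient, if given, must be negative.
    """

    sections: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        alpha = self.sections.get("thermo", {}).get("alpha_ppm_per_C")
        if alpha is not None and alpha >= 0:
            raise ValueError("thermo.alpha_ppm_per_C must be negative")

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    def as_dict(self) -> dict:
        return {"seed": self.seed, **self.sections}


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    seed = raw.pop("seed", None)
    return RunConfig(sections=raw, seed=seed)
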