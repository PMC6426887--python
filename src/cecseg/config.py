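"""Single-file pipeline configuration (YAML or JSON).

Sections map onto the parameter dataclasses of each stage; unknown keys
are rejected so silent typos cannot change a run.  One global seed derives
per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

from .density import ScaleCalibration
from .postprocess import PostprocessParams
from .preprocess import PreprocessParams
from .unet import UNetConfig
from .vincent import VincentParams

__all__ = ["PipelineConfig", "load_config", "SEED_OFFSETS"]

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"synth": 11, "split": 23, "unet": 37}

_DEFAULT_SYNTH = {
    "n": 40,
    "density_range": [500.0, 3000.0],
    "ungradable_fraction": 0.1,
    "degraded_fraction": 0.3,
    "guttae_fraction": 0.2,
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessParams = PreprocessParams()
    unet: UNetConfig = UNetConfig()
    postprocess: PostprocessParams = PostprocessParams()
    vincent: VincentParams = VincentParams()
    density: ScaleCalibration = ScaleCalibration()
    synth: dict = dataclasses.field(default_factory=lambda: dict(_DEFAULT_SYNTH))
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return self.seed + SEED_OFFSETS[stage]

    def digest(self) -> str:
        payload = {
            name: dataclasses.asdict(getattr(self, name))
            if dataclasses.is_dataclass(getattr(self, name))
            else getattr(self, name)
            for name in ("preprocess", "unet", "postprocess", "vincent", "density", "synth", "seed")
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


_SECTIONS = {
    "preprocess": PreprocessParams,
    "unet": UNetConfig,
    "postprocess": PostprocessParams,
    "vincent": VincentParams,
    "density": ScaleCalibration,
}


def load_config(path: str | None = None) -> PipelineConfig:
    """Load a YAML/JSON config; missing sections take defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path!r} must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"synth", "seed"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - fields
        if bad:
            raise ValueError(f"unknown key(s) in section {name!r}: {sorted(bad)}")
        kwargs[name] = cls(**section)
    synth = dict(_DEFAULT_SYNTH)
    bad = set(raw.get("synth", {})) - set(synth)
    if bad:
        raise ValueError(f"unknown key(s) in section 'synth': {sorted(bad)}")
    synth.update(raw.get("synth", {}))
    return PipelineConfig(synth=synth, seed=int(raw.get("seed", 0)), **kwargs)
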