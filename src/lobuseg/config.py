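"""YAML configuration handling for the command-line pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import PreprocessParams
from .segmentation import SegmentationParams
from .types import ParameterError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything the end-to-end ``run`` pipeline needs.

    Every parameter has a documented default (see :class:`PreprocessParams`
    and :class:`SegmentationParams`); a YAML file overrides per block:

    .. code-block:: yaml

        spacing: [10, 10, 20]
        downscale: [1, 1, 1]
        preprocess:
          box_radius: [1, 1, 1]
          variance_epsilon: 1.0
        segmentation:
          distance_threshold: 25.0
          merge_threshold: 0.3
        graph:
          weight_threshold: 0.1
    """

    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    downscale: tuple[int, int, int] = (1, 1, 1)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    graph_weight_threshold: float = 0.1
    use_sla: bool = True
    debug: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "spacing": list(self.spacing),
            "downscale": list(self.downscale),
            "preprocess": dataclasses.asdict(self.preprocess),
            "segmentation": dataclasses.asdict(self.segmentation),
            "graph": {"weight_threshold": self.graph_weight_threshold},
            "use_sla": self.use_sla,
            "debug": self.debug,
            "seed": self.seed,
        }


def _build(cls, block: dict, what: str):
    fields = set(cls.__dataclass_fields__)
    unknown = set(block) - fields
    if unknown:
        raise ParameterError(f"unknown {what} parameter(s): {sorted(unknown)}")
    kwargs = dict(block)
    for key, value in kwargs.items():
        if isinstance(value, list):
            kwargs[key] = tuple(value)
    return cls(**kwargs)


def load_config(path=None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; missing keys take their defaults."""
    raw = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ParameterError(f"config file does not exist: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        preprocess=_build(PreprocessParams, raw.get("preprocess", {}), "preprocess"),
        segmentation=_build(
            SegmentationParams, raw.get("segmentation", {}), "segmentation"
        ),
    )
    if "spacing" in raw:
        cfg.spacing = tuple(float(v) for v in raw["spacing"])
    if "downscale" in raw:
        cfg.downscale = tuple(int(v) for v in raw["downscale"])
    graph_block = raw.get("graph", {})
    if "weight_threshold" in graph_block:
        cfg.graph_weight_threshold = float(graph_block["weight_threshold"])
    if "use_sla" in raw:
        cfg.use_sla = bool(raw["use_sla"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    return cfg
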