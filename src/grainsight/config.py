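"""YAML configuration loading for the command-line interface.

A config file may define any of the sections ``anchors``, ``suppress``,
``pspm``, ``model``, ``train`` and ``scene``; omitted keys fall back to the
package defaults (which mirror the published pipeline settings).

Example::

    anchors: {scales: [8, 16, 24, 32, 48], ratios: [1.0, 0.5, 2.0], stride: 4}
    suppress: {mode: gaussian, Nt: 0.3, sigma: 0.5, floor: 0.001}
    pspm: {k: 3}
    model: {arch: tiny}
    train: {lr: 0.0005, epochs: 100, weight_decay: 0.0005, seed: 0}
    scene: {width: 160, height: 160, count_range: [3, 8]}
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .anchors import AnchorConfig
from .detector import TrainConfig
from .suppression import SuppressionConfig
from .synthetic import SceneConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclasses.dataclass
class PipelineConfig:
    anchors: AnchorConfig
    suppress: SuppressionConfig
    train: TrainConfig
    scene: SceneConfig
    arch: str = "tiny"
    pspm_k: int = 3


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path=None) -> PipelineConfig:
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}

    a = _tupled(raw.get("anchors", {}))
    arch = raw.get("model", {}).get("arch", "tiny")
    if "stride" not in a:
        a["stride"] = 4 if arch == "tiny" else 16
    anchors = AnchorConfig(**a)

    s = raw.get("suppress", {})
    suppress = SuppressionConfig(
        mode=s.get("mode", "gaussian"),
        nt=s.get("Nt", s.get("nt", 0.3)),
        sigma=s.get("sigma", 0.5),
        score_floor=s.get("floor", s.get("score_floor", 0.001)),
    )

    train = TrainConfig(**raw.get("train", {}))
    scene = SceneConfig(**_tupled(raw.get("scene", {})))
    return PipelineConfig(
        anchors=anchors,
        suppress=suppress,
        train=train,
        scene=scene,
        arch=arch,
        pspm_k=raw.get("pspm", {}).get("k", 3),
    )
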