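"""Mapping metric values onto the 1-5 quality scale and aggregating them.

Every metric is scored onto the ordinal range 1..5 by threshold bands
(1 "not acceptable", 3 "minimally acceptable", 5 "exceeds the
requirements").  Subcharacteristic scores are weighted means of metric
scores; characteristic scores are weighted means of subcharacteristic
scores.  A metric may feed any number of subcharacteristics and a
subcharacteristic any number of characteristics — the quality model is a
weighted many-to-many mapping loaded from YAML/JSON configuration.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .metrics import METRIC_NAMES, MetricVector, compute_metrics
from .owl_model import OntologyGraph

_DIRECTIONS = ("higher_better", "lower_better")


class ConfigError(ValueError):
    """Raised for an invalid quality-model configuration."""


@dataclass(frozen=True)
class MetricScale:
    """Direction and threshold bands for one metric."""

    direction: str
    bands: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ConfigError(f"direction must be one of {_DIRECTIONS}, got {self.direction!r}")
        bands = tuple(float(b) for b in self.bands)
        if len(bands) != 4 or any(b >= c for b, c in zip(bands, bands[1:])):
            raise ConfigError(f"bands must be 4 strictly increasing cut points, got {self.bands!r}")
        object.__setattr__(self, "bands", bands)


def _normalize_weights(entries: Mapping[str, float], owner: str) -> dict[str, float]:
    weights = {k: float(v) for k, v in entries.items()}
    if not weights:
        raise ConfigError(f"{owner!r} has no contributing entries")
    if any(w < 0 for w in weights.values()):
        raise ConfigError(f"{owner!r} has a negative weight")
    total = sum(weights.values())
    if total <= 0:
        raise ConfigError(f"{owner!r} has all-zero weights")
    if abs(total - 1.0) < 1e-9:  # already normalized: keep bytes stable for round-trips
        return weights
    return {k: w / total for k, w in weights.items()}


@dataclass(frozen=True)
class QualityModelConfig:
    """The quality model: metric scales plus the two aggregation layers.

    Weights are normalized to sum to 1 within each entry at construction.
    """

    metrics: Mapping[str, MetricScale]
    subcharacteristics: Mapping[str, Mapping[str, float]]
    characteristics: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        metrics = dict(self.metrics)
        unknown = set(metrics) - set(METRIC_NAMES)
        if unknown:
            raise ConfigError(f"unknown metrics in config: {sorted(unknown)}")
        subs = {}
        for name, entries in self.subcharacteristics.items():
            entries = _normalize_weights(entries, name)
            missing = set(entries) - set(metrics)
            if missing:
                raise ConfigError(f"subcharacteristic {name!r} references undefined metrics {sorted(missing)}")
            subs[name] = entries
        chars = {}
        for name, entries in self.characteristics.items():
            entries = _normalize_weights(entries, name)
            missing = set(entries) - set(subs)
            if missing:
                raise ConfigError(
                    f"characteristic {name!r} references undefined subcharacteristics {sorted(missing)}"
                )
            chars[name] = entries
        object.__setattr__(self, "metrics", metrics)
        object.__setattr__(self, "subcharacteristics", subs)
        object.__setattr__(self, "characteristics", chars)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_mapping(cls, data: Mapping) -> "QualityModelConfig":
        try:
            metrics = {
                name: MetricScale(direction=entry["direction"], bands=tuple(entry["bands"]))
                for name, entry in data["metrics"].items()
            }
            return cls(
                metrics=metrics,
                subcharacteristics=data["subcharacteristics"],
                characteristics=data["characteristics"],
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed quality-model configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path_or_text) -> "QualityModelConfig":
        """Load from a YAML (or JSON, a YAML subset) file path or text."""
        text = path_or_text
        if hasattr(path_or_text, "read_text"):
            text = path_or_text.read_text()
        elif isinstance(path_or_text, str) and "\n" not in path_or_text and path_or_text.endswith(
            (".yaml", ".yml", ".json")
        ):
            with open(path_or_text) as fh:
                text = fh.read()
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError("quality-model configuration must be a mapping")
        return cls.from_mapping(data)

    @classmethod
    def default(cls) -> "QualityModelConfig":
        """The packaged default model (29 subcharacteristics, 7 characteristics)."""
        text = resources.files("oquare.data").joinpath("default_model.yaml").read_text()
        return cls.from_yaml(text)

    def to_mapping(self) -> dict:
        return {
            "metrics": {
                name: {"direction": s.direction, "bands": list(s.bands)} for name, s in self.metrics.items()
            },
            "subcharacteristics": {n: dict(w) for n, w in self.subcharacteristics.items()},
            "characteristics": {n: dict(w) for n, w in self.characteristics.items()},
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_mapping(), sort_keys=True)


def score_metric(value: float, direction: str, bands: Sequence[float]) -> int:
    """Map a metric value onto the ordinal 1..5 scale.

    ``higher_better``: value < b1 -> 1, [b1,b2) -> 2, [b2,b3) -> 3,
    [b3,b4) -> 4, >= b4 -> 5.  ``lower_better`` is the mirror image.
    """
    scale = MetricScale(direction=direction, bands=tuple(bands))
    if not math.isfinite(value):
        raise ValueError(f"metric value must be finite, got {value!r}")
    rank = bisect_right(scale.bands, value)
    return 1 + rank if scale.direction == "higher_better" else 5 - rank


def _weighted_mean(scores: Mapping[str, float], weights: Mapping[str, float], owner: str) -> float:
    weights = _normalize_weights(weights, owner)
    missing = set(weights) - set(scores)
    if missing:
        raise ConfigError(f"{owner!r}: no score for {sorted(missing)}")
    value = sum(w * scores[name] for name, w in weights.items())
    # the exact weighted mean lies in [min, max]; clamp out float drift
    used = [scores[name] for name in weights]
    return min(max(value, min(used)), max(used))


def score_subcharacteristic(metric_scores: Mapping[str, float], weights: Mapping[str, float]) -> float:
    """Weighted mean of metric scores; lies within [min, max] of the inputs."""
    return _weighted_mean(metric_scores, weights, "subcharacteristic")


def score_characteristic(subchar_scores: Mapping[str, float], weights: Mapping[str, float]) -> float:
    """Weighted mean of subcharacteristic scores."""
    return _weighted_mean(subchar_scores, weights, "characteristic")


@dataclass(frozen=True)
class ScoreCard:
    """Scores at all three levels for one ontology, plus the raw metrics."""

    metric_values: MetricVector
    metric_scores: Mapping[str, int]
    subcharacteristic_scores: Mapping[str, float]
    characteristic_scores: Mapping[str, float]
    degenerate: frozenset[str] = frozenset()

    def all_scores(self) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        out.update({("metric", k): float(v) for k, v in self.metric_scores.items()})
        out.update({("subcharacteristic", k): v for k, v in self.subcharacteristic_scores.items()})
        out.update({("characteristic", k): v for k, v in self.characteristic_scores.items()})
        return out

    def rows(self) -> list[tuple[str, str, float]]:
        """Long-format (level, name, score) rows, in stable order."""
        return [
            (level, name, score)
            for (level, name), score in sorted(self.all_scores().items())
        ]

    def to_dict(self) -> dict:
        return {
            "metric_values": self.metric_values.as_dict(),
            "metric_scores": dict(self.metric_scores),
            "subcharacteristic_scores": dict(self.subcharacteristic_scores),
            "characteristic_scores": dict(self.characteristic_scores),
            "degenerate_metrics": sorted(self.degenerate),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def score_vector(mv: MetricVector, config: QualityModelConfig) -> ScoreCard:
    """Score an already-computed metric vector through the quality model.

    Degenerate metrics (zero denominators) score 1 and stay flagged on the
    card rather than aborting the pipeline.
    """
    metric_scores: dict[str, int] = {}
    for name, scale in config.metrics.items():
        if name in mv.degenerate:
            metric_scores[name] = 1
        else:
            metric_scores[name] = score_metric(mv[name], scale.direction, scale.bands)
    sub_scores = {
        name: score_subcharacteristic(metric_scores, weights)
        for name, weights in config.subcharacteristics.items()
    }
    char_scores = {
        name: score_characteristic(sub_scores, weights)
        for name, weights in config.characteristics.items()
    }
    return ScoreCard(
        metric_values=mv,
        metric_scores=metric_scores,
        subcharacteristic_scores=sub_scores,
        characteristic_scores=char_scores,
        degenerate=mv.degenerate,
    )


def evaluate_ontology(
    g: OntologyGraph,
    config: QualityModelConfig | None = None,
    rfc_inherited: bool = False,
) -> ScoreCard:
    """Metric computation + scoring + both aggregation layers in one call."""
    if config is None:
        config = QualityModelConfig.default()
    return score_vector(compute_metrics(g, rfc_inherited=rfc_inherited), config)
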