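"""Pipeline configuration: the method's constants in one validated object.

Defaults reproduce the published operating point: a 45-sample analysis
window with stride 2, a 2.5% SNR gate with a 3 bpm peak half-width, a
50-180 bpm target band, 5 s minimum segments, at most 10 exposure
iterations toward the (190, 230) face-percentile band, and evaluation
splits at 225 valid samples and the [190, 250] exposure interval.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .hr import HRConfig

__all__ = ["ExposureConfig", "DenoiseConfig", "RppgConfig", "EvalConfig", "PipelineConfig"]


@dataclass(frozen=True)
class ExposureConfig:
    target_low: int = 190
    target_high: int = 230
    max_iterations: int = 10
    initial_exposure_ms: float = 10.0


@dataclass(frozen=True)
class DenoiseConfig:
    use_sources: tuple[str, ...] = ()  # empty = all 15 sources
    center: bool = True


@dataclass(frozen=True)
class RppgConfig:
    methods: tuple[str, ...] = ("CHROM", "POS")


@dataclass(frozen=True)
class EvalConfig:
    motion_threshold_samples: int = 225
    exposure_low: float = 190.0
    exposure_high: float = 250.0


@dataclass(frozen=True)
class PipelineConfig:
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    rppg: RppgConfig = field(default_factory=RppgConfig)
    hr: HRConfig = field(default_factory=HRConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    min_segment_seconds: float = 5.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs = {}
        sub = {
            "exposure": ExposureConfig,
            "denoise": DenoiseConfig,
            "rppg": RppgConfig,
            "hr": HRConfig,
            "evaluation": EvalConfig,
        }
        top_fields = {f.name for f in fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, sub_cls in sub.items():
            if name in data:
                sub_data = dict(data.pop(name) or {})
                valid = {f.name for f in fields(sub_cls)}
                bad = set(sub_data) - valid
                if bad:
                    raise ValueError(f"unknown config keys under {name!r}: {sorted(bad)}")
                for k, v in sub_data.items():
                    if isinstance(v, list):
                        sub_data[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                kwargs[name] = sub_cls(**sub_data)
        for k, v in data.items():
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
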