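"""Pipeline configuration: defaults, YAML/TOML loading, and hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ConfigurationError
from .peaks import BitePolicy
from .processing import DEFAULT_SPEED_BANDS, LpfSpec


@dataclass
class PipelineConfig:
    """Everything tunable between a landmark track and a chew count."""

    lpf: LpfSpec = field(default_factory=LpfSpec)
    wavelet: str = "db2"
    speed_bands_hz: dict = field(default_factory=lambda: dict(DEFAULT_SPEED_BANDS))
    dwd_count_on: str = "coefficients"  # or "reconstruction"
    bite_factor: float = 2.5
    bite_exclusion: bool = True
    baseline_window_s: float | None = 10.0
    include_bites_in_mph: bool = False
    gap_policy: str = "linear"

    def bite_policy(self) -> BitePolicy:
        return BitePolicy(bite_factor=self.bite_factor, enabled=self.bite_exclusion)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lpf"] = asdict(self.lpf)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        lpf = d.pop("lpf", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if lpf is not None:
            cfg.lpf = LpfSpec(**lpf)
        if cfg.dwd_count_on not in ("reconstruction", "coefficients"):
            raise ConfigurationError("dwd_count_on must be 'reconstruction' or 'coefficients'")
        return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a YAML or TOML config file; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(path.read_text()) or {}
    elif path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        raise ConfigurationError(f"unsupported config format {path.suffix!r}")
    return PipelineConfig.from_dict(data)
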