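"""Run configuration: defaults, YAML round trip, per-stage seed derivation."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


def seed_for(master: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from a master seed.

    The stage label is hashed with CRC-32 and xor-ed into the master seed;
    the result is masked to 31 bits so it is a valid seed everywhere.
    """
    return (int(master) ^ zlib.crc32(stage.encode("utf-8"))) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Every knob of the pipeline, with defaults; YAML round-trips losslessly."""

    kernels: tuple = ("left", "centered", "right")
    measures: tuple = ("rmse", "mae", "std")
    k_min: int = 2
    k_max: int | None = None  # None -> floor(M/2) - 1 per signal
    seed: int = 0
    compare_to: str = "reconstruction"
    drift_form: str = "affine"
    mode: str = "window"
    # synthetic-ensemble parameters
    amplitude: float = 1.0
    tau_ref: float = 80.0
    m: int = 1200
    dt: float = 1.0
    noise_mean: float = 0.0
    noise_sd: float = 2e-3
    outdir: str = "stochreg-out"

    def k_range(self, m: int) -> range:
        hi = self.k_max if self.k_max is not None else m // 2 - 1
        return range(self.k_min, hi + 1)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["kernels"] = list(self.kernels)
        data["measures"] = list(self.measures)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kernels", "measures"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
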