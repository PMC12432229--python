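"""Run configuration: validated defaults, YAML round-trip, seed fan-out.

Every threshold default is the mapping method's published operating point:
fusion presence/shape thresholds 0.6/0.5, water persistence and deposit
water-coverage limits of 20%, a 5-hole maximum per deposit, the 10 km hex
grid, the 512 m evaluation grid, and hotspot significance alpha = 0.002.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .segmentation import SegModelConfig
from .synthetic_scene import LandscapeConfig


class ConfigValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    model: SegModelConfig = field(default_factory=SegModelConfig)
    upsample_factor: float = 1.0        # bicubic pre-training upsampling (3 at full scale)
    t_presence: float = 0.6
    t_shape: float = 0.5
    water_persistence: float = 0.2
    max_water_fraction: float = 0.2
    max_holes: int = 5
    hex_cell_m: float = 10_000.0
    eval_cell_m: float = 512.0
    n_permutations: int = 999
    lisa_alpha: float = 0.002
    hdi_mass: float = 0.95
    n_train_patches: int = 80
    n_areas: int = 10
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "t_presence": 0 < self.t_presence <= 1,
            "t_shape": 0 < self.t_shape <= self.t_presence,
            "water_persistence": 0 <= self.water_persistence < 1,
            "max_water_fraction": 0 <= self.max_water_fraction <= 1,
            "max_holes": self.max_holes >= 0,
            "hex_cell_m": self.hex_cell_m > 0,
            "eval_cell_m": self.eval_cell_m > 0,
            "n_permutations": self.n_permutations >= 1,
            "lisa_alpha": 0 < self.lisa_alpha <= 1,
            "hdi_mass": 0 < self.hdi_mass < 1,
            "upsample_factor": self.upsample_factor >= 1,
        }
        for key, ok in checks.items():
            if not ok:
                raise ConfigValidationError(f"invalid value for '{key}': {getattr(self, key)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["landscape"] = self.landscape.to_dict()
        d["split_fractions"] = list(self.split_fractions)
        return d


_NESTED = {"landscape", "model"}


def _build_landscape(d: dict) -> LandscapeConfig:
    from .synthetic_scene import CLASS_NAMES, LandscapeConfig

    d = dict(d)
    if "spectra" in d and d["spectra"] and isinstance(next(iter(d["spectra"])), str):
        d["spectra"] = {CLASS_NAMES.index(k): tuple(v) for k, v in d["spectra"].items()}
    if "river_mouths" in d:
        d["river_mouths"] = [(float(x), bool(f)) for x, f in d["river_mouths"]]
    if "extent_m" in d:
        d["extent_m"] = tuple(d["extent_m"])
    if "size_lognormal_params" in d:
        d["size_lognormal_params"] = {k: tuple(v) for k, v in d["size_lognormal_params"].items()}
    _check_keys(d, LandscapeConfig, "landscape")
    return LandscapeConfig(**d)


def _check_keys(d: dict, cls, prefix: str) -> None:
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigValidationError(f"unknown key '{prefix}.{sorted(unknown)[0]}'")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing keys take the defaults,
    unknown keys are rejected with the offending key named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigValidationError("configuration root must be a mapping")
    kwargs = {}
    for key, val in raw.items():
        if key == "landscape":
            kwargs["landscape"] = _build_landscape(val or {})
        elif key == "model":
            _check_keys(val or {}, SegModelConfig, "model")
            kwargs["model"] = SegModelConfig(**(val or {}))
        else:
            known = {f.name for f in fields(RunConfig)}
            if key not in known:
                raise ConfigValidationError(f"unknown key '{key}'")
            kwargs[key] = tuple(val) if key == "split_fractions" else val
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived by hashing."""
    digest = hashlib.blake2b(f"{stage}:{global_seed}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)
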