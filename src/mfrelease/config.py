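"""TOML run configuration with validated defaults."""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ConfigError
from .regimes import regime_presets

__all__ = ["RunConfig", "load_config", "DEFAULTS"]


@dataclass
class RunConfig:
    """Validated run parameters (all fields have model defaults)."""

    r: float = 0.5
    tau0: float = 0.0
    n_modes: int = 64
    tau_max: float = 50.0
    tau_step: float = 0.01
    threshold_rel: float = 0.1
    lam: float = 1.0
    f_alpha: float = 2.0
    dt_res: float = 1.0
    omega_max: float = 2.0
    preset: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r < 1.0:
            raise ConfigError(f"r: must be in [0, 1), got {self.r}")
        if self.n_modes < 1:
            raise ConfigError(f"n_modes: must be >= 1, got {self.n_modes}")
        if self.tau_max <= 0 or self.tau_step <= 0:
            raise ConfigError("tau_max and tau_step must be > 0")
        if not 0.0 < self.threshold_rel <= 1.0:
            raise ConfigError(f"threshold_rel: must be in (0, 1], got {self.threshold_rel}")
        if self.lam <= 0 or self.f_alpha <= 0 or self.dt_res <= 0:
            raise ConfigError("lam, f_alpha and dt_res must be > 0")
        if self.omega_max <= 0:
            raise ConfigError(f"omega_max: must be > 0, got {self.omega_max}")
        if self.preset is not None:
            presets = {name: (om, r) for name, om, r in regime_presets()}
            if self.preset not in presets:
                raise ConfigError(
                    f"preset: unknown {self.preset!r}; valid: {sorted(presets)}"
                )
            om, r = presets[self.preset]
            self.omega_max = om
            self.r = r

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULTS = RunConfig().to_dict()
_KNOWN_KEYS = {f.name for f in fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML configuration file.

    Missing keys take the model defaults; unknown keys are rejected with
    their key path.
    """
    path = Path(path)
    try:
        with path.open("rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: TOML parse error: {exc}") from exc
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {', '.join(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
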