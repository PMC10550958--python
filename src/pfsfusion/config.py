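"""Fusion pipeline configuration.

Every knob the method leaves open is collected in :class:`FusionConfig`:
Gaussian smoothing (σ, kernel size), block partition geometry, the
spatial-frequency decision threshold TH, the fuzzy hedge λ, the α search
grid, and the enhancement switch.  Configs load from YAML files with the
same dotted keys the CLI flags use; flags override file values, which
override defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any

import numpy as np
import yaml

from .decomposition import GaussianParams
from .pfs import default_alpha_grid

__all__ = ["FusionConfig", "load_config"]

# dotted config key -> dataclass field
_KEYMAP = {
    "gaussian.sigma": "sigma",
    "gaussian.kernel_size": "kernel_size",
    "block.h": "block_h",
    "block.w": "block_w",
    "detail.th": "th",
    "enhance.lambda": "lambda_hedge",
    "enhance.enabled": "enhance_enabled",
    "alpha.start": "alpha_start",
    "alpha.stop": "alpha_stop",
    "alpha.step": "alpha_step",
}
_FIELD_TO_KEY = {v: k for k, v in _KEYMAP.items()}


@dataclass(frozen=True)
class FusionConfig:
    """All tunable parameters of the fusion pipeline, with defaults.

    Defaults: σ = 5 (kernel derived as 2·ceil(3σ)+1 = 31), 8×8 blocks,
    TH = 0, λ = 2, α grid 0.01…1.00 in steps of 0.01, enhancement on.
    """

    sigma: float = 5.0
    kernel_size: int | None = None
    block_h: int = 8
    block_w: int = 8
    th: float = 0.0
    lambda_hedge: float = 2.0
    alpha_start: float = 0.01
    alpha_stop: float = 1.0
    alpha_step: float = 0.01
    enhance_enabled: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every field against its domain, naming the dotted key on failure."""
        if not (self.sigma > 0):
            raise ValueError(f"gaussian.sigma must be positive, got {self.sigma}")
        if self.kernel_size is not None:
            k = int(self.kernel_size)
            if k < 3 or k % 2 == 0:
                raise ValueError(
                    f"gaussian.kernel_size must be odd and >= 3, got {self.kernel_size}"
                )
        if int(self.block_h) < 1:
            raise ValueError(f"block.h must be a positive integer, got {self.block_h}")
        if int(self.block_w) < 1:
            raise ValueError(f"block.w must be a positive integer, got {self.block_w}")
        if self.th < 0:
            raise ValueError(f"detail.th must be nonnegative, got {self.th}")
        if self.lambda_hedge < 1:
            raise ValueError(f"enhance.lambda must be >= 1, got {self.lambda_hedge}")
        if not (0 < self.alpha_start <= self.alpha_stop <= 1):
            raise ValueError(
                "alpha.start/alpha.stop must satisfy 0 < start <= stop <= 1, "
                f"got start={self.alpha_start}, stop={self.alpha_stop}"
            )
        if self.alpha_step <= 0:
            raise ValueError(f"alpha.step must be positive, got {self.alpha_step}")

    def gaussian_params(self) -> GaussianParams:
        return GaussianParams(sigma=self.sigma, kernel_size=self.kernel_size)

    def alpha_grid(self) -> np.ndarray:
        return default_alpha_grid(self.alpha_start, self.alpha_stop, self.alpha_step)

    def updated(self, overrides: dict[str, Any]) -> "FusionConfig":
        """Return a copy with dotted-key overrides applied (None values skipped)."""
        changes: dict[str, Any] = {}
        for key, value in overrides.items():
            if value is None:
                continue
            if key not in _KEYMAP:
                raise ValueError(f"unknown config key: {key}")
            changes[_KEYMAP[key]] = value
        return replace(self, **changes) if changes else self

    def to_dict(self) -> dict[str, Any]:
        """Flat dotted-key snapshot (for manifests and YAML round trips)."""
        return {
            _FIELD_TO_KEY[f.name]: getattr(self, f.name) for f in fields(self)
        }


def _flatten(mapping: dict[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in mapping.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, f"{dotted}."))
        else:
            flat[dotted] = value
    return flat


def load_config(path: str | None = None,
                overrides: dict[str, Any] | None = None) -> FusionConfig:
    """Build a config from defaults <- YAML file <- explicit overrides.

    The YAML file may use nested sections (``gaussian: {sigma: 3}``) or
    dotted keys (``gaussian.sigma: 3``); both map onto the same fields.
    Out-of-domain values raise :class:`ValueError` naming the key.
    """
    cfg = FusionConfig()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = cfg.updated(_flatten(data))
    if overrides:
        cfg = cfg.updated(overrides)
    return cfg
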