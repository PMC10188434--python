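"""Run configuration: frozen method constants and a flat key=value config file.

Precedence when building a :class:`RunConfig`: CLI flags > config file >
defaults.  The defaults encode the method constants used throughout the
package: RBF shape constant epsilon = 0.1 (work units), IDW power alpha = 3,
vertical divisor 1000, bloom threshold 10 ug/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

#: Depth (m) is divided by this before distances are computed.
VERTICAL_DIVISOR = 1000.0

#: RBF shape constant for the gaussian / multiquadric kernels (work units).
DEFAULT_EPSILON = 0.1

#: IDW power exponent.
DEFAULT_ALPHA = 3.0

#: Chl-a bloom threshold (ug/L); cells strictly above count as bloom area.
BLOOM_THRESHOLD = 10.0

#: Optional detection-limit floor for censored data (ug/L); off by default.
DETECTION_LIMIT = 0.01

METHOD_NAMES = ("rbf-linear", "rbf-gaussian", "rbf-multiquadric", "idw")


@dataclass
class RunConfig:
    """All tunables for a pipeline run."""

    method: str = "rbf-linear"
    epsilon: float = DEFAULT_EPSILON
    alpha: float = DEFAULT_ALPHA
    vertical_divisor: float = VERTICAL_DIVISOR
    grid_resolution_deg: float = 0.05
    layer_depths: tuple = (0.5, 10.0)
    cv_seed: int = 0
    detection_limit: float = DETECTION_LIMIT
    apply_detection_floor: bool = False
    bloom_threshold: float = BLOOM_THRESHOLD
    idw_log_transform: bool = False
    region_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("epsilon", "alpha", "vertical_divisor", "grid_resolution_deg",
                     "detection_limit", "bloom_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.method not in METHOD_NAMES and self.method != "plugin":
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {METHOD_NAMES} or 'plugin'"
            )


def _coerce(raw: str, target_type):
    raw = raw.strip()
    if target_type is bool:
        return raw.lower() in ("1", "true", "yes", "on")
    if target_type is int:
        return int(raw)
    if target_type is float:
        return float(raw)
    if target_type is tuple:
        return tuple(float(v) for v in raw.split(","))
    return raw


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional flat ``key = value`` file plus overrides.

    Lines starting with '#' and blank lines are ignored; unknown keys raise.
    """
    values: dict = {}
    known = {f.name: f for f in fields(RunConfig)}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            target = known[key].type
            base = RunConfig()
            values[key] = _coerce(raw, type(getattr(base, key)))
    for key, val in overrides.items():
        if val is None:
            continue
        if key not in known:
            raise ValueError(f"unknown config override {key!r}")
        values[key] = val
    return RunConfig(**values)
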