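"""Run configuration: thresholds, reference line, output precision.

Defaults encode the published analysis settings: fits are trusted at
R^2 >= 0.8, effects are biologically meaningful at |dS mean| > 0.5
(about 3-fold on an arithmetic scale), and the non-inferiority margin
on the variance-discounted effect is 0.3 (about 2-fold).  All logs are
base 10; this is not configurable because the deposited LAC50 scale and
the fold-change readings of the thresholds are decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Union


@dataclass
class RunConfig:
    reference_cell_line: Optional[str] = None
    r2_threshold: float = 0.8
    r2_mode: str = "per_line"  # or "mean": average test-line R^2 clears the threshold
    ds_mean_threshold: float = 0.5
    variance_floor: float = 0.3
    precision: int = 2
    seed: Optional[int] = None
    eff_floor: Optional[float] = None  # impute EFF for no-response records when set

    #: fixed log base; exposed read-only for provenance echoes
    log_base: int = 10

    def __post_init__(self) -> None:
        for name in ("r2_threshold", "ds_mean_threshold", "variance_floor"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.r2_mode not in ("per_line", "mean"):
            raise ValueError(f"r2_mode must be 'per_line' or 'mean', got {self.r2_mode!r}")
        if self.log_base != 10:
            raise ValueError("log_base is fixed at 10")
        if self.precision < 0:
            raise ValueError("precision must be >= 0")
        if self.eff_floor is not None and not self.eff_floor > 0:
            raise ValueError(f"eff_floor must be positive when set, got {self.eff_floor}")


_FIELD_TYPES = {
    "reference_cell_line": str,
    "r2_threshold": float,
    "r2_mode": str,
    "ds_mean_threshold": float,
    "variance_floor": float,
    "precision": int,
    "seed": int,
    "eff_floor": float,
    "log_base": int,
}


def load_config(path: Union[str, Path]) -> RunConfig:
    """Read a flat ``key = value`` config file into a :class:`RunConfig`.

    Lines starting with ``#`` and blank lines are ignored.  Unknown keys
    are rejected by name rather than silently dropped.
    """
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        caster = _FIELD_TYPES[key]
        values[key] = raw if caster is str else caster(raw)
    return RunConfig(**values)


def dump_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Echo the effective configuration, one ``key = value`` per line."""
    lines = []
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if v is not None:
            lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")
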