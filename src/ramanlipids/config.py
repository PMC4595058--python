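"""Run configuration: a flat key-value text file with strict key checking."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, fields

from .errors import FormatError, ValidationError
from .spectrum import GRID_MIN, GRID_MAX, GRID_STEP

__all__ = ["RunConfig", "read_config"]


@dataclass
class RunConfig:
    """All tunable pipeline constants in one place.

    Windows are (lo, hi) in cm-1 and must lie inside the grid; generator
    constants mirror the synthesis module defaults.
    """

    grid_min_cm1: float = GRID_MIN
    grid_max_cm1: float = GRID_MAX
    grid_step_cm1: float = GRID_STEP
    background_window_cm1: float = 300.0
    window_1440_lo: float = 1380.0
    window_1440_hi: float = 1500.0
    window_1650_lo: float = 1600.0
    window_1650_hi: float = 1700.0
    window_ch_lo: float = 2800.0
    window_ch_hi: float = 3100.0
    protein_threshold_sigma: float = 5.0
    photobleach_max_ratio: float = 0.5
    coupling_532: float = 7.3
    coupling_785: float = 4.2
    bleach_tau_s: float = 25.0
    noise_sd: float = 0.0
    class_threshold_lo: float = 0.35
    class_threshold_hi: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in ((self.window_1440_lo, self.window_1440_hi),
                       (self.window_1650_lo, self.window_1650_hi),
                       (self.window_ch_lo, self.window_ch_hi)):
            if not (self.grid_min_cm1 <= lo < hi <= self.grid_max_cm1):
                raise ValidationError(
                    f"window ({lo}, {hi}) outside grid "
                    f"({self.grid_min_cm1}, {self.grid_max_cm1})")

    def digest(self) -> str:
        """Short hash of the full configuration, logged with every run."""
        blob = ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_text(self) -> str:
        return "".join(f"{k}: {v}\n" for k, v in asdict(self).items())


def read_config(path) -> RunConfig:
    """Parse a flat ``key: value`` config file; unknown keys are errors."""
    known = {f.name: f.type for f in fields(RunConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, val = line.partition(":")
            if not sep:
                key, sep, val = line.partition("=")
            if not sep:
                raise FormatError(f"{path}: line {lineno}: expected key: value")
            key = key.strip()
            if key not in known:
                raise FormatError(f"{path}: line {lineno}: unknown key {key!r}")
            caster = int if key == "seed" else float
            try:
                kwargs[key] = caster(val.strip())
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: bad value for {key}")
    return RunConfig(**kwargs)
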