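"""Run configuration for the characterization pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one characterization run.

    Defaults reproduce the reference pipeline: inclusive threshold at 100,
    no component filtering, EDT radii, voxel-count total-length formula.
    Every value is recorded in the output provenance block.
    """

    threshold: int = 100
    threshold_inclusive: bool = True
    min_component_voxels: int = 0
    radius_mode: str = "edt"           # "edt" | "peel_iterations"
    length_mode: str = "paper"         # "paper" | "edge_sum"
    rng_seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if not (0 <= self.threshold <= 255):
            raise ValueError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.radius_mode not in ("edt", "peel_iterations"):
            raise ValueError(f"unknown radius_mode '{self.radius_mode}'")
        if self.length_mode not in ("paper", "edge_sum"):
            raise ValueError(f"unknown length_mode '{self.length_mode}'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a plain key-value text file (``key = value`` lines,
        '#' comments)."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"threshold": int, "threshold_inclusive": _as_bool,
                 "min_component_voxels": int, "radius_mode": str,
                 "length_mode": str, "rng_seed": int, "verbosity": int}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"expected 'key = value', got: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in casts:
                raise ValueError(f"unknown config key '{key}'")
            kwargs[key] = casts[key](value)
        return cls(**kwargs)


def _as_bool(s: str) -> bool:
    s = s.strip().lower()
    if s in ("1", "true", "yes", "on"):
        return True
    if s in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {s!r}")
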