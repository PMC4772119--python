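"""Run configuration for the TMD scanning pipeline.

All method constants (scan window, flank budget, hydrophobicity threshold,
burial rule, identity threshold) live here so sensitivity analyses can be
scripted by overriding a flat key=value config file or CLI flags.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

#: Residues treated as charged during edge refinement. Histidine is included
#: by default; it can be dropped via ``charged_residues``.
DEFAULT_CHARGED = "DEKRH"


@dataclasses.dataclass
class RunConfig:
    """Tunable parameters of the scan/refine/cluster/compare pipeline.

    Defaults are the method's published constants: an 18-residue scan
    window, at most 8 flanking residues per side, a hydrophobicity
    threshold of 0 (scale units), a 3+3 burial rule and a 30% identity
    threshold for redundancy clustering.
    """

    scale: str = "GES"
    window: int = 18
    max_flank: int = 8
    hydrophobic_threshold: float = 0.0
    identity_threshold: float = 0.30
    burial_run: int = 3
    charged_residues: str = DEFAULT_CHARGED
    expand_before_contract: bool = True
    kldm_log_base: float = math.e
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.max_flank < 0:
            raise ValueError(f"max_flank must be >= 0, got {self.max_flank}")
        if not (0.0 <= self.identity_threshold <= 1.0):
            raise ValueError(
                f"identity_threshold must be in [0, 1], got {self.identity_threshold}"
            )
        if self.burial_run < 1:
            raise ValueError(f"burial_run must be >= 1, got {self.burial_run}")
        if self.kldm_log_base <= 0 or self.kldm_log_base == 1.0:
            raise ValueError("kldm_log_base must be positive and != 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a flat ``key = value`` text file."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(
                    f"{path}:{lineno}: unknown config key {key!r}; "
                    f"known keys: {', '.join(sorted(fields))}"
                )
            ftype = fields[key].type
            if ftype in ("int", int):
                kwargs[key] = int(value)
            elif ftype in ("float", float):
                kwargs[key] = float(value)
            elif ftype in ("bool", bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")
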