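"""Run configuration: the pinned defaults of the measurement pipeline."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

from .calibration import DEFAULT_TOLERANCE
from .cohort import DEFAULT_MIN_SIDE_N, DEFAULT_SPAN
from .segmentation import DEFAULT_K, DEFAULT_K_GRID, GRAY_WEIGHTS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline defaults, every one pinned to its documented value.

    ``k`` is the SD-outlier multiplier; ``k_grid`` the calibration sweep;
    ``tolerance`` the smallest-k-within-tolerance selection rule;
    ``gray_weights`` the BT.601 luma; the group fields the tape-strip
    binning; ``min_side_n`` the breakpoint-scan side constraint; ``span``
    the local-regression fraction.
    """

    k: float = DEFAULT_K
    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    tolerance: float = DEFAULT_TOLERANCE
    gray_weights: tuple[float, float, float] = GRAY_WEIGHTS
    group_start: float = 80.0
    group_interval: float = 35.0
    n_groups: int = 5
    min_side_n: int = DEFAULT_MIN_SIDE_N
    span: float = DEFAULT_SPAN
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` text file; unknown keys are an error."""
        cfg = cls()
        known = {f.name: f for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, tuple):
                parsed = tuple(float(v) for v in val.split(","))
            elif isinstance(current, bool):
                parsed = val.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                parsed = int(val)
            else:
                parsed = float(val)
            setattr(cfg, key, parsed)
        return cfg

    def log_values(self) -> None:
        """Print every pinned value into the run log for provenance."""
        for f in fields(self):
            logger.info("config: %s = %r", f.name, getattr(self, f.name))
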