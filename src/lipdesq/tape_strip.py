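"""Tape-stripping comparator: grayscale grouping of sampled corneocytes.

Corneocytes lifted from the lip on adhesive tape are imaged under UV and
graded by brightness into five groups, G0 (even layer) to G4 (thick
flakes), over 35-grayscale-unit intervals starting at 80. Groups G0
(80-115) and G1 (115-150) are excluded as a quality-control step, so the
tape-strip desquamation rate is the summed area proportion of G2 + G3 + G4.
Only this grouping model is implemented; instrument file formats and the
UV-absorption physics are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GroupScheme:
    """Grayscale binning into the five corneocyte groups.

    Bins are lower-closed half-open ``[edge_i, edge_{i+1})``, the last
    closed at 255; values below ``start`` fall into G0 (the low bound is a
    display default and G0 never enters the rate). With the defaults the
    edges are 80, 115, 150, 185, 220, 255.
    """

    start: float = 80.0
    interval: float = 35.0
    n_groups: int = 5

    def __post_init__(self) -> None:
        if self.interval <= 0 or self.n_groups < 1:
            raise ValueError("interval must be > 0 and n_groups >= 1")

    @property
    def edges(self) -> np.ndarray:
        """Bin boundaries, ``n_groups + 1`` values from start to the top edge."""
        return self.start + self.interval * np.arange(self.n_groups + 1)

    @property
    def min_retained_value(self) -> float:
        """Quality-control cutoff: the lowest grayscale kept in the rate (G2 lower edge)."""
        return float(self.edges[2])


@dataclass(frozen=True)
class TapeStripProfile:
    """G0..G4 area proportions (percent of analyzed area) and the flake rate."""

    proportions: tuple[float, ...]
    rate: float
    counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.proportions):
            raise ValueError("group proportions must be non-negative")


def classify_groups(values, scheme: GroupScheme = GroupScheme()) -> TapeStripProfile:
    """Assign grayscale values to groups and compute the tape-strip rate.

    ``values`` are per-pixel grayscale readings in [0, 255]. Proportions
    are normalized over the supplied values; rate = G2 + G3 + G4.
    """
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("no grayscale values supplied")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("grayscale values must lie in [0, 255]")
    idx = np.floor((arr - scheme.start) / scheme.interval).astype(int)
    idx = np.clip(idx, 0, scheme.n_groups - 1)  # <start -> G0; top edge -> last group
    counts = np.bincount(idx, minlength=scheme.n_groups)
    props = 100.0 * counts / arr.size
    rate = float(props[2:].sum())
    return TapeStripProfile(
        proportions=tuple(float(p) for p in props),
        rate=rate,
        counts=tuple(int(c) for c in counts),
    )


def tape_rate_from_proportions(proportions) -> float:
    """Rate from precomputed G0..G4 percentages: G2 + G3 + G4."""
    props = np.asarray(proportions, dtype=np.float64)
    if props.size != 5:
        raise ValueError(f"expected 5 group proportions, got {props.size}")
    if (props < 0).any():
        raise ValueError("group proportions must be non-negative")
    if props.sum() > 100.0 + 1e-6:
        raise ValueError(f"group proportions sum to {props.sum():.4f} > 100")
    return float(props[2:].sum())
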