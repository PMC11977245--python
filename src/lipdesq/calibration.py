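"""Calibration of the threshold multiplier k against visual-assessment scores.

The rate is computed for every k on the grid 1.5-4.5 (step 0.1) across a
scored cohort; each k's rates are correlated with the final visual scores.
The correlation rises steeply at small k (texture and distractor pixels
leak into the mask), plateaus at intermediate k, and falls once genuine
flakes start dropping below the threshold. The selection rule picks the
smallest k whose correlation is within a tolerance of the grid maximum —
maximizing agreement with the visual scores while minimizing the omission
of existing flakes (larger thresholds detect less area).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import DEFAULT_K_GRID, rates_over_grid

#: Default tolerance for the smallest-k-within-tolerance-of-max rule.
DEFAULT_TOLERANCE = 0.05


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-k correlation with visual scores and mean rate across subjects.

    ``table`` has one row per grid k with columns ``k``, ``r``, ``p``,
    ``mean_rate``. Entries where the rates are constant across subjects
    (e.g. every mask empty at large k) carry NaN r and p — recorded as
    missing, not raised.
    """

    table: pd.DataFrame
    metric: str = "pearson"

    @property
    def k_grid(self) -> np.ndarray:
        return self.table["k"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationResult:
    chosen_k: float
    chosen_r: float
    curve: CalibrationCurve
    selection_rule: str


def _rate_matrix(subjects, grid: Sequence[float]) -> np.ndarray:
    """Accept either gray images or precomputed per-k rates (n_subjects x n_k)."""
    if isinstance(subjects, pd.DataFrame):
        mat = subjects.to_numpy(dtype=np.float64)
    else:
        subjects = list(subjects)
        first = np.asarray(subjects[0])
        if first.ndim == 2:  # gray images
            mat = np.vstack([rates_over_grid(img, grid) for img in subjects])
        else:  # per-subject rate vectors
            mat = np.vstack([np.asarray(s, dtype=np.float64) for s in subjects])
    if mat.shape[1] != len(grid):
        raise ValueError(
            f"rate matrix has {mat.shape[1]} columns but the grid has {len(grid)} values"
        )
    return mat


def sweep_k(
    subjects,
    va: Sequence[float],
    grid: Sequence[float] = DEFAULT_K_GRID,
    metric: str = "pearson",
) -> CalibrationCurve:
    """Correlate desquamation rates with final VA scores at every grid k.

    Parameters
    ----------
    subjects
        Either a sequence of 2D grayscale regions (rates are computed over
        the grid for each) or precomputed rates as an ``n_subjects x n_k``
        array / DataFrame.
    va
        One final visual-assessment score per subject.
    metric
        ``"pearson"`` (default, matching the calibration analysis) or
        ``"spearman"``.
    """
    va_arr = np.asarray(va, dtype=np.float64)
    rates = _rate_matrix(subjects, grid)
    if rates.shape[0] != va_arr.size:
        raise ValueError(
            f"{rates.shape[0]} subjects but {va_arr.size} VA scores"
        )
    if rates.shape[0] < 2:
        raise ValueError("need at least two subjects to correlate")
    corr = stats.pearsonr if metric == "pearson" else stats.spearmanr
    if metric not in ("pearson", "spearman"):
        raise ValueError(f"unknown metric {metric!r}")

    rows = []
    for j, k in enumerate(grid):
        col = rates[:, j]
        if np.ptp(col) == 0 or np.ptp(va_arr) == 0:
            r, p = float("nan"), float("nan")
        else:
            res = corr(col, va_arr)
            r, p = float(res[0]), float(res[1])
        rows.append({"k": float(k), "r": r, "p": p, "mean_rate": float(col.mean())})
    return CalibrationCurve(table=pd.DataFrame(rows), metric=metric)


def select_k(curve: CalibrationCurve, tolerance: float = DEFAULT_TOLERANCE) -> CalibrationResult:
    """Smallest grid k whose correlation is within ``tolerance`` of the maximum.

    ``chosen_k = min { k : r(k) >= (1 - tolerance) * max_k r }``; ties break
    toward smaller k by construction, and ``tolerance = 0`` recovers the
    plain argmax rule.
    """
    tab = curve.table
    valid = tab[np.isfinite(tab["r"])]
    if valid.empty:
        raise ValueError("all calibration entries are missing; cannot select k")
    rmax = valid["r"].max()
    cut = (1.0 - tolerance) * rmax
    ok = valid[valid["r"] >= cut - 1e-12]
    chosen = ok.sort_values("k").iloc[0]
    return CalibrationResult(
        chosen_k=float(chosen["k"]),
        chosen_r=float(chosen["r"]),
        curve=curve,
        selection_rule=f"smallest k with r >= (1 - {tolerance}) * max r",
    )
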