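"""Visual-assessment scoring: the 0-4 photonumeric scale and rater agreement.

Several trained raters independently grade each subject's lip desquamation
on a five-level photonumeric scale; the subject's final score is the plain
mean of the rater scores, and inter-rater reliability is summarized by the
mean pairwise correlation between rater score sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Clinical anchors of the photonumeric scale.
SCORE_DESCRIPTORS: dict[int, str] = {
    0: "None - no chapping or desquamated flakes",
    1: "Normal - very few small flakes",
    2: "Moderate - a few small flakes",
    3: "Marked - obvious flakes in various sizes and shapes",
    4: "Severe - very marked scaling, mainly forming large flakes",
}


@dataclass(frozen=True)
class VAScorePanel:
    """Subjects x raters score matrix, integer scores in {0..4} (NaN = missing)."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=np.float64)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0).any() or (finite > 4).any()):
            raise ValueError("scores must lie in {0, 1, 2, 3, 4}")
        if finite.size and not np.allclose(finite, np.rint(finite)):
            raise ValueError("rater scores must be integers")

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "VAScorePanel":
        """Build from a long table with columns subject_id, rater_id, score."""
        wide = df.pivot(index="subject_id", columns="rater_id", values="score")
        return cls(scores=wide)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VAScorePanel":
        return cls.from_long(pd.read_csv(path))


def final_scores(panel: VAScorePanel) -> pd.Series:
    """Per-subject final score: arithmetic mean across raters, no rounding.

    Missing cells are skipped (mean over available raters) with a logged
    warning naming the subjects affected.
    """
    if panel.scores.shape[1] < 1:
        raise ValueError("panel has no raters")
    incomplete = panel.scores.index[panel.scores.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "final_scores: subjects %s have missing rater scores; "
            "averaging over available raters", list(incomplete)
        )
    if panel.scores.isna().all(axis=1).any():
        raise ValueError("some subjects have no rater scores at all")
    out = panel.scores.mean(axis=1, skipna=True)
    out.name = "va_final"
    return out


def inter_rater_reliability(
    panel: VAScorePanel, metric: str = "pearson"
) -> tuple[pd.DataFrame, float]:
    """Pairwise correlations between rater score sets.

    Returns the symmetric rater x rater correlation matrix (unit diagonal)
    and the mean of its upper-triangle entries. A zero-variance rater's
    pairwise entries are undefined (NaN) and excluded from the mean.
    """
    if panel.n_raters < 2:
        raise ValueError("need at least two raters")
    if panel.n_subjects < 3:
        raise ValueError("need at least three subjects")
    if metric not in ("pearson", "spearman"):
        raise ValueError(f"unknown metric {metric!r}")
    mat = panel.scores.corr(method=metric)
    # pandas leaves diag 1 even for constant raters; mark those rows/cols NaN
    const = panel.scores.std(ddof=0) == 0
    for rater in panel.scores.columns[const]:
        mat.loc[rater, :] = np.nan
        mat.loc[:, rater] = np.nan
    np.fill_diagonal(mat.values, np.where(const, np.nan, 1.0))
    iu = np.triu_indices(mat.shape[0], k=1)
    upper = mat.to_numpy()[iu]
    mean_r = float(np.nanmean(upper)) if np.isfinite(upper).any() else float("nan")
    return mat, mean_r
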