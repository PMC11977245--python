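"""Lower-lip target-region geometry from face-mesh landmarks.

The measurement works on a rectangular patch of the lower-lip premucosa,
the driest band of the vermilion. The patch is located from eight keypoints
of the 478-point face-mesh convention: 14, 15, 16, 17 on the midline of the
lower lip and 84, 87, 314, 317 flanking its centre. The rectangle's width is
the larger of the two horizontal spans |x84 - x87| and |x314 - x317|; its
height is the vertical distance between the midpoints of the 14-15 and
16-17 pairs. Landmark acquisition is pluggable: the core consumes landmark
files (JSON), and an optional external-detector adapter lives in
:mod:`lipdesq.detectors`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Face-mesh indices delimiting the lower-lip centre.
REQUIRED_INDICES: tuple[int, ...] = (14, 15, 16, 17, 84, 87, 314, 317)

#: Total keypoint count of the face-mesh convention.
FACE_MESH_SIZE = 478


class IncompleteLandmarkError(ValueError):
    """A required lower-lip landmark index is missing."""


class DegenerateROIError(ValueError):
    """The landmark geometry yields a rectangle with zero width or height."""


@dataclass(frozen=True)
class LandmarkSet:
    """Indexed 2D landmarks in pixel coordinates.

    Parameters
    ----------
    points
        Mapping from face-mesh index to ``(x, y)`` pixel coordinates.
        Only x and y are used; any z component of 3D landmarks is dropped
        before construction.
    image_width, image_height
        Dimensions of the image the coordinates refer to.
    index_space
        Size of the indexing convention (478 for the face mesh).
    """

    points: dict[int, tuple[float, float]]
    image_width: int
    image_height: int
    index_space: int = FACE_MESH_SIZE

    def __post_init__(self) -> None:
        missing = [i for i in REQUIRED_INDICES if i not in self.points]
        if missing:
            raise IncompleteLandmarkError(
                "incomplete landmark set: missing required indices "
                f"{sorted(missing)}"
            )
        for idx, (x, y) in self.points.items():
            if not (0 <= x <= self.image_width and 0 <= y <= self.image_height):
                raise ValueError(
                    f"landmark {idx} at ({x}, {y}) lies outside the "
                    f"{self.image_width}x{self.image_height} image"
                )

    def __getitem__(self, idx: int) -> tuple[float, float]:
        return self.points[idx]

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Write the landmark file (pixel coordinates, ``normalized: false``)."""
        payload = {
            "normalized": False,
            "image_width": self.image_width,
            "image_height": self.image_height,
            "index_space": self.index_space,
            "points": {str(i): [float(x), float(y)] for i, (x, y) in self.points.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        """Read a landmark file, denormalizing unit coordinates if flagged."""
        payload = json.loads(Path(path).read_text())
        raw = {int(i): tuple(xy[:2]) for i, xy in payload["points"].items()}
        w = int(payload["image_width"])
        h = int(payload["image_height"])
        space = int(payload.get("index_space", FACE_MESH_SIZE))
        if payload.get("normalized", False):
            return denormalize_landmarks(raw, w, h, index_space=space)
        return cls(points={i: (float(x), float(y)) for i, (x, y) in raw.items()},
                   image_width=w, image_height=h, index_space=space)


@dataclass(frozen=True)
class LipROI:
    """Axis-aligned rectangle, 0-based, half-open ``[x0, x0+width) x [y0, y0+height)``."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise DegenerateROIError(
                f"degenerate ROI: width={self.width}, height={self.height}"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI origin ({self.x0}, {self.y0}) is negative")

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) with exclusive upper edges."""
        return self.x0, self.y0, self.x0 + self.width, self.y0 + self.height


def denormalize_landmarks(
    raw: Mapping[int, Sequence[float]],
    image_width: int,
    image_height: int,
    index_space: int = FACE_MESH_SIZE,
) -> LandmarkSet:
    """Map unit-normalized detector output onto pixel coordinates.

    Face-mesh detectors emit coordinates in [0, 1]; a point ``(u, v)``
    becomes ``(u * image_width, v * image_height)``.
    """
    if image_width < 1 or image_height < 1:
        raise ValueError("image dimensions must be >= 1")
    missing = [i for i in REQUIRED_INDICES if i not in raw]
    if missing:
        raise IncompleteLandmarkError(
            f"incomplete landmark set: missing required indices {sorted(missing)}"
        )
    points: dict[int, tuple[float, float]] = {}
    for idx, xy in raw.items():
        u, v = float(xy[0]), float(xy[1])
        if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
            raise ValueError(f"normalized landmark {idx} outside [0, 1]: ({u}, {v})")
        points[int(idx)] = (u * image_width, v * image_height)
    return LandmarkSet(points=points, image_width=image_width,
                       image_height=image_height, index_space=index_space)


def extract_target_region(lm: LandmarkSet) -> LipROI:
    """Derive the lower-lip rectangle from the eight landmarks.

    width  = max(|x84 - x87|, |x314 - x317|)
    height = |mid_y(14, 15) - mid_y(16, 17)|

    The rectangle is centred horizontally on the mean x of landmarks
    {84, 87, 314, 317}; vertically it runs from the upper to the lower of
    the two pair midpoints. Geometry is computed in floating point and the
    bounds rounded to integers last. Rectangles extending past the image
    are clipped with a logged warning.
    """
    p = lm.points
    span_a = abs(p[84][0] - p[87][0])
    span_b = abs(p[314][0] - p[317][0])
    width_f = max(span_a, span_b)
    mid_top = (p[14][1] + p[15][1]) / 2.0
    mid_bot = (p[16][1] + p[17][1]) / 2.0
    height_f = abs(mid_top - mid_bot)
    if width_f < 0.5 or height_f < 0.5:
        raise DegenerateROIError(
            f"degenerate ROI: landmark spans give width {width_f:.3f}, "
            f"height {height_f:.3f}"
        )
    cx = (p[84][0] + p[87][0] + p[314][0] + p[317][0]) / 4.0
    top = min(mid_top, mid_bot)

    x0 = int(round(cx - width_f / 2.0))
    y0 = int(round(top))
    width = int(round(width_f))
    height = int(round(height_f))

    # clip to image bounds
    cx0, cy0 = max(x0, 0), max(y0, 0)
    cx1 = min(x0 + width, lm.image_width)
    cy1 = min(y0 + height, lm.image_height)
    if (cx0, cy0, cx1, cy1) != (x0, y0, x0 + width, y0 + height):
        logger.warning(
            "ROI [%d:%d)x[%d:%d) extends past the %dx%d image; clipping",
            x0, x0 + width, y0, y0 + height, lm.image_width, lm.image_height,
        )
    if cx1 - cx0 < 1 or cy1 - cy0 < 1:
        raise DegenerateROIError("degenerate ROI after clipping to image bounds")
    return LipROI(x0=cx0, y0=cy0, width=cx1 - cx0, height=cy1 - cy0)


def crop(image: np.ndarray, roi: LipROI) -> np.ndarray:
    """Cut the ROI out of ``image`` (H x W [x C]); pixel values are copied unmodified."""
    h, w = image.shape[:2]
    x0, y0, x1, y1 = roi.bounds
    if x1 > w or y1 > h:
        raise ValueError(
            f"ROI {roi} exceeds image bounds {w}x{h}"
        )
    return image[y0:y1, x0:x1].copy()
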