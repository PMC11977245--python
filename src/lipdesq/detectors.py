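"""Optional adapter to an external face-mesh landmark detector.

The core pipeline consumes :class:`~lipdesq.landmarks.LandmarkSet` files;
this adapter is the only place a face model is touched, so everything else
runs without one. It is imported lazily and degrades to a clear error when
mediapipe is not installed.
"""

from __future__ import annotations

import numpy as np

from .landmarks import LandmarkSet, denormalize_landmarks


def detect_landmarks(image: np.ndarray) -> LandmarkSet:
    """Run a mediapipe face-mesh detection on an RGB image.

    Requires the optional ``mediapipe`` dependency; raises ImportError with
    installation guidance when it is absent. The detector's unit-normalized
    478-point output is denormalized to pixel coordinates (z is dropped).
    """
    try:
        import mediapipe as mp  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "face-mesh detection needs the optional 'mediapipe' package "
            "(pip install mediapipe); alternatively supply landmarks as JSON"
        ) from exc
    h, w = image.shape[:2]
    with mp.solutions.face_mesh.FaceMesh(
        static_image_mode=True, refine_landmarks=True, max_num_faces=1
    ) as mesh:  # pragma: no cover - optional dependency
        result = mesh.process(image)
        if not result.multi_face_landmarks:
            raise ValueError("no face detected")
        raw = {
            i: (p.x, p.y)
            for i, p in enumerate(result.multi_face_landmarks[0].landmark)
        }
        return denormalize_landmarks(raw, w, h)
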