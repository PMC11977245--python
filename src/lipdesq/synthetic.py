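"""Ground-truthed synthetic data: lip-patch images, scored cohorts, trend cohorts.

The study's facial photographs are privacy-restricted, so every pipeline
stage is exercised on synthetic data built to reproduce the statistical
features the method depends on:

* **Lip patches** — a smooth, spatially correlated background texture with
  a compact (tanh-squashed Gaussian) intensity distribution, on which
  bright, irregular, soft-edged flakes are composited. Flakes occupy a few
  percent of the area at several background-SDs of contrast, so the patch
  histogram is unimodal with a long right tail — the regime in which
  bimodal-assuming thresholds fail and the SD-outlier threshold works.
  Each image ships with its ground-truth flake mask.
* **Face fixtures** — a lip patch embedded in a neutral frame together
  with the eight lower-lip landmarks placed so ROI extraction recovers
  exactly the embedded patch.
* **VA calibration cohorts** — subjects with a latent severity driving
  both the planted flake fraction and noisy integer rater scores, plus a
  per-subject amount of sub-threshold "distractor" speckle (specular
  micro-texture) that pollutes low-k masks, shaping the r(k) curve.
* **Age/sex trend cohorts** — piecewise-linear female and linear male
  rate-vs-age profiles with Gaussian noise, parameterized by the reported
  slopes and intercepts.

All draws flow from one per-call seed through ``numpy.random.SeedSequence``
spawning, so every generator is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks
from skimage.draw import ellipse as draw_ellipse

from .landmarks import LandmarkSet
from .visual import VAScorePanel

_EPS = 1e-12

# ---------------------------------------------------------------------------
# flake image generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlakeImageSpec:
    """Parameters of one synthetic lip patch.

    Defaults describe a realistic cropped lower-lip region: a 160 x 96
    patch, mid-gray (mean 120) background with sd 12 and ~4 px texture
    correlation, flakes covering 2% of the area at 5.5 background-SDs of
    base contrast (per-flake brightness modulated by U(0.9, 1.25), so the
    dimmest flakes sit near 5 sd). ``n_flakes = None`` sizes the flake
    count automatically toward a ~70 px mean flake area.
    """

    width: int = 160
    height: int = 96
    background_mean: float = 120.0
    background_sd: float = 12.0
    texture_correlation_length: float = 4.0
    n_flakes: int | None = None
    flake_area_fraction: float = 0.02
    flake_contrast: float = 5.5
    contrast_modulation: tuple[float, float] = (0.9, 1.25)
    speckle_fraction: float = 0.0
    speckle_contrast: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flake_area_fraction <= 0.2:
            raise ValueError("flake_area_fraction must be in [0, 0.2]")
        if self.flake_contrast < 0:
            raise ValueError("flake_contrast must be >= 0")
        if self.width < 8 or self.height < 8:
            raise ValueError("patch must be at least 8 x 8")


def _background_field(h, w, corr, mean, sd, rng, squash=2.2):
    """Spatially correlated texture with a compact (light-tailed) marginal."""
    g = rng.standard_normal((h, w))
    if corr > 0:
        g = gaussian_filter(g, corr, mode="reflect")
    g = (g - g.mean()) / max(g.std(), _EPS)
    g = squash * np.tanh(g / squash)          # bound excursions; flakes own the tail
    g = (g - g.mean()) / max(g.std(), _EPS)
    return mean + sd * g


def _flake_blob(h, w, area, rng):
    """Irregular soft ellipse of roughly the requested pixel area."""
    aspect = rng.uniform(0.35, 1.0)
    a = max(1.0, np.sqrt(area / (np.pi * aspect)))
    b = max(1.0, a * aspect)
    a = min(a, (min(h, w) - 2) / 2.0)
    cy = rng.uniform(a, h - a)
    cx = rng.uniform(a, w - a)
    rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=rng.uniform(0, np.pi))
    base = np.zeros((h, w), dtype=bool)
    base[rr, cc] = True
    if not base.any():
        base[int(cy) % h, int(cx) % w] = True
    # perturb the boundary with a smooth noise field, confined to the vicinity
    f = gaussian_filter(base.astype(float), 1.2)
    noise = gaussian_filter(rng.standard_normal((h, w)), 2.0)
    noise /= max(noise.std(), _EPS)
    blob = (f + 0.18 * noise > 0.5) & (f > 0.05)
    if not blob.any():
        blob = base
    return blob


def generate_flake_image(spec: FlakeImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one lip patch; returns ``(rgb_uint8, truth_mask_bool)``.

    Flakes are composited by alpha replacement: under a flake the surface
    is the flake plane (background mean + contrast x background SD, with
    the per-flake modulation), blended into the texture over a soft ~1 px
    rim. Total planted area lands within +-10% of the requested fraction;
    identical specs (including seed) render bit-identical images.
    """
    h, w = spec.height, spec.width
    ss = np.random.SeedSequence(spec.seed)
    bg_rng, flake_rng, speck_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    field = _background_field(
        h, w, spec.texture_correlation_length,
        spec.background_mean, spec.background_sd, bg_rng,
    )
    bg_sd = float(field.std())

    target = int(round(spec.flake_area_fraction * h * w))
    mask = np.zeros((h, w), dtype=bool)
    img = field.copy()

    if target > 0:
        n_flakes = spec.n_flakes or max(2, int(round(target / 70)))
        weights = flake_rng.lognormal(0.0, 0.5, n_flakes)
        areas = np.maximum(6.0, target * weights / weights.sum())
        blobs = []
        for area in areas:
            blobs.append(_flake_blob(h, w, area, flake_rng))
            mask |= blobs[-1]
        # top up toward the requested area (overlap eats into it)
        tries = 0
        while mask.sum() < 0.93 * target and tries < 60:
            deficit = target - int(mask.sum())
            blobs.append(_flake_blob(h, w, max(6, deficit), flake_rng))
            mask |= blobs[-1]
            tries += 1
        if mask.sum() < 0.9 * target:
            raise ValueError(
                "infeasible flake packing: could not reach the requested "
                f"area fraction {spec.flake_area_fraction} on a {w}x{h} patch"
            )
        lo, hi = spec.contrast_modulation
        # within-flake brightness relief: thick ridges run brighter, so the
        # flake pixels form a decaying right tail instead of a narrow bump
        relief = gaussian_filter(flake_rng.standard_normal((h, w)), 2.0)
        relief = np.maximum(relief / max(relief.std(), _EPS), 0.0)
        for blob in blobs:
            c = spec.flake_contrast * flake_rng.uniform(lo, hi)
            alpha = np.clip(1.5 * gaussian_filter(blob.astype(float), 0.7), 0.0, 1.0)
            plane = spec.background_mean + c * bg_sd * (1.0 + 0.45 * relief)
            img = img * (1.0 - alpha) + alpha * plane

    if spec.speckle_fraction > 0:
        n_sp = int(round(spec.speckle_fraction * h * w))
        ys = speck_rng.integers(0, h, n_sp)
        xs = speck_rng.integers(0, w, n_sp)
        amp = spec.speckle_contrast * bg_sd * speck_rng.uniform(0.75, 1.25, n_sp)
        np.add.at(img, (ys, xs), amp)

    gray8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    rgb = np.repeat(gray8[:, :, None], 3, axis=2)
    return rgb, mask


def histogram_mode_count(
    gray, smooth_sigma: float = 3.0, min_prominence: float = 0.10
) -> int:
    """Number of modes of the smoothed 256-bin intensity histogram.

    A mode is a local maximum whose prominence exceeds ``min_prominence``
    (default 10%) of the histogram peak; a lower-amplitude ripple riding
    on the long flake tail reads as part of the tail, not a second mode —
    the judgement a practitioner makes when calling such a histogram
    "long-tailed unimodal" by eye.
    """
    arr = np.asarray(gray, dtype=np.float64).ravel()
    hist, _ = np.histogram(arr, bins=256, range=(0, 256))
    smooth = gaussian_filter(hist.astype(float), smooth_sigma, mode="constant")
    peaks, _ = find_peaks(smooth, prominence=min_prominence * smooth.max())
    return max(1, len(peaks))


# ---------------------------------------------------------------------------
# face fixture
# ---------------------------------------------------------------------------

def generate_face_fixture(
    spec: FlakeImageSpec,
    offset: tuple[int, int] = (40, 30),
    frame_size: tuple[int, int] = (240, 160),
    frame_gray: int = 60,
) -> tuple[np.ndarray, LandmarkSet, np.ndarray]:
    """Embed a lip patch in a neutral frame and emit matching landmarks.

    Returns ``(frame_rgb, landmarks, truth_mask)``; the landmarks are
    placed so ROI extraction recovers exactly the embedded patch (the
    84-87 span is the patch width, the 14-15 / 16-17 midpoints its top and
    bottom edges), making ``quantify`` on the fixture identical to running
    the stages on the bare patch.
    """
    fw, fh = frame_size
    x0, y0 = offset
    W, H = spec.width, spec.height
    if x0 < 0 or y0 < 0 or x0 + W > fw or y0 + H > fh:
        raise ValueError(
            f"lip placement ({x0},{y0})+{W}x{H} does not fit in frame {fw}x{fh}"
        )
    rgb, mask = generate_flake_image(spec)
    frame = np.full((fh, fw, 3), frame_gray, dtype=np.uint8)
    frame[y0:y0 + H, x0:x0 + W] = rgb

    cx = x0 + W / 2.0
    pts = {
        84: (float(x0), y0 + H / 2.0),
        87: (float(x0 + W), y0 + H / 2.0),
        314: (x0 + W / 4.0, y0 + H / 2.0),
        317: (x0 + 3 * W / 4.0, y0 + H / 2.0),
        14: (cx, float(y0)),
        15: (cx, float(y0)),
        16: (cx, float(y0 + H)),
        17: (cx, float(y0 + H)),
    }
    lm = LandmarkSet(points=pts, image_width=fw, image_height=fh)
    return frame, lm, mask


# ---------------------------------------------------------------------------
# VA-linked calibration cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VACohort:
    """A scored synthetic cohort: images, rater panel, and planted truth."""

    subject_ids: list[str]
    images: list[np.ndarray]          # grayscale uint8 patches (lip regions)
    masks: list[np.ndarray]
    panel: VAScorePanel
    true_fractions: np.ndarray
    severities: np.ndarray
    specs: list[FlakeImageSpec]


def generate_va_cohort(
    n_subjects: int = 55,
    n_raters: int = 5,
    rater_noise_sd: float = 0.5,
    fraction_intercept: float = 0.002,
    fraction_slope: float = 0.010,
    base_spec: FlakeImageSpec = FlakeImageSpec(),
    seed: int = 0,
) -> VACohort:
    """Simulate the calibration study design: scored subjects with images.

    Each subject has a latent severity ~ U(0.3, 3.7); the planted flake
    fraction is ``fraction_intercept + fraction_slope * severity``
    (monotone in severity), and each rater reports
    ``round(severity + N(0, rater_noise_sd))`` clamped to {0..4}. Flake
    contrast and the distractor-speckle load (fraction U(0.005, 0.05) at
    ~2 background-SD) vary per subject independently of severity — the
    speckle inflates masks only at small k, which is what carves out the
    calibration plateau.
    """
    if n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    sev_ss, rater_ss, img_ss = np.random.SeedSequence(seed).spawn(3)
    sev_rng = np.random.default_rng(sev_ss)
    rater_rng = np.random.default_rng(rater_ss)

    severities = sev_rng.uniform(0.3, 3.7, n_subjects)
    fractions = fraction_intercept + fraction_slope * severities
    contrasts = sev_rng.uniform(0.95, 1.15, n_subjects) * base_spec.flake_contrast
    speckle = sev_rng.uniform(0.005, 0.05, n_subjects)

    img_seeds = img_ss.generate_state(n_subjects) % (2 ** 31)
    images, masks, specs = [], [], []
    for i in range(n_subjects):
        spec = replace(
            base_spec,
            flake_area_fraction=float(fractions[i]),
            flake_contrast=float(contrasts[i]),
            speckle_fraction=float(speckle[i]),
            speckle_contrast=float(sev_rng.uniform(2.2, 2.9)),
            seed=int(img_seeds[i]),
        )
        rgb, mask = generate_flake_image(spec)
        images.append(rgb[:, :, 0])       # channels identical; keep gray
        masks.append(mask)
        specs.append(spec)

    noise = rater_rng.normal(0.0, rater_noise_sd, (n_subjects, n_raters))
    scores = np.clip(np.rint(severities[:, None] + noise), 0, 4).astype(int)
    ids = [f"S{i + 1:03d}" for i in range(n_subjects)]
    panel = VAScorePanel(
        scores=pd.DataFrame(
            scores, index=pd.Index(ids, name="subject_id"),
            columns=[f"rater_{j + 1}" for j in range(n_raters)],
        )
    )
    return VACohort(
        subject_ids=ids, images=images, masks=masks, panel=panel,
        true_fractions=fractions, severities=severities, specs=specs,
    )


# ---------------------------------------------------------------------------
# age/sex trend cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Population design: 10 subjects per sex per year of age, 20-69.

    Female rates follow a piecewise-linear profile rising at
    ``female_slope_young`` %/yr from ``female_intercept`` (the rate at
    ``age_min``) up to ``female_breakpoint``, then declining at
    ``female_slope_old``; male rates decline linearly at ``male_slope``
    from ``male_intercept``. The male intercept is set so the male cohort
    mean is 0.440%. Gaussian noise (sd ``noise_sd``) is added and rates
    are truncated at zero. ``female_breakpoint = None`` makes the female
    arm purely linear at ``female_slope_young``.
    """

    n_per_age: int = 10
    age_min: int = 20
    age_max: int = 69
    female_breakpoint: float | None = 38.0
    female_slope_young: float = 0.019
    female_slope_old: float = -0.005
    female_intercept: float = 0.217
    male_slope: float = -0.005
    male_intercept: float = 0.5625
    noise_sd: float = 0.1
    seed: int = 0


def expected_rate(spec: SyntheticCohortSpec, age, sex: str) -> np.ndarray:
    """Noise-free rate profile of the generator at the given ages."""
    a = np.asarray(age, dtype=float)
    if sex == "male":
        return spec.male_intercept + spec.male_slope * (a - spec.age_min)
    if spec.female_breakpoint is None:
        return spec.female_intercept + spec.female_slope_young * (a - spec.age_min)
    bp = spec.female_breakpoint
    at_bp = spec.female_intercept + spec.female_slope_young * (bp - spec.age_min)
    return np.where(
        a <= bp,
        spec.female_intercept + spec.female_slope_young * (a - spec.age_min),
        at_bp + spec.female_slope_old * (a - bp),
    )


def generate_trend_cohort(spec: SyntheticCohortSpec = SyntheticCohortSpec()) -> pd.DataFrame:
    """Draw a cohort table (subject_id, age, sex, rate) from the spec."""
    ages = np.arange(spec.age_min, spec.age_max + 1)
    for sex in ("male", "female"):
        if (expected_rate(spec, ages, sex) < 0).any():
            raise ValueError(f"expected {sex} rate goes negative in the age range")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows = []
    sid = 0
    for sex in ("male", "female"):
        age_col = np.repeat(ages, spec.n_per_age)
        mu = expected_rate(spec, age_col, sex)
        rate = np.clip(mu + rng.normal(0.0, spec.noise_sd, age_col.size), 0.0, None)
        for a, r in zip(age_col, rate):
            sid += 1
            rows.append({"subject_id": f"C{sid:04d}", "age": int(a),
                         "sex": sex, "rate": float(r)})
    return pd.DataFrame(rows)
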