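"""Synthetic fundus-like images and planted feature matrices.

The image generator emulates the visual logic of diabetic-retinopathy
grading — higher grade means more lesions — on a cartoon retina: a dark
background, a bright circular retinal disc, a brighter optic-disc blob,
curvilinear vessels grown as random walks, and grade-dependent counts of
small dark-red lesions (hemorrhage-like) and bright yellow blobs
(exudate-like), all under Gaussian pixel noise.  Class g draws
Poisson(6g) lesions and Poisson(3g) exudates by default, so grade 0
(normal) has none and lesion load rises monotonically with grade.  It
supports the two class regimes of interest: 3 classes
(normal / non-proliferative / proliferative) and 5 classes (the
normal / mild / moderate / severe / proliferative grading scheme).

The planted-matrix generator builds a Gaussian feature matrix with a known
informative subset (between-class mean shift in noise-sd units) as ground
truth for the feature-selection stage.

Neither generator claims photorealism; they exist so every pipeline stage is
testable offline and deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.draw import disk as _disk

from .errors import ParameterError
from .imaging import FundusImage

# approximate sRGB palette of the cartoon retina
_BACKGROUND = (18, 10, 8)
_RETINA = (172, 88, 38)
_OPTIC_DISC = (235, 202, 130)
_VESSEL = (112, 28, 18)
_LESION = (55, 10, 10)
_EXUDATE = (246, 236, 150)


@dataclass
class SynthSpec:
    """Parameters of the synthetic fundus generator.

    ``lesion_rate`` / ``exudate_rate`` give the expected count of dark
    lesions / bright blobs per class; the defaults 6g and 3g for grade g put
    zero lesions on the normal class and a monotone lesion load above it.
    """

    n_per_class: int = 50
    n_classes: int = 3
    image_side: int = 256
    lesion_rate: Optional[Sequence[float]] = None
    exudate_rate: Optional[Sequence[float]] = None
    vessel_count: int = 8
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (3, 5):
            raise ParameterError(
                f"n_classes must be 3 or 5 (the two grading regimes), got {self.n_classes}"
            )
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be positive")
        if self.image_side < 64:
            raise ParameterError("image_side must be at least 64")
        if self.lesion_rate is None:
            self.lesion_rate = [6.0 * g for g in range(self.n_classes)]
        if self.exudate_rate is None:
            self.exudate_rate = [3.0 * g for g in range(self.n_classes)]
        for name, rates in (("lesion_rate", self.lesion_rate),
                            ("exudate_rate", self.exudate_rate)):
            if len(rates) != self.n_classes:
                raise ParameterError(f"{name} needs one rate per class")
            if any(r < 0 for r in rates):
                raise ParameterError(f"{name} rates must be nonnegative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")


def _paint_disk(canvas, center, radius, color, alpha=1.0):
    rr, cc = _disk(center, radius, shape=canvas.shape[:2])
    canvas[rr, cc] = (1 - alpha) * canvas[rr, cc] + alpha * np.asarray(color, float)


def _vessel_template(rng, vessel_count, n_steps):
    """Per-dataset arcade template: base direction and curvature per vessel.

    Retinal vasculature is anatomically stereotyped — every eye shows a
    similar fan of arcades leaving the optic disc — so the vessel tree is
    drawn once per dataset and only slightly jittered per image.  Inter-image
    vascular variation is deliberately small: it is nuisance, not signal.
    """
    template = []
    for k in range(vessel_count):
        spread = (k / max(vessel_count - 1, 1) - 0.5) * 2.4
        template.append(
            (spread + rng.normal(0, 0.08), rng.normal(0, 0.18, size=n_steps))
        )
    return template


def _grow_vessel(canvas, rng, start, base_angle, turns, retina_center,
                 retina_radius, macula_center, macula_radius, thickness=1.5):
    """Draw one arcade: template curvature plus tiny per-image jitter,
    steered inside the retinal disc and around the avascular macular zone."""
    pos = np.asarray(start, dtype=float)
    angle = base_angle
    for turn in turns:
        angle += turn + rng.normal(0, 0.01)
        nxt = pos + 2.0 * np.array([np.sin(angle), np.cos(angle)])
        if np.linalg.norm(nxt - retina_center) > 0.92 * retina_radius:
            back = nxt - retina_center
            angle = np.arctan2(-back[0], -back[1])
            nxt = pos + 2.0 * np.array([np.sin(angle), np.cos(angle)])
        elif np.linalg.norm(nxt - macula_center) < macula_radius:
            away = nxt - macula_center
            angle = np.arctan2(away[0], away[1])
            nxt = pos + 2.0 * np.array([np.sin(angle), np.cos(angle)])
        pos = nxt
        _paint_disk(canvas, pos, thickness, _VESSEL, alpha=0.9)


def _render_fundus(
    rng: np.random.Generator, spec: SynthSpec, grade: int, template
) -> np.ndarray:
    side = spec.image_side
    canvas = np.empty((side, side, 3), dtype=np.float64)
    canvas[:] = _BACKGROUND

    # protocol fundus photography frames the retina reproducibly: the disc
    # geometry is held (nearly) fixed and only illumination tint varies a little
    center = np.array([side / 2, side / 2]) + rng.normal(0, side * 0.002, size=2)
    radius = side * 0.44
    _paint_disk(canvas, center, radius, _RETINA)
    # slightly brighter macular region off-center
    _paint_disk(canvas, center + rng.normal(0, 1, 2), radius * 0.55,
                np.asarray(_RETINA) + 14, alpha=0.5)

    # optic disc near the nasal edge of the retina
    od_angle = rng.normal(0, 0.01)
    od_center = center + 0.6 * radius * np.array([np.sin(od_angle), np.cos(od_angle)])
    _paint_disk(canvas, od_center, side * 0.064, _OPTIC_DISC)

    # the avascular macular zone sits opposite the optic disc
    macula_center = center
    macula_radius = 0.40 * radius
    # venous caliber increases with disease severity (dilation/beading is a
    # cardinal non-proliferative grading sign)
    toward_center = np.arctan2(*(center - od_center))
    for spread, turns in template:
        _grow_vessel(
            canvas, rng, od_center,
            base_angle=toward_center + spread, turns=turns,
            retina_center=center, retina_radius=radius,
            macula_center=macula_center, macula_radius=macula_radius,
            thickness=1.5 + 0.3 * grade,
        )

    def _in_annulus(r_lo, r_hi):
        ang = rng.uniform(0, 2 * np.pi)
        rad = radius * np.sqrt(rng.uniform(r_lo**2, r_hi**2))
        return center + rad * np.array([np.sin(ang), np.cos(ang)])

    # the top grade is proliferative: neovascular tufts — short, highly
    # tortuous new vessels — sprout around the optic disc, which is the
    # defining structural finding of proliferative disease
    if grade == spec.n_classes - 1:
        for _ in range(6 + rng.poisson(2.0)):
            sprout = od_center + rng.normal(0, side * 0.05, size=2)
            ang = rng.uniform(0, 2 * np.pi)
            pos = sprout.copy()
            for _ in range(35):
                ang += rng.normal(0, 0.8)
                pos += 1.6 * np.array([np.sin(ang), np.cos(ang)])
                _paint_disk(canvas, pos, 1.1, _VESSEL, alpha=0.85)

    # hemorrhage-like dark blots scatter over the peripheral retina;
    # hard-exudate-like bright dots cluster in the macular zone, as in
    # clinically significant macular edema
    for _ in range(rng.poisson(spec.lesion_rate[grade])):
        _paint_disk(canvas, _in_annulus(0.45, 0.90), rng.uniform(3.0, 6.5), _LESION)
    for _ in range(rng.poisson(spec.exudate_rate[grade])):
        _paint_disk(canvas, _in_annulus(0.0, 0.40), rng.uniform(2.5, 5.0), _EXUDATE)

    # mild shot-to-shot illumination shift across the whole frame,
    # background included, so classifiers can reference it away
    canvas += rng.normal(0, 0.5) + rng.normal(0, 0.25, size=3)
    if spec.noise_sd > 0:
        canvas += rng.normal(0, spec.noise_sd, canvas.shape)
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def generate_images(spec: SynthSpec) -> Tuple[List[FundusImage], np.ndarray]:
    """Generate ``n_per_class * n_classes`` labeled fundus-like images.

    Deterministic per seed; images are ordered class 0 first, labels returned
    aligned as an integer array.
    """
    rng = np.random.default_rng(spec.seed)
    template = _vessel_template(
        rng, spec.vessel_count, n_steps=int(spec.image_side * 0.45)
    )
    images, labels = [], []
    for grade in range(spec.n_classes):
        for i in range(spec.n_per_class):
            px = _render_fundus(rng, spec, grade, template)
            images.append(
                FundusImage(px, source_id=f"synth_g{grade}_{i:04d}", label=grade)
            )
            labels.append(grade)
    return images, np.asarray(labels)


@dataclass
class PlantedMatrixSpec:
    """Parameters of the planted-feature-matrix generator."""

    n: int = 200
    D: int = 50
    n_informative: int = 10
    effect_size: float = 1.5
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_informative <= self.D:
            raise ParameterError("n_informative must be in [0, D]")
        if self.n < self.n_classes or self.n_classes < 2:
            raise ParameterError("need n >= n_classes >= 2")


def generate_planted_matrix(
    spec: PlantedMatrixSpec,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian noise matrix with a known informative column subset.

    Noise features are standard normal.  Informative features are shifted by
    ``effect_size * (class - mean_class)`` so classes separate along them by
    ``effect_size`` noise-sd units per grade step.  Returns
    ``(matrix, labels, informative_indices)``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n) % spec.n_classes
    rng.shuffle(labels)
    X = rng.standard_normal((spec.n, spec.D))
    informative = np.sort(rng.choice(spec.D, size=spec.n_informative, replace=False))
    centered = labels - labels.mean()
    X[:, informative] += spec.effect_size * centered[:, None]
    return X, labels, informative
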