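"""Synthetic fluorescence images and study matrices with known ground truth.

Two generators make the whole pipeline testable without any acquisition
hardware:

* :func:`generate_synthetic_image` emulates a fluorescence-mode laparoscopy
  still: a uniform green intensity field with per-pixel Gaussian noise,
  optional pure-white specular reflections, and near-saturated (G = 255)
  vertical vessel streaks.
* :func:`simulate_study` emulates the pre/post measurement matrix: each
  subject draws a baseline perfusion level, the control segment fluctuates
  around it over time, and the ischemic segment drops by a multiplicative
  factor after vessel division (a relative drop, matching the scale-relative
  RMISD metric).  Late time points can be lost at random, mimicking animal
  dropout.

All randomness flows from a single seed; both generators are deterministic
given their spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SpecValidationError
from .image import RGBImage
from .study import POST_LABELS, StudyMatrix

_VESSEL_WIDTH = 3  # columns per synthetic vessel streak


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one synthetic fluorescence frame.

    ``base_green`` is the ground-truth tissue intensity on the 0-255 scale;
    ``background_rb`` sets the red/blue floor and must stay below
    ``base_green`` so tissue pixels are green-dominant.
    """

    height: int = 256
    width: int = 256
    base_green: float = 147.0
    noise_sd: float = 5.0
    reflection_fraction: float = 0.0
    n_vessels: int = 0
    background_rb: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.height < 1 or self.width < 1:
            problems.append("height and width must be >= 1")
        if not (0 <= self.base_green <= 255):
            problems.append(f"base_green must be in [0, 255], got {self.base_green}")
        if not (0 <= self.reflection_fraction <= 0.5):
            problems.append(
                f"reflection_fraction must be in [0, 0.5], got {self.reflection_fraction}"
            )
        if self.background_rb >= self.base_green:
            problems.append(
                f"background_rb ({self.background_rb}) must be below "
                f"base_green ({self.base_green})"
            )
        if self.n_vessels < 0 or self.noise_sd < 0:
            problems.append("n_vessels and noise_sd must be non-negative")
        if not problems:
            vessel_area = min(self.n_vessels * _VESSEL_WIDTH, self.width) * self.height
            covered = self.reflection_fraction + vessel_area / (self.height * self.width)
            if covered > 0.9:
                problems.append(
                    "infeasible spec: reflections plus vessel area cover "
                    f"{covered:.0%} of the image (> 90%)"
                )
        if problems:
            raise SpecValidationError("; ".join(problems))


@dataclass
class ImageGroundTruth:
    """What the generator actually drew, for recovery checks."""

    base_green: float
    true_mean: float  # realized mean G over clean tissue pixels (post-clipping)
    n_tissue: int
    vessel_columns: list[int]
    reflection_count: int
    tissue_mask: np.ndarray = field(repr=False)  # True where neither vessel nor reflection


def generate_synthetic_image(
    spec: SyntheticImageSpec,
) -> tuple[RGBImage, ImageGroundTruth]:
    """Draw one synthetic frame and report its realized ground truth.

    Green = base_green + N(0, noise_sd), rounded and clipped to [0, 255];
    red/blue = background_rb + independent noise.  Vessel streaks force
    G = 255 over ``_VESSEL_WIDTH``-column bands; reflections set exactly
    ``floor(reflection_fraction * H * W)`` pixels to (255, 255, 255).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    shape = (h, w)

    def channel(base: float) -> np.ndarray:
        vals = base + rng.normal(0.0, spec.noise_sd, size=shape)
        return np.clip(np.rint(vals), 0, 255).astype(np.uint8)

    g = channel(spec.base_green)
    r = channel(spec.background_rb)
    b = channel(spec.background_rb)

    vessel_mask = np.zeros(shape, dtype=bool)
    vessel_columns: list[int] = []
    if spec.n_vessels > 0:
        starts = rng.choice(
            max(w - _VESSEL_WIDTH + 1, 1), size=spec.n_vessels, replace=False
        ) if w - _VESSEL_WIDTH + 1 >= spec.n_vessels else rng.integers(
            0, max(w - _VESSEL_WIDTH + 1, 1), size=spec.n_vessels
        )
        for c0 in np.sort(starts):
            cols = range(int(c0), min(int(c0) + _VESSEL_WIDTH, w))
            for c in cols:
                vessel_mask[:, c] = True
                vessel_columns.append(c)
    g[vessel_mask] = 255

    n_reflect = int(np.floor(spec.reflection_fraction * h * w))
    reflect_flat = rng.choice(h * w, size=n_reflect, replace=False)
    reflect_mask = np.zeros(h * w, dtype=bool)
    reflect_mask[reflect_flat] = True
    reflect_mask = reflect_mask.reshape(shape)
    for ch in (r, g, b):
        ch[reflect_mask] = 255

    tissue = ~(vessel_mask | reflect_mask)
    img = RGBImage(np.stack([r, g, b], axis=-1))
    truth = ImageGroundTruth(
        base_green=spec.base_green,
        true_mean=float(g[tissue].mean()) if tissue.any() else float("nan"),
        n_tissue=int(tissue.sum()),
        vessel_columns=sorted(set(vessel_columns)),
        reflection_count=n_reflect,
        tissue_mask=tissue,
    )
    return img, truth


@dataclass(frozen=True)
class StudySimSpec:
    """Recipe for a simulated pre/post study matrix.

    Defaults mirror the experimental conditions: 8 subjects, baseline
    perfusion around 147 on the 0-255 scale with a between-subject SD of 13,
    within-subject between-time SD of 5, a 32.6% multiplicative drop in the
    ischemic segment, and a 25% per-subject chance of losing the two late
    time points.
    """

    n_subjects: int = 8
    mu_pre: float = 147.0
    sigma_between: float = 13.0
    sigma_time: float = 5.0
    drop_fraction: float = 0.326
    dropout_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if not (0 <= self.drop_fraction < 1):
            problems.append(f"drop_fraction must be in [0, 1), got {self.drop_fraction}")
        if self.sigma_between < 0 or self.sigma_time < 0:
            problems.append("standard deviations must be non-negative")
        if not (0 <= self.dropout_prob <= 1):
            problems.append(f"dropout_prob must be in [0, 1], got {self.dropout_prob}")
        if not (0 < self.mu_pre <= 255):
            problems.append(f"mu_pre must be in (0, 255], got {self.mu_pre}")
        if problems:
            raise SpecValidationError("; ".join(problems))


@dataclass
class StudyGroundTruth:
    drop_fraction: float
    mu_pre: float
    subject_baselines: dict[str, float]
    ischemic_segment: str = "left"


_LATE_LABELS = ("post105", "post135")


def simulate_study(spec: StudySimSpec) -> tuple[StudyMatrix, StudyGroundTruth]:
    """Simulate a study matrix with a known multiplicative ischemic drop.

    Per subject i with baseline ``pre_i ~ N(mu_pre, sigma_between)``:
    every control-segment ('right') observation is ``pre_i + N(0,
    sigma_time)``; every ischemic-segment ('left') post observation is
    ``pre_i * (1 - drop_fraction) + N(0, sigma_time)``.  Pre observations of
    both segments carry the same measurement noise.  All values are clipped
    to [0, 255].  With probability ``dropout_prob`` a subject loses its
    post105/post135 readings in both segments.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    baselines: dict[str, float] = {}
    for i in range(spec.n_subjects):
        sid = str(i + 1)
        pre_i = float(np.clip(rng.normal(spec.mu_pre, spec.sigma_between), 0, 255))
        baselines[sid] = pre_i
        lost_late = rng.random() < spec.dropout_prob

        def obs(level: float) -> float:
            return float(np.clip(level + rng.normal(0.0, spec.sigma_time), 0, 255))

        rows.append((sid, "right", "pre", obs(pre_i)))
        rows.append((sid, "left", "pre", obs(pre_i)))
        ischemic_level = pre_i * (1.0 - spec.drop_fraction)
        for label in POST_LABELS:
            if lost_late and label in _LATE_LABELS:
                continue
            rows.append((sid, "right", label, obs(pre_i)))
            rows.append((sid, "left", label, obs(ischemic_level)))
    frame = pd.DataFrame(
        rows, columns=["subject_id", "segment", "time_label", "saturation"]
    )
    return StudyMatrix(frame), StudyGroundTruth(
        drop_fraction=spec.drop_fraction,
        mu_pre=spec.mu_pre,
        subject_baselines=baselines,
    )


def images_for_study(
    study: StudyMatrix,
    height: int = 64,
    width: int = 64,
    noise_sd: float = 4.0,
    seed: int = 0,
) -> list[tuple[str, str, str, RGBImage, ImageGroundTruth]]:
    """Render one synthetic frame per study observation.

    Each observation's saturation becomes the frame's ``base_green``; the
    returned tuples are ``(subject_id, segment, time_label, image, truth)``.
    Used by the end-to-end pipeline tests: quantifying these frames and
    re-assembling a study matrix should recover the simulation's drop.
    """
    out = []
    base = np.random.SeedSequence(seed)
    frame = study.frame
    for child, (_, row) in zip(base.spawn(len(frame)), frame.iterrows()):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        base_green = float(row["saturation"])
        spec = SyntheticImageSpec(
            height=height,
            width=width,
            base_green=base_green,
            noise_sd=noise_sd,
            background_rb=min(40.0, base_green / 2),
            seed=sub_seed,
        )
        img, truth = generate_synthetic_image(spec)
        out.append((row["subject_id"], row["segment"], row["time_label"], img, truth))
    return out
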