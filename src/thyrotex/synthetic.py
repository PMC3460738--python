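"""Synthetic two-class ultrasound-like textures and cohorts.

The generator emulates, at the level of gray-value statistics, the
sonographic contrast between normal thyroid parenchyma and Hashimoto-like
tissue: a Hashimoto-like ROI has a lower mean echogenicity, stronger
multiplicative speckle (heterogeneous structure), more bright follicle-like
blobs and hyperechogenic linear fibrosis streaks.  It is a statistical test
phantom, not a physical B-mode simulation — see ``docs/methods.md`` for
what that implies about the scope of any results obtained on it.

A cohort mirrors the study design the pipeline targets: ``n_control``
healthy and ``n_case`` diseased subjects, four views per subject (left and
right lobe, transverse and longitudinal sections), with a per-subject
brightness effect so the four views of one subject are correlated.  The
default spec (29 controls + 65 cases × 4 views = 376 images) reproduces
that cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .image_io import median_filter_3x3
from .texture_features import FEATURE_NAMES, extract_feature_vector

VIEW_NAMES = (
    "left-transverse",
    "left-longitudinal",
    "right-transverse",
    "right-longitudinal",
)


@dataclass(frozen=True)
class TextureParams:
    """Parameters of one synthetic ROI texture.

    ``mean`` is the base echogenicity (0–255); ``speckle`` the relative
    dispersion of the multiplicative speckle; ``follicle_rate`` the expected
    (Poisson) number of bright elliptical blobs; ``streaks`` the number of
    bright linear fibrosis-like segments; ``side`` the square ROI size.
    """

    mean: float = 180.0
    speckle: float = 0.10
    follicle_rate: float = 3.0
    follicle_lift: float = 40.0
    follicle_radius: tuple = (2, 5)
    streaks: int = 0
    streak_lift: float = 60.0
    side: int = 64
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.mean <= 255:
            raise ValueError("mean brightness must lie in [0, 255]")
        if self.follicle_rate < 0:
            raise ValueError("follicle rate must be >= 0")
        if self.side < 8:
            raise ValueError("ROI side must be >= 8")


def control_params(side: int = 64, seed: int = 0) -> TextureParams:
    """Normal-echogenic parenchyma: bright, mildly speckled, few follicles."""
    return TextureParams(mean=160.0, speckle=0.12, follicle_rate=3.0, streaks=0, side=side, seed=seed)


def hashimoto_params(side: int = 64, seed: int = 0) -> TextureParams:
    """Hashimoto-like parenchyma: hypoechogenic, heterogeneous, fibrotic."""
    return TextureParams(
        mean=125.0,
        speckle=0.20,
        follicle_rate=6.0,
        follicle_lift=50.0,
        streaks=2,
        side=side,
        seed=seed,
    )


def make_texture(p: TextureParams) -> np.ndarray:
    """Render one synthetic ROI; deterministic given ``p.seed``.

    Base level × multiplicative Gaussian speckle, plus Poisson-count bright
    elliptical follicle blobs and optional bright line segments, clamped to
    the 8-bit range.
    """
    rng = np.random.default_rng(p.seed)
    s = p.side
    img = p.mean * (1.0 + p.speckle * rng.standard_normal((s, s)))

    rr, cc = np.mgrid[0:s, 0:s]
    for _ in range(rng.poisson(p.follicle_rate)):
        cy, cx = rng.uniform(0, s, size=2)
        a, b = rng.uniform(*p.follicle_radius, size=2)
        mask = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
        img[mask] += p.follicle_lift

    from skimage.draw import line

    for _ in range(p.streaks):
        y0, x0 = rng.uniform(0, s, size=2)
        angle = rng.uniform(0, np.pi)
        length = 0.6 * s
        y1 = np.clip(y0 + length * np.sin(angle), 0, s - 1)
        x1 = np.clip(x0 + length * np.cos(angle), 0, s - 1)
        seg = line(int(y0), int(x0), int(y1), int(x1))
        img[seg] += p.streak_lift

    return np.clip(np.round(img), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic two-class cohort.

    ``subject_sd`` is the SD of a per-subject brightness random effect (the
    four views of a subject share it); ``view_offsets``, if given, adds a
    fixed brightness offset per view to exercise split-stratification logic
    — by default views carry no signal.
    """

    n_control: int = 29
    n_case: int = 65
    views: int = 4
    control: TextureParams = field(default_factory=control_params)
    case: TextureParams = field(default_factory=hashimoto_params)
    subject_sd: float = 15.0
    view_offsets: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("need at least one subject per class")
        if self.views < 1:
            raise ValueError("need at least one view per subject")


@dataclass
class Cohort:
    """Labelled synthetic image set with its manifest.

    ``manifest`` columns: image_id, subject_id, view, class_label
    (0 = control/KON, 1 = Hashimoto-like/HAS); ``images[i]`` corresponds to
    ``manifest`` row ``i``.
    """

    images: list
    manifest: object  # pandas.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["class_label"].to_numpy()


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate ``(n_control + n_case) × views`` labelled ROI images."""
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    images, rows = [], []
    for label, n, base, tag in (
        (0, spec.n_control, spec.control, "kon"),
        (1, spec.n_case, spec.case, "has"),
    ):
        for s in range(n):
            subject_id = f"{tag}{s:03d}"
            mu = float(np.clip(base.mean + rng.normal(0.0, spec.subject_sd), 0, 255))
            for v in range(spec.views):
                view = VIEW_NAMES[v % len(VIEW_NAMES)]
                offset = spec.view_offsets[v] if spec.view_offsets else 0.0
                params = replace(
                    base,
                    mean=float(np.clip(mu + offset, 0, 255)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                images.append(make_texture(params))
                rows.append(
                    {
                        "image_id": f"{subject_id}-{view}",
                        "subject_id": subject_id,
                        "view": view,
                        "class_label": label,
                    }
                )
    return Cohort(images, pd.DataFrame(rows))


def cohort_features(cohort: Cohort, median: bool = True, **feature_kwargs):
    """Feature table of a cohort: manifest columns plus w1..w10.

    By default each ROI passes through the 3×3 median filter first,
    mirroring the preprocessing applied to clinical frames.
    """
    import pandas as pd

    rows = []
    for img in cohort.images:
        roi = median_filter_3x3(img) if median else img
        rows.append(extract_feature_vector(roi, **feature_kwargs).to_array())
    feats = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    return pd.concat([cohort.manifest.reset_index(drop=True), feats], axis=1)


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write the cohort as 8-bit PNGs plus a ``manifest.csv``."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for img, image_id in zip(cohort.images, cohort.manifest["image_id"]):
        iio.imwrite(directory / f"{image_id}.png", img)
    manifest_path = directory / "manifest.csv"
    cohort.manifest.to_csv(manifest_path, index=False)
    return manifest_path
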