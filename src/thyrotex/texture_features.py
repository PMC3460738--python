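"""The ten scalar texture features w(1)–w(10) of a thyroid-lobe ROI.

The features quantify the sonographic signature of chronic autoimmune
thyroiditis — decreased echogenicity, heterogeneous parenchyma, bright
follicles and fibrosis — on an 8-bit grayscale region of interest:

========  =============================================================
feature   meaning
========  =============================================================
w(1)      mean image power spectrum, Σ|DFT|²/(M·N); by Parseval this
          equals the sum of squared brightness values
w(2)      mean brightness over all regional-minimum pixels (8-connected
          plateaus every outside neighbour of which is strictly
          brighter) — average darkness after removing bright artifacts
w(3)      smoothness 1 − 1/(1+σ²), σ the standard deviation of
          brightness on the unit scale (values divided by 255)
w(4)      smallest gray level whose histogram count exceeds 20 % of the
          modal count — minimum brightness after suppressing sparsely
          populated dark bins
w(5)      distance from the origin of the centre of gravity of the
          binarized, normalized, symmetric gray-level co-occurrence
          matrix (GLCM, horizontal offset), 1-based indices
w(6)      number of set cells of that binary GLCM (spread of contrast)
w(7)–(10) quadtree block fractions: count(s)·s/(Ms·Ns) for block sides
          s = 1, 2, 4, 8 after decomposing the (power-of-two adjusted)
          ROI into brightness-homogeneous squares at a 10 % threshold
========  =============================================================

All operations take a 2-D uint8 array (see :func:`thyrotex.image_io.as_image`)
and are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix
from skimage.morphology import local_minima

from .image_io import as_image

FEATURE_NAMES = tuple(f"w{i}" for i in range(1, 11))


class DegenerateInputError(ValueError):
    """The input is too small or empty for the requested operation."""


@dataclass(frozen=True)
class FeatureVector:
    """The ten texture features of one ROI."""

    w1: float
    w2: float
    w3: float
    w4: float
    w5: float
    w6: float
    w7: float
    w8: float
    w9: float
    w10: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def __getitem__(self, i: int) -> float:
        """1-based access: ``fv[2]`` is w(2)."""
        if not 1 <= i <= 10:
            raise IndexError("feature index must be in 1..10")
        return getattr(self, f"w{i}")


def power_spectrum_mean(img: np.ndarray) -> float:
    """w(1): mean power of the unnormalized forward 2-D DFT.

    ``w1 = Σ_{p,q} |F(p,q)|² / (M·N)``, which by Parseval's identity equals
    the plain sum of squared pixel values.  The transform is computed
    literally so the feature stays defined exactly as stated.
    """
    img = as_image(img)
    f = np.fft.fft2(img.astype(np.float64))
    return float((np.abs(f) ** 2).sum() / img.size)


def regional_minima_map(img: np.ndarray) -> np.ndarray:
    """Binary map of regional minima (8-connected plateaus).

    A regional minimum is a maximal connected set of equal-valued pixels
    every outside neighbour of which is strictly brighter.  A constant
    image is a single plateau with no outside neighbours and is therefore
    one all-image minimum.
    """
    img = as_image(img)
    if img.min() == img.max():
        return np.ones(img.shape, dtype=bool)
    return local_minima(img, connectivity=2)


def regional_minima_mean(img: np.ndarray, reduce: str = "mean") -> float:
    """w(2): mean brightness of all regional-minimum pixels.

    Bright follicles and isolated bright speckle never form minima, so the
    feature reads out the background darkness of the tissue.  With
    ``reduce="min"`` the darkest minimum value is returned instead of the
    mean.
    """
    img = as_image(img)
    vals = img[regional_minima_map(img)]
    if reduce == "mean":
        return float(vals.mean())
    if reduce == "min":
        return float(vals.min())
    raise ValueError(f"reduce must be 'mean' or 'min', got {reduce!r}")


def smoothness(img: np.ndarray) -> float:
    """w(3): 1 − 1/(1+σ²) with σ the brightness std on the unit scale.

    Homogeneous tissue gives values close to 0; strongly heterogeneous
    texture pushes the feature towards (but never reaches) 1.
    """
    img = as_image(img)
    sigma = (img.astype(np.float64) / 255.0).std()
    return float(1.0 - 1.0 / (1.0 + sigma**2))


def filtered_histogram_minimum(img: np.ndarray, fraction: float = 0.2) -> float:
    """w(4): smallest gray level with histogram count > ``fraction``·mode.

    Bins holding fewer pixels than the fraction of the modal bin are treated
    as noise (isolated dark pixels) and skipped, so the feature is the
    minimum brightness after removing such distortions.
    """
    img = as_image(img)
    hist = np.bincount(img.ravel(), minlength=256)
    surviving = np.flatnonzero(hist > fraction * hist.max())
    return float(surviving[0])


@dataclass
class GLCMResult:
    """Gray-level co-occurrence matrix at the horizontal (0, +1) offset.

    ``raw[i, j]`` counts pairs with left-pixel level ``i`` and right-pixel
    level ``j`` (0-based storage; the feature formulas use 1-based indices).
    ``symmetric`` adds the transpose, ``normalized`` divides by the total,
    and ``binary`` keeps cells exceeding ``threshold`` times the normalized
    maximum.
    """

    raw: np.ndarray
    symmetric: np.ndarray
    normalized: np.ndarray
    binary: np.ndarray
    levels: int = 256


def glcm_build(img: np.ndarray, threshold: float = 0.1, levels: int = 256) -> GLCMResult:
    """Build the raw, symmetric, normalized and binarized GLCM.

    Horizontal nearest-neighbour pairs only: an Ms×Ns image yields exactly
    Ms·(Ns−1) raw pairs.  Binarization removes the effect of sparsely
    occurring neighbourhoods: cells survive iff their normalized value is
    strictly greater than ``threshold`` times the normalized maximum.
    """
    img = as_image(img)
    if img.shape[1] < 2:
        raise DegenerateInputError("GLCM needs at least two columns of pixels")
    raw = graycomatrix(img, distances=[1], angles=[0], levels=levels)[:, :, 0, 0]
    raw = raw.astype(np.int64)
    symmetric = raw + raw.T
    normalized = symmetric / symmetric.sum()
    binary = (normalized > threshold * normalized.max()).astype(np.uint8)
    return GLCMResult(raw, symmetric, normalized, binary, levels)


def glcm_features(g: GLCMResult) -> tuple[float, float]:
    """w(5), w(6): centre-of-gravity distance and area of the binary GLCM.

    Using 1-based matrix indices (gray level + 1), the centroid
    ``(x̄, ȳ) = (Σ B·m / ΣB, Σ B·n / ΣB)`` moves away from the origin for
    brighter textures; ``w5 = √(x̄² + ȳ²)`` and ``w6`` is the number of set
    cells, a measure of how many distinct neighbour-brightness combinations
    occur.
    """
    b = g.binary.astype(np.float64)
    total = b.sum()
    if total == 0:
        raise DegenerateInputError("binary GLCM has no set cells")
    m = np.arange(1, b.shape[0] + 1, dtype=np.float64)[:, None]
    n = np.arange(1, b.shape[1] + 1, dtype=np.float64)[None, :]
    xbar = (b * m).sum() / total
    ybar = (b * n).sum() / total
    return float(np.hypot(xbar, ybar)), float(total)


@dataclass
class QuadtreeResult:
    """Quadtree decomposition of the power-of-two adjusted ROI.

    ``counts[s]`` is the number of homogeneous s×s blocks; the block sides
    tile the S×S square exactly: Σ counts[s]·s² = S².
    """

    counts: dict[int, int]
    side: int
    threshold: float


def _largest_pow2(n: int) -> int:
    return 1 << (int(n).bit_length() - 1)


def quadtree_decompose(img: np.ndarray, t: float = 0.10) -> QuadtreeResult:
    """Recursive 4-way split into brightness-homogeneous square blocks.

    The image is first adjusted to a power-of-two square by centrally
    cropping to the largest inscribed 2^k × 2^k block (padding would
    fabricate homogeneous area).  A block is split whenever its brightness
    range exceeds ``t`` of the full dynamic range (t·255); leaves are
    homogeneous blocks or single pixels.
    """
    img = as_image(img)
    m, n = img.shape
    side = _largest_pow2(min(m, n))
    r0 = (m - side) // 2
    c0 = (n - side) // 2
    sq = img[r0 : r0 + side, c0 : c0 + side]
    limit = t * 255.0
    counts: dict[int, int] = {}

    def recurse(block: np.ndarray) -> None:
        s = block.shape[0]
        if s == 1 or int(block.max()) - int(block.min()) <= limit:
            counts[s] = counts.get(s, 0) + 1
            return
        h = s // 2
        recurse(block[:h, :h])
        recurse(block[:h, h:])
        recurse(block[h:, :h])
        recurse(block[h:, h:])

    recurse(sq)
    return QuadtreeResult(counts, side, t)


def quadtree_features(
    q: QuadtreeResult, ms: int | None = None, ns: int | None = None
) -> tuple[float, float, float, float]:
    """w(7)–w(10): normalized counts of 1×1, 2×2, 4×4 and 8×8 blocks.

    Each feature is ``counts(s)·s/(Ms·Ns)`` with the block *side* in the
    numerator and the adjusted dimensions in the denominator.  Many small
    blocks (w7, w8) indicate heterogeneous, contrast-rich texture; many
    large ones (w9, w10) indicate homogeneous parenchyma.
    """
    ms = q.side if ms is None else ms
    ns = q.side if ns is None else ns
    area = ms * ns
    return tuple(q.counts.get(s, 0) * s / area for s in (1, 2, 4, 8))


def extract_feature_vector(
    img: np.ndarray,
    *,
    quadtree_threshold: float = 0.10,
    glcm_threshold: float = 0.1,
    histogram_fraction: float = 0.2,
    minima_reduce: str = "mean",
) -> FeatureVector:
    """Compute all ten features of one ROI with the default parameters.

    The ROI must be at least 8×8 so that every feature — in particular the
    8×8 quadtree fraction w(10) — is defined.
    """
    img = as_image(img)
    if min(img.shape) < 8:
        raise DegenerateInputError("ROI must be at least 8x8 pixels")
    w1 = power_spectrum_mean(img)
    w2 = regional_minima_mean(img, reduce=minima_reduce)
    w3 = smoothness(img)
    w4 = filtered_histogram_minimum(img, fraction=histogram_fraction)
    w5, w6 = glcm_features(glcm_build(img, threshold=glcm_threshold))
    q = quadtree_decompose(img, t=quadtree_threshold)
    w7, w8, w9, w10 = quadtree_features(q)
    return FeatureVector(w1, w2, w3, w4, w5, w6, w7, w8, w9, w10)


def feature_table(images, labels=None, ids=None, **feature_kwargs):
    """Feature vectors of many ROIs as a DataFrame.

    Columns: ``image_id``, ``class_label`` (if given), ``w1``…``w10`` —
    one row per image, the on-disk CSV layout of the pipeline.
    """
    import pandas as pd

    images = list(images)
    if ids is None:
        ids = [f"img{i:04d}" for i in range(len(images))]
    rows = []
    for i, img in enumerate(images):
        fv = extract_feature_vector(img, **feature_kwargs)
        row = {"image_id": ids[i]}
        if labels is not None:
            row["class_label"] = labels[i]
        row.update(dict(zip(FEATURE_NAMES, fv.to_array())))
        rows.append(row)
    return pd.DataFrame(rows)
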