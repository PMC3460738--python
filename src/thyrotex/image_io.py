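"""Loading, denoising and cropping of grayscale ultrasound images.

All downstream texture features assume an 8-bit brightness scale, so every
loader in this module returns a 2-D ``uint8`` array with values in [0, 255].
Deeper DICOM pixel data are brought onto that scale by a linear min–max
mapping.  Preprocessing follows the usual speckle-denoising recipe: a 3×3
median filter applied to the full frame, after which a rectangular region
of interest (ROI) — in practice the upper part of a thyroid lobe, marked by
an operator — is cropped and analysed as a texture.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter


class FormatError(ValueError):
    """The file could not be read as a grayscale image."""


class ChannelError(FormatError):
    """The image has colour channels; a single-channel image is required."""


class BoundsError(ValueError):
    """A region of interest does not lie wholly inside the image."""


def as_image(arr) -> np.ndarray:
    """Validate and return a 2-D uint8 brightness matrix."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise FormatError(f"expected a nonempty 2-D image, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.floating) and (a.min() < 0 or a.max() > 255):
            raise FormatError("pixel values outside [0, 255]")
        if np.issubdtype(a.dtype, np.integer) and (a.min() < 0 or a.max() > 255):
            raise FormatError("pixel values outside [0, 255]")
        a = a.astype(np.uint8)
    return a


@dataclass(frozen=True)
class ROIRect:
    """Rectangular region of interest, 1-based inclusive origin.

    ``top``/``left`` index the first row/column of the rectangle using the
    matrix convention (row m, column n) starting at 1; ``height`` and
    ``width`` are pixel counts.
    """

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.top < 1 or self.left < 1:
            raise BoundsError("ROI origin indices are 1-based and must be >= 1")
        if self.height < 1 or self.width < 1:
            raise BoundsError("ROI height and width must be positive")

    @classmethod
    def parse(cls, text: str) -> "ROIRect":
        """Parse ``"top,left,height,width"`` as used on the command line."""
        parts = [int(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError("ROI must be 'top,left,height,width'")
        return cls(*parts)


def _rescale_to_8bit(arr: np.ndarray) -> np.ndarray:
    """Linear min–max mapping of an integer array onto 0–255."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def load_grayscale(path) -> np.ndarray:
    """Load a grayscale image from DICOM, PNG or TIFF.

    DICOM files must carry a single-frame monochrome pixel array; pixel data
    deeper than 8 bits are rescaled to 0–255 by linear min–max mapping (the
    texture features are defined on 8-bit brightness).  PNG/TIFF input must
    be single-channel; deeper-than-8-bit data are rescaled the same way.

    Raises
    ------
    FormatError
        If the file cannot be read as an image.
    ChannelError
        If the image has colour channels.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in {".dcm", ".dicom", ".ima"}:
        return _load_dicom(path)
    try:
        import imageio.v3 as iio

        arr = iio.imread(path)
    except Exception as exc:
        # Fall back to DICOM without an extension before giving up.
        try:
            return _load_dicom(path)
        except Exception:
            raise FormatError(f"cannot read {path} as an image: {exc}") from exc
    if arr.ndim == 3:
        raise ChannelError(f"{path} has {arr.shape[-1]} channels; expected grayscale")
    if arr.ndim != 2:
        raise FormatError(f"{path}: unsupported image dimensionality {arr.ndim}")
    if arr.dtype != np.uint8:
        arr = _rescale_to_8bit(arr)
    return as_image(arr)


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"cannot read {path} as DICOM: {exc}") from exc
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise ChannelError(f"{path}: colour DICOM (SamplesPerPixel > 1)")
    if arr.ndim == 3:
        raise FormatError(f"{path}: multi-frame DICOM not supported")
    if arr.dtype != np.uint8:
        arr = _rescale_to_8bit(arr)
    return as_image(arr)


def median_filter_3x3(img: np.ndarray) -> np.ndarray:
    """3×3 median filter with edge replication at the borders.

    The standard first step against ultrasound speckle; edge replication
    keeps the output range inside the input range.
    """
    img = as_image(img)
    return median_filter(img, size=3, mode="nearest")


def crop_roi(img: np.ndarray, roi: ROIRect) -> np.ndarray:
    """Return an independent copy of the ROI submatrix.

    Raises :class:`BoundsError` if the rectangle extends past the image.
    """
    img = as_image(img)
    m, n = img.shape
    r0, c0 = roi.top - 1, roi.left - 1
    r1, c1 = r0 + roi.height, c0 + roi.width
    if r1 > m or c1 > n:
        raise BoundsError(
            f"ROI {roi} extends past the {m}x{n} image (rows to {r1}, cols to {c1})"
        )
    return img[r0:r1, c0:c1].copy()
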