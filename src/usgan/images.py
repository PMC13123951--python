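"""Grey-scale image loading, saving, and preprocessing.

Conventions used throughout the package:

* in-memory images are 2-D float arrays with values in [0, 1];
* coordinates are (row, col), origin top-left, 0-based;
* crop windows are half-open;
* 8-bit PNG is the canonical interchange format between pipeline stages,
  DICOM is accepted on input only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger("usgan")


class ImageFormatError(ValueError):
    """Raised for unsupported image layouts (multi-frame, true-color, ...)."""


@dataclass
class GreyImage:
    """A 2-D grey-scale image with values in [0, 1].

    Attributes
    ----------
    values : ndarray
        2-D float array, every entry finite and within [0, 1].
    source_path : str or None
        Where the image was loaded from, if anywhere.
    bit_depth_of_origin : int
        Bit depth of the originating file (8, 12 or 16); 8 for
        images created in memory.
    """

    values: np.ndarray
    source_path: str | None = None
    bit_depth_of_origin: int = 8

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ImageFormatError(f"expected a 2-D array, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("image values must lie in [0, 1]")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def as_array(img) -> np.ndarray:
    """Accept a GreyImage or a bare array; return the float array in [0,1]."""
    if isinstance(img, GreyImage):
        return img.values
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ImageFormatError(f"expected a 2-D image, got shape {a.shape}")
    return a


def _load_png(path: Path) -> GreyImage:
    with Image.open(path) as im:
        im.load()
        if im.mode in ("L", "P"):
            arr = np.asarray(im.convert("L"), dtype=np.float64)
            return GreyImage(arr / 255.0, str(path), 8)
        if im.mode in ("I", "I;16"):
            arr = np.asarray(im, dtype=np.float64)
            return GreyImage(np.clip(arr / 65535.0, 0, 1), str(path), 16)
        if im.mode in ("RGB", "RGBA"):
            arr = np.asarray(im, dtype=np.float64)[..., :3]
            if not (np.array_equal(arr[..., 0], arr[..., 1])
                    and np.array_equal(arr[..., 0], arr[..., 2])):
                raise ImageFormatError(
                    f"{path}: true-color image; only grey-scale input is supported")
            return GreyImage(arr[..., 0] / 255.0, str(path), 8)
    raise ImageFormatError(f"{path}: unsupported PNG mode")


def _load_dicom(path: Path) -> GreyImage:
    import pydicom

    ds = pydicom.dcmread(path)
    nframes = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if nframes != 1:
        raise ImageFormatError(f"{path}: multi-frame DICOM not supported")
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise ImageFormatError(
            f"{path}: unsupported photometric interpretation {photometric!r}")
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: expected a single grey-scale frame")
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    arr = arr * slope + intercept
    bits = int(getattr(ds, "BitsStored", 8) or 8)
    if bits not in (8, 12, 16):
        raise ImageFormatError(f"{path}: unsupported bit depth {bits}")
    arr = np.clip(arr / (2**bits - 1), 0.0, 1.0)
    if photometric == "MONOCHROME1":
        logger.info("inverting MONOCHROME1 image %s on load", path)
        arr = 1.0 - arr
    return GreyImage(arr, str(path), bits)


def load_image(path) -> GreyImage:
    """Load a single-frame grey-scale PNG or DICOM image, rescaled to [0, 1].

    PNG values are divided by the bit-depth maximum; DICOM pixel data is
    passed through the stored rescale slope/intercept first, and
    MONOCHROME1 images are inverted so bright always means echogenic.
    RGB files whose three channels are identical are collapsed to one
    channel; genuinely colored input is rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return _load_dicom(path)
    return _load_png(path)


def save_image(img, path) -> None:
    """Write an image as 8-bit grey-scale PNG (values rounded to v*255)."""
    arr = as_array(img)
    q = np.round(np.clip(arr, 0, 1) * 255.0).astype(np.uint8)
    Image.fromarray(q, mode="L").save(Path(path))


def _resize_short_side(arr: np.ndarray, resize_to: int) -> np.ndarray:
    h, w = arr.shape
    short = min(h, w)
    if short == resize_to:
        return arr
    scale = resize_to / short
    nh, nw = max(int(round(h * scale)), resize_to), max(int(round(w * scale)), resize_to)
    im = Image.fromarray(np.clip(arr, 0, 1).astype(np.float32), mode="F")
    out = np.asarray(im.resize((nw, nh), Image.BILINEAR), dtype=np.float64)
    return np.clip(out, 0.0, 1.0)


def preprocess(img, resize_to: int, crop: int | None = None,
               seed: int | None = None) -> np.ndarray:
    """Resize so the short side equals ``resize_to``, then crop.

    With ``seed`` given the crop origin is drawn from a seeded generator
    (training augmentation); with ``seed=None`` a deterministic center
    crop is taken (inference). No-op when dimensions already match.
    """
    arr = as_array(img)
    if crop is not None and crop > resize_to:
        raise ValueError(f"crop ({crop}) exceeds resize_to ({resize_to})")
    out = _resize_short_side(arr, resize_to)
    if crop is None:
        return out
    h, w = out.shape
    if crop > h or crop > w:
        raise ValueError(f"crop ({crop}) exceeds resized dimensions {out.shape}")
    if seed is not None:
        rng = np.random.default_rng(seed)
        r0 = int(rng.integers(0, h - crop + 1))
        c0 = int(rng.integers(0, w - crop + 1))
    else:
        r0, c0 = (h - crop) // 2, (w - crop) // 2
    return out[r0:r0 + crop, c0:c0 + crop]
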