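"""Raw-capture preprocessing: grayscale conversion, denoising, binarization,
background flooding, speck removal, and the border-continuity trigger.

Images are plain numpy arrays throughout.  A grayscale image is a 2-D array of
intensities in [0, 255]; a binary mask is a 2-D array over {0, 1} with 1 marking
root foreground.  Coordinates are 0-based ``(row, col)`` with the origin at the
top-left corner, rows increasing downward (the direction of gravity for a root
system photographed in situ).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "to_grayscale",
    "denoise",
    "binarize",
    "flood_background",
    "remove_specks",
    "edge_continuity",
    "read_image",
    "write_mask",
    "as_mask",
]

# Rec. 601 luma weights, the conversion used by skimage.color.rgb2gray's
# predecessor and by most camera pipelines for single-channel previews.
_LUMA = np.array([0.299, 0.587, 0.114])


class InputError(ValueError):
    """Raised when an input image or coordinate violates a precondition."""


class ConfigError(ValueError):
    """Raised when a parameter value is outside its legal range."""


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to a single luminance channel.

    Single-channel input is passed through unchanged (idempotent).  RGB input
    is reduced with Rec. 601 weights (0.299 R + 0.587 G + 0.114 B); an alpha
    channel, if present, is ignored.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InputError("empty image")
    if image.ndim == 2:
        return image.astype(float)
    if image.ndim == 3 and image.shape[2] in (3, 4):
        rgb = image[..., :3].astype(float)
        return rgb @ _LUMA
    raise InputError(f"unsupported image shape {image.shape}")


def denoise(gray: np.ndarray, method: str = "median", window: int = 3) -> np.ndarray:
    """Smooth a grayscale image with a median or gaussian filter.

    ``window`` is the side of the square neighborhood and must be odd so the
    filter is centred.  For the gaussian variant the window is converted to a
    truncated kernel with ``sigma = window / 6`` (the conventional 3-sigma
    radius), which reproduces a direct small-kernel convolution.
    """
    gray = np.asarray(gray, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 3, got {window}")
    if method == "median":
        return ndimage.median_filter(gray, size=window, mode="nearest")
    if method == "gaussian":
        sigma = window / 6.0
        radius = window // 2
        return ndimage.gaussian_filter(gray, sigma=sigma, mode="nearest",
                                       truncate=radius / sigma)
    raise ConfigError(f"unknown denoise method {method!r}")


def binarize(gray: np.ndarray, threshold: float | None = None,
             invert: bool = False) -> np.ndarray:
    """Threshold a grayscale image into a {0, 1} root mask.

    With ``threshold=None`` the cut is chosen automatically by maximizing the
    between-class variance (Otsu's criterion).  Pixels at or above the cut
    become foreground; pass ``invert=True`` when roots are darker than the
    background.  A constant image yields an all-background mask rather than
    an error.
    """
    gray = np.asarray(gray, dtype=float)
    if threshold is None:
        if gray.min() == gray.max():
            return np.zeros(gray.shape, dtype=np.uint8)
        threshold = float(threshold_otsu(gray))
        # threshold_otsu returns the upper edge of the background class; use
        # a strict "greater" cut so the two classes split exactly.
        mask = gray > threshold
    else:
        if not 0 <= threshold <= 255:
            raise ConfigError(f"threshold {threshold} outside [0, 255]")
        mask = gray >= threshold
    if invert:
        mask = ~mask
    return mask.astype(np.uint8)


def flood_background(mask: np.ndarray, seed: tuple[int, int],
                     fill_holes: bool = True) -> np.ndarray:
    """Normalize the background by flooding from ``seed``.

    The 4-connected background component containing ``seed`` is kept as
    background.  When ``fill_holes`` is on, every other background component
    (a hole fully enclosed by roots, typically trapped soil) is filled with
    foreground.  Foreground pixels are never altered otherwise.
    """
    mask = as_mask(mask)
    r, c = seed
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        raise InputError(f"seed {seed} outside image")
    if mask[r, c]:
        raise InputError(f"seed {seed} lies on foreground")
    if not fill_holes:
        return mask.copy()
    # 4-connected background labelling preserves duality with the
    # 8-connected foreground.
    bg_labels, _ = ndimage.label(mask == 0, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    out = mask.copy()
    out[(mask == 0) & (bg_labels != bg_labels[r, c])] = 1
    return out


def remove_specks(mask: np.ndarray, min_px: int = 20) -> np.ndarray:
    """Drop every 8-connected foreground component smaller than ``min_px``.

    Components of exactly ``min_px`` pixels are retained.  This clears the
    isolated bright speckles produced by reflections and soil impurities
    before any skeleton-level processing.
    """
    if min_px < 1:
        raise ConfigError(f"min_px must be >= 1, got {min_px}")
    mask = as_mask(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.copy()
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_px) + 1
    return np.isin(labels, keep).astype(np.uint8)


def _has_long_run(line: np.ndarray, min_run: int = 5) -> bool:
    """True when ``line`` contains >= min_run consecutive foreground pixels."""
    run = 0
    for v in line:
        run = run + 1 if v else 0
        if run >= min_run:
            return True
    return False


def edge_continuity(mask: np.ndarray) -> dict[str, bool]:
    """Flag border sides where a root visibly continues past the frame.

    A side is flagged when its border row/column contains a run of more than
    four consecutive foreground pixels (read strictly: at least five).  This
    is the trigger that tells an acquisition loop the current view is
    incomplete and an adjacent view should be stitched; the stitching itself
    is outside this package.
    """
    mask = as_mask(mask)
    return {
        "top": _has_long_run(mask[0, :]),
        "bottom": _has_long_run(mask[-1, :]),
        "left": _has_long_run(mask[:, 0]),
        "right": _has_long_run(mask[:, -1]),
    }


def as_mask(mask: np.ndarray) -> np.ndarray:
    """Validate and coerce an array-like into a uint8 {0, 1} mask."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise InputError(f"mask must be a nonempty 2-D array, got shape {mask.shape}")
    if mask.dtype == bool:
        return mask.astype(np.uint8)
    vals = np.unique(mask)
    if np.isin(vals, (0, 1)).all():
        return mask.astype(np.uint8)
    if np.isin(vals, (0, 255)).all():
        return (mask > 0).astype(np.uint8)
    raise InputError("mask values must be in {0,1} (or 0/255 for serialized masks)")


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF raster as a numpy array (gray or RGB)."""
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_mask(path, mask: np.ndarray) -> None:
    """Serialize a {0, 1} mask as an 8-bit 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, (as_mask(mask) * 255).astype(np.uint8))
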