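"""Image containers, luminance conversion, file I/O and synthetic fixtures.

Images are plain :class:`numpy.ndarray` objects with a thin validation layer:

* a *gray image* is a 2-D ``float64`` array with intensities in ``[0, 1]``,
  indexed ``(row, col)`` = ``(y, x)``, 0-based, pixel centers on the integer
  grid;
* an *RGB image* is an ``(h, w, 3)`` array of linear channels in ``[0, 1]``;
* a *ground-truth mask* is a 2-D boolean array whose foreground component
  never touches the image border (the object of interest is assumed to lie
  entirely inside the displayed region).

Intensities are normalized to ``[0, 1]`` regardless of the source bit depth.
"""

from __future__ import annotations

import numpy as np

try:  # imageio v3 API
    import imageio.v3 as iio
except ImportError:  # pragma: no cover
    import imageio as iio

__all__ = [
    "validate_gray",
    "validate_rgb",
    "validate_mask",
    "to_luminance",
    "make_synthetic_image",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

#: ITU-R BT.709 luminance coefficients for linear R', G', B'.
BT709_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


def validate_gray(image: np.ndarray) -> np.ndarray:
    """Check gray-image invariants and return the array as float64."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"gray image must be at least 3x3, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("gray image contains non-finite intensities")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("gray image intensities must lie in [0, 1]")
    return arr


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check RGB-image invariants and return an (h, w, 3) float64 array."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"RGB image must have shape (h, w, 3), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("RGB image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("RGB channels must lie in [0, 1]")
    return arr


def validate_mask(mask: np.ndarray, *, image_shape: tuple[int, int] | None = None,
                  require_interior: bool = False) -> np.ndarray:
    """Check mask invariants; optionally that foreground avoids the border."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask values must be binary")
        arr = arr.astype(bool)
    if image_shape is not None and arr.shape != tuple(image_shape):
        raise ValueError(f"mask shape {arr.shape} does not match image {image_shape}")
    if require_interior:
        border = np.concatenate([arr[0], arr[-1], arr[:, 0], arr[:, -1]])
        if border.any():
            raise ValueError("foreground touches the image border")
    return arr


def to_luminance(rgb: np.ndarray) -> np.ndarray:
    """Convert linear RGB to true luminance (ITU-R BT.709).

    Computes ``0.2126 R' + 0.7152 G' + 0.0722 B'`` pixelwise.  The
    coefficients sum to one, so the output stays in ``[0, 1]``.
    """
    arr = validate_rgb(rgb)
    return arr @ BT709_WEIGHTS


def _star_mask(shape: tuple[int, int], shape_complexity: float,
               rng: np.random.Generator) -> np.ndarray:
    """Rasterize a star-domain region with a Fourier-perturbed boundary."""
    h, w = shape
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w
    base_r = 0.30 * min(h, w)

    # High-frequency boundary terms grow with the roughness knob so the
    # measured box-counting dimension of the contour increases with it.
    ks = np.arange(2, 17)
    amps = shape_complexity * 0.35 * ks.astype(float) ** -0.7
    phases = rng.uniform(0.0, 2.0 * np.pi, size=ks.size)

    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    theta = np.arctan2(dy, dx)
    radius = np.hypot(dy, dx)
    r_theta = base_r * (1.0 + np.sum(
        amps[:, None, None] * np.cos(ks[:, None, None] * theta[None] + phases[:, None, None]),
        axis=0))
    return radius < r_theta


def make_synthetic_image(shape_complexity: float = 0.3, noise_sd: float = 0.03,
                         size: tuple[int, int] = (64, 64), rng_seed: int = 0,
                         contrast: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Generate a gray image and ground-truth mask of graded boundary roughness.

    The foreground is a radial star domain whose boundary carries Fourier
    perturbations; the amplitude of high-frequency terms scales with
    ``shape_complexity`` in ``[0, 1]``, giving a monotone, measurable proxy
    for boundary fractal dimension.  Foreground and background mean
    intensities are separated by ``contrast``, with i.i.d. Gaussian pixel
    noise of standard deviation ``noise_sd``.  Deterministic given
    ``rng_seed``; the mask never touches the image border (regenerated with
    shrinking radius if necessary).

    Returns ``(image, mask)`` with the image in ``[0, 1]``.
    """
    if not 0.0 <= shape_complexity <= 1.0:
        raise ValueError("shape_complexity must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    h, w = size
    if h < 16 or w < 16:
        raise ValueError("size must be at least 16x16")

    rng = np.random.default_rng(rng_seed)
    mask = None
    for _ in range(20):
        cand = _star_mask((h, w), shape_complexity, rng)
        border = np.concatenate([cand[0], cand[-1], cand[:, 0], cand[:, -1]])
        if cand.any() and not border.any():
            mask = cand
            break
    if mask is None:
        raise RuntimeError("could not generate a border-free foreground")

    bg, fg = 0.5 - contrast / 2.0, 0.5 + contrast / 2.0
    image = np.where(mask, fg, bg).astype(np.float64)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return np.clip(image, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# File I/O: PNG and TIFF, intensities rescaled to [0, 1] internally.

_KNOWN_SUFFIXES = {".png", ".tif", ".tiff"}


def _check_format(path) -> None:
    from pathlib import Path
    suffix = Path(path).suffix.lower()
    if suffix not in _KNOWN_SUFFIXES:
        raise ValueError(f"unsupported image format {suffix!r}; use PNG or TIFF")


def write_image(path, image: np.ndarray, *, bit_depth: int = 8) -> None:
    _check_format(path)
    arr = validate_gray(image)
    if bit_depth == 8:
        iio.imwrite(path, np.round(arr * 255).astype(np.uint8))
    elif bit_depth == 16:
        iio.imwrite(path, np.round(arr * 65535).astype(np.uint16))
    else:
        raise ValueError("bit_depth must be 8 or 16")


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image; integer intensities are rescaled to [0, 1]."""
    _check_format(path)
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., :3]
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        arr = raw.astype(np.float64) / scale
    else:
        arr = raw.astype(np.float64)
    if arr.ndim == 3:
        return to_luminance(np.clip(arr, 0.0, 1.0))
    return validate_gray(np.clip(arr, 0.0, 1.0))


def write_mask(path, mask: np.ndarray) -> None:
    """Store a binary mask as a 0/255 single-channel PNG."""
    _check_format(path)
    arr = validate_mask(mask)
    iio.imwrite(path, np.where(arr, 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    _check_format(path)
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw > (np.iinfo(raw.dtype).max // 2 if np.issubdtype(raw.dtype, np.integer) else 0.5)
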