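"""Sobel gradient-magnitude preprocessing.

Bright-field micrographs of settled phytoplankton carry a smooth background
intensity gradient and weak absolute contrast.  Both problems vanish in the
gradient domain: a discrete 2D convolution with the two Sobel kernels, followed
by the Euclidean recombination ``H = sqrt(h_v**2 + h_h**2)``, produces an
edge-energy image in which filament borders dominate regardless of local
background level.

Conventions
-----------
* Images are 2D float arrays indexed ``(row, col)``, origin top-left.
* True convolution semantics (the kernel is index-reversed relative to
  correlation).  ``H`` is insensitive to this choice for the Sobel pair: flipping
  a kernel only flips the sign of its response, and the recombination squares it.
* Zero padding with same-size output: pixels outside the frame contribute 0.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d as _scipy_convolve2d

from acqua.errors import ValidationError

#: Sobel kernel enhancing vertical contrast (responds to horizontal gradients).
SOBEL_V = np.array([[-1.0, 0.0, 1.0],
                    [-2.0, 0.0, 2.0],
                    [-1.0, 0.0, 1.0]])

#: Sobel kernel enhancing horizontal contrast (responds to vertical gradients).
SOBEL_H = np.array([[1.0, 2.0, 1.0],
                    [0.0, 0.0, 0.0],
                    [-1.0, -2.0, -1.0]])

#: ITU-R BT.601 luminance weights for RGB → gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray(image: np.ndarray) -> np.ndarray:
    """Coerce an image to a 2D float array in roughly [0, 1].

    RGB(A) inputs are collapsed with fixed luminance weights; integer dtypes are
    rescaled by their type range so thresholds are portable across 8-/16-bit
    sources.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    elif arr.ndim != 2:
        raise ValidationError(f"expected a 2D or 3D image, got ndim={arr.ndim}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("image contains non-finite pixels")
    return arr


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2D image, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("image contains non-finite pixels")
    return arr


def convolve2d(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Discrete 2D convolution, zero-padded, same-size output.

    Parameters
    ----------
    image : 2D float array with finite values.
    kernel : 2D array with odd height and width, no larger than the image.

    Returns
    -------
    2D array of the same shape as ``image`` holding the true-convolution
    response (kernel index-reversed relative to correlation).
    """
    arr = _validate_image(image)
    ker = np.asarray(kernel, dtype=np.float64)
    if ker.ndim != 2 or ker.shape[0] % 2 == 0 or ker.shape[1] % 2 == 0:
        raise ValidationError(f"kernel must be 2D with odd dimensions, got {ker.shape}")
    if ker.shape[0] > arr.shape[0] or ker.shape[1] > arr.shape[1]:
        raise ValidationError(f"kernel {ker.shape} larger than image {arr.shape}")
    return _scipy_convolve2d(arr, ker, mode="same", boundary="fill", fillvalue=0.0)


def sobel_magnitude(image: np.ndarray) -> dict[str, np.ndarray]:
    """Two Sobel passes and their Euclidean recombination.

    Returns a dict with keys ``h_v`` (vertical-kernel response), ``h_h``
    (horizontal-kernel response) and ``H = sqrt(h_v**2 + h_h**2)``, all of the
    input's shape.  ``H`` is non-negative and invariant to the sign convention
    of the kernels.
    """
    arr = _validate_image(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValidationError(f"image must be at least 3x3 for Sobel, got {arr.shape}")
    h_v = convolve2d(arr, SOBEL_V)
    h_h = convolve2d(arr, SOBEL_H)
    return {"h_v": h_v, "h_h": h_h, "H": np.hypot(h_v, h_h)}


def normalize_gradient(H: np.ndarray) -> np.ndarray:
    """Linearly rescale a gradient-magnitude image to [0, 1].

    A constant (e.g. all-zero) input maps to all zeros rather than dividing by
    zero.
    """
    arr = _validate_image(H)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)
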