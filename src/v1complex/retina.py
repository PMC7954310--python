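"""Retinal/LGN-input pre-processing.

Models retinal ganglion-cell filtering as a divisively normalized
difference-of-Gaussians: a center Gaussian (std ``sigma_center``) minus a
surround Gaussian (std ``sigma_surround``), divided by a local-luminance
Gaussian (std ``sigma_divisive``).  This approximately whitens the 1/f
spectrum of natural input and removes local mean luminance.  Whitened
patches are then attenuated by a centered 2-D Gaussian window and split into
non-negative ON (positive part) and OFF (negative part, sign-flipped)
channels, one LGN cell per pixel per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["WhitenConfig", "NumericalDegeneracyError", "whiten_image",
           "whiten_stack", "to_luminance", "gaussian_window",
           "window_and_split", "window_and_split_batch"]


class NumericalDegeneracyError(ArithmeticError):
    """The divisive denominator of the whitening filter is non-positive."""


@dataclass
class WhitenConfig:
    """Pre-processing constants (all standard deviations in pixels).

    Defaults: center 1 px, surround 1.5 px (1.5 x center, the classic
    retinal center/surround ratio), divisive filter equal to the surround,
    window 3 px.  ``epsilon_div`` guards the divisive denominator, which can
    vanish on signed synthetic inputs (raw photographs are positive, so
    there it is a no-op).

    ``input_gain`` is a fixed gain applied to the whitened output.  It sets
    the overall contrast scale of everything the network sees — the model's
    learning dynamics have a definite operating range, and the absolute
    scale of the divisively normalized output depends on the stimulus
    ensemble.  The default (10) places the synthetic textures at a whitened
    standard deviation near 0.5.  The same gain applies to training images
    and characterization gratings, so learned responses and measured tuning
    are mutually consistent.
    """

    sigma_center: float = 1.0
    sigma_surround: float = 1.5
    sigma_divisive: float = 1.5
    sigma_window: float = 3.0
    epsilon_div: float = 1e-6
    input_gain: float = 10.0

    def __post_init__(self):
        for name in ("sigma_center", "sigma_surround", "sigma_divisive",
                     "sigma_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.epsilon_div < 0:
            raise ValueError("epsilon_div must be >= 0")


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Map an image affinely onto [0, 1] luminance.

    Whitening divides by local luminance, which is only meaningful for
    non-negative input (photographs and video frames are).  Signed
    zero-mean synthetic textures are mapped onto [0, 1] first; an already
    non-negative image is only rescaled by its maximum.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image) if lo == 0 else np.ones_like(image)
    if lo >= 0:
        return image / hi
    return (image - lo) / (hi - lo)


def _smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    # Truncated at 4 sigma; scipy renormalizes the discrete kernel to sum 1.
    # Mirror borders avoid edge artifacts that would dominate small patches.
    return ndimage.gaussian_filter(image, sigma, mode="mirror", truncate=4.0)


def whiten_image(image: np.ndarray, config: WhitenConfig | None = None,
                 ) -> np.ndarray:
    """Divisively normalized difference-of-Gaussians whitening.

    Returns ``(I0 - I1) / (Id + epsilon_div)`` where I0, I1, Id are the
    center, surround and divisive Gaussian convolutions of ``image``.
    A constant image whitens to exactly zero (unit-normalized kernels make
    numerator terms cancel).  Raises :class:`NumericalDegeneracyError` if
    the guarded denominator is non-positive anywhere.
    """
    config = config or WhitenConfig()
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    I0 = _smooth(image, config.sigma_center)
    I1 = _smooth(image, config.sigma_surround)
    Id = _smooth(image, config.sigma_divisive)
    den = Id + config.epsilon_div
    if np.any(den <= 0):
        raise NumericalDegeneracyError(
            "divisive denominator non-positive; input too negative for "
            "divisive normalization (increase epsilon_div or offset input)")
    return config.input_gain * (I0 - I1) / den


def whiten_stack(images: np.ndarray, config: WhitenConfig | None = None,
                 ) -> np.ndarray:
    """Vectorized :func:`whiten_image` for a ``(B, M, M)`` stack.

    Each image is whitened independently (zero smoothing along the batch
    axis); identical numerics to the single-image path.
    """
    config = config or WhitenConfig()
    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise ValueError(f"expected a (B, M, M) stack, got {images.shape}")

    def sm(sigma):
        return ndimage.gaussian_filter(images, (0.0, sigma, sigma),
                                       mode="mirror", truncate=4.0)

    I0 = sm(config.sigma_center)
    I1 = sm(config.sigma_surround)
    den = sm(config.sigma_divisive) + config.epsilon_div
    if np.any(den <= 0):
        raise NumericalDegeneracyError(
            "divisive denominator non-positive in stack whitening")
    return config.input_gain * (I0 - I1) / den


def gaussian_window(M: int, sigma: float = 3.0) -> np.ndarray:
    """Centered 2-D Gaussian attenuation window, peak value 1.

    Centered at the patch midpoint ``(M-1)/2`` so the window is symmetric.
    Amplitude-normalized (peak 1): it attenuates the periphery without
    rescaling the patch center.
    """
    c = (M - 1) / 2.0
    coords = np.arange(M, dtype=float) - c
    g = np.exp(-coords ** 2 / (2.0 * sigma ** 2))
    return np.outer(g, g)


def window_and_split(patch: np.ndarray, config: WhitenConfig | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Window a whitened M-by-M patch and split it into ON/OFF drives.

    The patch is multiplied elementwise by the Gaussian window, then
    positive values drive ON cells and the magnitudes of negative values
    drive OFF cells: ``x_on = max(w*p, 0)``, ``x_off = max(-w*p, 0)``.
    Both are returned flattened to length M².  At every pixel at most one
    channel is nonzero and ``x_on - x_off`` reconstructs the windowed patch.
    """
    config = config or WhitenConfig()
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square 2-D, got shape {patch.shape}")
    w = gaussian_window(patch.shape[0], config.sigma_window)
    v = (patch * w).ravel()
    return np.maximum(v, 0.0), np.maximum(-v, 0.0)


def window_and_split_batch(patches: np.ndarray,
                           config: WhitenConfig | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`window_and_split` for a ``(B, M, M)`` stack.

    Returns ``(x_on, x_off)`` of shape ``(M*M, B)`` each — the layout the
    network dynamics consume (cells along rows, stimuli along columns).
    """
    config = config or WhitenConfig()
    patches = np.asarray(patches, dtype=float)
    if patches.ndim != 3 or patches.shape[1] != patches.shape[2]:
        raise ValueError(f"expected (B, M, M) stack, got {patches.shape}")
    B, M, _ = patches.shape
    w = gaussian_window(M, config.sigma_window)
    v = (patches * w).reshape(B, M * M).T
    return np.maximum(v, 0.0), np.maximum(-v, 0.0)
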