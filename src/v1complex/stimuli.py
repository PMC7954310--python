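"""Stimulus generation.

Everything the network ever sees comes from here: sinusoidal gratings for
receptive-field characterization, synthetic naturalistic textures (1/f noise
and Gabor mixtures) that stand in for calibrated natural photographs and
natural video, jittered frame sequences that emulate the frame-to-frame
translations of video (or fixational eye movements over a static scene), and
random patch sampling.

Conventions
-----------
Images are 2-D float arrays indexed ``image[row, col]``.  The x-axis runs
rightward along columns, the y-axis downward along rows.  Grating orientation
is measured counter-clockwise from the x-axis in degrees; the spatial
coordinate origin sits at the pixel ``(size // 2, size // 2)`` so pixel
coordinates are integers.  All randomness is driven by explicit seeds or
`numpy.random.Generator` instances and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Grating",
    "FrameSequence",
    "make_grating",
    "make_jitter_sequence",
    "make_synthetic_naturalistic",
    "sample_patch",
    "sample_patches",
    "load_image",
    "write_fixture_set",
]


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed or a Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Gratings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grating:
    """Parameters of a static sinusoidal grating.

    Attributes
    ----------
    orientation : float
        Degrees in [0, 180), counter-clockwise from the x-axis.
    spatial_frequency : float
        Cycles per pixel, > 0.
    phase : float
        Degrees in [0, 360).
    size : int
        Side length of the square image in pixels.
    contrast : float
        Peak amplitude of the sinusoid (pixel values lie in ±contrast).
    """

    orientation: float
    spatial_frequency: float
    phase: float
    size: int
    contrast: float = 1.0

    def render(self) -> np.ndarray:
        return make_grating(
            self.orientation, self.spatial_frequency, self.phase,
            self.size, self.contrast,
        )


def make_grating(orientation: float, spatial_frequency: float, phase: float,
                 size: int, contrast: float = 1.0) -> np.ndarray:
    """Render a sinusoidal grating.

    ``image[y, x] = contrast * sin(2*pi*sf*(x*cos(theta) + y*sin(theta)) + phase)``
    with integer pixel coordinates, origin at ``(size//2, size//2)``.

    Parameters are in the units documented on :class:`Grating`.  Raises
    ``ValueError`` for non-positive ``size`` or ``spatial_frequency``.
    """
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    if spatial_frequency <= 0:
        raise ValueError(
            f"spatial_frequency must be > 0, got {spatial_frequency}")
    theta = np.deg2rad(orientation)
    phi = np.deg2rad(phase)
    coords = np.arange(size, dtype=float) - size // 2
    x = coords[np.newaxis, :]   # columns
    y = coords[:, np.newaxis]   # rows, downward
    arg = 2.0 * np.pi * spatial_frequency * (x * np.cos(theta)
                                             + y * np.sin(theta)) + phi
    return contrast * np.sin(arg)


def grating_batch(orientations, spatial_frequencies, phases, size,
                  contrast: float = 1.0) -> np.ndarray:
    """Render a stack of gratings for matched parameter vectors.

    ``orientations``, ``spatial_frequencies`` and ``phases`` are broadcast
    against each other; the result has shape ``(n, size, size)``.
    """
    ori, sf, ph = np.broadcast_arrays(
        np.atleast_1d(np.asarray(orientations, dtype=float)),
        np.atleast_1d(np.asarray(spatial_frequencies, dtype=float)),
        np.atleast_1d(np.asarray(phases, dtype=float)),
    )
    if np.any(sf <= 0):
        raise ValueError("spatial_frequency must be > 0")
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    theta = np.deg2rad(ori)[:, None, None]
    phi = np.deg2rad(ph)[:, None, None]
    coords = np.arange(size, dtype=float) - size // 2
    x = coords[np.newaxis, np.newaxis, :]
    y = coords[np.newaxis, :, np.newaxis]
    sf3 = sf[:, None, None]
    arg = 2.0 * np.pi * sf3 * (x * np.cos(theta) + y * np.sin(theta)) + phi
    return contrast * np.sin(arg)


# ---------------------------------------------------------------------------
# Frame sequences
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """An ordered stack of same-sized frames.

    ``frames`` has shape ``(n_frames, M, M)``.  ``provenance`` records where
    the frames came from: ``"video"``, ``"jitter"`` or ``"synthetic"``.
    """

    frames: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, M, M) array")
        if self.frames.shape[0] < 1:
            raise ValueError("a FrameSequence needs at least one frame")
        if self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be square")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_size(self) -> int:
        return self.frames.shape[1]


def make_jitter_sequence(image: np.ndarray, M: int, n_frames: int,
                         max_shift: int = 2, seed=None,
                         base_corner: tuple[int, int] | None = None,
                         ) -> FrameSequence:
    """Cut ``n_frames`` jittered M-by-M crops around one base location.

    Each frame is the base crop offset by an integer shift drawn uniformly
    from ``[-max_shift, max_shift]^2``, independently per frame.  The base
    top-left corner is drawn uniformly over positions for which every
    jittered crop stays in bounds (or may be supplied explicitly).  The same
    seed always yields the identical sequence.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    H, W = image.shape
    lo = max_shift
    hi_r = H - M - max_shift
    hi_c = W - M - max_shift
    if hi_r < lo or hi_c < lo:
        raise ValueError(
            f"image of shape {image.shape} too small for M={M} crops "
            f"with max_shift={max_shift}")
    rng = _as_rng(seed)
    if base_corner is None:
        r0 = int(rng.integers(lo, hi_r + 1))
        c0 = int(rng.integers(lo, hi_c + 1))
    else:
        r0, c0 = base_corner
        if not (lo <= r0 <= hi_r and lo <= c0 <= hi_c):
            raise ValueError(f"base_corner {base_corner} leaves jittered "
                             "crops out of bounds")
    shifts = rng.integers(-max_shift, max_shift + 1, size=(n_frames, 2))
    frames = np.empty((n_frames, M, M), dtype=float)
    for k, (dr, dc) in enumerate(shifts):
        frames[k] = image[r0 + dr:r0 + dr + M, c0 + dc:c0 + dc + M]
    return FrameSequence(frames, provenance="jitter")


# ---------------------------------------------------------------------------
# Synthetic naturalistic textures
# ---------------------------------------------------------------------------

def make_synthetic_naturalistic(size: int, seed=None,
                                kind: str = "pink") -> np.ndarray:
    """Generate a zero-mean, unit-variance naturalistic texture.

    kind="pink"
        Gaussian noise shaped to a 1/f amplitude spectrum — the second-order
        statistics of natural scenes.
    kind="gabor"
        A sum of random elongated Gabor patches (anisotropic envelopes,
        aspect ratio 2-9): oriented, non-Gaussian structure resembling the
        edge and contour content of natural images, which a pure 1/f
        Gaussian texture lacks.

    Both kinds are explicitly centered to zero mean and scaled to unit
    standard deviation, and are bit-reproducible for a fixed seed.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    rng = _as_rng(seed)
    if kind == "pink":
        white = rng.standard_normal((size, size))
        spec = np.fft.fft2(white)
        fy = np.fft.fftfreq(size)[:, None]
        fx = np.fft.fftfreq(size)[None, :]
        f = np.hypot(fy, fx)
        amp = np.zeros_like(f)
        nz = f > 0
        amp[nz] = 1.0 / f[nz]
        img = np.fft.ifft2(spec * amp).real
    elif kind == "gabor":
        img = np.zeros((size, size))
        n_gabors = max(16, (size * size) // 384)
        coords = np.arange(size, dtype=float)
        X, Y = np.meshgrid(coords, coords)
        for _ in range(n_gabors):
            cx, cy = rng.uniform(0, size, size=2)
            theta = rng.uniform(0, np.pi)
            sf = rng.uniform(0.10, 0.30)
            phi = rng.uniform(0, 2 * np.pi)
            sigma_across = rng.uniform(1.0, 2.0)
            sigma_along = rng.uniform(4.0, 9.0)
            ampl = rng.uniform(0.5, 1.5)
            dx, dy = X - cx, Y - cy
            u = dx * np.cos(theta) + dy * np.sin(theta)   # across stripes
            v = -dx * np.sin(theta) + dy * np.cos(theta)  # along stripes
            env = np.exp(-u ** 2 / (2 * sigma_across ** 2)
                         - v ** 2 / (2 * sigma_along ** 2))
            img += ampl * env * np.sin(2 * np.pi * sf * u + phi)
    else:
        raise ValueError(f"unknown kind {kind!r}; expected 'pink' or 'gabor'")
    img = img - img.mean()
    std = img.std()
    if std > 0:
        img = img / std
    return img


# ---------------------------------------------------------------------------
# Patch sampling
# ---------------------------------------------------------------------------

def sample_patch(source, M: int, seed=None):
    """Cut one random M-by-M patch (uniform top-left corner).

    ``source`` may be a 2-D image (returns an ``(M, M)`` array) or a
    :class:`FrameSequence` (returns ``(n_frames, M, M)``, the same window
    applied to every frame).
    """
    rng = _as_rng(seed)
    if isinstance(source, FrameSequence):
        F = source.frames
        H, W = F.shape[1], F.shape[2]
        r0, c0 = _random_corner(H, W, M, rng)
        return F[:, r0:r0 + M, c0:c0 + M].copy()
    image = np.asarray(source, dtype=float)
    H, W = image.shape
    r0, c0 = _random_corner(H, W, M, rng)
    return image[r0:r0 + M, c0:c0 + M].copy()


def sample_patches(image: np.ndarray, M: int, n: int, seed=None) -> np.ndarray:
    """Cut ``n`` independent random M-by-M patches from one image.

    Returns an ``(n, M, M)`` array.  Used for the batched simple-cell
    training protocol (a batch of independently placed patches per epoch).
    """
    rng = _as_rng(seed)
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    if H < M or W < M:
        raise ValueError(f"image of shape {image.shape} smaller than M={M}")
    r0 = rng.integers(0, H - M + 1, size=n)
    c0 = rng.integers(0, W - M + 1, size=n)
    out = np.empty((n, M, M), dtype=float)
    for k in range(n):
        out[k] = image[r0[k]:r0[k] + M, c0[k]:c0[k] + M]
    return out


def _random_corner(H, W, M, rng):
    if H < M or W < M:
        raise ValueError(f"source of shape ({H}, {W}) smaller than M={M}")
    return int(rng.integers(0, H - M + 1)), int(rng.integers(0, W - M + 1))


# ---------------------------------------------------------------------------
# File I/O (fixtures and external images)
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read an image file as grayscale double in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:            # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def write_fixture_set(out_dir, n_images: int, size: int, seed: int,
                      kind: str = "gabor") -> "pathlib.Path":
    """Write a directory of PNG textures plus a CSV manifest.

    Returns the manifest path.  Pixel values are affinely mapped to 8-bit
    [0, 255] per image; the manifest records filename, seed, kind and size.
    """
    import csv

    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "seed", "kind", "size"])
        for k in range(n_images):
            img = make_synthetic_naturalistic(size, seed=seed + k, kind=kind)
            lo, hi = img.min(), img.max()
            img8 = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
            name = f"{kind}_{seed + k:05d}.png"
            iio.imwrite(out_dir / name, (img8 * 255).astype(np.uint8))
            writer.writerow([name, seed + k, kind, size])
    return manifest
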