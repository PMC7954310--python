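"""Receptive-field characterization battery.

Model cells are probed with sinusoidal gratings exactly as in drifting-
grating physiology: an exhaustive coarse search finds each cell's preferred
orientation / spatial frequency / phase; a 100-point spatial-phase tuning
curve at the preferred grating yields the F1/F0 modulation ratio (F1 = the
amplitude of the fundamental across one phase cycle, F0 = the mean) — the
standard simple/complex classifier (complex: F1/F0 < 1); a 100-point
orientation tuning curve (mean over all phases per orientation), smoothed by
a Hanning filter of 13.5° half-width at half-height, yields the preferred
orientation and the orientation half-bandwidth (half of the full width at
half height, capped at 90°; 90° ≈ orientation invariant).

A *model cell* here is any callable mapping a stack of images ``(B, M, M)``
to non-negative rates — shape ``(B,)`` for a single cell or ``(B, n)`` for a
population evaluated jointly.  Factories are provided for the trained
network and for closed-form reference cells (the quadrature-pair energy
model, which is perfectly phase invariant, and a rectified linear cell,
which has F1/F0 = pi/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import complex_layer, lgn_simple, retina
from .stimuli import grating_batch, make_grating

__all__ = [
    "TuningSummary", "SearchGrids", "grating_search", "phase_tuning_curve",
    "f1f0_ratio", "orientation_tuning_curve", "hanning_kernel",
    "smooth_orientation_curve", "orientation_summary", "energy_model_cell",
    "rectified_linear_cell", "network_response_fn", "simple_response_fn",
    "orientation_selectivity_index", "characterize_population",
    "spontaneous_rates",
]


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchGrids:
    """Search and tuning-curve grids (degrees / cycles per pixel).

    Defaults: coarse search over 12 orientations (15° steps) x 8 spatial
    frequencies (0.05–0.40 in 0.05 steps) x 36 phases (10° steps); tuning
    curves use 100 phases (3.6° steps) and 100 orientations (1.8° steps).
    """

    orientations: tuple = tuple(np.arange(0.0, 180.0, 15.0))
    spatial_frequencies: tuple = tuple(np.round(np.arange(1, 9) * 0.05, 10))
    phases: tuple = tuple(np.arange(0.0, 360.0, 10.0))
    n_curve_phases: int = 100
    n_curve_orientations: int = 100
    contrast: float = 1.0


def _eval(cell_fn, images: np.ndarray) -> np.ndarray:
    """Evaluate a model cell on a stack, returning (B, n_cells)."""
    r = np.asarray(cell_fn(images), dtype=float)
    if r.ndim == 1:
        r = r[:, None]
    return r


# ---------------------------------------------------------------------------
# Model-cell factories
# ---------------------------------------------------------------------------

def _quadrature_filters(orientation, spatial_frequency, phase, size,
                        sigma=None):
    theta = np.deg2rad(orientation)
    phi = np.deg2rad(phase)
    coords = np.arange(size, dtype=float) - size // 2
    x = coords[np.newaxis, :]
    y = coords[:, np.newaxis]
    u = 2 * np.pi * spatial_frequency * (x * np.cos(theta)
                                         + y * np.sin(theta)) + phi
    env = 1.0 if sigma is None else np.exp(-(x ** 2 + y ** 2)
                                           / (2.0 * sigma ** 2))
    return env * np.cos(u), env * np.sin(u)


def energy_model_cell(orientation: float, spatial_frequency: float,
                      phase: float = 0.0, size: int = 16,
                      sigma: float | None = None, gain: float = 1.0):
    """Closed-form quadrature-pair energy model: r = (f1·s)² + (f2·s)².

    ``f1`` and ``f2`` are 90°-phase-shifted (cosine/sine) Gabors; with
    ``sigma=None`` the envelope is flat, making the cell *exactly* phase
    invariant at its matched on-grid grating.  Serves as the oracle for the
    invariance metrics.
    """
    f1, f2 = _quadrature_filters(orientation, spatial_frequency, phase,
                                 size, sigma)
    v1, v2 = f1.ravel(), f2.ravel()

    def cell(images: np.ndarray) -> np.ndarray:
        S = np.asarray(images, dtype=float).reshape(len(images), -1)
        return gain * ((S @ v1) ** 2 + (S @ v2) ** 2)

    return cell


def rectified_linear_cell(filt: np.ndarray, threshold: float = 0.0):
    """Half-wave-rectified linear cell r = max(f·s - threshold, 0)."""
    v = np.asarray(filt, dtype=float).ravel()

    def cell(images: np.ndarray) -> np.ndarray:
        S = np.asarray(images, dtype=float).reshape(len(images), -1)
        return np.maximum(S @ v - threshold, 0.0)

    return cell


def simple_response_fn(simple_connectome, constants=None, whiten=None,
                       whiten_input: bool = True):
    """Model-cell callable for the simple-cell population.

    Maps ``(B, M, M)`` images through the retinal pipeline (optional
    whitening, Gaussian window, ON/OFF split) and the network dynamics,
    returning steady-state simple rates ``(B, n_simple)``.
    """
    constants = constants or lgn_simple.LayerConstants()
    whiten = whiten or retina.WhitenConfig()

    def cells(images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if whiten_input:
            # Present each image as screen luminance in [0, 1] (a grating
            # modulates around mean gray), then whiten with the same
            # config — including input gain — used during training.
            images = np.stack([retina.to_luminance(im) for im in images])
            images = retina.whiten_stack(images, whiten)
        x_on, x_off = retina.window_and_split_batch(images, whiten)
        state = lgn_simple.run_dynamics(x_on, x_off, simple_connectome,
                                        constants)
        return state.r_S.T

    return cells


def network_response_fn(simple_connectome, complex_connectome,
                        constants=None, whiten=None,
                        whiten_input: bool = True, evoked: bool = True):
    """Model-cell callable for the complex-cell population.

    A static grating is one self-similar "sequence", so the complex input
    is just the scaled simple response, ``x_C = input_scale * r_S``, pooled
    linearly by the learned weights.  With ``evoked`` (default) the simple
    cells' spontaneous rates are subtracted (rectified) first, matching the
    input convention used during complex-layer training.
    """
    simple_fn = simple_response_fn(simple_connectome, constants, whiten,
                                   whiten_input)
    scale = complex_connectome.input_scale
    spont = (complex_layer.simple_spontaneous_rates(simple_connectome,
                                                    constants)
             if evoked else None)

    def cells(images: np.ndarray) -> np.ndarray:
        r_S = simple_fn(images).T               # (n_simple, B)
        if spont is not None:
            r_S = np.maximum(r_S - spont[:, None], 0.0)
        return complex_layer.complex_response(scale * r_S,
                                              complex_connectome).T

    return cells


# ---------------------------------------------------------------------------
# Grating search
# ---------------------------------------------------------------------------

def grating_search(model_cell, size: int, grids: SearchGrids | None = None):
    """Exhaustive coarse search for each cell's preferred grating.

    Evaluates the full orientation x spatial-frequency x phase grid (in
    that, lexicographic, order) and returns
    ``(preferred_orientation, preferred_sf, preferred_phase, degenerate)``
    as arrays over cells.  Ties break to the lowest grid point (first
    argmax); a cell whose response is constant over the whole grid is
    flagged degenerate and assigned the first grid point.
    """
    grids = grids or SearchGrids()
    O, F, P = np.meshgrid(grids.orientations, grids.spatial_frequencies,
                          grids.phases, indexing="ij")
    images = grating_batch(O.ravel(), F.ravel(), P.ravel(), size,
                           grids.contrast)
    resp = _eval(model_cell, images)          # (n_grid, n_cells)
    best = np.argmax(resp, axis=0)
    degenerate = resp.max(axis=0) - resp.min(axis=0) <= 0
    return (O.ravel()[best], F.ravel()[best], P.ravel()[best], degenerate)


# ---------------------------------------------------------------------------
# Phase tuning and F1/F0
# ---------------------------------------------------------------------------

def phase_tuning_curve(model_cell, preferred_orientation, preferred_sf,
                       size: int, grids: SearchGrids | None = None):
    """Steady-state responses to 100 phases at the preferred grating.

    Phases span 0–360° in steps of 3.6°, each grating presented
    independently.  Returns ``(phases_deg, responses)`` with responses of
    shape ``(100,)`` or ``(100, n_cells)``.
    """
    grids = grids or SearchGrids()
    n = grids.n_curve_phases
    phases = np.arange(n) * (360.0 / n)
    images = grating_batch(np.full(n, preferred_orientation),
                           np.full(n, preferred_sf), phases, size,
                           grids.contrast)
    resp = _eval(model_cell, images)
    return phases, (resp[:, 0] if resp.shape[1] == 1 else resp)


def f1f0_ratio(phase_curve: np.ndarray) -> float:
    """Modulation ratio of a tuning curve sampled over one full phase cycle.

    F0 is the curve mean; F1 is the peak amplitude of the fundamental,
    ``2 |DFT_1| / n``.  A constant curve gives 0 (complete phase
    invariance); values near 2 indicate sharp phase selectivity (for a
    non-negative curve F1/F0 <= 2).  An identically zero curve is defined
    as 0; F0 = 0 with a nonzero curve is impossible for non-negative rates
    and raises ``ValueError``.
    """
    curve = np.asarray(phase_curve, dtype=float)
    if curve.ndim != 1 or curve.size < 2:
        raise ValueError("phase curve must be 1-D with >= 2 points")
    n = curve.size
    f0 = curve.mean()
    if f0 == 0.0:
        if np.any(curve != 0.0):
            raise ValueError("zero-mean but nonzero curve: rates must be "
                             "non-negative")
        return 0.0
    if np.ptp(curve) == 0.0:
        return 0.0          # constant curve: exactly unmodulated
    f1 = 2.0 * np.abs(np.fft.rfft(curve)[1]) / n
    return float(f1 / f0)


# ---------------------------------------------------------------------------
# Orientation tuning
# ---------------------------------------------------------------------------

def orientation_tuning_curve(model_cell, preferred_sf, size: int,
                             grids: SearchGrids | None = None):
    """Mean response over all phases, per orientation.

    100 orientations (0–180°, 1.8° steps) x 100 phases = 10^4 gratings at
    the preferred spatial frequency; the curve holds the phase-averaged
    response per orientation.  Returns ``(orientations_deg, curve)``.
    """
    grids = grids or SearchGrids()
    n_o = grids.n_curve_orientations
    n_p = grids.n_curve_phases
    oris = np.arange(n_o) * (180.0 / n_o)
    phases = np.arange(n_p) * (360.0 / n_p)
    O, P = np.meshgrid(oris, phases, indexing="ij")
    images = grating_batch(O.ravel(), np.full(O.size, preferred_sf),
                           P.ravel(), size, grids.contrast)
    resp = _eval(model_cell, images)              # (n_o*n_p, n_cells)
    curve = resp.reshape(n_o, n_p, -1).mean(axis=1)
    return oris, (curve[:, 0] if curve.shape[1] == 1 else curve)


def hanning_kernel(step_deg: float = 1.8,
                   half_width_half_height: float = 13.5) -> np.ndarray:
    """Unit-sum Hanning window sampled on the tuning-curve grid.

    A raised cosine of half-support W has half-height at W/2, so the window
    spans ±2*half_width_half_height.  The default (13.5° at 1.8° steps)
    gives a 31-tap kernel.
    """
    W = 2.0 * half_width_half_height
    n_side = int(np.floor(W / step_deg))
    offsets = np.arange(-n_side, n_side + 1) * step_deg
    w = 0.5 * (1.0 + np.cos(np.pi * offsets / W))
    return w / w.sum()


def smooth_orientation_curve(curve: np.ndarray,
                             step_deg: float = 1.8) -> np.ndarray:
    """Circular (period-180°) convolution with the Hanning kernel."""
    curve = np.asarray(curve, dtype=float)
    kernel = hanning_kernel(step_deg)
    n_side = len(kernel) // 2
    padded = np.concatenate([curve[-n_side:], curve, curve[:n_side]])
    return np.convolve(padded, kernel, mode="valid")


def orientation_summary(orientation_curve: np.ndarray,
                        orientations: np.ndarray | None = None):
    """Preferred orientation and half-bandwidth from a 100-point curve.

    The curve is circularly smoothed with the Hanning kernel; the preferred
    orientation is the smoothed argmax; the half-bandwidth is half of the
    full width at half of the smoothed peak (crossings located by linear
    interpolation, measured circularly around the peak), capped at 90°.
    Returns ``(preferred_orientation, half_bandwidth, untuned)``; a curve
    that is zero everywhere is flagged untuned (bandwidth 90°).
    """
    curve = np.asarray(orientation_curve, dtype=float)
    n = curve.size
    step = 180.0 / n
    if orientations is None:
        orientations = np.arange(n) * step
    if np.all(curve == 0):
        return float(orientations[0]), 90.0, True
    s = smooth_orientation_curve(curve, step)
    i0 = int(np.argmax(s))
    half = s[i0] / 2.0

    def extent(direction: int) -> float:
        # Steps from the peak to the half-height crossing, interpolated.
        for k in range(1, n):
            j = (i0 + direction * k) % n
            if s[j] < half:
                prev = s[(i0 + direction * (k - 1)) % n]
                frac = (prev - half) / (prev - s[j])
                return (k - 1) + frac
        return float(n)  # never drops below half: full circle

    left, right = extent(-1), extent(+1)
    full_width = min((left + right) * step, 180.0)
    return float(orientations[i0]), float(min(full_width / 2.0, 90.0)), False


def orientation_selectivity_index(orientation_curve: np.ndarray) -> float:
    """(r_max - r_min) / (r_max + r_min); 0 for an all-zero curve."""
    curve = np.asarray(orientation_curve, dtype=float)
    hi, lo = curve.max(), curve.min()
    if hi + lo == 0:
        return 0.0
    return float((hi - lo) / (hi + lo))


# ---------------------------------------------------------------------------
# Population characterization
# ---------------------------------------------------------------------------

@dataclass
class TuningSummary:
    """Per-cell tuning summary.

    ``preferred_orientation`` (deg), ``preferred_sf`` (cycles/pixel) and
    ``preferred_phase`` (deg) come from the coarse search; ``f1f0`` from the
    100-point phase curve; ``half_bandwidth`` (deg, in (0, 90]) from the
    smoothed 100-point orientation curve.  ``label`` is "complex" iff
    F1/F0 < 1 (otherwise "simple"); degenerate cells are labelled
    "untuned".
    """

    cell_id: int
    preferred_orientation: float
    preferred_sf: float
    preferred_phase: float
    f1f0: float
    half_bandwidth: float
    label: str
    phase_curve: np.ndarray | None = None
    orientation_curve: np.ndarray | None = None


def spontaneous_rates(model_cell, size: int) -> np.ndarray:
    """Response to a blank (all-zero) stimulus, per cell."""
    return _eval(model_cell, np.zeros((1, size, size)))[0]


def characterize_population(model_cell, n_cells: int, size: int,
                            grids: SearchGrids | None = None,
                            keep_curves: bool = False,
                            subtract_spontaneous: bool = False):
    """Full battery for a population callable; returns a pandas DataFrame.

    Cells sharing a preferred (orientation, sf) — or just an sf for the
    orientation curves — are measured with shared grating batches, so the
    cost scales with the number of distinct preferences rather than the
    number of cells.  Columns: cell_id, preferred_orientation, preferred_sf,
    preferred_phase, f1f0, half_bandwidth, label.  With ``keep_curves`` the
    raw 100-point curves are attached as list columns.

    ``subtract_spontaneous`` computes F1/F0 and the orientation summary on
    evoked responses (rate minus the blank-stimulus rate, floored at zero)
    — the drifting-grating convention when cells have a spontaneous rate.
    Closed-form reference cells have none, so the default is off.
    """
    import pandas as pd

    grids = grids or SearchGrids()
    spont = (spontaneous_rates(model_cell, size) if subtract_spontaneous
             else None)
    pref_ori, pref_sf, pref_phase, degenerate = grating_search(
        model_cell, size, grids)
    n = len(pref_ori)
    if n != n_cells:
        raise ValueError(f"model returned {n} cells, expected {n_cells}")

    f1f0 = np.zeros(n)
    phase_curves = [None] * n
    ori_curves = [None] * n
    half_bw = np.zeros(n)
    ori_from_curve = np.array(pref_ori, dtype=float)

    for ori, sf in sorted({(o, s) for o, s in zip(pref_ori, pref_sf)}):
        members = np.flatnonzero((pref_ori == ori) & (pref_sf == sf))
        _, resp = phase_tuning_curve(model_cell, ori, sf, size, grids)
        resp = np.atleast_2d(resp.T).T       # (100, n_cells)
        if spont is not None:
            resp = np.maximum(resp - spont[None, :], 0.0)
        for i in members:
            phase_curves[i] = resp[:, i]
            f1f0[i] = f1f0_ratio(resp[:, i])

    for sf in sorted(set(pref_sf)):
        members = np.flatnonzero(pref_sf == sf)
        oris, curves = orientation_tuning_curve(model_cell, sf, size, grids)
        curves = np.atleast_2d(curves.T).T   # (100, n_cells)
        if spont is not None:
            curves = np.maximum(curves - spont[None, :], 0.0)
        for i in members:
            ori_curves[i] = curves[:, i]
            po, bw, untuned = orientation_summary(curves[:, i], oris)
            half_bw[i] = bw
            if not untuned:
                ori_from_curve[i] = po

    no_evoked = np.array([c is None or not np.any(c) for c in phase_curves])
    labels = np.where(degenerate | no_evoked, "untuned",
                      np.where(f1f0 < 1.0, "complex", "simple"))
    table = pd.DataFrame({
        "cell_id": np.arange(n),
        "preferred_orientation": pref_ori,
        "preferred_sf": pref_sf,
        "preferred_phase": pref_phase,
        "f1f0": f1f0,
        "half_bandwidth": half_bw,
        "label": labels,
    })
    if keep_curves:
        table["phase_curve"] = phase_curves
        table["orientation_curve"] = ori_curves
    return table
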