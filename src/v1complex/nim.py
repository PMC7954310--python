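"""Nonlinear Input Model (NIM) fitting and feature-subspace tuning breadths.

The NIM is an LN-cascade with K parallel streams: the rate is
``r = f(sum_k g_k(h_k . s))`` where the ``h_k`` are spatial filters, the
``g_k`` are nonparametric scalar input nonlinearities (here piecewise-linear
tent functions on a fixed knot grid) and ``f`` is the softplus-family
spiking nonlinearity ``f(x) = sigma * log(1 + exp((x - theta)/sigma)) +
delta``.  Fitting maximizes the Poisson log-likelihood of the observed
rates by alternating maximization over (filters | nonlinearities | spiking
parameters), with restarts; filters are initialized from the response-
weighted stimulus statistics (spike-triggered average and covariance),
which for quadrature-energy responses already point at the true subspace.

The fitted filters span the cell's *feature subspace*: the set of spatial
features the cell is sensitive to.  Tuning breadths probe that subspace
directly: unit-norm features are sampled densely from the span, the minimal
contrast driving the cell to a reference rate is found per feature by
bisection, and the orientation / spatial-frequency / spatial-phase breadths
are the (circular) ranges of those attributes over the features needing
less than twice the contrast of the cell's most sensitive feature —
capped at 180°, 0.6 cpd and 360°.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import expit

from .stimuli import _as_rng

__all__ = [
    "NIMModel", "BreadthSummary", "FitConfig", "FitDegeneracyError",
    "UnreachableRateError", "nim_predict", "nim_fit", "feature_breadths",
    "rescale_model", "spiking_nonlinearity", "feature_attributes",
    "save_nim", "load_nim",
]

_EPS = 1e-9


class FitDegeneracyError(ValueError):
    """The response data carry no information (constant rates)."""


class UnreachableRateError(ArithmeticError):
    """No feature reaches the reference rate within the contrast ceiling."""


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class NIMModel:
    """K spatial filters + K tent-basis input nonlinearities + spiking fn.

    ``filters``: (K, D) with D = M*M pixels; ``knots``: strictly increasing
    grid shared by all nonlinearities; ``g_coefs``: (K, n_knots) tent
    coefficients (g_k is linear between knots, clamped outside the grid).
    ``spike_sigma`` (> 0) sets the softness of the spiking threshold
    ``spike_theta``; ``spike_delta`` is the rate floor.
    """

    filters: np.ndarray
    knots: np.ndarray
    g_coefs: np.ndarray
    spike_sigma: float = 0.5
    spike_theta: float = 0.0
    spike_delta: float = 0.0

    def __post_init__(self):
        self.filters = np.atleast_2d(np.asarray(self.filters, dtype=float))
        self.knots = np.asarray(self.knots, dtype=float)
        self.g_coefs = np.atleast_2d(np.asarray(self.g_coefs, dtype=float))
        if self.knots.ndim != 1 or np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be a strictly increasing 1-D grid")
        if self.g_coefs.shape != (self.filters.shape[0], self.knots.size):
            raise ValueError("g_coefs must be (K, n_knots)")
        if not np.all(np.isfinite(self.filters)):
            raise ValueError("filters must be finite")
        if self.spike_sigma <= 0:
            raise ValueError("spike_sigma must be > 0")

    @property
    def K(self) -> int:
        return self.filters.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.filters.shape[1]


def spiking_nonlinearity(x, sigma: float, theta: float, delta: float):
    """f(x) = sigma * log(1 + exp((x - theta)/sigma)) + delta (monotone)."""
    return sigma * np.logaddexp(0.0, (np.asarray(x, dtype=float) - theta)
                                / sigma) + delta


def _tent_eval(z: np.ndarray, knots: np.ndarray,
               coefs: np.ndarray) -> np.ndarray:
    """Piecewise-linear g(z) on the knot grid, clamped outside it."""
    z = np.clip(z, knots[0], knots[-1])
    return np.interp(z, knots, coefs)


def _generator(model: NIMModel, S: np.ndarray) -> np.ndarray:
    Z = S @ model.filters.T                     # (n, K)
    gen = np.zeros(S.shape[0])
    for k in range(model.K):
        gen += _tent_eval(Z[:, k], model.knots, model.g_coefs[k])
    return gen


def nim_predict(model: NIMModel, stimulus: np.ndarray):
    """Predicted rate(s) for one stimulus or a stack.

    ``stimulus`` may be a flat length-D vector, an (M, M) image, or a stack
    ``(n, D)`` / ``(n, M, M)``.  Returns a scalar or an ``(n,)`` array.
    """
    S = np.asarray(stimulus, dtype=float)
    single = S.ndim == 1 or (S.ndim == 2 and S.size == model.n_pixels)
    S = S.reshape(1, -1) if single else S.reshape(S.shape[0], -1)
    if S.shape[1] != model.n_pixels:
        raise ValueError(
            f"stimulus has {S.shape[1]} pixels, filters expect "
            f"{model.n_pixels}")
    rates = spiking_nonlinearity(_generator(model, S), model.spike_sigma,
                                 model.spike_theta, model.spike_delta)
    return float(rates[0]) if single else rates


def rescale_model(model: NIMModel, factor: float) -> NIMModel:
    """Equivalent reparameterization: h_k -> factor*h_k, g_k(z) -> g_k(z/factor).

    Scaling every filter by a common positive factor while stretching the
    knot grid by the same factor leaves every prediction unchanged.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return replace(model, filters=model.filters * factor,
                   knots=model.knots * factor)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Alternating-maximization settings.

    ``n_rounds`` alternations of (filters, nonlinearities, spiking
    parameters); ``restarts`` independent initializations (the first uses
    the response-weighted-covariance subspace, later ones perturb it);
    ``maxiter`` caps each inner L-BFGS solve.  ``n_knots`` tent knots span
    the empirical generator range.  ``ridge`` is a small curvature penalty
    on the nonlinearity coefficients for conditioning.
    """

    n_rounds: int = 6
    restarts: int = 2
    maxiter: int = 60
    n_knots: int = 21
    ridge: float = 1e-4


def _poisson_ll(rates_pred: np.ndarray, y: np.ndarray) -> float:
    # Rates treated as Poisson means for the observed (rate) data.
    return float(np.sum(y * np.log(rates_pred + _EPS) - rates_pred))


def _model_ll(model: NIMModel, S: np.ndarray, y: np.ndarray) -> float:
    return _poisson_ll(spiking_nonlinearity(
        _generator(model, S), model.spike_sigma, model.spike_theta,
        model.spike_delta), y)


def _sta_stc_init(S: np.ndarray, y: np.ndarray, K: int,
                  rng: np.random.Generator, perturb: float) -> np.ndarray:
    """Initial filters from response-weighted first/second moments.

    Candidates are the spike-triggered average plus the top spike-
    triggered-covariance eigenvectors; each is scored by how strongly the
    (linear or squared) filter output covaries with the response, so a
    near-zero STA (as for a symmetric energy-type cell) cannot displace an
    informative covariance axis.
    """
    D = S.shape[1]
    w = y / (y.sum() + _EPS)
    sta = S.T @ w
    C_y = (S * w[:, None]).T @ S
    C_0 = S.T @ S / S.shape[0]
    evals, evecs = np.linalg.eigh(C_y - C_0)
    order = np.argsort(-np.abs(evals))
    cands = [sta] + [evecs[:, i] for i in order[:K + 3]]
    y_c = y - y.mean()
    y_sd = y.std() + _EPS

    def relevance(v):
        z = S @ v
        lin = abs(z @ y_c) / (np.linalg.norm(z) * y_sd + _EPS)
        z2 = z ** 2
        z2 -= z2.mean()
        quad = abs(z2 @ y_c) / (np.linalg.norm(z2) * y_sd + _EPS)
        return lin + quad

    scored = []
    for v in cands:
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            v = v / nv
            scored.append((relevance(v), v))
    scored.sort(key=lambda t: -t[0])

    filters = []
    for _, v in scored:
        for u in filters:           # Gram-Schmidt against accepted filters
            v = v - (u @ v) * u
        nv = np.linalg.norm(v)
        if nv > 1e-6:
            filters.append(v / nv)
        if len(filters) == K:
            break
    while len(filters) < K:
        v = rng.standard_normal(D)
        filters.append(v / np.linalg.norm(v))
    F = np.array(filters)
    if perturb > 0:
        F = F + perturb * rng.standard_normal(F.shape)
        F /= np.linalg.norm(F, axis=1, keepdims=True)
    return F


def nim_fit(stimuli: np.ndarray, rates: np.ndarray, K: int = 2,
            fit_config: FitConfig | None = None, seed=None):
    """Fit an NIM to stimulus/response data by alternating maximization.

    ``stimuli``: (n, D) or (n, M, M); ``rates``: non-negative (n,).
    Returns ``(model, ll_history)`` for the best restart, where
    ``ll_history`` is the non-decreasing per-round log-likelihood trace.
    With ``fit_config.n_rounds == 0`` the seeded initial model and its
    likelihood are returned.  Raises :class:`FitDegeneracyError` on a
    constant response.
    """
    cfg = fit_config or FitConfig()
    rng = _as_rng(seed)
    S = np.asarray(stimuli, dtype=float)
    S = S.reshape(S.shape[0], -1)
    y = np.asarray(rates, dtype=float)
    if y.shape != (S.shape[0],):
        raise ValueError("rates must be one value per stimulus")
    if np.any(y < 0):
        raise ValueError("rates must be non-negative")
    if np.ptp(y) == 0:
        raise FitDegeneracyError("constant response: nothing to fit")

    best_model, best_hist = None, None
    for restart in range(cfg.restarts):
        filters = _sta_stc_init(S, y, K, rng,
                                perturb=0.0 if restart == 0 else 0.3)
        Z = S @ filters.T
        z_max = max(np.abs(Z).max(), 1e-3)
        knots = np.linspace(-z_max, z_max, cfg.n_knots)
        # Start the nonlinearities as a symmetric rectifier |z| — a neutral
        # shape between linear and quadratic subunits.
        g_coefs = np.tile(np.abs(knots), (K, 1))
        y_mean = max(y.mean(), 10 * _EPS)
        model = NIMModel(filters=filters, knots=knots, g_coefs=g_coefs,
                         spike_sigma=max(0.1 * z_max, 1e-2),
                         spike_theta=float(np.median(np.abs(Z))),
                         spike_delta=0.01 * y_mean)
        hist = [_model_ll(model, S, y)]
        for _ in range(cfg.n_rounds):
            model = _refresh_knots(model, S)
            model = _fit_filters(model, S, y, cfg)
            model = _fit_nonlinearities(model, S, y, cfg)
            model = _fit_spiking(model, S, y, cfg)
            ll = _model_ll(model, S, y)
            hist.append(max(ll, hist[-1]))
        if best_hist is None or hist[-1] > best_hist[-1]:
            best_model, best_hist = model, hist
    return best_model, best_hist


def _refresh_knots(model: NIMModel, S: np.ndarray) -> NIMModel:
    """Re-span the knot grid over the current generator range.

    Filters grow during fitting, so a grid fixed at initialization ends up
    clamping a growing share of the generator samples (zero gradient
    there, biased filters).  The nonlinearities are resampled onto the new
    grid, which preserves them inside the old range.
    """
    Z = S @ model.filters.T
    z_max = 1.05 * max(np.abs(Z).max(), 1e-3)
    knots = np.linspace(-z_max, z_max, model.knots.size)
    coefs = np.stack([
        # Linear extrapolation beyond the old grid via the edge slopes.
        np.interp(knots, model.knots, model.g_coefs[k],
                  left=None, right=None)
        for k in range(model.K)])
    for k in range(model.K):
        old_k, old_c = model.knots, model.g_coefs[k]
        lo_slope = (old_c[1] - old_c[0]) / (old_k[1] - old_k[0])
        hi_slope = (old_c[-1] - old_c[-2]) / (old_k[-1] - old_k[-2])
        below = knots < old_k[0]
        above = knots > old_k[-1]
        coefs[k, below] = old_c[0] + lo_slope * (knots[below] - old_k[0])
        coefs[k, above] = old_c[-1] + hi_slope * (knots[above] - old_k[-1])
    return replace(model, knots=knots, g_coefs=coefs)


def _f_and_grad_common(model, S, y, gen):
    """dLL/d(generator) for each sample."""
    w = (gen - model.spike_theta) / model.spike_sigma
    rate = model.spike_sigma * np.logaddexp(0.0, w) + model.spike_delta
    fprime = expit(w)
    dll_dr = y / (rate + _EPS) - 1.0
    ll = _poisson_ll(rate, y)
    return ll, dll_dr * fprime


def _tent_slopes(z, knots, coefs):
    """g'(z): piecewise-constant slope, 0 outside the knot range."""
    idx = np.clip(np.searchsorted(knots, z) - 1, 0, len(knots) - 2)
    slopes = np.diff(coefs) / np.diff(knots)
    out = slopes[idx]
    out[(z < knots[0]) | (z > knots[-1])] = 0.0
    return out


def _accept_if_better(model, new_model, S, y):
    return new_model if _model_ll(new_model, S, y) >= _model_ll(model, S, y) \
        else model


def _fit_filters(model, S, y, cfg):
    K, D = model.filters.shape

    def negll(flat):
        F = flat.reshape(K, D)
        Z = S @ F.T
        gen = np.zeros(S.shape[0])
        for k in range(K):
            gen += _tent_eval(Z[:, k], model.knots, model.g_coefs[k])
        ll, dgen = _f_and_grad_common(model, S, y, gen)
        grad = np.empty((K, D))
        for k in range(K):
            gk = _tent_slopes(Z[:, k], model.knots, model.g_coefs[k])
            grad[k] = (dgen * gk) @ S
        return -ll, -grad.ravel()

    res = optimize.minimize(negll, model.filters.ravel(), jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": cfg.maxiter})
    return _accept_if_better(
        model, replace(model, filters=res.x.reshape(K, D)), S, y)


def _tent_basis(z, knots):
    """(n, n_knots) interpolation-weight matrix for clamped tent functions."""
    n_knots = knots.size
    z = np.clip(z, knots[0], knots[-1])
    idx = np.clip(np.searchsorted(knots, z) - 1, 0, n_knots - 2)
    t = (z - knots[idx]) / (knots[idx + 1] - knots[idx])
    B = np.zeros((z.size, n_knots))
    rows = np.arange(z.size)
    B[rows, idx] = 1.0 - t
    B[rows, idx + 1] = t
    return B


def _fit_nonlinearities(model, S, y, cfg):
    K = model.K
    Z = S @ model.filters.T
    bases = [_tent_basis(Z[:, k], model.knots) for k in range(K)]
    D2 = np.diff(np.eye(model.knots.size), n=2, axis=0)   # curvature penalty

    def negll(flat):
        C = flat.reshape(K, -1)
        gen = sum(bases[k] @ C[k] for k in range(K))
        ll, dgen = _f_and_grad_common(model, S, y, gen)
        grad = np.stack([bases[k].T @ dgen for k in range(K)])
        pen = cfg.ridge * sum(np.sum((D2 @ C[k]) ** 2) for k in range(K))
        gpen = 2 * cfg.ridge * np.stack([D2.T @ (D2 @ C[k])
                                         for k in range(K)])
        return -(ll - pen), -(grad - gpen).ravel()

    res = optimize.minimize(negll, model.g_coefs.ravel(), jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": cfg.maxiter})
    return _accept_if_better(
        model, replace(model, g_coefs=res.x.reshape(model.g_coefs.shape)),
        S, y)


def _fit_spiking(model, S, y, cfg):
    gen = _generator(model, S)

    def negll(p):
        sigma, theta, delta = p
        rate = sigma * np.logaddexp(0.0, (gen - theta) / sigma) + delta
        return -_poisson_ll(rate, y)

    res = optimize.minimize(
        negll, [model.spike_sigma, model.spike_theta, model.spike_delta],
        method="Nelder-Mead",
        bounds=[(1e-4, None), (None, None), (0.0, None)],
        options={"maxiter": 40 * cfg.maxiter, "xatol": 1e-8, "fatol": 1e-10})
    sigma, theta, delta = res.x
    return _accept_if_better(
        model, replace(model, spike_sigma=float(max(sigma, 1e-4)),
                       spike_theta=float(theta),
                       spike_delta=float(max(delta, 0.0))), S, y)


# ---------------------------------------------------------------------------
# Feature-subspace tuning breadths
# ---------------------------------------------------------------------------

@dataclass
class BreadthSummary:
    """Tuning breadths over the cell's feature subspace.

    ``orientation_breadth`` (deg, <= 180), ``sf_breadth`` (cycles/degree,
    <= 0.6), ``phase_breadth`` (deg, <= 360); ``most_sensitive_feature`` is
    the M-by-M feature needing the least contrast to reach the reference
    rate.
    """

    orientation_breadth: float
    sf_breadth: float
    phase_breadth: float
    most_sensitive_feature: np.ndarray
    min_contrast: float
    n_invariant: int


def feature_attributes(feature: np.ndarray, deg_per_pixel: float = 0.025):
    """Orientation (deg), spatial frequency (cpd) and phase (deg) of a
    spatial feature, read from the peak of its 2-D Fourier amplitude.

    The wave vector is canonicalized to the half-plane fx > 0 (or fx == 0,
    fy > 0) so orientation lies in [0, 180); the phase is the argument of
    the complex coefficient at the peak (a fixed convention — only
    consistency across features matters for breadths).
    """
    feat = np.asarray(feature, dtype=float)
    M = int(round(np.sqrt(feat.size)))
    img = feat.reshape(M, M)
    F = np.fft.fft2(img)
    fy = np.fft.fftfreq(M)[:, None]
    fx = np.fft.fftfreq(M)[None, :]
    amp = np.abs(F)
    amp[0, 0] = 0.0                     # ignore DC
    iy, ix = np.unravel_index(np.argmax(amp), amp.shape)
    ky, kx = float(fy[iy, 0]), float(fx[0, ix])
    coef = F[iy, ix]
    if kx < 0 or (kx == 0 and ky < 0):  # use the conjugate partner
        kx, ky, coef = -kx, -ky, np.conj(coef)
    orientation = np.degrees(np.arctan2(ky, kx)) % 180.0
    sf_cpp = float(np.hypot(kx, ky))
    phase = np.degrees(np.angle(coef)) % 360.0
    return orientation, sf_cpp / deg_per_pixel, phase


def _min_contrast(model, feature, reference_rate, tol, ceiling):
    """Smallest c with rate(c * feature) >= reference_rate (bisection)."""
    c_hi = 1e-3
    while nim_predict(model, c_hi * feature) < reference_rate:
        c_hi *= 2.0
        if c_hi > ceiling:
            return np.inf
    c_lo = 0.0
    while c_hi - c_lo > tol * max(c_hi, 1.0):
        mid = 0.5 * (c_lo + c_hi)
        if nim_predict(model, mid * feature) >= reference_rate:
            c_hi = mid
        else:
            c_lo = mid
    return c_hi


def _circular_range(angles_deg: np.ndarray, period: float) -> float:
    """Minimal covering arc of a set of angles on a circle of given period."""
    a = np.sort(np.asarray(angles_deg, dtype=float) % period)
    if a.size <= 1:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + period]]))
    return float(period - gaps.max())


def feature_breadths(model: NIMModel, reference_rate: float,
                     n_directions: int = 360,
                     deg_per_pixel: float = 0.025,
                     contrast_tol: float = 1e-4,
                     contrast_ceiling: float = 1e3) -> BreadthSummary:
    """Tuning breadths of an NIM over its feature subspace.

    Unit-norm features are sampled densely from the span of the K filters
    (for K = 2, ``n_directions`` points on the coefficient circle; for
    K = 1, the two polarities of the single filter).  Each feature's
    minimal contrast to reach ``reference_rate`` is found by bisection;
    features needing less than twice the minimum form the invariant set,
    and the breadths are the ranges of their orientation / spatial
    frequency / phase (circular ranges for the angular attributes), capped
    at 180°, 0.6 cpd and 360°.
    """
    if reference_rate <= model.spike_delta:
        raise ValueError("reference_rate must exceed the model's rate floor")
    # Orthonormal basis of the filter span.
    Q, R = np.linalg.qr(model.filters.T)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10))
    Q = Q[:, :rank]
    if rank == 1:
        coefs = np.array([[1.0], [-1.0]])
    else:
        ang = np.linspace(0.0, 2 * np.pi, n_directions, endpoint=False)
        coefs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        if rank > 2:       # dense grid on the first two principal directions
            coefs = np.pad(coefs, ((0, 0), (0, rank - 2)))
    features = coefs @ Q.T                       # unit-norm rows

    contrasts = np.array([
        _min_contrast(model, f, reference_rate, contrast_tol,
                      contrast_ceiling) for f in features])
    if not np.any(np.isfinite(contrasts)):
        raise UnreachableRateError(
            f"no feature reaches rate {reference_rate} within contrast "
            f"{contrast_ceiling}")
    i_best = int(np.argmin(contrasts))
    c_min = contrasts[i_best]
    invariant = np.flatnonzero(contrasts < 2.0 * c_min)

    attrs = np.array([feature_attributes(features[i], deg_per_pixel)
                      for i in invariant])
    ori_b = min(_circular_range(attrs[:, 0], 180.0), 180.0)
    sf_b = min(float(attrs[:, 1].max() - attrs[:, 1].min()), 0.6)
    ph_b = min(_circular_range(attrs[:, 2], 360.0), 360.0)
    M = int(round(np.sqrt(model.n_pixels)))
    return BreadthSummary(
        orientation_breadth=ori_b, sf_breadth=sf_b, phase_breadth=ph_b,
        most_sensitive_feature=features[i_best].reshape(M, M),
        min_contrast=float(c_min), n_invariant=int(invariant.size))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_nim(path, model: NIMModel) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("filters", data=model.filters)
        fh.create_dataset("knots", data=model.knots)
        fh.create_dataset("g_coefs", data=model.g_coefs)
        fh.attrs["spike_sigma"] = model.spike_sigma
        fh.attrs["spike_theta"] = model.spike_theta
        fh.attrs["spike_delta"] = model.spike_delta


def load_nim(path) -> NIMModel:
    import h5py

    with h5py.File(path, "r") as fh:
        return NIMModel(
            filters=fh["filters"][()], knots=fh["knots"][()],
            g_coefs=fh["g_coefs"][()],
            spike_sigma=float(fh.attrs["spike_sigma"]),
            spike_theta=float(fh.attrs["spike_theta"]),
            spike_delta=float(fh.attrs["spike_delta"]))
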