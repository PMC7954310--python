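"""Complex-cell layer: linear pooling of simple cells, learned with
sliding-threshold (BCM-family) plasticity.

A complex cell's response is a non-negative weighted sum of its simple-cell
inputs, ``r_C = A_SC^T x_C``.  The input ``x_C`` is the simple-cell response
averaged over a short frame sequence (a trace-rule surrogate for temporal
integration) and scaled up by ``input_scale``; averaging over frames related
by small translations makes co-oriented simple cells with different phase
preferences co-active, which is exactly what a phase-invariant complex cell
must pool.

Two learning rules are implemented:

modified BCM
    Hebbian with a sliding threshold theta_j tracking the average squared
    response, plus weight decay and a [0, a2_max] box.  Each cell competes
    only with itself, so a population trained on shared input tends to
    collapse onto the same pooling pattern.

modified NBCM
    The same rule applied to divisively normalized responses
    ``r_N = beta * r / (alpha + sum_k r_k^2)``.  Normalization introduces
    soft competition across the population — cells that fire together
    depress each other's effective gain — so different cells learn different
    pooling patterns.  The gain ``beta`` sets the competition strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import lgn_simple, retina, stimuli

__all__ = [
    "ComplexConnectome", "init_complex_connectome", "average_frame_input",
    "complex_response", "normalize_responses", "update_bcm", "update_nbcm",
    "ComplexTrainConfig", "compute_complex_inputs", "train_complex_layer",
    "simple_spontaneous_rates",
    "substantial_inputs", "substantial_patterns", "recruited_simple_cells",
    "mean_pairwise_cosine", "save_complex_connectome",
    "load_complex_connectome", "SUBSTANTIAL_WEIGHT",
]

#: Reporting threshold: a simple->complex weight above this counts as a
#: "substantial" input (a reporting constant, not part of learning).
SUBSTANTIAL_WEIGHT = 0.4


@dataclass
class ComplexConnectome:
    """Simple->complex weights, per-cell BCM thresholds and constants.

    ``A_SC`` has shape ``(n_simple, n_complex)``, elementwise in
    [0, a2_max]; ``theta`` is the length-n_complex vector of sliding
    thresholds.  ``alpha`` (floor) and ``beta`` (gain) parameterize the
    divisive normalization used by the NBCM rule; ``input_scale`` is the
    fixed gain applied to the frame-averaged simple responses; ``n_frames``
    is the number of frames averaged per learning iteration.
    """

    A_SC: np.ndarray
    theta: np.ndarray
    a2_max: float = 1.0
    eta_a: float = 1e-3
    eta_theta: float = 1e-3
    gamma_a: float = 1e-4
    alpha: float = 0.01
    beta: float = 12.0
    input_scale: float = 10.0
    n_frames: int = 15

    def __post_init__(self):
        self.A_SC = np.asarray(self.A_SC, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.A_SC.ndim != 2:
            raise ValueError("A_SC must be (n_simple, n_complex)")
        if self.theta.shape != (self.A_SC.shape[1],):
            raise ValueError("theta must have length n_complex")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def n_simple(self) -> int:
        return self.A_SC.shape[0]

    @property
    def n_complex(self) -> int:
        return self.A_SC.shape[1]


def init_complex_connectome(n_simple: int, n_complex: int, seed=None,
                            a_init: float = 0.1, theta0: float = 1.0,
                            **kwargs) -> ComplexConnectome:
    """Seeded initialization: weights i.i.d. uniform [0, a_init], all
    thresholds at ``theta0`` (the threshold is input-driven, so theta0 only
    shifts the early transient)."""
    rng = stimuli._as_rng(seed)
    A = rng.uniform(0.0, a_init, size=(n_simple, n_complex))
    theta = np.full(n_complex, float(theta0))
    return ComplexConnectome(A_SC=A, theta=theta, **kwargs)


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------

def average_frame_input(frame_rates_S, input_scale: float = 10.0,
                        ) -> np.ndarray:
    """Average simple-cell rate vectors over frames and apply the input gain.

    ``frame_rates_S`` is an ``(n_frames, n_simple)`` array (or list of rate
    vectors).  The frame average is small, so it is scaled up by
    ``input_scale`` before reaching the complex cells.
    """
    rates = np.asarray(frame_rates_S, dtype=float)
    if rates.size == 0:
        raise ValueError("need at least one frame of simple-cell rates")
    rates = np.atleast_2d(rates)
    return input_scale * rates.mean(axis=0)


def complex_response(x_C: np.ndarray, connectome: ComplexConnectome,
                     ) -> np.ndarray:
    """Linear pooling ``r_C = A_SC^T x_C``.

    ``x_C`` may be a length-n_simple vector or an ``(n_simple, B)`` batch.
    Non-negative whenever the input is (the weights are non-negative).
    """
    x_C = np.asarray(x_C, dtype=float)
    if x_C.shape[0] != connectome.n_simple:
        raise ValueError(
            f"x_C has leading dimension {x_C.shape[0]}; expected "
            f"{connectome.n_simple}")
    return connectome.A_SC.T @ x_C


def normalize_responses(r_C: np.ndarray, alpha: float = 0.01,
                        beta: float = 12.0) -> np.ndarray:
    """Divisive normalization across the complex-cell population.

    ``r_N = beta * r_C / (alpha + sum_k r_k^2)``.  The pooled squared
    activity is shared by all cells, so response ratios are preserved;
    ``alpha > 0`` guards the denominator.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    r_C = np.asarray(r_C, dtype=float)
    return beta * r_C / (alpha + np.sum(r_C ** 2))


# ---------------------------------------------------------------------------
# Plasticity
# ---------------------------------------------------------------------------

def _bcm_step(x_C, r, conn: ComplexConnectome) -> ComplexConnectome:
    # Weight and threshold updates computed simultaneously from the same r.
    dA = conn.eta_a * (np.outer(x_C, r * (r - conn.theta))
                       - conn.gamma_a * conn.A_SC)
    dtheta = conn.eta_theta * (r ** 2 - conn.theta)
    return replace(conn,
                   A_SC=np.clip(conn.A_SC + dA, 0.0, conn.a2_max),
                   theta=conn.theta + dtheta)


def update_bcm(x_C: np.ndarray, r_C: np.ndarray,
               connectome: ComplexConnectome) -> ComplexConnectome:
    """Modified BCM update on raw responses.

        da_ij    = eta_a * (x_i r_j (r_j - theta_j) - gamma_a a_ij)
        dtheta_j = eta_theta * (r_j^2 - theta_j)

    Weights are clipped to [0, a2_max] after the step.
    """
    x_C = np.asarray(x_C, dtype=float)
    r_C = np.asarray(r_C, dtype=float)
    if x_C.shape != (connectome.n_simple,) or r_C.shape != (connectome.n_complex,):
        raise ValueError("x_C / r_C shapes do not match the connectome")
    return _bcm_step(x_C, r_C, connectome)


def update_nbcm(x_C: np.ndarray, r_C: np.ndarray,
                connectome: ComplexConnectome) -> ComplexConnectome:
    """Modified NBCM update: BCM applied to the normalized responses.

    Responses are first divisively normalized with the connectome's
    ``alpha``/``beta``; both the weight and the threshold updates then use
    the normalized rates.
    """
    x_C = np.asarray(x_C, dtype=float)
    r_C = np.asarray(r_C, dtype=float)
    if x_C.shape != (connectome.n_simple,) or r_C.shape != (connectome.n_complex,):
        raise ValueError("x_C / r_C shapes do not match the connectome")
    r_N = normalize_responses(r_C, connectome.alpha, connectome.beta)
    return _bcm_step(x_C, r_N, connectome)


_RULES = {"bcm": update_bcm, "nbcm": update_nbcm}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class ComplexTrainConfig:
    """Protocol for training the simple->complex weights.

    Reference protocol: 100 complex cells, N = 15 frames per iteration,
    4e6 iterations, eta_a = eta_theta = 1e-3, gamma_a = 1e-4, a2_max = 1,
    beta in {11, 12, 13}.  One iteration = one frame sequence = one update.

    ``a_init``/``theta0``: "auto" (default) places the initial population
    at the chosen rule's own operating point, computed from the input
    statistics: the BCM threshold dynamics have a unit-rate attractor
    (theta = r^2 meets r at 1), while divisive normalization equilibrates
    where the population power sum(r^2) ~ beta.  Initial weights are drawn
    uniform with mean set so initial responses sit at that target rate,
    and theta0 = target^2.  Starting far below the operating point is
    fatal under clipping: the sliding threshold overshoots on the way
    down and an all-zero weight column is an absorbing state (r = 0
    forever).  Numeric values override the calibration.
    """

    n_complex: int = 100
    epochs: int = 4_000_000
    rule: str = "nbcm"
    a_init: float | str = "auto"
    theta0: float | str = "auto"
    a2_max: float = 1.0
    eta_a: float = 1e-3
    eta_theta: float = 1e-3
    gamma_a: float = 1e-4
    alpha: float = 0.01
    beta: float = 12.0
    input_scale: float = 10.0
    n_frames: int = 15
    constants: lgn_simple.LayerConstants = field(
        default_factory=lgn_simple.LayerConstants)
    whiten: retina.WhitenConfig = field(default_factory=retina.WhitenConfig)
    log_every: int = 10_000


def simple_spontaneous_rates(simple_connectome, constants=None,
                             ) -> np.ndarray:
    """Steady-state simple rates for a blank stimulus (LGN at baseline)."""
    constants = constants or lgn_simple.LayerConstants()
    M2 = simple_connectome.n_lgn // 2
    state = lgn_simple.run_dynamics(np.zeros(M2), np.zeros(M2),
                                    simple_connectome, constants)
    return state.r_S


def compute_complex_inputs(simple_connectome, sequences,
                           constants=None, whiten=None,
                           input_scale: float = 10.0,
                           evoked: bool = True) -> np.ndarray:
    """Frame-averaged, scaled simple-cell responses for many sequences.

    ``sequences`` is a list of :class:`~v1complex.stimuli.FrameSequence`
    whose frames are already whitened crops.  All frames of all sequences
    are windowed, split and integrated through the network dynamics in one
    batched call; the per-sequence frame averages (times ``input_scale``)
    are returned as an ``(n_sequences, n_simple)`` array.

    With ``evoked`` (default) each cell's spontaneous (blank-stimulus)
    rate is subtracted before averaging, rectified at zero.  At the
    reference operating point simple cells are silent at rest, so evoked
    and absolute rates coincide; when a trained stand-in layer carries a
    tonic baseline, the baseline holds no stimulus information and would
    otherwise swamp the pattern structure the pooling rule must see.
    """
    constants = constants or lgn_simple.LayerConstants()
    whiten = whiten or retina.WhitenConfig()
    if len(sequences) == 0:
        raise ValueError("need at least one frame sequence")
    counts = [seq.n_frames for seq in sequences]
    frames = np.concatenate([seq.frames for seq in sequences], axis=0)
    x_on, x_off = retina.window_and_split_batch(frames, whiten)
    state = lgn_simple.run_dynamics(x_on, x_off, simple_connectome, constants)
    r_S = state.r_S  # (n_simple, total_frames)
    if evoked:
        spont = simple_spontaneous_rates(simple_connectome, constants)
        r_S = np.maximum(r_S - spont[:, None], 0.0)
    out = np.empty((len(sequences), simple_connectome.n_simple))
    start = 0
    for i, n in enumerate(counts):
        out[i] = input_scale * r_S[:, start:start + n].mean(axis=1)
        start += n
    return out


def train_complex_layer(frozen_simple_layer, stimulus_source, rule: str,
                        config: ComplexTrainConfig, seed=None):
    """Train simple->complex weights with the chosen rule.

    ``frozen_simple_layer`` is a trained :class:`SimpleConnectome` (its
    weights stay fixed).  ``stimulus_source`` is a list of
    :class:`FrameSequence` objects (whitened frames); their simple-cell
    responses are computed once up front, and each iteration draws one
    sequence at random, forms the frame-averaged input, computes the
    complex responses and applies one plasticity update.

    Returns ``(connectome, log)``; the log tracks the threshold mean, the
    substantial-connection count (weights > 0.4) and weight sparsity per
    checkpoint.  ``epochs = 0`` returns the seeded initial connectome.
    """
    import pandas as pd

    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}; expected 'bcm' or 'nbcm'")
    update = _RULES[rule]
    rng = stimuli._as_rng(seed)

    x_pool = None
    if config.epochs > 0 or config.a_init == "auto":
        x_pool = compute_complex_inputs(
            frozen_simple_layer, stimulus_source,
            constants=config.constants, whiten=config.whiten,
            input_scale=config.input_scale)

    a_init, theta0 = config.a_init, config.theta0
    if a_init == "auto" or theta0 == "auto":
        if rule == "bcm":
            r_target = 1.0
        else:
            r_target = np.sqrt(max(config.beta - config.alpha, config.alpha)
                               / config.n_complex)
        mean_input_sum = float(x_pool.sum(axis=1).mean()) if x_pool is not None \
            else 1.0
        if a_init == "auto":
            # Initial weights kept below the substantial-connection
            # reporting threshold so initialization cannot masquerade as
            # learned pooling (weights on silent inputs receive no Hebbian
            # drive and decay only slowly).
            a_init = min(2.0 * r_target / max(mean_input_sum, 1e-9),
                         0.75 * SUBSTANTIAL_WEIGHT, config.a2_max)
        if theta0 == "auto":
            # Match the threshold to the actual initial responses (mean
            # weight = a_init/2), normalized when the rule is NBCM:
            # starting theta far above the operating rate is fatal under
            # clipping (all-zero columns are absorbing).
            r_init = max(0.5 * a_init * mean_input_sum, 1e-6)
            if rule == "nbcm":
                r_init = (config.beta * r_init
                          / (config.alpha + config.n_complex * r_init ** 2))
            theta0 = r_init ** 2

    conn = init_complex_connectome(
        frozen_simple_layer.n_simple, config.n_complex, seed=rng,
        a_init=a_init, theta0=theta0, a2_max=config.a2_max,
        eta_a=config.eta_a, eta_theta=config.eta_theta,
        gamma_a=config.gamma_a, alpha=config.alpha, beta=config.beta,
        input_scale=config.input_scale, n_frames=config.n_frames)

    records = []
    if config.epochs > 0:
        n_pool = x_pool.shape[0]
        draws = rng.integers(0, n_pool, size=config.epochs)
        for it in range(config.epochs):
            x_C = x_pool[draws[it]]
            r_C = complex_response(x_C, conn)
            conn = update(x_C, r_C, conn)
            if (it + 1) % config.log_every == 0 or it == config.epochs - 1:
                A = conn.A_SC
                records.append({
                    "epoch": it + 1,
                    "theta_mean": float(conn.theta.mean()),
                    "n_substantial": int((A > SUBSTANTIAL_WEIGHT).sum()),
                    "frac_near_zero": float((A < 0.01).mean()),
                })
    log = pd.DataFrame.from_records(
        records, columns=["epoch", "theta_mean", "n_substantial",
                          "frac_near_zero"])
    return conn, log


# ---------------------------------------------------------------------------
# Population summaries of the learned pooling
# ---------------------------------------------------------------------------

def substantial_inputs(A_SC: np.ndarray,
                       threshold: float = SUBSTANTIAL_WEIGHT) -> np.ndarray:
    """Boolean (n_simple, n_complex) mask of substantial connections."""
    return np.asarray(A_SC) > threshold


def substantial_patterns(A_SC: np.ndarray,
                         threshold: float = SUBSTANTIAL_WEIGHT) -> int:
    """Number of distinct substantial-input patterns across complex cells.

    Each complex cell's pattern is the set of simple cells it pools with a
    substantial weight; cells pooling nothing substantial share the empty
    pattern.
    """
    mask = substantial_inputs(A_SC, threshold)
    return len({tuple(col) for col in mask.T})


def recruited_simple_cells(A_SC: np.ndarray,
                           threshold: float = SUBSTANTIAL_WEIGHT) -> int:
    """Number of simple cells substantially pooled by >= 1 complex cell."""
    return int(substantial_inputs(A_SC, threshold).any(axis=1).sum())


def mean_pairwise_cosine(A_SC: np.ndarray) -> float:
    """Mean cosine similarity over all pairs of complex-cell weight columns.

    Zero columns are excluded (their direction is undefined).  Returns NaN
    if fewer than two nonzero columns remain.
    """
    A = np.asarray(A_SC, dtype=float)
    norms = np.linalg.norm(A, axis=0)
    keep = norms > 0
    if keep.sum() < 2:
        return float("nan")
    U = A[:, keep] / norms[keep]
    G = U.T @ U
    iu = np.triu_indices(G.shape[0], k=1)
    return float(G[iu].mean())


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_complex_connectome(path, connectome: ComplexConnectome) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("A_SC", data=connectome.A_SC)
        fh.create_dataset("theta", data=connectome.theta)
        grp = fh.create_group("constants")
        for key in ("a2_max", "eta_a", "eta_theta", "gamma_a", "alpha",
                    "beta", "input_scale", "n_frames"):
            grp.attrs[key] = getattr(connectome, key)


def load_complex_connectome(path) -> ComplexConnectome:
    import h5py

    with h5py.File(path, "r") as fh:
        A = fh["A_SC"][()]
        theta = fh["theta"][()]
        attrs = dict(fh["constants"].attrs)
    return ComplexConnectome(
        A_SC=A, theta=theta, a2_max=float(attrs["a2_max"]),
        eta_a=float(attrs["eta_a"]), eta_theta=float(attrs["eta_theta"]),
        gamma_a=float(attrs["gamma_a"]), alpha=float(attrs["alpha"]),
        beta=float(attrs["beta"]), input_scale=float(attrs["input_scale"]),
        n_frames=int(attrs["n_frames"]))
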