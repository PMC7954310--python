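"""Bottom two layers: LGN and V1 simple cells.

Rate-based membrane dynamics solved by forward Euler, and Hebbian /
anti-Hebbian plasticity of the four LGN<->simple connection matrices.

The LGN layer holds 2M² threshold-linear cells (M² ON then M² OFF).  Each
LGN cell integrates its stimulus drive, a spontaneous rate ``r_b_L`` and
feedback from simple cells; each simple cell integrates feedforward LGN
drive, a leak toward ``v_leak_S`` and a self-excitation term, and fires
through a rectifier with threshold ``lambda_S`` (the sparsity level).  With
feedback weights mirroring the feedforward ones the LGN potentials carry the
residual between the stimulus and the simple-cell reconstruction, so the
network performs sparse coding: simple cells learn localized, oriented,
bandpass receptive fields from naturalistic input.

Plasticity is Hebbian in the feedforward direction and anti-Hebbian in the
feedback direction, with a weight-decay regularizer and hard sign/magnitude
bounds (excitatory weights in [0, a1_max], inhibitory in [-a1_max, 0]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import retina, stimuli

__all__ = [
    "LayerConstants", "SimpleConnectome", "NetworkState",
    "DynamicsDivergenceError", "init_simple_connectome", "run_dynamics",
    "update_weights_simple", "SimpleTrainConfig", "train_simple_layer",
    "synaptic_field", "save_connectome", "load_connectome",
]


class DynamicsDivergenceError(ArithmeticError):
    """Membrane potentials left the admissible range during integration."""


@dataclass
class LayerConstants:
    """Dynamics constants for the bottom two layers.

    tau_L, tau_S : s
        Membrane time constants of LGN and simple cells (10 ms each).
    r_b_L : Hz
        LGN spontaneous rate (0.5); sets the dynamic working point.
    lambda_S : Hz
        Threshold of the simple-cell rectifier (0.1); the sparsity level.
    v_leak_S : mV-equivalent
        Simple-cell leak potential; 0 keeps cells silent at rest.
    dt, n_steps
        Forward-Euler step (4 ms) and number of steps (20) per stimulus:
        enough for the fast dynamics to settle to a numerically stable
        response.
    """

    tau_L: float = 0.010
    tau_S: float = 0.010
    r_b_L: float = 0.5
    lambda_S: float = 0.1
    v_leak_S: float = 0.0
    dt: float = 0.004
    n_steps: int = 20

    def __post_init__(self):
        if self.tau_L <= 0 or self.tau_S <= 0 or self.dt <= 0:
            raise ValueError("tau_L, tau_S and dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.lambda_S < 0:
            raise ValueError("lambda_S must be >= 0")


@dataclass
class SimpleConnectome:
    """The four LGN<->simple connection matrices plus learning constants.

    All four matrices have shape ``(2*M*M, n_simple)`` with the first M²
    rows the ON channel and the last M² rows the OFF channel.  ``A_u_*``
    are feedforward (LGN -> simple, used transposed), ``A_d_*`` feedback
    (simple -> LGN).  ``*_plus`` are excitatory (>= 0), ``*_minus``
    inhibitory (<= 0); magnitudes are bounded by ``a1_max``.
    """

    A_u_plus: np.ndarray
    A_u_minus: np.ndarray
    A_d_plus: np.ndarray
    A_d_minus: np.ndarray
    a1_max: float = 0.3
    eta1: float = 3.0
    gamma1: float = 1e-3

    def __post_init__(self):
        shape = self.A_u_plus.shape
        for name in ("A_u_minus", "A_d_plus", "A_d_minus"):
            if getattr(self, name).shape != shape:
                raise ValueError("all four weight matrices must share one "
                                 f"shape; {name} differs from A_u_plus")
        if shape[0] % 2:
            raise ValueError("first dimension must be 2*M*M (ON then OFF)")

    @property
    def n_lgn(self) -> int:
        return self.A_u_plus.shape[0]

    @property
    def n_simple(self) -> int:
        return self.A_u_plus.shape[1]

    @property
    def M(self) -> int:
        return int(round(np.sqrt(self.n_lgn // 2)))

    def clipped(self) -> "SimpleConnectome":
        """Copy with every matrix projected onto its sign/bound box."""
        a = self.a1_max
        return replace(
            self,
            A_u_plus=np.clip(self.A_u_plus, 0.0, a),
            A_u_minus=np.clip(self.A_u_minus, -a, 0.0),
            A_d_plus=np.clip(self.A_d_plus, 0.0, a),
            A_d_minus=np.clip(self.A_d_minus, -a, 0.0),
        )

    def check_bounds(self, atol: float = 0.0) -> bool:
        a = self.a1_max + atol
        return bool(
            np.all(self.A_u_plus >= -atol) and np.all(self.A_u_plus <= a)
            and np.all(self.A_u_minus <= atol) and np.all(self.A_u_minus >= -a)
            and np.all(self.A_d_plus >= -atol) and np.all(self.A_d_plus <= a)
            and np.all(self.A_d_minus <= atol) and np.all(self.A_d_minus >= -a)
        )


@dataclass
class NetworkState:
    """Final membrane potentials and rates after one stimulus presentation.

    Vectors (single stimulus) or matrices with stimuli along columns.
    Invariants: ``r_L = max(v_L, 0)``, ``r_S = max(v_S - lambda_S, 0)``.
    """

    v_L: np.ndarray
    r_L: np.ndarray
    v_S: np.ndarray
    r_S: np.ndarray


def init_simple_connectome(M: int, n_simple: int, seed=None,
                           col_norm: float = 1.0, a1_max: float = 0.3,
                           eta1: float = 3.0, gamma1: float = 1e-3,
                           ) -> SimpleConnectome:
    """Seeded random initialization with the feedforward/feedback mirror.

    Each simple cell's net feedforward column starts as Gaussian noise made
    zero-sum (no tonic drive from the LGN background rate) and scaled to
    ``col_norm`` (default 1).  Unit-norm columns matter: the simple cells'
    self-excitation is calibrated against the unit diagonal of the weight
    Gram matrix, so columns far from unit norm make the code amplitudes
    transiently run away.  The positive part of the column seeds the
    excitatory matrix and the negative part the inhibitory one, and the
    feedback matrices are set to the mirror ``A_d_minus = -A_u_plus``,
    ``A_d_plus = -A_u_minus`` (imposed at initialization only — training is
    free to break it).
    """
    rng = stimuli._as_rng(seed)
    n_lgn = 2 * M * M
    w = rng.standard_normal((n_lgn, n_simple))
    w -= w.mean(axis=0)
    w *= col_norm / np.linalg.norm(w, axis=0)
    A_u_plus = np.clip(w, 0.0, a1_max)
    A_u_minus = np.clip(w, -a1_max, 0.0)
    return SimpleConnectome(
        A_u_plus=A_u_plus, A_u_minus=A_u_minus,
        A_d_plus=-A_u_minus, A_d_minus=-A_u_plus,
        a1_max=a1_max, eta1=eta1, gamma1=gamma1,
    )


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

_V_DIVERGE = 1e6


def run_dynamics(x_on: np.ndarray, x_off: np.ndarray,
                 connectome: SimpleConnectome,
                 constants: LayerConstants | None = None) -> NetworkState:
    """Integrate the coupled LGN/simple dynamics for one stimulus (or batch).

    ``x_on``/``x_off`` are length-M² vectors, or ``(M*M, B)`` matrices for a
    batch of B stimuli integrated in parallel (each column is an independent
    presentation; there is no interaction across columns).

    Forward Euler from ``v_L = v_S = 0``:

        tau_L dv_L/dt = -v_L + x_L + (A_d_plus + A_d_minus) r_S + r_b_L
        tau_S dv_S/dt = -(v_S - v_leak_S) + (A_u_plus + A_u_minus)^T r_L + r_S

    with ``r_L = max(v_L, 0)`` and ``r_S = max(v_S - lambda_S, 0)`` refreshed
    after every step.  The ``+ r_S`` term is the simple cells'
    self-excitation.  Raises :class:`DynamicsDivergenceError` (naming the
    offending Euler step) if any |v| exceeds 1e6 or turns non-finite.
    """
    constants = constants or LayerConstants()
    x_on = np.asarray(x_on, dtype=float)
    x_off = np.asarray(x_off, dtype=float)
    if x_on.shape != x_off.shape:
        raise ValueError("x_on and x_off must have the same shape")
    squeeze = x_on.ndim == 1
    if squeeze:
        x_on = x_on[:, None]
        x_off = x_off[:, None]
    if 2 * x_on.shape[0] != connectome.n_lgn:
        raise ValueError(
            f"stimulus has {x_on.shape[0]} pixels per channel but the "
            f"connectome expects {connectome.n_lgn // 2}")
    x_L = np.concatenate([x_on, x_off], axis=0)
    B = x_L.shape[1]

    A_d = connectome.A_d_plus + connectome.A_d_minus
    A_u_T = (connectome.A_u_plus + connectome.A_u_minus).T
    c = constants

    v_L = np.zeros((connectome.n_lgn, B))
    v_S = np.zeros((connectome.n_simple, B))
    r_L = np.zeros_like(v_L)
    r_S = np.zeros_like(v_S)
    dv_L = np.empty_like(v_L)
    dv_S = np.empty_like(v_S)

    kL = c.dt / c.tau_L
    kS = c.dt / c.tau_S
    # Staggered (Gauss-Seidel) Euler: the LGN potentials step first and
    # their refreshed rates feed the simple-cell step within the same
    # iteration.  For the leak/feedback loop this is far more stable than
    # the simultaneous update (the continuous system is unconditionally
    # stable; simultaneous Euler at dt/tau = 0.4 is not once the weight
    # spectrum grows during learning).
    for step in range(c.n_steps):
        np.dot(A_d, r_S, out=dv_L)
        dv_L += x_L
        dv_L -= v_L
        dv_L += c.r_b_L
        v_L += np.multiply(dv_L, kL, out=dv_L)
        np.maximum(v_L, 0.0, out=r_L)

        np.dot(A_u_T, r_L, out=dv_S)
        dv_S += r_S                       # self-excitation
        dv_S -= v_S
        dv_S += c.v_leak_S
        v_S += np.multiply(dv_S, kS, out=dv_S)
        np.subtract(v_S, c.lambda_S, out=r_S)
        np.maximum(r_S, 0.0, out=r_S)

        # max <= bound is False for NaN too, so this also catches non-finite
        # states.
        vmax = max(np.abs(v_L).max(), np.abs(v_S).max())
        if not vmax <= _V_DIVERGE:
            raise DynamicsDivergenceError(
                f"membrane potentials diverged at Euler step {step + 1}")

    if squeeze:
        v_L, r_L, v_S, r_S = (a[:, 0] for a in (v_L, r_L, v_S, r_S))
    return NetworkState(v_L=v_L, r_L=r_L, v_S=v_S, r_S=r_S)


# ---------------------------------------------------------------------------
# Plasticity
# ---------------------------------------------------------------------------

def update_weights_simple(batch_rates_L: np.ndarray,
                          batch_rates_S: np.ndarray,
                          connectome: SimpleConnectome,
                          constants: LayerConstants | None = None,
                          center: bool = False) -> SimpleConnectome:
    """One Hebbian/anti-Hebbian weight update from a batch of responses.

    ``batch_rates_L``: (2M², B); ``batch_rates_S``: (n_simple, B).  The
    Hebbian matrix is the batch average H = <(r_L - r_b_L) r_S^T>.  The
    feedforward matrices move along +H, the feedback matrices along -H
    (anti-Hebbian); every matrix decays toward zero at rate gamma1 and is
    then clipped to its sign/bound box:

        dA_u_± = eta1 (H - gamma1 A_u_±)
        dA_d_± = eta1 (-H - gamma1 A_d_±)

    With ``center=True`` the spontaneous-rate reference is replaced by the
    empirical batch means of both factors, making H the batch covariance
    of LGN and simple rates.  At the model's working point the mean LGN
    rate equals the spontaneous rate, so the two coincide; away from it,
    centering removes a rank-one drive that exists only because the
    rectified ON/OFF input has positive total mass.  That mode feeds back
    positively on itself through the network (more total input drive ->
    more firing -> more outer-product mass on the same direction) and at
    eta1 = 3 destabilizes batch training, so the training loop uses the
    centered estimator (see the methods note).
    """
    constants = constants or LayerConstants()
    r_L = np.atleast_2d(np.asarray(batch_rates_L, dtype=float))
    r_S = np.atleast_2d(np.asarray(batch_rates_S, dtype=float))
    if r_L.ndim != 2 or r_S.ndim != 2 or r_L.shape[1] != r_S.shape[1]:
        raise ValueError("rate batches must be 2-D with matching batch size")
    if r_L.shape[0] != connectome.n_lgn or r_S.shape[0] != connectome.n_simple:
        raise ValueError("rate dimensions do not match the connectome")
    B = r_L.shape[1]
    if center:
        H = ((r_L - r_L.mean(axis=1, keepdims=True))
             @ (r_S - r_S.mean(axis=1, keepdims=True)).T) / B
    else:
        H = (r_L - constants.r_b_L) @ r_S.T / B
    eta, g = connectome.eta1, connectome.gamma1
    updated = replace(
        connectome,
        A_u_plus=connectome.A_u_plus + eta * (H - g * connectome.A_u_plus),
        A_u_minus=connectome.A_u_minus + eta * (H - g * connectome.A_u_minus),
        A_d_plus=connectome.A_d_plus + eta * (-H - g * connectome.A_d_plus),
        A_d_minus=connectome.A_d_minus + eta * (-H - g * connectome.A_d_minus),
    )
    return updated.clipped()


@dataclass
class SimpleTrainConfig:
    """Protocol for training the bottom two layers.

    The reference protocol is M=16, 100 simple cells, batches of 100
    patches, 1e5 epochs; scaled-down runs shrink M, the cell count and the
    epoch count.
    """

    M: int = 16
    n_simple: int = 100
    batch_size: int = 100
    epochs: int = 100_000
    col_norm_init: float = 1.0
    a1_max: float = 0.3
    eta1: float = 3.0
    gamma1: float = 1e-3
    center_hebbian: bool = True
    constants: LayerConstants = field(default_factory=LayerConstants)
    whiten: retina.WhitenConfig = field(default_factory=retina.WhitenConfig)
    log_every: int = 1000


def train_simple_layer(stimulus_source, config: SimpleTrainConfig, seed=None):
    """Train the LGN<->simple connectome on whitened naturalistic images.

    ``stimulus_source`` is a sequence of 2-D images (already raw; they are
    whitened once up front).  Each epoch samples ``batch_size`` random
    patches from a random image, windows/splits them, integrates the
    dynamics for the whole batch in parallel, and applies one plasticity
    update.  Returns ``(connectome, log)`` where ``log`` is a pandas
    DataFrame of per-checkpoint mean rates and weight norms.

    ``epochs = 0`` returns the seeded initial connectome unchanged.
    """
    import pandas as pd

    rng = stimuli._as_rng(seed)
    conn = init_simple_connectome(
        config.M, config.n_simple, seed=rng, col_norm=config.col_norm_init,
        a1_max=config.a1_max, eta1=config.eta1, gamma1=config.gamma1)

    whitened = [retina.whiten_image(retina.to_luminance(img), config.whiten)
                for img in stimulus_source]
    if not whitened and config.epochs > 0:
        raise ValueError("stimulus_source is empty")

    records = []
    for epoch in range(config.epochs):
        img = whitened[rng.integers(len(whitened))]
        patches = stimuli.sample_patches(img, config.M, config.batch_size,
                                         seed=rng)
        x_on, x_off = retina.window_and_split_batch(patches, config.whiten)
        state = run_dynamics(x_on, x_off, conn, config.constants)
        conn = update_weights_simple(state.r_L, state.r_S, conn,
                                     config.constants,
                                     center=config.center_hebbian)
        if (epoch + 1) % config.log_every == 0 or epoch == config.epochs - 1:
            records.append({
                "epoch": epoch + 1,
                "mean_rate_L": float(state.r_L.mean()),
                "mean_rate_S": float(state.r_S.mean()),
                "frac_active_S": float((state.r_S > 0).mean()),
                "norm_A_u_plus": float(np.linalg.norm(conn.A_u_plus)),
                "norm_A_u_minus": float(np.linalg.norm(conn.A_u_minus)),
            })
    log = pd.DataFrame.from_records(
        records, columns=["epoch", "mean_rate_L", "mean_rate_S",
                          "frac_active_S", "norm_A_u_plus", "norm_A_u_minus"])
    return conn, log


def synaptic_field(connectome: SimpleConnectome, cell_index: int,
                   ) -> np.ndarray:
    """Net ON-minus-OFF feedforward weight map of one simple cell.

    ``S_f = (A_u_plus_ON + A_u_minus_ON) - (A_u_plus_OFF + A_u_minus_OFF)``
    reshaped to M-by-M.  This is the standard visualization of a simple
    cell's receptive field: positive = net ON (bright-excitatory) drive,
    negative = net OFF drive.
    """
    if not 0 <= cell_index < connectome.n_simple:
        raise IndexError(
            f"cell_index {cell_index} out of range "
            f"[0, {connectome.n_simple})")
    M = connectome.M
    net = connectome.A_u_plus[:, cell_index] + connectome.A_u_minus[:, cell_index]
    return (net[:M * M] - net[M * M:]).reshape(M, M)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_connectome(path, connectome: SimpleConnectome,
                    constants: LayerConstants | None = None) -> None:
    """Write a connectome (and optional dynamics constants) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name in ("A_u_plus", "A_u_minus", "A_d_plus", "A_d_minus"):
            fh.create_dataset(name, data=getattr(connectome, name))
        grp = fh.create_group("constants")
        grp.attrs["a1_max"] = connectome.a1_max
        grp.attrs["eta1"] = connectome.eta1
        grp.attrs["gamma1"] = connectome.gamma1
        if constants is not None:
            for key in ("tau_L", "tau_S", "r_b_L", "lambda_S", "v_leak_S",
                        "dt", "n_steps"):
                grp.attrs[key] = getattr(constants, key)


def load_connectome(path):
    """Read a connectome written by :func:`save_connectome`.

    Returns ``(SimpleConnectome, LayerConstants | None)``.
    """
    import h5py

    with h5py.File(path, "r") as fh:
        mats = {name: fh[name][()] for name in
                ("A_u_plus", "A_u_minus", "A_d_plus", "A_d_minus")}
        attrs = dict(fh["constants"].attrs)
    conn = SimpleConnectome(
        **mats, a1_max=float(attrs["a1_max"]), eta1=float(attrs["eta1"]),
        gamma1=float(attrs["gamma1"]))
    constants = None
    if "tau_L" in attrs:
        constants = LayerConstants(
            tau_L=float(attrs["tau_L"]), tau_S=float(attrs["tau_S"]),
            r_b_L=float(attrs["r_b_L"]), lambda_S=float(attrs["lambda_S"]),
            v_leak_S=float(attrs["v_leak_S"]), dt=float(attrs["dt"]),
            n_steps=int(attrs["n_steps"]))
    return conn, constants
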