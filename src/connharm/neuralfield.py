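"""Wilson-Cowan neural field dynamics on the connectome graph.

Mean excitatory (E) and inhibitory (I) population activity at each graph
node evolves as a reaction-diffusion system,

    tau_s dE/dt = -d_E E + S( a_EE D_EE(E) - a_IE D_IE(I) )
    tau_s dI/dt = -d_I I + S( a_EI D_EI(E) - a_II D_II(I) )

where S is a sigmoidal activation and each D_sigma is a graph-diffusion
(spatial propagation) operator built from the connectome Laplacian by
iterated application,

    D_sigma = (I - (sigma/s) L)^s  ~=  exp(-sigma L),

the explicit-Euler approximation of heat diffusion with extent sigma (the
number of substeps s is chosen for stability; as s grows the operator tends
to the heat kernel).  Short-range excitation combined with broader lateral
inhibition ("Mexican hat" circuitry, sigma_EE < sigma_II) lets oscillatory
patterns self-organize; because every D_sigma is a polynomial in L, the
harmonics diagonalize the linearized dynamics, which is what ties the
emerging patterns to the connectome harmonics.

Time is measured in units of the characteristic time scale tau_s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal
import scipy.special

from .errors import InvalidInputError, NumericalError
from .harmonics import LaplacianMatrix

__all__ = [
    "NeuralFieldParams",
    "SimulationResult",
    "DIFFUSION_PRESETS",
    "sigmoid",
    "substeps_for",
    "diffusion_gain",
    "DiffusionOperator",
    "simulate",
    "power_spectrum",
    "dominant_frequency",
    "seed_correlation",
]

# Named diffusion-extent regimes (sigma_EE, sigma_EI, sigma_IE, sigma_II).
# "fast_excitation" produces faster coherent oscillations than
# "slow_excitation"; the remaining parameters keep their defaults
# (d_E = d_I = 2, all alpha = 150).
DIFFUSION_PRESETS = {
    "fast_excitation": dict(sigma_ee=20.0, sigma_ei=4.0, sigma_ie=4.0, sigma_ii=50.0),
    "slow_excitation": dict(sigma_ee=6.0, sigma_ei=4.0, sigma_ie=4.0, sigma_ii=50.0),
    "slow_excitation_fast_ie": dict(sigma_ee=6.0, sigma_ei=4.0, sigma_ie=10.0, sigma_ii=50.0),
    "slow_excitation_strong_ii": dict(sigma_ee=6.0, sigma_ei=4.0, sigma_ie=10.0, sigma_ii=90.0),
}


@dataclass(frozen=True)
class NeuralFieldParams:
    """Parameters of the neural field model.

    Diffusion extents ``sigma_**`` are dimensionless multiples of the
    Laplacian scale; coupling gains ``alpha_**``, decay rates ``d_e``/``d_i``
    and the sigmoid gain ``a`` / threshold ``theta`` are dimensionless;
    ``tau_s`` is the characteristic time scale and ``dt`` the integration
    step (both in the same time units).
    """

    sigma_ee: float = 6.0
    sigma_ei: float = 4.0
    sigma_ie: float = 4.0
    sigma_ii: float = 50.0
    alpha_ee: float = 150.0
    alpha_ie: float = 150.0
    alpha_ei: float = 150.0
    alpha_ii: float = 150.0
    d_e: float = 2.0
    d_i: float = 2.0
    tau_s: float = 1.0
    a: float = 1.0
    theta: float = 0.0
    dt: float = 0.01
    t_end: float = 50.0
    diffusion_steps: int | None = None  # substeps s per operator; None = auto
    init: str = "uniform_noise"  # uniform_noise | constant | given
    init_amplitude: float = 0.1
    seed: int = 0
    scheme: str = "euler"  # euler | rk4
    record_stride: int = 1

    def __post_init__(self) -> None:
        for name in ("sigma_ee", "sigma_ei", "sigma_ie", "sigma_ii"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        for name in ("alpha_ee", "alpha_ie", "alpha_ei", "alpha_ii"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.d_e <= 0 or self.d_i <= 0 or self.tau_s <= 0:
            raise InvalidInputError("decay rates and tau_s must be positive")
        if not 0 < self.dt < self.tau_s:
            raise InvalidInputError("dt must satisfy 0 < dt < tau_s")
        if self.diffusion_steps is not None and self.diffusion_steps < 1:
            raise InvalidInputError("diffusion_steps must be >= 1")
        if self.scheme not in ("euler", "rk4"):
            raise InvalidInputError(f"unknown scheme {self.scheme!r}")
        if self.init not in ("uniform_noise", "constant", "given"):
            raise InvalidInputError(f"unknown init {self.init!r}")

    @classmethod
    def preset(cls, name: str, **overrides) -> "NeuralFieldParams":
        """Parameters for one of the named diffusion regimes."""
        if name not in DIFFUSION_PRESETS:
            raise InvalidInputError(
                f"unknown preset {name!r}; choose from {sorted(DIFFUSION_PRESETS)}"
            )
        return cls(**{**DIFFUSION_PRESETS[name], **overrides})

    def replace(self, **changes) -> "NeuralFieldParams":
        return replace(self, **changes)


def sigmoid(x, a: float = 1.0, theta: float = 0.0):
    """Sigmoidal activation S(x) = 1 / (1 + exp(-a (x - theta))).

    Strictly increasing with S(theta) = 1/2 and range (0, 1).  Evaluated
    with the numerically stable logistic (no overflow for large |x|).
    """
    return scipy.special.expit(a * (np.asarray(x, dtype=np.float64) - theta))


def sigmoid_deriv(x, a: float = 1.0, theta: float = 0.0):
    """S'(x) = a S(x) (1 - S(x)); equals a/4 at x = theta."""
    s = sigmoid(x, a, theta)
    return a * s * (1.0 - s)


def substeps_for(sigma: float, lam_max: float, target: float = 0.5) -> int:
    """Number of substeps s so that (sigma/s) * lam_max <= target < 1.

    Keeps every factor (1 - (sigma/s) lambda) in (-1, 1] for the whole
    spectrum, making the iterated operator stable, and close enough to the
    heat kernel exp(-sigma L) for the default target of 0.5.
    """
    if sigma <= 0 or lam_max <= 0:
        return 1
    return max(1, math.ceil(sigma * lam_max / target))


def diffusion_gain(sigma: float, lam, s: int):
    """Eigenvalue response of the diffusion operator: (1 - (sigma/s) lambda)^s.

    A harmonic psi_j with eigenvalue lambda_j is an eigenvector of D_sigma
    with this gain; gain(0) = 1 and gain decays ~ exp(-sigma lambda).
    """
    lam = np.asarray(lam, dtype=np.float64)
    return (1.0 - (sigma / s) * lam) ** s


class DiffusionOperator:
    """Graph diffusion D_sigma = (I - (sigma/s) L)^s applied to node vectors."""

    def __init__(self, laplacian: LaplacianMatrix, sigma: float, s: int | None = None):
        if sigma < 0:
            raise InvalidInputError("sigma must be non-negative")
        self.sigma = float(sigma)
        self.laplacian = laplacian
        lam_max = laplacian.lambda_max_bound()
        if s is None:
            s = substeps_for(sigma, lam_max)
        elif sigma > 0 and lam_max > 0 and (sigma / s) * lam_max >= 1.0:
            raise InvalidInputError(
                f"unstable diffusion substepping: (sigma/s)*lambda_max = "
                f"{(sigma / s) * lam_max:.3f} >= 1; use s >= {substeps_for(sigma, lam_max, 0.99)}"
            )
        self.s = int(s)
        n = laplacian.n
        self._dense: np.ndarray | None = None
        if sigma == 0.0:
            self._dense = None
        elif n <= 1500:
            step = np.eye(n) - (self.sigma / self.s) * laplacian.matrix.toarray()
            self._dense = np.linalg.matrix_power(step, self.s)

    def gain(self, lam):
        """Spectral gain of this operator at eigenvalue(s) ``lam``."""
        if self.sigma == 0.0:
            return np.ones_like(np.asarray(lam, dtype=np.float64))
        return diffusion_gain(self.sigma, lam, self.s)

    def apply(self, u: np.ndarray) -> np.ndarray:
        if self.sigma == 0.0:
            return u
        if self._dense is not None:
            return self._dense @ u
        coef = self.sigma / self.s
        L = self.laplacian.matrix
        v = u
        for _ in range(self.s):
            v = v - coef * (L @ v)
        return v


@dataclass
class SimulationResult:
    """E/I trajectories on graph nodes plus run metadata.

    ``E`` and ``I`` are (n_nodes, n_samples) arrays recorded every
    ``record_stride`` integration steps; ``t`` is the matching time axis in
    units of ``tau_s``.
    """

    E: np.ndarray
    I: np.ndarray
    t: np.ndarray
    params: NeuralFieldParams
    log: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.E.shape[0]

    @property
    def dt_sample(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.shape[0] > 1 else self.params.dt

    def final_state(self) -> tuple[np.ndarray, np.ndarray]:
        return self.E[:, -1].copy(), self.I[:, -1].copy()


def _rhs(E, I, ops, p: NeuralFieldParams):
    u_e = p.alpha_ee * ops["ee"].apply(E) - p.alpha_ie * ops["ie"].apply(I)
    u_i = p.alpha_ei * ops["ei"].apply(E) - p.alpha_ii * ops["ii"].apply(I)
    dE = (-p.d_e * E + sigmoid(u_e, p.a, p.theta)) / p.tau_s
    dI = (-p.d_i * I + sigmoid(u_i, p.a, p.theta)) / p.tau_s
    return dE, dI


def build_operators(laplacian: LaplacianMatrix, params: NeuralFieldParams) -> dict:
    """The four diffusion operators (EE, EI, IE, II) for one Laplacian."""
    s = params.diffusion_steps
    return {
        "ee": DiffusionOperator(laplacian, params.sigma_ee, s),
        "ei": DiffusionOperator(laplacian, params.sigma_ei, s),
        "ie": DiffusionOperator(laplacian, params.sigma_ie, s),
        "ii": DiffusionOperator(laplacian, params.sigma_ii, s),
    }


def simulate(
    laplacian: LaplacianMatrix,
    params: NeuralFieldParams,
    init_state: tuple[np.ndarray, np.ndarray] | None = None,
    operators: dict | None = None,
    t_offset: float = 0.0,
) -> SimulationResult:
    """Integrate the neural field equations on a connectome Laplacian.

    Explicit Euler by default (``scheme="rk4"`` for fourth-order
    Runge-Kutta), recording every ``record_stride`` steps.  The initial
    condition is i.i.d. uniform noise in [0, init_amplitude] per node
    (seed-deterministic), a constant state, or the given ``init_state``.
    Raises :class:`NumericalError` with the failing step index if the state
    leaves the finite range.
    """
    n = laplacian.n
    p = params
    ops = operators if operators is not None else build_operators(laplacian, p)

    if init_state is not None:
        E = np.array(init_state[0], dtype=np.float64, copy=True)
        I = np.array(init_state[1], dtype=np.float64, copy=True)
        if E.shape != (n,) or I.shape != (n,):
            raise InvalidInputError("init_state arrays must have shape (n,)")
    elif p.init == "uniform_noise":
        rng = np.random.default_rng(p.seed)
        E = rng.uniform(0.0, p.init_amplitude, size=n)
        I = rng.uniform(0.0, p.init_amplitude, size=n)
    elif p.init == "constant":
        E = np.full(n, p.init_amplitude)
        I = np.full(n, p.init_amplitude)
    else:
        raise InvalidInputError('init="given" requires init_state')

    n_steps = int(round(p.t_end / p.dt))
    stride = max(1, p.record_stride)
    n_rec = n_steps // stride + 1
    E_rec = np.empty((n, n_rec))
    I_rec = np.empty((n, n_rec))
    t_rec = np.empty(n_rec)
    E_rec[:, 0], I_rec[:, 0], t_rec[0] = E, I, t_offset
    max_step = 0.0
    r = 1
    for step in range(1, n_steps + 1):
        if p.scheme == "euler":
            dE, dI = _rhs(E, I, ops, p)
            E_new = E + p.dt * dE
            I_new = I + p.dt * dI
        else:  # rk4
            k1E, k1I = _rhs(E, I, ops, p)
            k2E, k2I = _rhs(E + 0.5 * p.dt * k1E, I + 0.5 * p.dt * k1I, ops, p)
            k3E, k3I = _rhs(E + 0.5 * p.dt * k2E, I + 0.5 * p.dt * k2I, ops, p)
            k4E, k4I = _rhs(E + p.dt * k3E, I + p.dt * k3I, ops, p)
            E_new = E + (p.dt / 6.0) * (k1E + 2 * k2E + 2 * k3E + k4E)
            I_new = I + (p.dt / 6.0) * (k1I + 2 * k2I + 2 * k3I + k4I)
        if not (np.isfinite(E_new).all() and np.isfinite(I_new).all()):
            raise NumericalError(f"simulation diverged (non-finite state) at step {step}")
        max_step = max(max_step, float(np.abs(E_new - E).max()))
        E, I = E_new, I_new
        if step % stride == 0 and r < n_rec:
            E_rec[:, r], I_rec[:, r] = E, I
            t_rec[r] = t_offset + step * p.dt
            r += 1
    return SimulationResult(
        E=E_rec[:, :r],
        I=I_rec[:, :r],
        t=t_rec[:r],
        params=p,
        log={"n_steps": n_steps, "max_abs_dE_per_step": max_step},
    )


def _post_transient(result: SimulationResult, transient_frac: float) -> slice:
    n_samp = result.E.shape[1]
    start = int(np.floor(transient_frac * n_samp))
    return slice(start, n_samp)


def power_spectrum(
    result: SimulationResult, transient_frac: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Node-averaged periodogram of E after discarding an initial transient.

    Returns (frequencies in cycles per tau_s, mean power per frequency).
    """
    sl = _post_transient(result, transient_frac)
    segment = result.E[:, sl]
    if segment.shape[1] < 2:
        raise InvalidInputError("need at least 2 samples after transient removal")
    fs = 1.0 / result.dt_sample
    # no detrending: a constant signal then puts all power exactly in the
    # zero-frequency bin (DFT orthogonality), and the nonzero bins are unaffected
    freqs, power = scipy.signal.periodogram(segment, fs=fs, axis=1, detrend=False)
    return freqs, power.mean(axis=0)


def dominant_frequency(result: SimulationResult, transient_frac: float = 0.2) -> float:
    """Frequency (cycles per tau_s) of the largest nonzero-frequency peak."""
    freqs, power = power_spectrum(result, transient_frac)
    if freqs.shape[0] < 2:
        raise InvalidInputError("spectrum too short to locate a nonzero peak")
    j = 1 + int(np.argmax(power[1:]))
    return float(freqs[j])


def seed_correlation(
    result: SimulationResult, seeds, transient_frac: float = 0.2
) -> np.ndarray:
    """Pearson correlation of each seed node's E series with every node's.

    Returns an (n_seeds, n_nodes) array in [-1, 1]; a node (or seed) with
    zero temporal variance yields NaN entries, the explicit "undefined"
    marker, rather than a fabricated 0.
    """
    seeds = np.atleast_1d(np.asarray(seeds, dtype=np.int64))
    if seeds.size == 0:
        raise InvalidInputError("no seed vertices given")
    if seeds.min() < 0 or seeds.max() >= result.n_nodes:
        raise InvalidInputError("seed vertex index out of range")
    sl = _post_transient(result, transient_frac)
    X = result.E[:, sl]
    if X.shape[1] < 3:
        raise InvalidInputError("need at least 3 samples after transient removal")
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc[seeds] @ Xc.T) / (sd[seeds][:, None] * sd[None, :])
    corr = np.clip(corr, -1.0, 1.0)  # roundoff guard; NaN passes through
    corr[:, sd == 0] = np.nan
    corr[sd[seeds] == 0, :] = np.nan
    return corr
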