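"""Linear (Hopf) and Lyapunov stability analysis of the neural field model.

Because every diffusion operator is a polynomial in the Laplacian, the
linearization of the two-population dynamics around the spatially uniform
fixed point block-diagonalizes in the harmonic basis: each harmonic with
eigenvalue lambda evolves under a 2x2 Jacobian whose diffusion couplings
are scaled by the spectral gains g_sigma(lambda).  The trace/determinant of
that 2x2 matrix classify each (parameter, lambda) cell:

* ``stable``               tr < 0, det > 0
* ``hopf_critical``        |tr| < tol, det > 0 (oscillatory instability threshold)
* ``unstable_oscillatory`` tr > 0, tr^2 < 4 det (growing oscillation)
* ``unstable_monotonic``   det < 0 (saddle) or tr > 0 with real growth

The red "Hopf regime" of a diffusion-parameter sweep is the set of cells at
or beyond the oscillatory threshold; those harmonics are the ones the
nonlinear model can spontaneously activate.

The Lyapunov analysis is trajectory-based: the integrated (generally
oscillatory) solution is perturbed by white noise at a time t*, several
times independently, and the worst-case L-infinity distance L(t) between
perturbed and unperturbed trajectories is tracked.  A stable limit cycle
re-attracts the perturbed copies up to a small phase shift, so the verdict
can optionally use a phase-aligned distance for the tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .errors import InvalidInputError, NumericalError
from .harmonics import LaplacianMatrix
from .neuralfield import (
    NeuralFieldParams,
    SimulationResult,
    build_operators,
    sigmoid,
    sigmoid_deriv,
    simulate,
    substeps_for,
    diffusion_gain,
)

__all__ = [
    "StabilityMap",
    "LyapunovResult",
    "fixed_point",
    "jacobian_per_harmonic",
    "classify_cell",
    "hopf_region_map",
    "perturbation_growth_rate",
    "lyapunov_test",
    "CLASSES",
]

CLASSES = ("stable", "hopf_critical", "unstable_oscillatory", "unstable_monotonic")


def fixed_point(params: NeuralFieldParams, residual_tol: float = 1e-10) -> tuple[float, float]:
    """Spatially uniform steady state (E*, I*) of the reaction dynamics.

    Solves d_E E = S(a_EE E - a_IE I), d_I I = S(a_EI E - a_II I); the
    uniform state sees unit diffusion gain (a combinatorial Laplacian
    annihilates constants), so the diffusion extents drop out.  Solved by
    multi-start root finding with Newton polish; residual < ``residual_tol``
    guaranteed on return.
    """
    p = params

    def res(x):
        E, I = x
        return [
            -p.d_e * E + sigmoid(p.alpha_ee * E - p.alpha_ie * I, p.a, p.theta),
            -p.d_i * I + sigmoid(p.alpha_ei * E - p.alpha_ii * I, p.a, p.theta),
        ]

    def jac(x):
        E, I = x
        se = sigmoid_deriv(p.alpha_ee * E - p.alpha_ie * I, p.a, p.theta)
        si = sigmoid_deriv(p.alpha_ei * E - p.alpha_ii * I, p.a, p.theta)
        return np.array(
            [
                [-p.d_e + p.alpha_ee * se, -p.alpha_ie * se],
                [p.alpha_ei * si, -p.d_i - p.alpha_ii * si],
            ]
        )

    starts = [(0.5 / p.d_e, 0.5 / p.d_i)]
    for ge in np.linspace(0.05, 0.95, 5):
        for gi in np.linspace(0.05, 0.95, 5):
            starts.append((ge / p.d_e, gi / p.d_i))
    best = None
    for x0 in starts:
        sol = scipy.optimize.root(res, x0, jac=jac, method="hybr", tol=1e-13)
        r = float(np.linalg.norm(res(sol.x)))
        if best is None or r < best[1]:
            best = (sol.x, r)
        if r < residual_tol:
            break
    x, r = best
    for _ in range(50):  # Newton polish to full precision
        if r < residual_tol:
            break
        try:
            x = x - np.linalg.solve(jac(x), np.asarray(res(x)))
        except np.linalg.LinAlgError:
            break
        r = float(np.linalg.norm(res(x)))
    if r >= residual_tol:
        raise NumericalError(f"fixed point residual {r:.3e} exceeds {residual_tol:.1e}")
    return float(x[0]), float(x[1])


def _gains(params: NeuralFieldParams, lam: float, lam_max: float) -> dict:
    out = {}
    for key, sigma in (
        ("ee", params.sigma_ee),
        ("ei", params.sigma_ei),
        ("ie", params.sigma_ie),
        ("ii", params.sigma_ii),
    ):
        s = params.diffusion_steps or substeps_for(sigma, lam_max)
        out[key] = 1.0 if sigma == 0.0 else float(diffusion_gain(sigma, lam, s))
    return out


def jacobian_per_harmonic(
    params: NeuralFieldParams,
    lam: float,
    lam_max: float,
    fixed_pt: tuple[float, float] | None = None,
) -> np.ndarray:
    """2x2 Jacobian of the linearized dynamics restricted to one harmonic.

    ``lam`` is the harmonic's Laplacian eigenvalue and ``lam_max`` the upper
    bound used to pick diffusion substeps (must match the simulation's, so
    the analytic gains equal the operators actually applied).  At lam = 0
    all gains are 1 and this reduces to the space-less two-population
    Jacobian.
    """
    p = params
    if fixed_pt is None:
        fixed_pt = fixed_point(p)
    E, I = fixed_pt
    g = _gains(p, lam, lam_max)
    u_e = p.alpha_ee * E - p.alpha_ie * I
    u_i = p.alpha_ei * E - p.alpha_ii * I
    se = sigmoid_deriv(u_e, p.a, p.theta)
    si = sigmoid_deriv(u_i, p.a, p.theta)
    return (
        np.array(
            [
                [-p.d_e + p.alpha_ee * g["ee"] * se, -p.alpha_ie * g["ie"] * se],
                [p.alpha_ei * g["ei"] * si, -p.d_i - p.alpha_ii * g["ii"] * si],
            ]
        )
        / p.tau_s
    )


def classify_cell(trace: float, det: float, tau_s: float = 1.0, hopf_tol: float = 1e-3) -> str:
    """Classify a 2x2 Jacobian cell from its trace and determinant.

    ``hopf_tol`` applies to the trace normalized by the 1/tau_s time scale.
    """
    tr_n = trace * tau_s
    if det < 0:
        return "unstable_monotonic"
    if abs(tr_n) < hopf_tol and det > 0:
        return "hopf_critical"
    if trace > 0:
        return "unstable_oscillatory" if trace**2 < 4.0 * det else "unstable_monotonic"
    return "stable"


@dataclass
class StabilityMap:
    """Per-(sweep value, eigenvalue) classification grid with trace/det."""

    sweep_name: str
    sweep_values: np.ndarray
    lambdas: np.ndarray
    classification: np.ndarray  # (n_sweep, n_lambda) of str
    trace: np.ndarray
    det: np.ndarray
    hopf_tol: float

    def fraction(self, cls: str) -> float:
        return float(np.mean(self.classification == cls))


def hopf_region_map(
    params: NeuralFieldParams,
    sweep_name: str,
    sweep_values,
    lambdas,
    lam_max: float | None = None,
    hopf_tol: float = 1e-3,
) -> StabilityMap:
    """Classify the (swept diffusion parameter) x (eigenvalue) plane.

    ``sweep_name`` is any :class:`NeuralFieldParams` field (typically one of
    the four sigma's; none is privileged).  ``lam_max`` defaults to the
    largest eigenvalue in ``lambdas`` and fixes the diffusion substepping
    for the whole map.
    """
    sweep_values = np.asarray(sweep_values, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if sweep_values.size == 0 or lambdas.size == 0:
        raise InvalidInputError("sweep and eigenvalue grids must be nonempty")
    if not hasattr(params, sweep_name):
        raise InvalidInputError(f"unknown sweep parameter {sweep_name!r}")
    if lam_max is None:
        lam_max = float(lambdas.max())
    cls = np.empty((sweep_values.size, lambdas.size), dtype=object)
    tr = np.empty_like(cls, dtype=np.float64)
    dt = np.empty_like(tr)
    for i, v in enumerate(sweep_values):
        p = params.replace(**{sweep_name: float(v)})
        fp = fixed_point(p)
        for j, lam in enumerate(lambdas):
            J = jacobian_per_harmonic(p, float(lam), lam_max, fixed_pt=fp)
            tr[i, j] = np.trace(J)
            dt[i, j] = np.linalg.det(J)
            cls[i, j] = classify_cell(tr[i, j], dt[i, j], p.tau_s, hopf_tol)
    return StabilityMap(
        sweep_name=sweep_name,
        sweep_values=sweep_values,
        lambdas=lambdas,
        classification=cls.astype(str),
        trace=tr,
        det=dt,
        hopf_tol=hopf_tol,
    )


def perturbation_growth_rate(
    laplacian: LaplacianMatrix,
    params: NeuralFieldParams,
    psi: np.ndarray,
    lam: float,
    eps: float = 1e-4,
    t_end: float = 2.0,
    lam_max: float | None = None,
) -> float:
    """Measured exponential rate of a harmonic-seeded perturbation.

    The full nonlinear model is integrated from the uniform fixed point
    plus ``eps`` times the harmonic ``psi`` (seeded along the leading
    eigendirection of the per-harmonic 2x2 Jacobian), and the log amplitude
    of the (E, I) projection onto ``psi`` is regressed against time over
    the window where the perturbation stays in the linear regime.  Positive
    return value = growth, negative = decay; compare with the real part of
    the leading Jacobian eigenvalue.
    """
    if lam_max is None:
        lam_max = laplacian.lambda_max_bound()
    fp = fixed_point(params)
    J = jacobian_per_harmonic(params, lam, lam_max, fixed_pt=fp)
    eigvals, eigvecs = np.linalg.eig(J)
    lead = int(np.argmax(eigvals.real))
    v = eigvecs[:, lead].real
    v = v / np.linalg.norm(v)
    psi = np.asarray(psi, dtype=np.float64)
    psi = psi / np.linalg.norm(psi)
    E0 = fp[0] + eps * v[0] * psi
    I0 = fp[1] + eps * v[1] * psi
    res = simulate(laplacian, params.replace(t_end=t_end, init="given"), init_state=(E0, I0))
    pE = psi @ (res.E - fp[0])
    pI = psi @ (res.I - fp[1])
    r = np.hypot(pE, pI)
    cap = min(1e3 * eps, 0.05)
    floor = 1e-3 * eps
    valid = (r > floor) & (r < cap)
    # keep the contiguous valid stretch starting at t=0
    stop = int(np.argmin(valid)) if not valid.all() else valid.size
    if stop < 5:
        raise NumericalError("perturbation left the linear regime too quickly to fit a rate")
    t, logr = res.t[:stop], np.log(r[:stop])
    slope = np.polyfit(t, logr, 1)[0]
    return float(slope)


@dataclass
class LyapunovResult:
    """Worst-case perturbation distance L(t) and the stability verdict.

    ``L`` is exactly zero before ``t_star`` (the copies coincide with the
    reference), and afterwards is the maximum over perturbed copies and
    nodes of |perturbed - unperturbed| across both E and I.  ``verdict`` is
    True iff every copy stayed finite, sup L is finite, and the tail-window
    mean distance (phase-aligned if requested) is below ``epsilon``.
    """

    t: np.ndarray
    L: np.ndarray
    t_star: float
    n_perturb: int
    noise_amp: float
    epsilon: float
    sup_L: float
    tail_mean: float
    tail_mean_aligned: float | None
    verdict: bool
    diverged: bool = False


def lyapunov_test(
    laplacian: LaplacianMatrix,
    params: NeuralFieldParams,
    t_star: float,
    n_perturb: int = 10,
    noise_amp: float | None = None,
    seed: int = 0,
    epsilon: float | None = None,
    tail_frac: float = 0.2,
    phase_align: bool = True,
) -> LyapunovResult:
    """Perturb the trajectory ``n_perturb`` times with white noise at ``t_star``.

    The reference trajectory is integrated to ``params.t_end``; at ``t_star``
    each copy receives i.i.d. symmetric uniform noise of amplitude
    ``noise_amp`` (default: 1% of the reference E range) added to both E and
    I, and is integrated alongside the reference.  L(t) is the worst-case
    L-infinity distance over copies and nodes.

    The tail verdict uses the last ``tail_frac`` of post-perturbation
    samples; with ``phase_align=True`` each tail sample is compared against
    the best-matching reference sample within a small time-shift window,
    which is the appropriate notion of convergence for a limit cycle (a
    perturbation leaves a permanent small phase shift).  ``epsilon``
    defaults to ``noise_amp``: the perturbation must not have grown.
    """
    p = params
    if not 0.0 < t_star < p.t_end:
        raise InvalidInputError("t_star must lie strictly inside (0, t_end)")
    if n_perturb < 1:
        raise InvalidInputError("n_perturb must be >= 1")
    ops = build_operators(laplacian, p)
    pre = simulate(laplacian, p.replace(t_end=t_star), operators=ops)
    E_star, I_star = pre.final_state()
    t_rest = p.t_end - t_star
    ref = simulate(
        laplacian,
        p.replace(t_end=t_rest, init="given"),
        init_state=(E_star, I_star),
        operators=ops,
        t_offset=t_star,
    )
    if noise_amp is None:
        noise_amp = 0.01 * float(np.ptp(ref.E))
    if epsilon is None:
        epsilon = noise_amp if noise_amp > 0 else 1e-12
    rng = np.random.default_rng(seed)
    n_samp = ref.E.shape[1]
    L_post = np.zeros(n_samp)
    diverged = False
    copies_E = []
    for _ in range(n_perturb):
        dE = rng.uniform(-noise_amp, noise_amp, size=laplacian.n)
        dI = rng.uniform(-noise_amp, noise_amp, size=laplacian.n)
        try:
            pert = simulate(
                laplacian,
                p.replace(t_end=t_rest, init="given"),
                init_state=(E_star + dE, I_star + dI),
                operators=ops,
                t_offset=t_star,
            )
        except NumericalError:
            diverged = True
            continue
        diff = np.maximum(
            np.abs(pert.E - ref.E).max(axis=0), np.abs(pert.I - ref.I).max(axis=0)
        )
        L_post = np.maximum(L_post, diff)
        copies_E.append(pert.E)

    t = np.concatenate([pre.t, ref.t[1:]])
    L = np.concatenate([np.zeros(pre.t.shape[0]), L_post[1:]])
    n_tail = max(1, int(np.ceil(tail_frac * n_samp)))
    tail = slice(n_samp - n_tail, n_samp)
    tail_mean = float(L_post[tail].mean())

    tail_aligned = None
    if phase_align and copies_E:
        W = max(1, n_tail // 10)
        idx = np.arange(n_samp - n_tail, n_samp)
        per_t = np.zeros(n_tail)
        for Ep in copies_E:
            best = np.full(n_tail, np.inf)
            for shift in range(-W, W + 1):
                j = np.clip(idx + shift, 0, n_samp - 1)
                d = np.abs(Ep[:, j] - ref.E[:, idx]).max(axis=0)
                best = np.minimum(best, d)
            per_t = np.maximum(per_t, best)
        tail_aligned = float(per_t.mean())

    sup_L = float(L.max()) if not diverged else float("inf")
    crit = tail_aligned if (phase_align and tail_aligned is not None) else tail_mean
    verdict = (not diverged) and np.isfinite(sup_L) and crit < epsilon
    return LyapunovResult(
        t=t,
        L=L,
        t_star=t_star,
        n_perturb=n_perturb,
        noise_amp=float(noise_amp),
        epsilon=float(epsilon),
        sup_L=sup_L,
        tail_mean=tail_mean,
        tail_mean_aligned=tail_aligned,
        verdict=bool(verdict),
        diverged=diverged,
    )
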