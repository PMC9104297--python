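"""Sparse phasic/tonic decomposition of EDA segments.

The conductance segment ``x`` (µS, sampled at ``fs``) is modelled as

    x = K p + B l + C d + e,

where ``p >= 0`` is a sparse sudomotor driver, ``K`` convolves with a
unit-peak biexponential SCR kernel, ``B`` is a cubic B-spline basis with
knots every ``tonic_knot_spacing_s`` seconds, ``C`` an offset + linear
drift basis, and ``e`` white residual noise.  The components solve the
convex program

    minimize  1/2 ||K p + B l + C d - x||^2 + alpha * ||p||_1
              + gamma/2 * ||l||^2      subject to  p >= 0.

Because ``p`` is nonnegative the L1 term is linear on the feasible set, so
this is a strictly convex bound-constrained quadratic program.  It is
solved with a block principal-pivoting active-set method (Kunisch-Rendl
style): the optimal driver support is sparse, so only a few small dense
KKT solves are needed.  A bound-constrained L-BFGS solver over the same
objective (FFT convolution operators, analytic gradients) is kept as a
fallback and as an alternative route for cross-checks.

``phasic = K p`` and ``tonic = B l + C d``; the residual is defined as
``x - phasic - tonic`` so the additive reconstruction identity is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import interpolate, linalg, optimize
from scipy import signal as sps

from .io import ValidationError

__all__ = [
    "DecompositionConfig",
    "DecompositionResult",
    "build_response_kernel",
    "effective_response_kernel",
    "decompose",
    "tonic_design_matrices",
]

# tiny ridge on the driver: the kernel has k(0) = 0, so the trailing
# convolution columns are rank-deficient; this keeps the QP strictly convex
_DRIVER_RIDGE = 1e-9


@dataclass(frozen=True)
class DecompositionConfig:
    """Decomposition hyperparameters.

    ``driver_sparsity_alpha`` weights the L1 penalty on the driver (larger
    means sparser); ``tonic_smoothness_gamma`` ridge-penalizes the spline
    coefficients so the tonic stays slow; the offset + linear-drift columns
    are unpenalized so the absolute conductance level is preserved in µS.
    ``solver`` is ``"active-set"`` (default) or ``"lbfgs"``.
    """

    tau_rise_s: float = 0.7
    tau_decay_s: float = 2.0
    driver_sparsity_alpha: float = 8e-4
    tonic_smoothness_gamma: float = 1e-2
    tonic_knot_spacing_s: float = 10.0
    solver_tolerance: float = 1e-8
    # base relative KKT tolerance for the pivoting loop.  When pivoting
    # stalls (nearly collinear neighbouring kernel columns on noisy
    # segments), the effective tolerance is escalated stepwise up to 500x
    # this base; the associated phasic changes are far below measurement
    # noise, while clean segments still converge at the base tolerance.
    kkt_relative_tolerance: float = 1e-7
    max_iterations: int = 4000
    solver: str = "active-set"
    # when set, the response kernel is passed through the same zero-phase
    # low-pass as the analyzed signal, so the convolution model matches the
    # preprocessed data.  Without this the filter's acausal ringing around
    # each SCR cannot be represented by the causal kernel and the solver
    # compensates with dense spurious driver activity.
    match_lowpass_order: int | None = None
    match_lowpass_cutoff_hz: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_s < self.tau_decay_s:
            raise ValidationError("need 0 < tau_rise_s < tau_decay_s")
        if self.driver_sparsity_alpha <= 0 or self.tonic_smoothness_gamma <= 0:
            raise ValidationError("alpha and gamma must be positive")
        if self.solver not in ("active-set", "lbfgs"):
            raise ValidationError(f"unknown solver {self.solver!r}")
        if (self.match_lowpass_order is None) != (self.match_lowpass_cutoff_hz is None):
            raise ValidationError(
                "match_lowpass_order and match_lowpass_cutoff_hz go together"
            )


@dataclass
class DecompositionResult:
    """Tonic/phasic/driver/residual split of one segment.

    ``tonic + phasic + residual`` reconstructs the input exactly by
    construction; ``phasic`` is exactly the kernel convolution of
    ``driver``; ``driver >= 0`` elementwise.
    """

    tonic: np.ndarray
    phasic: np.ndarray
    driver: np.ndarray
    residual: np.ndarray
    objective_value: float
    converged: bool
    n_iterations: int = 0
    solver_message: str = ""

    def reconstruction(self) -> np.ndarray:
        return self.tonic + self.phasic + self.residual


def build_response_kernel(
    tau_rise_s: float, tau_decay_s: float, fs: float, tail_mass: float = 1e-6
) -> np.ndarray:
    """Discrete unit-peak biexponential SCR impulse response.

    k(t) = exp(-t/tau_decay) - exp(-t/tau_rise) sampled at 1/fs, truncated
    where the remaining tail mass drops below ``tail_mass`` of the total,
    and normalized to unit peak so driver amplitudes carry the µS scale of
    the SCRs they generate.  The continuous-time peak sits at
    t* = ln(tau_decay/tau_rise) * tau_rise*tau_decay / (tau_decay - tau_rise).
    """
    if not 0 < tau_rise_s < tau_decay_s:
        raise ValidationError(
            f"need 0 < tau_rise_s < tau_decay_s, got {tau_rise_s}, {tau_decay_s}"
        )
    if fs <= 0:
        raise ValidationError("fs must be positive")
    t_end = -tau_decay_s * np.log(tail_mass)
    t = np.arange(0.0, t_end, 1.0 / fs)
    k = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    k[k < 0] = 0.0
    peak = k.max()
    if peak <= 0:
        raise ValidationError("kernel vanishes on this sampling grid")
    return k / peak


def tonic_design_matrices(n: int, fs: float, knot_spacing_s: float):
    """Cubic-spline basis B (sparse, n x nb) and drift basis C (n x 2)."""
    t = np.arange(n) / fs
    span = n / fs
    interior = np.arange(knot_spacing_s, span - 1e-9, knot_spacing_s)
    knots = np.concatenate([np.zeros(4), interior, np.full(4, span)])
    B = interpolate.BSpline.design_matrix(t, knots, 3).tocsr()
    C = np.column_stack([np.ones(n), t / max(span, 1.0)])
    return B, C


def effective_response_kernel(
    tau_rise_s: float,
    tau_decay_s: float,
    fs: float,
    lowpass_order: int | None = None,
    lowpass_cutoff_hz: float | None = None,
) -> tuple[np.ndarray, int]:
    """Response kernel taps and the acausal offset of the first tap.

    Returns ``(taps, pre)`` where ``taps[pre]`` is the kernel value at
    lag 0; ``pre > 0`` only when the kernel is shaped by the zero-phase
    preprocessing low-pass, whose ringing extends a few seconds before
    each sudomotor impulse.
    """
    kernel = build_response_kernel(tau_rise_s, tau_decay_s, fs)
    if lowpass_order is None:
        return kernel, 0
    from .preprocess import lowpass_filter  # deferred: avoids import cycle

    pre = int(round(4.0 * fs))
    guard = int(round(20.0 * fs))
    padded = np.concatenate([np.zeros(guard + pre), kernel, np.zeros(guard)])
    shaped = lowpass_filter(padded, fs, lowpass_order, lowpass_cutoff_hz)
    return shaped[guard : guard + pre + kernel.size], pre


@lru_cache(maxsize=8)
def _cached_operators(n: int, fs: float, tau_rise_s: float, tau_decay_s: float,
                      knot_spacing_s: float,
                      lowpass_order: int | None, lowpass_cutoff_hz: float | None):
    """Dense Gram blocks for the QP, cached per segment geometry."""
    taps, pre = effective_response_kernel(
        tau_rise_s, tau_decay_s, fs, lowpass_order, lowpass_cutoff_hz
    )
    K = np.zeros((n, n))
    for j in range(n):
        lo = max(0, j - pre)
        hi = min(n, j - pre + taps.size)
        K[lo:hi, j] = taps[lo - j + pre : hi - j + pre]
    B, C = tonic_design_matrices(n, fs, knot_spacing_s)
    G = np.column_stack([B.toarray(), C])
    KtK = K.T @ K
    KtG = K.T @ G
    GtG = G.T @ G
    return taps, pre, G, KtK, KtG, GtG, B.shape[1]


def _solve_active_set(x, n, nw, alpha, gamma_diag, taps, pre, G, KtK, KtG, GtG,
                      tol, max_iter):
    """Block principal pivoting for  min 1/2 z'Qz - b'z,  p >= 0, w free.

    z = (p, w); Q = [[KtK + ridge, KtG], [KtG', GtG + diag(gamma)]],
    b = (K'x - alpha, G'x).  Returns (p, w, iterations, converged).
    """
    m = taps.size
    krev = taps[::-1]
    Ktx = sps.fftconvolve(x, krev)[m - 1 - pre : m - 1 - pre + n]
    bp = Ktx - alpha
    bw = G.T @ x
    Qpp_diag_ridge = _DRIVER_RIDGE * max(1.0, float(KtK[0, 0]))
    Qww = GtG + np.diag(gamma_diag)

    # relative tolerances: neighbouring kernel columns are nearly collinear,
    # so insisting on machine-precision KKT residuals makes the pivoting
    # thrash between adjacent indices with no material objective change.
    # The tolerance staircase keeps early iterations exact and relaxes only
    # if the combinatorial search stalls.
    gscale = max(1.0, np.abs(bp).max())
    pscale = max(1.0, np.abs(x).max())
    stair = ((15, 1.0), (25, 10.0), (35, 100.0), (np.inf, 500.0))

    passive = np.zeros(n, dtype=bool)  # p indices currently free
    p = np.zeros(n)
    w = np.zeros(nw)
    # Kim-Park backup rule state: full exchanges while the infeasibility
    # count improves, a few grace retries, then single swaps (highest
    # index) until it improves again -- guarantees finite termination
    best_infeas = np.inf
    backup = 3

    for it in range(1, max_iter + 1):
        factor = next(f for lim, f in stair if it <= lim)
        gtol = tol * factor * gscale
        ptol = tol * factor * pscale
        idx = np.flatnonzero(passive)
        s = idx.size
        # KKT solve on the free block
        A = np.empty((s + nw, s + nw))
        A[:s, :s] = KtK[np.ix_(idx, idx)]
        A[np.arange(s), np.arange(s)] += Qpp_diag_ridge
        A[:s, s:] = KtG[idx]
        A[s:, :s] = KtG[idx].T
        A[s:, s:] = Qww
        rhs = np.concatenate([bp[idx], bw])
        try:
            sol = linalg.solve(A, rhs, assume_a="pos")
        except linalg.LinAlgError:
            sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
        p_free, w = sol[:s], sol[s:]

        # gradient on the active (clamped) coordinates
        p_full = np.zeros(n)
        p_full[idx] = p_free
        conv_p = sps.fftconvolve(p_full, taps)[pre : pre + n]
        r = conv_p + G @ w - x
        g = sps.fftconvolve(r, krev)[m - 1 - pre : m - 1 - pre + n] + alpha

        neg_p = passive & (p_full < -ptol)
        neg_g = (~passive) & (g < -gtol)
        n_viol = int(neg_p.sum() + neg_g.sum())
        if n_viol == 0:
            p = np.maximum(p_full, 0.0)
            return p, w, it, True
        if n_viol < best_infeas:
            best_infeas = n_viol
            backup = 3
            passive[neg_p] = False
            passive[neg_g] = True
        elif backup > 0:
            backup -= 1
            passive[neg_p] = False
            passive[neg_g] = True
        else:
            cands = np.flatnonzero(neg_p | neg_g)
            passive[cands[-1]] = ~passive[cands[-1]]

    return np.maximum(p_full, 0.0), w, max_iter, False


def decompose(
    x: np.ndarray, fs: float, cfg: DecompositionConfig | None = None
) -> DecompositionResult:
    """Decompose one EDA segment into tonic, phasic, driver and residual.

    Requires at least 10 s of finite samples.  A constant segment yields a
    (numerically) zero driver and a tonic equal to the constant.
    """
    cfg = cfg or DecompositionConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("input must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite samples in input")
    n = x.size
    if n < 10 * fs:
        raise ValidationError(f"segment too short: need >= 10 s at {fs} Hz")

    taps, pre, G, KtK, KtG, GtG, nb = _cached_operators(
        n, float(fs), cfg.tau_rise_s, cfg.tau_decay_s, cfg.tonic_knot_spacing_s,
        cfg.match_lowpass_order, cfg.match_lowpass_cutoff_hz,
    )
    nw = G.shape[1]
    gamma_diag = np.concatenate(
        [np.full(nb, cfg.tonic_smoothness_gamma), np.zeros(nw - nb)]
    )
    alpha = cfg.driver_sparsity_alpha

    converged = False
    n_iter = 0
    message = ""
    p = w = None
    if cfg.solver == "active-set":
        p, w, n_iter, converged = _solve_active_set(
            x, n, nw, alpha, gamma_diag, taps, pre, G, KtK, KtG, GtG,
            tol=cfg.kkt_relative_tolerance, max_iter=200,
        )
        message = "active-set block pivoting"
    if p is None or not converged:
        p, w, n_iter, converged, message = _solve_lbfgs(
            x, n, nw, nb, alpha, cfg, taps, pre, G, gamma_diag
        )

    phasic = sps.fftconvolve(p, taps)[pre : pre + n]
    tonic = G @ w
    residual = x - phasic - tonic
    obj = (
        0.5 * float(residual @ residual)
        + alpha * float(p.sum())
        + 0.5 * float((gamma_diag * w) @ w)
    )
    return DecompositionResult(
        tonic=tonic,
        phasic=phasic,
        driver=p,
        residual=residual,
        objective_value=obj,
        converged=bool(converged),
        n_iterations=int(n_iter),
        solver_message=message,
    )


def _solve_lbfgs(x, n, nw, nb, alpha, cfg, taps, pre, G, gamma_diag):
    """Bound-constrained L-BFGS over the same objective (fallback route)."""
    m = taps.size
    krev = taps[::-1]

    def conv(p):
        return sps.fftconvolve(p, taps)[pre : pre + n]

    def conv_t(r):
        return sps.fftconvolve(r, krev)[m - 1 - pre : m - 1 - pre + n]

    def fun_grad(z):
        p, w = z[:n], z[n:]
        r = conv(p) + G @ w - x
        f = 0.5 * float(r @ r) + alpha * float(p.sum()) + 0.5 * float(
            (gamma_diag * w) @ w
        )
        g = np.empty_like(z)
        g[:n] = conv_t(r) + alpha
        g[n:] = G.T @ r + gamma_diag * w
        return f, g

    lhs = G.T @ G + np.diag(gamma_diag)
    try:
        w0 = np.linalg.solve(lhs, G.T @ x)
    except np.linalg.LinAlgError:
        w0 = np.zeros(nw)
    z0 = np.concatenate([np.zeros(n), w0])
    bounds = [(0.0, None)] * n + [(None, None)] * nw
    res = optimize.minimize(
        fun_grad, z0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={
            "maxiter": cfg.max_iterations,
            "maxfun": 4 * cfg.max_iterations,
            "ftol": cfg.solver_tolerance,
            "gtol": 1e-7,
            "maxcor": 20,
        },
    )
    p = np.maximum(res.x[:n], 0.0)
    return p, res.x[n:], int(res.nit), bool(res.success), str(res.message)
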