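"""1-D building blocks of the semi-implicit growth-diffusion scheme.

Every solver sweep acts on one habitable segment at a time.  A segment of
length n carries a tridiagonal (Crank-Nicolson-type) linear system whose
nonlinear logistic term has been linearized with an explicit Euler
predictor.  Two boundary treatments are supported:

* Dirichlet: the segment is conceptually padded with one zero cell at each
  end; only interior cells are updated.
* Neumann (zero net flux): boundary rows use the second-order one-sided
  derivative, giving rows (1, -4/3, 1/3 | 0).  The stray 1/3 entries are
  moved to the right-hand side with explicit Heun estimates so a plain
  tridiagonal solve suffices.  Segments of length 1, 2 and 3 carry no usable
  derivative information and are special-cased.

Coefficients are general: CFL parameter ``k = c h / dx^2`` and logistic
weight ``g = lam h``; the scaled equation (lam = 1, c = 1/2) recovers
``k = h / (2 dx^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "StepParams",
    "BoundarySpec",
    "TridiagonalSystem",
    "SingularSystemError",
    "diffusion_operator",
    "bc_operator",
    "solve_tridiagonal",
    "euler_predictor",
    "trapezoid_step_dirichlet",
    "assemble_neumann_step",
    "neumann_full_system",
    "short_segment_step",
    "diffusion_trapezoid_dirichlet",
    "diffusion_trapezoid_neumann",
    "clamp",
]

BCMode = Literal["dirichlet", "neumann"]


@dataclass(frozen=True)
class StepParams:
    """Time step, spacing and growth/diffusion coefficients.

    ``h`` and ``dx`` share time/length units with ``lam`` (1/time) and
    ``c`` (length^2/time, with D = 2c).
    """

    h: float
    dx: float
    c: float = 0.5
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.h <= 0 or self.dx <= 0:
            raise ValueError("h and dx must be positive")
        if self.c < 0 or self.lam < 0:
            raise ValueError("c and lam must be non-negative")

    @property
    def k(self) -> float:
        """CFL parameter c*h/dx^2 (h/(2 dx^2) in scaled units)."""
        return self.c * self.h / self.dx**2

    @property
    def growth(self) -> float:
        """Logistic weight lam*h."""
        return self.lam * self.h


@dataclass(frozen=True)
class BoundarySpec:
    mode: BCMode = "neumann"

    def __post_init__(self) -> None:
        if self.mode not in ("dirichlet", "neumann"):
            raise ValueError(f"unknown boundary mode {self.mode!r}")


class SingularSystemError(np.linalg.LinAlgError):
    pass


def diffusion_operator(u: np.ndarray) -> np.ndarray:
    """Raw (1, -2, 1) second-difference stencil with no ghost values."""
    u = np.asarray(u, dtype=float)
    out = -2.0 * u
    if u.size > 1:
        out[1:] += u[:-1]
        out[:-1] += u[1:]
    return out


def bc_operator(u: np.ndarray, mode: BCMode) -> np.ndarray:
    """Second-difference operator with boundary ghosts per ``mode``.

    Dirichlet uses zero ghosts (identical to the raw stencil); Neumann uses
    mirror ghosts ``u_0 = u_2`` and ``u_{n+1} = u_{n-1}`` so the explicit
    stencil has zero flux to second order.  A single Neumann cell has no
    neighbours: the operator action is 0.
    """
    out = diffusion_operator(u)
    if mode == "neumann":
        if u.size == 1:
            out[:] = 0.0
        else:
            out[0] += u[1]
            out[-1] += u[-2]
    return out


@dataclass
class TridiagonalSystem:
    """Tridiagonal system, optionally perturbed by isolated corner entries.

    ``sub`` and ``sup`` have length n-1.  ``corner_terms`` holds sparse
    (row, col, value) entries lying off the three main bands — e.g. the 1/3
    elements of the zero-flux boundary rows — which force a dense solve.
    """

    sub: np.ndarray
    diag: np.ndarray
    sup: np.ndarray
    rhs: np.ndarray
    corner_terms: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.diag)
        if n < 1 or len(self.rhs) != n:
            raise ValueError("inconsistent system sizes")
        if n > 1 and (len(self.sub) != n - 1 or len(self.sup) != n - 1):
            raise ValueError("sub/sup must have length n-1")

    def dense(self) -> np.ndarray:
        n = len(self.diag)
        mat = np.diag(np.asarray(self.diag, dtype=float))
        if n > 1:
            mat += np.diag(np.asarray(self.sub, dtype=float), -1)
            mat += np.diag(np.asarray(self.sup, dtype=float), 1)
        for r, c, v in self.corner_terms:
            mat[r, c] += v
        return mat


def _thomas(
    sub: np.ndarray, diag: np.ndarray, sup: np.ndarray, rhs: np.ndarray
) -> Optional[np.ndarray]:
    """Thomas elimination without pivoting; None signals a small pivot."""
    n = diag.size
    scale = float(np.max(np.abs(diag))) or 1.0
    tiny = 1e-12 * scale
    cp = np.empty(n - 1) if n > 1 else np.empty(0)
    dp = np.empty(n)
    den = diag[0]
    if abs(den) < tiny:
        return None
    dp[0] = rhs[0] / den
    if n > 1:
        cp[0] = sup[0] / den
    for i in range(1, n):
        den = diag[i] - sub[i - 1] * cp[i - 1]
        if abs(den) < tiny:
            return None
        dp[i] = (rhs[i] - sub[i - 1] * dp[i - 1]) / den
        if i < n - 1:
            cp[i] = sup[i] / den
    x = dp
    for i in range(n - 2, -1, -1):
        x[i] -= cp[i] * x[i + 1]
    return x


def solve_tridiagonal(system: TridiagonalSystem) -> np.ndarray:
    """Solve the system; Thomas elimination with a pivoting dense fallback.

    Corner-perturbed systems (non-empty ``corner_terms``) go straight to the
    dense path.  Raises :class:`SingularSystemError` on a singular matrix.
    """
    sub = np.asarray(system.sub, dtype=float)
    diag = np.asarray(system.diag, dtype=float)
    sup = np.asarray(system.sup, dtype=float)
    rhs = np.asarray(system.rhs, dtype=float)
    if not system.corner_terms:
        x = _thomas(sub, diag, sup, rhs)
        if x is not None:
            return x
    mat = system.dense()
    try:
        return np.linalg.solve(mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(str(exc)) from exc


def clamp(u: np.ndarray, K: np.ndarray | float) -> np.ndarray:
    """Regularize a stage field into [0, K] elementwise."""
    return np.minimum(np.maximum(u, 0.0), K)


def _check_capacity(*caps: np.ndarray) -> None:
    for K in caps:
        if np.any(np.asarray(K) <= 0):
            raise ValueError("carrying capacity must be positive on habitable cells")


def _growth_increment(
    u: np.ndarray, K: np.ndarray, params: StepParams, mode: BCMode
) -> np.ndarray:
    """Full explicit per-step increment k*A u + g*(1 - u/K)*u."""
    return params.k * bc_operator(u, mode) + params.growth * (1.0 - u / K) * u


def euler_predictor(
    u: np.ndarray,
    K: np.ndarray,
    params: StepParams,
    bc: BoundarySpec,
    K_next: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Explicit Euler estimate uE = u + k A u + g (1 - u/K) u, clamped.

    The operator action honours the boundary mode (zero ghosts for
    Dirichlet, mirror ghosts for Neumann).  The result is clamped into
    ``[0, K_next]`` (``K_next`` defaults to ``K``).
    """
    u = np.asarray(u, dtype=float)
    K = np.broadcast_to(np.asarray(K, dtype=float), u.shape)
    _check_capacity(K)
    uE = u + _growth_increment(u, K, params, bc.mode)
    return clamp(uE, K if K_next is None else np.asarray(K_next, dtype=float))


def trapezoid_step_dirichlet(
    u: np.ndarray,
    uE: np.ndarray,
    K_t: np.ndarray,
    K_th: np.ndarray,
    params: StepParams,
) -> np.ndarray:
    """Semi-implicit trapezoidal step on a zero-padded segment.

    The segment is bordered by one zero pixel at each end (whose capacity is
    irrelevant and unused); only the n interior cells are updated, so the
    zero ghosts drop out of both matrix and right-hand side.
    """
    u = np.asarray(u, dtype=float)
    K_t = np.broadcast_to(np.asarray(K_t, dtype=float), u.shape)
    K_th = np.broadcast_to(np.asarray(K_th, dtype=float), u.shape)
    _check_capacity(K_t, K_th)
    k, g = params.k, params.growth
    n = u.size
    rhs = u + 0.5 * k * diffusion_operator(u) + 0.5 * g * (1.0 - u / K_t) * u
    diag = 1.0 + k - 0.5 * g * (1.0 - uE / K_th)
    off = np.full(max(n - 1, 0), -0.5 * k)
    x = solve_tridiagonal(TridiagonalSystem(off, diag, off.copy(), rhs))
    return clamp(x, K_th)


def _heun_estimate(
    u: np.ndarray,
    uE: np.ndarray,
    K_t: np.ndarray,
    K_th: np.ndarray,
    params: StepParams,
) -> np.ndarray:
    """Explicit Heun (trapezoid predictor-corrector) estimate of u(t+h).

    Averages the explicit slope at ``u`` (capacities at t) and at the Euler
    stage ``uE`` (capacities at t+h); same operator and mirror-ghost BCs as
    the predictor.
    """
    f1 = _growth_increment(u, K_t, params, "neumann")
    f2 = _growth_increment(uE, K_th, params, "neumann")
    return clamp(u + 0.5 * (f1 + f2), K_th)


def neumann_full_system(
    u: np.ndarray,
    uE: np.ndarray,
    K_t: np.ndarray,
    K_th: np.ndarray,
    params: StepParams,
) -> TridiagonalSystem:
    """The uncorrected zero-flux system: bandwidth 5 via two corner 1/3 terms.

    Boundary rows are (1, -4/3, 1/3 | 0) and its mirror; interior rows are
    the semi-implicit trapezoid.  Kept solvable only through the dense path —
    used as the reference against the Heun-corrected tridiagonal variant.
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    if n <= 3:
        raise ValueError("zero-flux assembly requires n_seg > 3")
    k, g = params.k, params.growth
    sub = np.full(n - 1, -0.5 * k)
    sup = np.full(n - 1, -0.5 * k)
    diag = 1.0 + k - 0.5 * g * (1.0 - np.asarray(uE) / K_th)
    rhs = u + 0.5 * k * diffusion_operator(u) + 0.5 * g * (1.0 - u / K_t) * u
    diag = np.asarray(diag, dtype=float).copy()
    diag[0], diag[-1] = 1.0, 1.0
    sup[0], sub[-1] = -4.0 / 3.0, -4.0 / 3.0
    rhs = rhs.copy()
    rhs[0], rhs[-1] = 0.0, 0.0
    corners = [(0, 2, 1.0 / 3.0), (n - 1, n - 3, 1.0 / 3.0)]
    return TridiagonalSystem(sub, diag, sup, rhs, corner_terms=corners)


def assemble_neumann_step(
    u: np.ndarray,
    uE: np.ndarray,
    K_t: np.ndarray,
    K_th: np.ndarray,
    params: StepParams,
    refresh_ends: bool = False,
) -> np.ndarray:
    """Zero-flux semi-implicit step for a segment with n_seg > 3.

    The 1/3 corner entries of the boundary rows are replaced by explicit
    Heun estimates of u_3 and u_{n-2} moved to the right-hand side, leaving
    a strictly tridiagonal system.  ``refresh_ends`` recomputes the two end
    cells from the boundary rows after the solve (makes no discernible
    difference; off by default).
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    if n <= 3:
        raise ValueError("use short_segment_step for n_seg <= 3")
    K_t = np.broadcast_to(np.asarray(K_t, dtype=float), u.shape)
    K_th = np.broadcast_to(np.asarray(K_th, dtype=float), u.shape)
    _check_capacity(K_t, K_th)
    uE = np.asarray(uE, dtype=float)
    heun = _heun_estimate(u, uE, K_t, K_th, params)
    sys_ = neumann_full_system(u, uE, K_t, K_th, params)
    sys_.corner_terms = []
    sys_.rhs[0] = -heun[2] / 3.0
    sys_.rhs[-1] = -heun[n - 3] / 3.0
    x = solve_tridiagonal(sys_)
    if refresh_ends:
        x[0] = (4.0 * x[1] - x[2]) / 3.0
        x[-1] = (4.0 * x[-2] - x[-3]) / 3.0
    return clamp(x, K_th)


def short_segment_step(
    u: np.ndarray,
    K_t: np.ndarray,
    K_th: np.ndarray,
    params: StepParams,
) -> np.ndarray:
    """Zero-flux growth step for segments of length 1, 2 or 3.

    n = 1: the operator is dropped and only the semi-implicit logistic
    update remains.  n = 2: the 2x2 operator ((-2, 1), (1, -2)) acts on old
    data and equality of the two entries is enforced at every stage.
    n = 3: the bordered system forces u1 = u2 = u3 = RHS2 / (2 S1 + S2).
    All results are kept non-negative and capped by K(t+h).
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    if n > 3:
        raise ValueError("use assemble_neumann_step for n_seg > 3")
    K_t = np.broadcast_to(np.asarray(K_t, dtype=float), u.shape).astype(float)
    K_th = np.broadcast_to(np.asarray(K_th, dtype=float), u.shape).astype(float)
    _check_capacity(K_t, K_th)
    k, g = params.k, params.growth

    if n == 1:
        uE = clamp(u + g * (1.0 - u / K_t) * u, K_th)
        den = 1.0 - 0.5 * g * (1.0 - uE / K_th)
        rhs = (1.0 + 0.5 * g * (1.0 - u / K_t)) * u
        return clamp(rhs / den, K_th)

    if n == 2:
        a2 = np.array([[-2.0, 1.0], [1.0, -2.0]])
        uE = u + k * (a2 @ u) + g * (1.0 - u / K_t) * u
        uE = clamp(np.full(2, uE.mean()), K_th)
        lhs = np.eye(2) - 0.5 * k * a2 - 0.5 * g * np.diag(1.0 - uE / K_th)
        rhs = u + 0.5 * k * (a2 @ u) + 0.5 * g * (1.0 - u / K_t) * u
        x = np.linalg.solve(lhs, rhs)
        return clamp(np.full(2, x.mean()), K_th)

    # n == 3: bordered rows (1, -4/3, 1/3), (S1, S2, S1), (1/3, -4/3, 1)
    uE = euler_predictor(u, K_t, params, BoundarySpec("neumann"), K_next=K_th)
    s1 = -0.5 * k
    s2 = 1.0 + k - 0.5 * g * (1.0 - uE[1] / K_th[1])
    rhs2 = (
        u[1]
        + 0.5 * k * (u[0] - 2.0 * u[1] + u[2])
        + 0.5 * g * (1.0 - u[1] / K_t[1]) * u[1]
    )
    val = rhs2 / (2.0 * s1 + s2)
    return clamp(np.full(3, val), K_th)


def diffusion_trapezoid_dirichlet(u: np.ndarray, kw: float) -> np.ndarray:
    """Pure-diffusion trapezoid (1 - kw A) u' = (1 + kw A) u, zero padding.

    ``kw`` is the matrix weight: k/4 for a half step, k/2 when two adjacent
    half steps are fused into one full step.
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    rhs = u + kw * diffusion_operator(u)
    diag = np.full(n, 1.0 + 2.0 * kw)
    off = np.full(max(n - 1, 0), -kw)
    return solve_tridiagonal(TridiagonalSystem(off, diag, off.copy(), rhs))


def diffusion_trapezoid_neumann(u: np.ndarray, kw: float) -> np.ndarray:
    """Pure-diffusion trapezoid with zero-flux boundary rows.

    Boundary rows are (1, -4/3, 1/3 | 0) with the 1/3 entries replaced by
    explicit Heun estimates, mirroring the growth step's treatment.  Short
    segments: n = 1 is untouched (no diffusion), n = 2 collapses to the
    pair mean, n = 3 sets all cells to u2 + kw (u1 - 2 u2 + u3) since
    2 S1 + S2 = 1 there.
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    if n == 1:
        return u.copy()
    if n == 2:
        return np.full(2, u.mean())
    if n == 3:
        return np.full(3, u[1] + kw * (u[0] - 2.0 * u[1] + u[2]))
    # Heun estimate of the full-step increment 2 kw A u
    f1 = 2.0 * kw * bc_operator(u, "neumann")
    f2 = 2.0 * kw * bc_operator(u + f1, "neumann")
    heun = u + 0.5 * (f1 + f2)
    sub = np.full(n - 1, -kw)
    sup = np.full(n - 1, -kw)
    diag = np.full(n, 1.0 + 2.0 * kw)
    rhs = u + kw * diffusion_operator(u)
    diag[0], diag[-1] = 1.0, 1.0
    sup[0], sub[-1] = -4.0 / 3.0, -4.0 / 3.0
    rhs[0], rhs[-1] = -heun[2] / 3.0, -heun[n - 3] / 3.0
    return solve_tridiagonal(TridiagonalSystem(sub, diag, sup, rhs))
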