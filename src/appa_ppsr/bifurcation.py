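"""Pseudo-arclength continuation and limit-point (saddle-node) detection.

The engine is generic over one-parameter vector fields f(x, μ): a secant
predictor with a Newton corrector on the arclength-augmented system traces
the steady-state branch through folds, where the branch turns back in μ.
Folds are first bracketed by a sign reversal of Δμ between consecutive
arclength steps, then refined by Newton on the extended fold system

    f(x, μ) = 0,   J_x(x, μ)·v = 0,   ‖v‖² = 1,

whose solution pins the fold point and its null eigenvector simultaneously.

For the AppA/PpsR model the branch lives on the reduced (a, r, c) manifold
with μ = O; a pair of limit points brackets a bistable oxygen window, the
regime in which the aerobic→anaerobic transition shows hysteresis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import fsolve

from .core_model import (
    ModelParams,
    jacobian_mu_reduced,
    jacobian_reduced,
    rhs_reduced,
    state_from_reduced,
    steady_state,
)
from .errors import DomainError, SolverError

__all__ = [
    "Branch",
    "BranchPoint",
    "LimitPoint",
    "continue_branch",
    "continue_branch_generic",
    "detect_limit_points",
    "classify_bistability",
]

#: eigenvalue tolerance certifying a refined fold point
FOLD_EIG_TOL = 1e-6


@dataclass(frozen=True)
class BranchPoint:
    mu: float
    x: np.ndarray
    stable: bool


@dataclass(frozen=True)
class Branch:
    """Ordered continuation path; ``complete`` is False when step control
    gave up before reaching the end of the μ range."""

    points: list
    steps: list
    complete: bool = True
    # generic-problem callables kept so folds can be refined later
    f: object = None
    jac_x: object = None
    jac_mu: object = None

    def mus(self) -> np.ndarray:
        return np.array([p.mu for p in self.points])


@dataclass(frozen=True)
class LimitPoint:
    """A refined saddle-node: branch tangent perpendicular to the μ axis."""

    mu_fold: float
    x: np.ndarray
    direction: int  # +1: fold opens toward larger μ, −1: toward smaller μ
    eigenvalue: float  # real part of the critical eigenvalue


def _fd_jac_x(f, x, mu, eps=1e-7):
    n = len(x)
    J = np.empty((n, n))
    f0 = np.asarray(f(x, mu))
    for j in range(n):
        dx = np.zeros(n)
        dx[j] = eps * max(1.0, abs(x[j]))
        J[:, j] = (np.asarray(f(x + dx, mu)) - f0) / dx[j]
    return J


def _fd_jac_mu(f, x, mu, eps=1e-7):
    h = eps * max(1.0, abs(mu))
    return (np.asarray(f(x, mu + h)) - np.asarray(f(x, mu))) / h


def _corrector(f, jac_x, jac_mu, u_pred, tangent, tol=1e-10, max_iter=12):
    """Newton on [f(x, μ); tangent·(u − u_pred)] = 0."""
    u = u_pred.copy()
    n = len(u) - 1
    for it in range(max_iter):
        x, mu = u[:n], u[n]
        F = np.empty(n + 1)
        F[:n] = f(x, mu)
        F[n] = tangent @ (u - u_pred)
        if np.linalg.norm(F[:n]) < tol and abs(F[n]) < 1e-12:
            return u, it
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = jac_x(x, mu)
        A[:n, n] = jac_mu(x, mu)
        A[n, :] = tangent
        try:
            du = np.linalg.solve(A, -F)
        except np.linalg.LinAlgError:
            return None, it
        u = u + du
        if not np.all(np.isfinite(u)):
            return None, it
    x, mu = u[:n], u[n]
    if np.linalg.norm(f(x, mu)) < tol:
        return u, max_iter
    return None, max_iter


def _tangent_from_jacobian(jac_x, jac_mu, x, mu, orientation):
    """Null tangent of [J_x | J_mu]; oriented along ``orientation``."""
    Jx = jac_x(x, mu)
    Jmu = jac_mu(x, mu)
    try:
        tx = np.linalg.solve(Jx, -Jmu)
        t = np.append(tx, 1.0)
    except np.linalg.LinAlgError:
        # at (or very near) a fold J_x is singular; use the SVD null vector
        A = np.column_stack([Jx, Jmu])
        _, _, vt = np.linalg.svd(A)
        t = vt[-1]
    t = t / np.linalg.norm(t)
    if t @ orientation < 0:
        t = -t
    return t


def _stable(jac_x, x, mu, margin=0.0):
    eig = np.linalg.eigvals(jac_x(x, mu))
    return bool(np.all(eig.real < -margin))


def continue_branch_generic(f, x0, mu0, mu_end, jac_x=None, jac_mu=None,
                            h0=0.01, h_min=1e-4, h_max=0.5,
                            mu_floor=None, max_points=20000,
                            tol=1e-10) -> Branch:
    """Trace the solution branch of ``f(x, μ) = 0`` from (x0, μ0) toward μ_end.

    Secant predictor / Newton corrector with adaptive arclength step between
    ``h_min`` and ``h_max``; the path may traverse folds, so μ need not be
    monotone.  Stops at μ_end, below ``mu_floor``, or—flagging the branch
    incomplete—after corrector failure at the minimal step.
    """
    jac_x = jac_x or (lambda x, mu: _fd_jac_x(f, x, mu))
    jac_mu = jac_mu or (lambda x, mu: _fd_jac_mu(f, x, mu))
    x0 = np.asarray(x0, float)
    n = x0.size

    # converge the initial point
    u0, _ = _corrector(f, jac_x, jac_mu,
                       np.append(x0, mu0),
                       np.append(np.zeros(n), 1.0), tol=tol)
    if u0 is None:
        raise SolverError(f"no steady state at the start μ={mu0}")
    direction = 1.0 if mu_end >= mu0 else -1.0
    orientation = np.append(np.zeros(n), direction)
    tangent = _tangent_from_jacobian(jac_x, jac_mu, u0[:n], u0[n], orientation)

    points = [BranchPoint(mu=float(u0[n]), x=u0[:n].copy(),
                          stable=_stable(jac_x, u0[:n], u0[n]))]
    steps = []
    u, h = u0, h0
    complete = True
    mu_lo, mu_hi = sorted((mu0, mu_end))
    slack = max(h_max, 0.02 * (mu_hi - mu_lo))
    while len(points) < max_points:
        mu = u[n]
        if direction * (mu - mu_end) >= 0:
            break
        if mu_floor is not None and mu < mu_floor:
            break
        # after a fold the branch may leave the swept range on the far side
        if mu > mu_hi + slack or mu < mu_lo - slack:
            break
        u_pred = u + h * tangent
        u_new, iters = _corrector(f, jac_x, jac_mu, u_pred, tangent, tol=tol)
        # reject steps that leave the local branch: corrector landing far
        # from the predictor or bending sharply signals a branch jump
        jumped = False
        if u_new is not None:
            secant = u_new - u
            norm = np.linalg.norm(secant)
            if norm > 3.0 * h or (norm > 0 and secant @ tangent / norm < 0.5):
                jumped = True
        if u_new is None or jumped:
            if h <= h_min * (1 + 1e-12):
                complete = False
                break
            h = max(h / 2.0, h_min)
            continue
        tangent = secant / norm if norm > 0 else tangent
        u = u_new
        points.append(BranchPoint(mu=float(u[n]), x=u[:n].copy(),
                                  stable=_stable(jac_x, u[:n], u[n])))
        steps.append(h)
        h = min(h * 1.4, h_max) if iters <= 4 else h
    return Branch(points=points, steps=steps, complete=complete,
                  f=f, jac_x=jac_x, jac_mu=jac_mu)


def continue_branch(params: ModelParams, O_start: float, O_end: float,
                    h0: float = 0.01, h_min: float = 1e-4,
                    h_max: float = 0.5) -> Branch:
    """Continuation of the AppA/PpsR steady state in the oxygen parameter O.

    Starts from the steady state at ``O_start`` (continued from the
    anaerobic initial condition) on the reduced (a, r, c) manifold; the path
    stops below O = 0 rather than continuing to unphysical oxygen.
    """
    ss = steady_state(params, O_start, strict_stability=False)

    def f(x, mu):
        return rhs_reduced(params, mu, x)

    def jx(x, mu):
        return jacobian_reduced(params, mu, x)

    def jmu(x, mu):
        return jacobian_mu_reduced(params, mu, x)

    return continue_branch_generic(f, ss.state.reduced(), O_start, O_end,
                                   jac_x=jx, jac_mu=jmu, h0=h0, h_min=h_min,
                                   h_max=h_max, mu_floor=-1e-9)


def _refine_fold(branch: Branch, i: int) -> LimitPoint | None:
    """Newton on the extended fold system near branch point ``i``."""
    f, jac_x = branch.f, branch.jac_x
    pt = branch.points[i]
    n = pt.x.size
    J = jac_x(pt.x, pt.mu)
    eigvals, eigvecs = np.linalg.eig(J)
    k = np.argmin(np.abs(eigvals.real))
    v0 = np.real(eigvecs[:, k])
    v0 /= np.linalg.norm(v0)

    def ext(z):
        x, mu, v = z[:n], z[n], z[n + 1:]
        Jx = jac_x(x, mu)
        return np.concatenate([f(x, mu), Jx @ v, [v @ v - 1.0]])

    z0 = np.concatenate([pt.x, [pt.mu], v0])
    z, info, ier, _ = fsolve(ext, z0, full_output=True, xtol=1e-12)
    if ier != 1:
        return None
    x, mu, v = z[:n], float(z[n]), z[n + 1:]
    eig = np.linalg.eigvals(jac_x(x, mu))
    crit = eig.real[np.argmin(np.abs(eig.real))]
    if abs(crit) > FOLD_EIG_TOL:
        return None
    # fold opens toward larger mu when the branch attains a local mu-minimum
    prev_mu = branch.points[max(i - 1, 0)].mu
    next_mu = branch.points[min(i + 1, len(branch.points) - 1)].mu
    direction = 1 if prev_mu >= pt.mu <= next_mu else -1
    return LimitPoint(mu_fold=mu, x=x, direction=direction,
                      eigenvalue=float(crit))


def detect_limit_points(branch: Branch) -> list[LimitPoint]:
    """Locate folds on a branch: Δμ sign reversals refined by the extended
    fold system.  Returns an empty list for monotone branches."""
    if len(branch.points) < 3:
        raise DomainError("branch needs at least 3 points")
    mus = branch.mus()
    dmu = np.diff(mus)
    folds = []
    for i in range(1, len(dmu)):
        if dmu[i - 1] * dmu[i] < 0 or (dmu[i - 1] != 0 and dmu[i] == 0):
            lp = _refine_fold(branch, i)
            if lp is not None and not any(
                    abs(lp.mu_fold - q.mu_fold) < 1e-6 and
                    np.linalg.norm(lp.x - q.x) < 1e-5 for q in folds):
                folds.append(lp)
    folds.sort(key=lambda q: q.mu_fold)
    return folds


def classify_bistability(params: ModelParams, O_range=(0.0, 40.0),
                         h0: float = 0.01):
    """Classify the oxygen response as monostable or bistable.

    Continues the steady-state branch across ``O_range``, detects limit
    points, and—when at least two are found—verifies that some O inside the
    outermost fold pair carries two distinct stable states.

    Returns
    -------
    dict with keys ``bistable`` (bool), ``limit_points`` (list), and when
    bistable ``interval`` = (O_lo, O_hi).
    """
    O_lo, O_hi = O_range
    branch = continue_branch(params, O_lo, O_hi, h0=h0)
    folds = detect_limit_points(branch) if len(branch.points) >= 3 else []
    if len(folds) < 2:
        return {"bistable": False, "limit_points": folds, "branch": branch}
    lo = min(f.mu_fold for f in folds)
    hi = max(f.mu_fold for f in folds)
    O_mid = 0.5 * (lo + hi)
    # the S-shaped branch passes O_mid several times; collect stable crossings
    stable_states = []
    pts = branch.points
    for a, b in zip(pts[:-1], pts[1:]):
        if (a.mu - O_mid) * (b.mu - O_mid) <= 0 and (a.stable or b.stable):
            seed = a if abs(a.mu - O_mid) < abs(b.mu - O_mid) else b
            try:
                ss = steady_state(params, O_mid,
                                  init=state_from_reduced(seed.x, params),
                                  strict_stability=False)
            except SolverError:
                continue
            if ss.stable and not any(
                    np.allclose(ss.state.reduced(), s, atol=1e-6)
                    for s in stable_states):
                stable_states.append(ss.state.reduced())
    bistable = len(stable_states) >= 2
    out = {"bistable": bistable, "limit_points": folds, "branch": branch}
    if bistable:
        out["interval"] = (lo, hi)
    return out
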