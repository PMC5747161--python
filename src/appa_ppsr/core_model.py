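"""Dimensionless mass-action model of the AppA/PpsR redox switch.

The model tracks five species of the light- and redox-dependent interaction
between the antirepressor AppA and the repressor PpsR:

* ``a`` — free reduced AppA, in units of total PpsR,
* ``b`` — free oxidized AppA, same units,
* ``p`` — free oxidized PpsR, as a fraction of total PpsR,
* ``r`` — free reduced PpsR, same fraction scale,
* ``c`` — the AppA–PpsR₂ complex, in units of AppA copies (each complex
  sequesters one AppA and two PpsR units).

Reactions (time in units of the AppA-reduction timescale):

* AppA redox cycling: ``b → a`` at unit rate, ``a → b`` at rate ``O`` (the
  dimensionless oxygen concentration, oxygen in units of K_O);
* PpsR reoxidation: ``r → p`` at rate ``alpha·O``;
* electron transfer AppA_red + PpsR_ox → AppA_ox + PpsR_red at rate ``beta``,
  with reverse rate ``beta/K_eq`` (``K_eq = ∞`` makes it irreversible);
* complex formation ``a + 2r → c`` at rate ``delta`` (bimolecular in reduced
  PpsR, encoding the 2:1 PpsR:AppA stoichiometry) and blue-light-driven
  dissociation ``c → a + 2r`` at rate ``delta·I``.

Two conservation laws hold exactly: ``a + b + c = gamma`` (total AppA) and
``p + r + 2c = 1`` (total PpsR).  All computations on steady states and
stability are done on the reduced 3-variable system ``(a, r, c)`` obtained by
eliminating ``b = gamma − a − c`` and ``p = 1 − r − 2c``.

Because ``delta`` multiplies both complex formation and light-driven
dissociation, the steady-state condition for the complex is
``c = a·r²/I`` — independent of ``delta`` — which reproduces the documented
delta-independence of the steady-state behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, SolverError, StabilityError

__all__ = [
    "ModelParams",
    "ModelState",
    "SteadyState",
    "DEFAULT_FIT_PARAMS",
    "rhs",
    "rhs_reduced",
    "jacobian",
    "jacobian_reduced",
    "simulate",
    "steady_state",
]

#: eigenvalue real parts closer to zero than this are treated as marginal
STABILITY_MARGIN = 1e-9

#: Newton convergence target for the steady-state residual (full rhs norm)
STEADY_STATE_TOL = 1e-10


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters of the AppA/PpsR system.

    Parameters
    ----------
    I : float
        Blue-light irradiance, dimensionless, >= 0.
    alpha : float
        Ratio of the PpsR reoxidation rate to the AppA oxidation rate.
    beta : float
        Ratio of the PpsR-reduction (electron transfer) timescale to the
        AppA-reduction timescale.
    gamma : float
        Copy-number ratio of total AppA to total PpsR.
    delta : float
        Timescale of the complex formation/dissociation kinetics; the steady
        state does not depend on it.
    K_eq : float
        Equilibrium constant of the AppA→PpsR electron transfer;
        ``math.inf`` means the transfer is irreversible.
    """

    I: float
    alpha: float
    beta: float
    gamma: float
    delta: float = 1.0
    K_eq: float = math.inf

    def __post_init__(self) -> None:
        if not (self.I >= 0 and math.isfinite(self.I)):
            raise DomainError(f"I must be finite and >= 0, got {self.I}")
        for name in ("alpha", "beta", "gamma", "delta"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise DomainError(f"{name} must be finite and > 0, got {v}")
        if not self.K_eq > 0:
            raise DomainError(f"K_eq must be > 0 (inf allowed), got {self.K_eq}")

    @property
    def irreversible(self) -> bool:
        return math.isinf(self.K_eq)


#: parameter combination that best recapitulates the pucB expression data
DEFAULT_FIT_PARAMS = ModelParams(I=0.001, alpha=6.0, beta=500.0, gamma=2.1,
                                 delta=1.0, K_eq=math.inf)


@dataclass(frozen=True)
class ModelState:
    """State of the five-species system; see module docstring for units."""

    a: float
    b: float
    p: float
    r: float
    c: float

    CONSERVATION_TOL = 1e-9

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.p, self.r, self.c], float)

    @staticmethod
    def from_array(x: np.ndarray) -> "ModelState":
        return ModelState(*(float(v) for v in x))

    def validate(self, gamma: float | None = None, tol: float = 1e-9) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise DomainError(f"non-finite state component in {self}")
        if np.any(arr < 0):
            raise DomainError(f"negative state component in {self}")
        if gamma is not None:
            if abs(self.a + self.b + self.c - gamma) > tol:
                raise DomainError(
                    f"AppA conservation violated: a+b+c = "
                    f"{self.a + self.b + self.c}, expected {gamma}")
            if abs(self.p + self.r + 2 * self.c - 1.0) > tol:
                raise DomainError(
                    f"PpsR conservation violated: p+r+2c = "
                    f"{self.p + self.r + 2 * self.c}, expected 1")

    def reduced(self) -> np.ndarray:
        """Coordinates (a, r, c) on the conservation manifold."""
        return np.array([self.a, self.r, self.c], float)


def state_from_reduced(x: np.ndarray, params: ModelParams) -> ModelState:
    """Lift reduced coordinates (a, r, c) back to the full state using the
    conservation laws.  Roundoff-level negatives are clamped to zero."""
    a, r, c = (float(v) for v in x)
    b = params.gamma - a - c
    p = 1.0 - r - 2.0 * c
    eps = 1e-12
    vals = [v if v > 0 else (0.0 if v > -eps else v)
            for v in (a, b, p, r, c)]
    return ModelState(*vals)


def anaerobic_start(params: ModelParams) -> ModelState:
    """Admissible initial state: all AppA reduced, all PpsR reduced, no complex."""
    return ModelState(a=params.gamma, b=0.0, p=0.0, r=1.0, c=0.0)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _fluxes(params: ModelParams, O: float, a: float, b: float, p: float,
            r: float, c: float) -> tuple[float, float]:
    """Electron-transfer flux E and net complex-formation flux F."""
    rev = 0.0 if params.irreversible else b * r / params.K_eq
    E = a * p - rev
    F = a * r * r - params.I * c
    return E, F


def rhs(params: ModelParams, O: float, state: ModelState) -> np.ndarray:
    """Time derivative (da, db, dp, dr, dc)/dτ of the full five-species system.

    Raises
    ------
    DomainError
        If ``O`` is negative or any state component is negative or non-finite.
    """
    if not (math.isfinite(O) and O >= 0):
        raise DomainError(f"O must be finite and >= 0, got {O}")
    state.validate()
    a, b, p, r, c = state.a, state.b, state.p, state.r, state.c
    E, F = _fluxes(params, O, a, b, p, r, c)
    beta, alpha, delta = params.beta, params.alpha, params.delta
    da = b - O * a - beta * E - delta * F
    db = -b + O * a + beta * E
    dp = alpha * O * r - beta * E
    dr = -alpha * O * r + beta * E - 2.0 * delta * F
    dc = delta * F
    return np.array([da, db, dp, dr, dc])


def rhs_reduced(params: ModelParams, O: float, x: np.ndarray) -> np.ndarray:
    """Time derivative of the reduced coordinates (a, r, c).

    Unlike :func:`rhs` this imposes no non-negativity guard: Newton iterates
    may leave the physical octant transiently.
    """
    a, r, c = x
    b = params.gamma - a - c
    p = 1.0 - r - 2.0 * c
    E, F = _fluxes(params, O, a, b, p, r, c)
    beta, alpha, delta = params.beta, params.alpha, params.delta
    return np.array([
        b - O * a - beta * E - delta * F,
        -alpha * O * r + beta * E - 2.0 * delta * F,
        delta * F,
    ])


def jacobian_reduced(params: ModelParams, O: float, x: np.ndarray) -> np.ndarray:
    """Analytic 3×3 Jacobian of :func:`rhs_reduced` at (a, r, c)."""
    a, r, c = x
    b = params.gamma - a - c
    p = 1.0 - r - 2.0 * c
    beta, alpha, delta, I = params.beta, params.alpha, params.delta, params.I
    kinv = 0.0 if params.irreversible else 1.0 / params.K_eq
    # E = a*p - b*r*kinv with b, p eliminated
    dE_da = p + r * kinv
    dE_dr = -a - b * kinv
    dE_dc = -2.0 * a + r * kinv
    dF_da = r * r
    dF_dr = 2.0 * a * r
    dF_dc = -I
    return np.array([
        [-1.0 - O - beta * dE_da - delta * dF_da,
         -beta * dE_dr - delta * dF_dr,
         -1.0 - beta * dE_dc - delta * dF_dc],
        [beta * dE_da - 2.0 * delta * dF_da,
         -alpha * O + beta * dE_dr - 2.0 * delta * dF_dr,
         beta * dE_dc - 2.0 * delta * dF_dc],
        [delta * dF_da, delta * dF_dr, delta * dF_dc],
    ])


def jacobian(params: ModelParams, O: float, state: ModelState) -> np.ndarray:
    """Reduced 3×3 Jacobian on the conservation manifold at a full state."""
    return jacobian_reduced(params, O, state.reduced())


def jacobian_mu_reduced(params: ModelParams, O: float, x: np.ndarray) -> np.ndarray:
    """Derivative of the reduced RHS with respect to O (used in continuation)."""
    a, r, c = x
    return np.array([-a, -params.alpha * r, 0.0])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(params: ModelParams, O: float, state0: ModelState,
             t_end: float, reltol: float = 1e-9, abstol: float = 1e-11,
             n_out: int = 200):
    """Integrate the full five-species system from ``state0`` to ``t_end``.

    Returns
    -------
    times : ndarray of shape (m,)
    states : list of ModelState
        Every state satisfies the conservation laws to within 1e-7.
    """
    state0.validate(gamma=params.gamma, tol=1e-7)
    if t_end == 0:
        return np.array([0.0]), [state0]
    if not (math.isfinite(O) and O >= 0):
        raise DomainError(f"O must be finite and >= 0, got {O}")

    def f(t, y):
        a, b, p, r, c = y
        E, F = _fluxes(params, O, a, b, p, r, c)
        beta, alpha, delta = params.beta, params.alpha, params.delta
        return [b - O * a - beta * E - delta * F,
                -b + O * a + beta * E,
                alpha * O * r - beta * E,
                -alpha * O * r + beta * E - 2.0 * delta * F,
                delta * F]

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(f, (0.0, t_end), state0.as_array(), method="LSODA",
                    rtol=reltol, atol=abstol, t_eval=t_eval)
    if not sol.success:
        raise SolverError(f"integration failed at O={O}: {sol.message}")
    states = []
    for col in sol.y.T:
        s = ModelState.from_array(np.clip(col, 0.0, None))
        drift_appa = abs(col[0] + col[1] + col[4] - params.gamma)
        drift_ppsr = abs(col[2] + col[3] + 2 * col[4] - 1.0)
        if max(drift_appa, drift_ppsr) > 1e-7:
            raise SolverError(
                f"conservation drift {max(drift_appa, drift_ppsr):.2e} "
                f"exceeds 1e-7 during integration at O={O}")
        states.append(s)
    return sol.t, states


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyState:
    """A classified steady state of the system at oxygen level ``O``."""

    state: ModelState
    O: float
    residual_norm: float
    stable: bool
    eigenvalues: tuple = field(default_factory=tuple)


def _newton_reduced(params: ModelParams, O: float, x0: np.ndarray,
                    tol: float, max_iter: int = 60) -> np.ndarray | None:
    """Damped Newton on the reduced system; returns None on failure."""
    x = np.asarray(x0, float).copy()
    for _ in range(max_iter):
        f = rhs_reduced(params, O, x)
        fn = np.linalg.norm(f)
        if fn < tol:
            return x
        try:
            step = np.linalg.solve(jacobian_reduced(params, O, x), -f)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        while lam > 1e-8:
            x_new = x + lam * step
            f_new = rhs_reduced(params, O, x_new)
            if np.all(np.isfinite(f_new)) and np.linalg.norm(f_new) < fn:
                x = x_new
                break
            lam *= 0.5
        else:
            return None
    f = rhs_reduced(params, O, x)
    return x if np.linalg.norm(f) < tol else None


def _steady_algebraic(params: ModelParams, O: float, x0: np.ndarray,
                      tol: float, max_iter: int = 80) -> np.ndarray | None:
    """Newton on the steady-state algebra in (a, r) after eliminating
    c = a·r²/I and p = αOr/(βa).

    This form stays well-scaled at large β, where the raw residual
    β·(a·p − …) amplifies roundoff and defeats Newton on the ODE right-hand
    side.  Requires I > 0 and returns None on failure.
    """
    if params.I <= 0:
        return None
    alpha, beta, gamma, I = params.alpha, params.beta, params.gamma, params.I
    a = min(max(float(x0[0]), 1e-10), gamma)
    r = min(max(float(x0[1]), 1e-10), 1.0)

    def g(a, r):
        return np.array([
            gamma - a * (1.0 + O + r * r / I) - alpha * O * r,
            alpha * O * r / (beta * a) + r + 2.0 * a * r * r / I - 1.0,
        ])

    def Jg(a, r):
        return np.array([
            [-(1.0 + O + r * r / I), -2.0 * a * r / I - alpha * O],
            [-alpha * O * r / (beta * a * a) + 2.0 * r * r / I,
             alpha * O / (beta * a) + 1.0 + 4.0 * a * r / I],
        ])

    # the ODE residual re-amplifies g2 by ~β·a, so converge g to near
    # machine precision before accepting
    g_target = max(1e-15, 0.01 * tol / (1.0 + beta))
    for _ in range(max_iter):
        f = g(a, r)
        if np.linalg.norm(f) < g_target:
            break
        try:
            step = np.linalg.solve(Jg(a, r), -f)
        except np.linalg.LinAlgError:
            return None
        lam, fn = 1.0, np.linalg.norm(f)
        while lam > 1e-10:
            a_new, r_new = a + lam * step[0], r + lam * step[1]
            if a_new > 0 and r_new > 0:
                f_new = g(a_new, r_new)
                if np.all(np.isfinite(f_new)) and np.linalg.norm(f_new) < fn:
                    a, r = a_new, r_new
                    break
            lam *= 0.5
        else:
            return None
    else:
        return None
    x = np.array([a, r, a * r * r / I])
    return x if np.linalg.norm(rhs_reduced(params, O, x)) < tol else None


def _classify(params: ModelParams, O: float, x: np.ndarray,
              margin: float = STABILITY_MARGIN,
              strict: bool = True) -> tuple[bool, tuple]:
    eig = np.linalg.eigvals(jacobian_reduced(params, O, x))
    reals = eig.real
    if strict and np.any(np.abs(reals) <= margin):
        raise StabilityError(
            f"marginal steady state at O={O}: eigenvalue real part "
            f"{reals[np.argmin(np.abs(reals))]:.3e} within margin {margin}")
    return bool(np.all(reals < 0)), tuple(complex(e) for e in eig)


def _relax_to_root(params, O, start, tol):
    """Integrate the reduced system toward the attractor, retrying Newton
    along the way.  Moderate integrator tolerances suffice: the role of the
    relaxation is only to enter the Newton basin; Newton does the polishing.
    """
    x = np.asarray(start.reduced(), float)
    t_done = 0.0
    for t_stage in (1e2, 1e3, 1e4, 1e5):
        sol = solve_ivp(lambda t, y: rhs_reduced(params, O, y),
                        (t_done, t_stage), x, method="LSODA",
                        jac=lambda t, y: jacobian_reduced(params, O, y),
                        rtol=1e-7, atol=1e-10)
        if not sol.success:
            return None
        x, t_done = sol.y[:, -1], t_stage
        polished = _newton_reduced(params, O, x, tol)
        if polished is None:
            polished = _steady_algebraic(params, O, x, tol)
        if polished is not None and np.all(polished > -1e-12):
            return polished
        if np.linalg.norm(rhs_reduced(params, O, x)) < tol:
            return x
    return None


def steady_state(params: ModelParams, O: float,
                 init: ModelState | None = None,
                 tol: float = STEADY_STATE_TOL,
                 strict_stability: bool = True,
                 ensure_stable: bool = False) -> SteadyState:
    """Locate and classify a steady state of the system at oxygen level ``O``.

    Strategy: damped Newton on the reduced (a, r, c) system with the analytic
    Jacobian, initialized from ``init`` or from the anaerobic state; on
    failure, or on convergence to a non-physical point, fall back to
    integration toward the attractor and retry Newton from there.  With
    ``ensure_stable`` a root classified unstable (e.g. the saddle near a
    fold) is likewise replaced by the attractor reached from ``init``.

    Raises
    ------
    SolverError
        If neither Newton nor the integration fallback converges.
    StabilityError
        If an eigenvalue real part is within the classification margin and
        ``strict_stability`` is set.
    """
    if not (math.isfinite(O) and O >= 0):
        raise DomainError(f"O must be finite and >= 0, got {O}")
    start = init if init is not None else anaerobic_start(params)

    x = _newton_reduced(params, O, start.reduced(), tol)
    if x is None:
        x = _steady_algebraic(params, O, start.reduced(), tol)
    if x is None or np.any(x < -1e-12):
        x = _relax_to_root(params, O, start, tol)
        if x is None:
            raise SolverError(f"steady state not found at O={O}")
    if np.any(x < -1e-12):
        raise SolverError(f"steady state at O={O} violates non-negativity: {x}")
    x = np.clip(x, 0.0, None)
    stable, eig = _classify(params, O, x, strict=strict_stability)
    if ensure_stable and not stable:
        x = _relax_to_root(params, O, start, tol)
        if x is None or np.any(x < -1e-12):
            raise SolverError(f"no stable steady state reached at O={O}")
        x = np.clip(x, 0.0, None)
        stable, eig = _classify(params, O, x, strict=strict_stability)
        if not stable:
            raise SolverError(f"attractor at O={O} classified unstable")
    res = float(np.linalg.norm(rhs_reduced(params, O, x)))
    return SteadyState(state=state_from_reduced(x, params), O=O,
                       residual_norm=res, stable=stable, eigenvalues=eig)
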