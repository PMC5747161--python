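"""Promoter occupancy: from free PpsR pools to pucB mRNA level.

PpsR represses photosynthesis genes by binding tandem sites upstream of the
*puc* operon.  Both redox forms bind in vitro (EC₅₀ 31 nM oxidized, 69 nM
reduced), and five binding scenarios are considered for what happens in vivo:

* case i   — oxidized PpsR alone represses;
* case ii  — reduced PpsR alone represses;
* case iii — reduced PpsR alone activates;
* case iv  — both forms repress (independent sites, multiplicative);
* case v   — oxidized represses while reduced activates (multiplicative).

Each protein–DNA interaction is a Hill function; the output is the pucB mRNA
level in the arbitrary units of the normalized microarray data (maximum 5.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core_model import ModelState
from .errors import DomainError, FitError

__all__ = [
    "BINDING_CASES",
    "PromoterParams",
    "HillFitResult",
    "free_concentrations",
    "mrna_level",
    "hill_fit",
    "read_isotherm_tsv",
]

BINDING_CASES = ("i", "ii", "iii", "iv", "v")


@dataclass(frozen=True)
class PromoterParams:
    """Hill-function constants of the PpsR–puc promoter interaction.

    ``K_ox``/``K_red`` are the EC₅₀ values (nM) for the oxidized and reduced
    form, ``n_ox``/``n_red`` the Hill coefficients, ``M_max`` the maximal
    expression level (a.u.) reached with no repressor bound, and
    ``PpsR_total`` the total cellular PpsR concentration in nM used to convert
    the model's dimensionless fractions into concentrations.
    """

    M_max: float = 5.1
    K_ox: float = 31.0
    n_ox: float = 4.1
    K_red: float = 69.0
    n_red: float = 3.4
    PpsR_total: float = 100.0
    case: str = "i"

    def __post_init__(self) -> None:
        for name in ("M_max", "K_ox", "n_ox", "K_red", "n_red", "PpsR_total"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if self.case not in BINDING_CASES:
            raise DomainError(
                f"unknown binding case {self.case!r}; expected one of "
                f"{BINDING_CASES}")


def free_concentrations(state: ModelState, PpsR_total: float):
    """Convert a model state's PpsR fractions to nM pools.

    Returns
    -------
    tuple ``(ox_free, red_free, complexed, appa_red, appa_ox)`` in nM.
    The three PpsR pools sum to ``PpsR_total`` (the complex carries two PpsR
    units per copy).
    """
    if PpsR_total <= 0:
        raise DomainError("PpsR_total must be > 0")
    state.validate()
    ox_free = state.p * PpsR_total
    red_free = state.r * PpsR_total
    complexed = 2.0 * state.c * PpsR_total
    appa_red = state.a * PpsR_total
    appa_ox = state.b * PpsR_total
    return ox_free, red_free, complexed, appa_red, appa_ox


def _repression(conc, K, n):
    """Fraction of promoters free of repressor: K^n / (K^n + x^n)."""
    x = np.asarray(conc, float)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + (x / K) ** n)  # overflow -> 0, the correct limit


def _activation(conc, K, n):
    """Hill activation: x^n / (K^n + x^n)."""
    x = np.asarray(conc, float)
    with np.errstate(divide="ignore", over="ignore"):
        return np.where(x > 0, 1.0 / (1.0 + (K / x) ** n), 0.0)


def mrna_level(pp: PromoterParams, ox_free: float, red_free: float) -> float:
    """pucB mRNA level (a.u.) for the given free PpsR pools (nM).

    The five binding cases combine repression/activation terms of the
    oxidized and reduced forms; mixed cases multiply the two Hill terms
    (independent-site approximation).  Output lies in ``[0, M_max]``.
    """
    if ox_free < 0 or red_free < 0:
        raise DomainError("concentrations must be >= 0")
    rep_ox = _repression(ox_free, pp.K_ox, pp.n_ox)
    rep_red = _repression(red_free, pp.K_red, pp.n_red)
    act_red = _activation(red_free, pp.K_red, pp.n_red)
    if pp.case == "i":
        level = rep_ox
    elif pp.case == "ii":
        level = rep_red
    elif pp.case == "iii":
        level = act_red
    elif pp.case == "iv":
        level = rep_ox * rep_red
    elif pp.case == "v":
        level = rep_ox * act_red
    else:  # pragma: no cover - guarded in PromoterParams
        raise DomainError(f"unknown binding case {pp.case!r}")
    return float(pp.M_max * level)


@dataclass(frozen=True)
class HillFitResult:
    """Least-squares estimate of a general Hill curve A·x^n/(K_d^n + x^n)."""

    A: float
    K_d: float
    n: float
    sse: float


def _hill(x, A, K_d, n):
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, A / (1.0 + (K_d / np.maximum(x, 1e-300)) ** n), 0.0)


def hill_fit(x, y, init=None, n_bounds=(0.5, 8.0), n_starts=5) -> HillFitResult:
    """Fit ``A·x^n/(K_d^n + x^n)`` to a binding isotherm by least squares.

    To avoid the local minima of the (K_d, n) landscape the optimizer is
    restarted from a grid of log-spaced K_d values spanning the data range
    and Hill coefficients across ``n_bounds``; the best residual wins.

    Parameters
    ----------
    init : optional (A, K_d, n)
        If given, used as an additional start.

    Raises
    ------
    FitError
        On degenerate data (all responses equal) or optimizer failure.
    DomainError
        On fewer than 4 points or negative concentrations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise DomainError(f"need at least 4 points, got {x.size}")
    if np.any(x < 0):
        raise DomainError("concentrations must be >= 0")
    if not np.any(x > 0):
        raise DomainError("need at least one positive concentration")
    if np.ptp(y) == 0:
        raise FitError("degenerate isotherm: all responses equal")

    def resid(theta):
        A, K_d, n = theta
        return _hill(x, A, K_d, n) - y

    xpos = x[x > 0]
    k_grid = np.geomspace(xpos.min(), xpos.max(), n_starts)
    n_grid = np.linspace(n_bounds[0], n_bounds[1], n_starts)
    A0 = max(float(y.max()), 1e-12)
    starts = [(A0, k, n) for k in k_grid for n in n_grid]
    if init is not None:
        starts.insert(0, tuple(init))

    lower = [1e-12, 1e-12, n_bounds[0]]
    upper = [np.inf, np.inf, n_bounds[1]]
    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lower, upper)
        try:
            sol = least_squares(resid, theta0, bounds=(lower, upper),
                                method="trf", xtol=1e-14, ftol=1e-14,
                                gtol=1e-14)
        except ValueError:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        raise FitError("Hill fit failed from every start")
    sse, (A, K_d, n) = best
    return HillFitResult(A=float(A), K_d=float(K_d), n=float(n), sse=sse)


def read_isotherm_tsv(path):
    """Read a binding isotherm from two-column TSV
    (concentration_nM, fraction_bound); returns (x, y) arrays."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DomainError("isotherm TSV needs two columns "
                          "(concentration_nM, fraction_bound)")
    x = df.iloc[:, 0].to_numpy(float)
    y = df.iloc[:, 1].to_numpy(float)
    return x, y
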