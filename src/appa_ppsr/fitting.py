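"""Oxygen calibration, model→data prediction and nSSE parameter estimation.

The microarray conditions are given as % O₂ of the sparging gas; the model's
oxygen variable O is dimensionless (dissolved oxygen over K_O, the ratio of
the AppA reduction and oxidation rate constants).  The calibration is the
linear map fixed by equating the maximal experimental oxygen (30%) with the
O value at which the system is fully aerobic (free oxidized PpsR above 50%
of total), and it implies K_O ≈ 6.7–12.7 μM for a 200–380 μM dissolved-O₂
aerobic range.

The objective for parameter estimation is the variance-normalized sum of
squared errors over oxygen levels j with replicates y_i and prediction Y_j::

    nSSE = Σ_j  Σ_i (y_i − Y_j)² / σ_j²

with σ_j the n−1 sample SD of the level.  Estimation is by exhaustive grid
search, mirroring one-at-a-time parameter exploration and avoiding
local-minimum ambiguity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_model import ModelParams, anaerobic_start, steady_state
from .errors import DomainError, SolverError, VarianceError
from .normalize import CombinedPoint
from .promoter import PromoterParams, free_concentrations, mrna_level

__all__ = [
    "OxygenMap",
    "FitConfig",
    "FitResult",
    "percent_to_dimensionless",
    "k_o_range",
    "predict_curve",
    "normalized_sse",
    "scan",
    "aerobic_O_threshold",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OxygenMap:
    """Linear calibration between % O₂, dimensionless O and dissolved μM."""

    O_max: float = 30.0
    pct_max: float = 30.0
    aerobic_dissolved_range: tuple = (200.0, 380.0)

    def __post_init__(self) -> None:
        if self.O_max <= 0 or self.pct_max <= 0:
            raise DomainError("O_max and pct_max must be > 0")
        low, high = self.aerobic_dissolved_range
        if not 0 < low <= high:
            raise DomainError("aerobic range must satisfy 0 < low <= high")


def percent_to_dimensionless(pct: float, oxygen_map: OxygenMap = OxygenMap()) -> float:
    """Map % O₂ of the sparging gas to the model's dimensionless O."""
    if pct < 0:
        raise DomainError(f"oxygen percent must be >= 0, got {pct}")
    return pct * oxygen_map.O_max / oxygen_map.pct_max


def k_o_range(oxygen_map: OxygenMap = OxygenMap()) -> tuple[float, float]:
    """Implied K_O range in μM, rounded to one decimal place.

    K_O converts dissolved oxygen to the dimensionless O, so the aerobic
    dissolved range divided by O_max bounds it.
    """
    low, high = oxygen_map.aerobic_dissolved_range
    return (round(low / oxygen_map.O_max, 1), round(high / oxygen_map.O_max, 1))


def predict_curve(params: ModelParams, PpsR_total: float,
                  pp: PromoterParams, conditions,
                  oxygen_map: OxygenMap = OxygenMap()) -> list[float]:
    """Predicted pucB expression (a.u.) at each oxygen-percent condition.

    For each condition the percent is mapped to O, the steady state is
    located on the branch continued from the anaerobic (O = 0) solution,
    the free PpsR pools are converted to nM, and the promoter model gives
    the expression level.  Solver failures propagate with the offending O.
    """
    pp = replace(pp, PpsR_total=PpsR_total)
    pcts = list(conditions)
    order = np.argsort(pcts)
    out = [0.0] * len(pcts)
    prev = anaerobic_start(params)
    # continue the anaerobic branch upward through the sorted oxygen levels
    last_O = 0.0
    for idx in order:
        O = percent_to_dimensionless(pcts[idx], oxygen_map)
        prev = _walk_branch(params, last_O, O, prev)
        ss = steady_state(params, O, init=prev, strict_stability=False,
                          ensure_stable=True)
        prev, last_O = ss.state, O
        ox_free, red_free, *_ = free_concentrations(ss.state, PpsR_total)
        out[idx] = mrna_level(pp, ox_free, red_free)
    return out


def _walk_branch(params, O_from, O_to, state, max_step=1.0):
    """Natural-parameter continuation: step O gradually so the steady-state
    solver stays on the branch it started on."""
    span = O_to - O_from
    if span <= max_step:
        return state
    n = int(math.ceil(span / max_step))
    for k in range(1, n):
        O = O_from + span * k / n
        state = steady_state(params, O, init=state, strict_stability=False,
                             ensure_stable=True).state
    return state


@dataclass(frozen=True)
class FitConfig:
    """Grid specification for the nSSE scan.

    ``grids`` maps parameter names among (I, alpha, beta, gamma, PpsR_total)
    to lists of candidate values; delta and K_eq stay fixed (delta is
    irrelevant at steady state; the electron transfer is irreversible).
    """

    case: str = "i"
    grids: dict = field(default_factory=dict)
    oxygen_map: OxygenMap = OxygenMap()
    delta: float = 1.0
    K_eq: float = math.inf

    SCANNABLE = ("I", "alpha", "beta", "gamma", "PpsR_total")

    def __post_init__(self) -> None:
        if not self.grids:
            raise DomainError("grids must be non-empty")
        for name, values in self.grids.items():
            if name not in self.SCANNABLE:
                raise DomainError(f"cannot scan parameter {name!r}")
            if len(values) == 0 or any(v <= 0 for v in values):
                raise DomainError(f"grid for {name!r} must be positive and "
                                  "non-empty")


@dataclass(frozen=True)
class FitResult:
    """One evaluated grid point: parameters and its nSSE decomposition."""

    params: ModelParams
    PpsR_total: float
    nsse: float
    per_level_nsse: dict = field(default_factory=dict)


def normalized_sse(data, predictions) -> tuple[float, dict]:
    """Variance-normalized SSE of predictions against per-level replicates.

    Parameters
    ----------
    data : list of CombinedPoint
        Must retain raw replicate values; every level needs n ≥ 2 and
        a positive SD.
    predictions : sequence of float
        Model value Y_j per level, aligned with ``data``.

    Returns
    -------
    (total, per_level) where per_level maps the level's oxygen percent to
    its contribution Σ_i (y_i − Y_j)² / σ_j².
    """
    if len(data) != len(predictions):
        raise DomainError("data and predictions must align")
    per_level = {}
    for point, Y in zip(data, predictions):
        if point.n_samples < 2 or len(point.replicates) < 2:
            raise VarianceError(
                f"level {point.oxygen_percent}%: needs >= 2 replicates")
        sigma = point.sd_rel_expr
        if sigma <= 0:
            raise VarianceError(
                f"level {point.oxygen_percent}%: zero variance")
        resid = np.asarray(point.replicates, float) - Y
        per_level[point.oxygen_percent] = float(np.sum(resid ** 2) / sigma ** 2)
    return float(sum(per_level.values())), per_level


def _usable_levels(data):
    """Drop n=1 levels (no within-level variance) with a warning."""
    usable = []
    for p in data:
        if p.n_samples < 2 or p.sd_rel_expr <= 0:
            log.warning("excluding level %s%% from the objective: "
                        "n=%d, sd=%g", p.oxygen_percent, p.n_samples,
                        p.sd_rel_expr)
        else:
            usable.append(p)
    return usable


def scan(data, config: FitConfig, pp_template: PromoterParams) -> list[FitResult]:
    """Exhaustive Cartesian grid search of the nSSE objective.

    Returns results sorted ascending by nSSE, ties broken by the parameter
    tuple in the order (I, alpha, beta, gamma, PpsR_total) so the output is
    deterministic.  Grid points where the solver fails are kept with
    ``nsse = inf``.
    """
    data = _usable_levels(data)
    if len(data) < 2:
        raise DomainError("need replicated data at >= 2 oxygen levels")
    pcts = [p.oxygen_percent for p in data]
    base = {"I": 0.001, "alpha": 6.0, "beta": 500.0, "gamma": 2.1,
            "PpsR_total": pp_template.PpsR_total}
    names = [n for n in FitConfig.SCANNABLE if n in config.grids]
    results = []
    for values in itertools.product(*(config.grids[n] for n in names)):
        point = dict(base)
        point.update(dict(zip(names, values)))
        params = ModelParams(I=point["I"], alpha=point["alpha"],
                             beta=point["beta"], gamma=point["gamma"],
                             delta=config.delta, K_eq=config.K_eq)
        pp = replace(pp_template, case=config.case,
                     PpsR_total=point["PpsR_total"])
        try:
            preds = predict_curve(params, point["PpsR_total"], pp, pcts,
                                  config.oxygen_map)
            total, per_level = normalized_sse(data, preds)
        except SolverError as exc:
            log.warning("solver failure at %s: %s", point, exc)
            total, per_level = math.inf, {}
        results.append(FitResult(params=params,
                                 PpsR_total=point["PpsR_total"],
                                 nsse=total, per_level_nsse=per_level))
    results.sort(key=lambda r: (r.nsse, r.params.I, r.params.alpha,
                                r.params.beta, r.params.gamma, r.PpsR_total))
    return results


def aerobic_O_threshold(params: ModelParams, PpsR_total: float,
                        O_grid) -> float | None:
    """Smallest grid O at which free oxidized PpsR reaches 50% of total.

    Walks the branch continued from the anaerobic solution.  Returns None
    when the threshold is never reached on the grid.
    """
    O_grid = sorted(float(O) for O in O_grid)
    prev = anaerobic_start(params)
    last_O = 0.0
    for O in O_grid:
        prev = _walk_branch(params, last_O, O, prev)
        ss = steady_state(params, O, init=prev, strict_stability=False,
                          ensure_stable=True)
        prev, last_O = ss.state, O
        if ss.state.p * PpsR_total >= 0.5 * PpsR_total:
            return O
    return None
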