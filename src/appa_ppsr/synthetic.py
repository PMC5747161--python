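"""Synthetic microarray-like expression series and binding isotherms.

Generates long-format MAS 5.0-style probe tables with the statistical
structure the downstream analysis assumes, so the whole pipeline is testable
without external downloads:

* six oxygen levels spanning 0–30% plus white-light and blue-light
  conditions, mirroring the combined public dataset's design;
* a condition-independent reference gene (rpoZ probe) with multiplicative
  lognormal sample-to-sample variation;
* target-probe (pucB) values proportional to the model-predicted relative
  expression times the sample's reference value, with heteroscedastic noise:
  the coefficient of variation is largest at 0% oxygen and decays
  log-linearly with oxygen percent, reproducing the observed pattern of
  very high variance at low oxygen.

All randomness is drawn from a seeded generator: the same seed yields a
byte-identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import ModelParams
from .errors import DomainError
from .fitting import OxygenMap, predict_curve
from .normalize import PUCB_PROBES, RPOZ_PROBE, ExpressionSample
from .promoter import PromoterParams

__all__ = [
    "NoiseConfig",
    "DEFAULT_CONDITIONS",
    "generate_series",
    "generate_isotherm",
]

#: study-like growth conditions: (oxygen %, light W/m², colour).  Anaerobic
#: cultures grow under 10 W/m² white light (plus a 100 W/m² arm), oxygenated
#: cultures in the dark, and one semi-aerobic blue-light arm.
DEFAULT_CONDITIONS = (
    (0.0, 10.0, "white"),
    (1.0, 0.0, "dark"),
    (3.0, 0.0, "dark"),
    (5.0, 0.0, "dark"),
    (10.0, 0.0, "dark"),
    (30.0, 0.0, "dark"),
    (0.0, 100.0, "white"),
    (10.0, 10.0, "blue"),
)


@dataclass(frozen=True)
class NoiseConfig:
    """Noise model of the synthetic series.

    ``ref_mean``/``ref_cv`` set the reference probe's lognormal distribution;
    ``target_cv_low_o2``/``target_cv_high_o2`` bound the target probes' CV at
    0% and at the maximal oxygen, between which the CV interpolates
    log-linearly in oxygen percent (variance shrinks with oxygen).
    """

    ref_mean: float = 500.0
    ref_cv: float = 0.1
    target_cv_low_o2: float = 0.4
    target_cv_high_o2: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ref_mean <= 0:
            raise DomainError("ref_mean must be > 0")
        for name in ("ref_cv", "target_cv_low_o2", "target_cv_high_o2"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.target_cv_low_o2 < self.target_cv_high_o2:
            raise DomainError(
                "target CV must not increase with oxygen "
                "(target_cv_low_o2 >= target_cv_high_o2)")

    def target_cv(self, oxygen_percent: float, pct_max: float = 30.0) -> float:
        lo, hi = self.target_cv_low_o2, self.target_cv_high_o2
        if lo == 0 or hi == 0:
            return 0.0 if lo == 0 else lo if oxygen_percent == 0 else hi
        frac = min(max(oxygen_percent / pct_max, 0.0), 1.0)
        return lo * (hi / lo) ** frac


def _lognormal_factor(rng, cv, size=None):
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2),
                         size=size)


def generate_series(truth: ModelParams, PpsR_total: float,
                    pp: PromoterParams,
                    conditions=DEFAULT_CONDITIONS,
                    n_per_condition: int = 5,
                    noise: NoiseConfig = NoiseConfig(),
                    oxygen_map: OxygenMap = OxygenMap(),
                    series_id: str = "synth",
                    blue_light_I: float = 1.0) -> list[ExpressionSample]:
    """Generate microarray-like samples from a ground-truth model.

    Per condition the expected relative expression is the model prediction
    at that oxygen level; blue-light conditions are evaluated at the
    elevated irradiance ``blue_light_I`` instead of the truth's (dark) I.
    White-light intensity effects are outside the redox model and are not
    emulated.  Each sample draws one reference value and five target-probe
    values; target = μ · reference · noise, so the relative expression is
    unbiased and heteroscedastic in oxygen.
    """
    conditions = list(conditions)
    if not conditions or n_per_condition < 1:
        raise DomainError("need conditions and n_per_condition >= 1")
    rng = np.random.default_rng(noise.seed)
    pct_max = max(c[0] for c in conditions) or 30.0

    # expected relative expression per condition (branch continued from O=0)
    mu = {}
    dark_pcts = sorted({c[0] for c in conditions if c[2] != "blue"})
    dark_mu = predict_curve(truth, PpsR_total, pp, dark_pcts, oxygen_map)
    mu.update(dict(zip(dark_pcts, dark_mu)))
    blue_pcts = sorted({c[0] for c in conditions if c[2] == "blue"})
    if blue_pcts:
        blue_params = ModelParams(I=blue_light_I, alpha=truth.alpha,
                                  beta=truth.beta, gamma=truth.gamma,
                                  delta=truth.delta, K_eq=truth.K_eq)
        blue_mu = predict_curve(blue_params, PpsR_total, pp, blue_pcts,
                                oxygen_map)

    samples = []
    for oxy, light, color in conditions:
        expected = (blue_mu[blue_pcts.index(oxy)] if color == "blue"
                    else mu[oxy])
        cv = noise.target_cv(oxy, pct_max)
        for k in range(n_per_condition):
            ref = noise.ref_mean * _lognormal_factor(rng, noise.ref_cv)
            values = {RPOZ_PROBE: float(ref)}
            factors = _lognormal_factor(rng, cv, size=len(PUCB_PROBES))
            for probe, fac in zip(PUCB_PROBES, np.atleast_1d(factors)):
                values[probe] = float(expected * ref * fac)
            samples.append(ExpressionSample(
                series_id=series_id,
                sample_id=f"{series_id}_{oxy:g}pct_{color}{light:g}_{k}",
                oxygen_percent=oxy, light_intensity=light,
                light_color=color, values=values))
    return samples


def generate_isotherm(A: float, K_d: float, n: float, concentrations,
                      noise_sd: float = 0.0, seed: int = 0):
    """Hill-curve binding isotherm y = A·x^n/(K_d^n + x^n) + N(0, noise_sd)."""
    x = np.asarray(concentrations, float)
    if np.any(x < 0):
        raise DomainError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore", over="ignore"):
        y = np.where(x > 0, A / (1.0 + (K_d / np.maximum(x, 1e-300)) ** n),
                     0.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return x, y
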