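"""Cross-series normalization of MAS 5.0-style microarray expression tables.

MAS 5.0 values are normalized within a GEO series but not across series from
different laboratories.  To combine them, each sample's pucB level (mean of
its five probes, ids 1194–1198) is divided by the same sample's rpoZ level
(probe id 2587, condition-independent reference), and the resulting relative
expressions are grouped by growth condition (oxygen %, light intensity,
light colour) across series.

The input/output format is long-format TSV with columns::

    series_id  sample_id  oxygen_percent  light_intensity_Wm2  light_color  probe_id  value

one probe measurement per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, NormalizationError

__all__ = [
    "PUCB_PROBES",
    "RPOZ_PROBE",
    "ExpressionSample",
    "CombinedPoint",
    "relative_expression",
    "combine",
    "reference_stability_check",
    "read_samples_tsv",
    "samples_to_frame",
    "write_combined_tsv",
    "combined_to_frame",
]

#: probe ids of the five pucB probes on the R. sphaeroides 2.4.1 GeneChip
PUCB_PROBES = ("1194", "1195", "1196", "1197", "1198")
#: probe id of the rpoZ reference gene
RPOZ_PROBE = "2587"

#: series excluded from combination by default (high 2%-oxygen variance)
DEFAULT_BLACKLIST = frozenset({"arai"})

LIGHT_COLORS = ("dark", "white", "blue")

TSV_COLUMNS = ["series_id", "sample_id", "oxygen_percent",
               "light_intensity_Wm2", "light_color", "probe_id", "value"]


@dataclass(frozen=True)
class ExpressionSample:
    """One microarray sample: probe values plus growth-condition metadata."""

    series_id: str
    sample_id: str
    oxygen_percent: float
    light_intensity: float
    light_color: str
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.oxygen_percent <= 100:
            raise DomainError(
                f"oxygen_percent must be in [0, 100], got {self.oxygen_percent}")
        if self.light_intensity < 0:
            raise DomainError("light_intensity must be >= 0")
        if self.light_color not in LIGHT_COLORS:
            raise DomainError(
                f"light_color must be one of {LIGHT_COLORS}, "
                f"got {self.light_color!r}")
        for probe, v in self.values.items():
            if v < 0:
                raise DomainError(f"negative value for probe {probe!r}")

    @property
    def condition(self):
        return (self.oxygen_percent, self.light_intensity, self.light_color)


@dataclass(frozen=True)
class CombinedPoint:
    """Mean ± SD relative expression at one growth condition."""

    oxygen_percent: float
    light_intensity: float
    light_color: str
    mean_rel_expr: float
    sd_rel_expr: float
    n_samples: int
    replicates: tuple = ()

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise DomainError("n_samples must be >= 1")
        if self.sd_rel_expr < 0:
            raise DomainError("sd_rel_expr must be >= 0")

    @property
    def condition(self):
        return (self.oxygen_percent, self.light_intensity, self.light_color)


def relative_expression(sample: ExpressionSample,
                        target_probes=PUCB_PROBES,
                        reference_probe=RPOZ_PROBE) -> float:
    """Relative expression: mean of target-probe values over the reference.

    Raises
    ------
    NormalizationError
        If the reference value is not strictly positive.
    DomainError
        If a target probe or the reference probe is missing.
    """
    missing = [p for p in (*target_probes, reference_probe)
               if p not in sample.values]
    if missing:
        raise DomainError(
            f"sample {sample.sample_id!r} missing probes {missing}")
    ref = sample.values[reference_probe]
    if ref <= 0:
        raise NormalizationError(
            f"reference probe {reference_probe!r} value {ref} <= 0 in sample "
            f"{sample.sample_id!r}")
    target = float(np.mean([sample.values[p] for p in target_probes]))
    return target / ref


def combine(samples, blacklist=DEFAULT_BLACKLIST,
            target_probes=PUCB_PROBES,
            reference_probe=RPOZ_PROBE) -> list[CombinedPoint]:
    """Group relative expressions by exact growth condition across series.

    Samples from blacklisted series are removed first.  Per condition the
    sample mean and the n−1 standard deviation are reported (sd = 0 for
    singleton groups).  Output is sorted by (oxygen, light intensity, colour)
    so it is invariant to input order and series relabeling.
    """
    blacklist = set(blacklist or ())
    kept = [s for s in samples if s.series_id not in blacklist]
    if not kept:
        raise DomainError("no samples remain after applying the blacklist")
    groups: dict[tuple, list[float]] = {}
    for s in kept:
        groups.setdefault(s.condition, []).append(
            relative_expression(s, target_probes, reference_probe))
    points = []
    for (oxy, li, color), vals in groups.items():
        arr = np.array(sorted(vals))
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        points.append(CombinedPoint(
            oxygen_percent=oxy, light_intensity=li, light_color=color,
            mean_rel_expr=float(arr.mean()), sd_rel_expr=sd,
            n_samples=int(arr.size), replicates=tuple(arr)))
    points.sort(key=lambda p: (p.oxygen_percent, p.light_intensity,
                               p.light_color))
    return points


def reference_stability_check(samples, reference_probe=RPOZ_PROBE,
                              cv_threshold=0.3):
    """Check that the reference gene is condition-independent.

    Computes the coefficient of variation (population SD over mean) of the
    raw reference-probe values within each condition, and the CV of the
    per-condition means across conditions.  The flag is raised when the
    across-condition CV exceeds ``cv_threshold`` (default 0.3), signalling
    that the reference gene is not a safe normalizer for these data.

    Returns
    -------
    dict with keys ``per_condition`` (condition → CV), ``across`` (float)
    and ``flag`` (bool).
    """
    groups: dict[tuple, list[float]] = {}
    for s in samples:
        if reference_probe not in s.values:
            raise DomainError(
                f"sample {s.sample_id!r} missing reference probe")
        groups.setdefault(s.condition, []).append(s.values[reference_probe])
    if len(groups) < 2:
        raise DomainError("need samples from at least 2 conditions")

    def cv(arr):
        arr = np.asarray(arr, float)
        m = arr.mean()
        return float(np.std(arr, ddof=0) / m) if m > 0 else np.inf

    per_condition = {cond: cv(vals) for cond, vals in groups.items()}
    cond_means = [float(np.mean(v)) for _, v in sorted(groups.items())]
    across = cv(cond_means)
    return {"per_condition": per_condition, "across": across,
            "flag": across > cv_threshold}


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

def samples_to_frame(samples) -> pd.DataFrame:
    rows = []
    for s in samples:
        for probe, v in s.values.items():
            rows.append((s.series_id, s.sample_id, s.oxygen_percent,
                         s.light_intensity, s.light_color, probe, v))
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def read_samples_tsv(path) -> list[ExpressionSample]:
    """Read long-format samples from TSV (one probe measurement per row)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str,
                                            "series_id": str,
                                            "sample_id": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"input TSV missing columns {sorted(missing)}")
    samples = []
    keys = ["series_id", "sample_id", "oxygen_percent",
            "light_intensity_Wm2", "light_color"]
    for (sid, samp, oxy, li, color), grp in df.groupby(keys, sort=False):
        samples.append(ExpressionSample(
            series_id=sid, sample_id=samp, oxygen_percent=float(oxy),
            light_intensity=float(li), light_color=color,
            values=dict(zip(grp["probe_id"], grp["value"].astype(float)))))
    return samples


def combined_to_frame(points) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.oxygen_percent, p.light_intensity, p.light_color,
          p.mean_rel_expr, p.sd_rel_expr, p.n_samples) for p in points],
        columns=["oxygen_percent", "light_intensity_Wm2", "light_color",
                 "mean_rel_expr", "sd_rel_expr", "n_samples"])


def write_combined_tsv(points, path) -> None:
    combined_to_frame(points).to_csv(path, sep="\t", index=False)
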