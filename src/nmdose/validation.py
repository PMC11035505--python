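"""Validation utilities: device intercomparison correction, voiding-regime
categorization, measured-vs-simulated comparison, morphology sensitivity
statistics, and a seeded synthetic measurement generator.

Measured ambient dose rates are normalised per unit administered activity
(residual-corrected when available) and compared against the simulated 95%
confidence band; patients are binned into voiding regimes by their first
bladder-voiding time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementSeries",
    "MorphologyReport",
    "VOIDING_ANCHORS",
    "device_correction",
    "categorize_voiding",
    "compare_within_ci",
    "morphology_stats",
    "generate_measurements",
    "read_measurements_csv",
    "write_measurements_csv",
]

# first-void anchors (min p.a.) of the four voiding regimes:
# (a) 30 min then hourly, (b) 45 min then hourly, (c) 120-min interval,
# (d) 210-min interval (the reference-model default).
VOIDING_ANCHORS = {"a": 30.0, "b": 45.0, "c": 120.0, "d": 210.0}
_BOUNDARIES = (37.5, 82.5, 165.0)  # midpoints between successive anchors


@dataclass
class MeasurementSeries:
    """Dose-rate readings at 1 m from one patient."""

    patient_id: str
    pharmaceutical: str
    administered_activity_mbq: float  # residual-corrected when available
    times_min: np.ndarray
    h10_rate_usv_h: np.ndarray
    device_id: str = ""
    first_void_min: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.h10_rate_usv_h = np.asarray(self.h10_rate_usv_h, dtype=float)
        if self.administered_activity_mbq <= 0:
            raise ValueError("administered activity must be positive")
        if np.any(self.h10_rate_usv_h < 0):
            raise ValueError("dose rates must be non-negative")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("measurement times must be strictly increasing")

    def normalized(self):
        """Rates per unit administered activity (uSv/h/MBq)."""
        return self.h10_rate_usv_h / self.administered_activity_mbq


@dataclass
class MorphologyReport:
    """Across-phantom sensitivity statistics."""

    factor_table: pd.DataFrame  # region x phantom
    max_min_ratio: pd.Series  # per region, rounded to 1 decimal
    rsd_percent: pd.Series | None = None  # per time point, of the cumulated series


def device_correction(series: MeasurementSeries, device_relative_deviation: float):
    """Correct readings for the device's intercomparison deviation.

    A device reading ``(1 + dev)`` times the nominal value has its rates
    divided by ``(1 + dev)``; the correction is recorded in the metadata.
    """
    if device_relative_deviation <= -1:
        raise ValueError("relative deviation must be > -1")
    corrected = series.h10_rate_usv_h / (1.0 + device_relative_deviation)
    meta = dict(series.meta)
    meta["device_correction"] = meta.get("device_correction", 0.0) or device_relative_deviation
    meta["device_correction_applied"] = device_relative_deviation
    return replace(series, h10_rate_usv_h=corrected, meta=meta)


def categorize_voiding(first_void_time: float) -> str:
    """Assign a first-void time to the nearest voiding regime (a-d).

    Boundaries are the midpoints between regime anchors; exact midpoints
    resolve to the lower (earlier) category.
    """
    if first_void_time <= 0:
        raise ValueError("first void time must be positive")
    for cat, bound in zip("abc", _BOUNDARIES):
        if first_void_time <= bound:
            return cat
    return "d"


def compare_within_ci(measured: MeasurementSeries, simulated) -> tuple:
    """Fraction of normalised measurements inside the simulated 95% band.

    The band (ci_low, ci_high of a DoseRateSeries) is linearly interpolated
    at the measurement times; times outside the simulated grid raise.
    Returns ``(fraction, per_point_flags)``.
    """
    if simulated.ci_low is None:
        raise ValueError("simulated series carries no confidence band")
    t = measured.times_min
    if t.min() < simulated.times.min() or t.max() > simulated.times.max():
        raise ValueError("measurement times fall outside the simulated grid")
    lo = np.interp(t, simulated.times, simulated.ci_low)
    hi = np.interp(t, simulated.times, simulated.ci_high)
    y = measured.normalized()
    inside = (y >= lo) & (y <= hi)
    return float(inside.mean()), inside


def morphology_stats(factor_table: pd.DataFrame, cumulated: pd.DataFrame | None = None
                     ) -> MorphologyReport:
    """Across-phantom spread of per-region factors and cumulated series.

    ``factor_table``: rows = source regions, columns = phantoms, values in
    uSv/h/MBq.  Per region the max/min ratio is reported rounded to one
    decimal.  ``cumulated`` (optional): rows = time points, columns =
    phantoms; per time point the relative standard deviation (sample SD /
    mean, percent) of the cumulated dose rate is reported.
    """
    if factor_table.shape[1] < 2:
        raise ValueError("need at least two phantoms")
    vmin = factor_table.min(axis=1)
    vmax = factor_table.max(axis=1)
    if np.any(vmin <= 0):
        raise ValueError("factors must be positive")
    ratio = (vmax / vmin).round(1)
    rsd = None
    if cumulated is not None:
        mean = cumulated.mean(axis=1)
        if np.any(mean == 0):
            raise ValueError("cumulated series has zero mean at some time point")
        rsd = 100.0 * cumulated.std(axis=1, ddof=1) / mean
    return MorphologyReport(factor_table=factor_table, max_min_ratio=ratio, rsd_percent=rsd)


def generate_measurements(true_series, n_points, seed, device_bias=0.0,
                          positioning_sd_cm=0.0, device_noise_rel=0.0,
                          nominal_distance_cm=100.0,
                          administered_activity_mbq=700.0,
                          patient_id="synthetic", pharmaceutical="Tc99m-HDP/MDP",
                          device_id="synthetic", first_void_min=None) -> MeasurementSeries:
    """Synthetic noisy readings drawn from a simulated dose-rate curve.

    Emulates a measurement campaign: times spread over the simulated grid,
    a multiplicative device bias, inverse-square jitter from a Gaussian
    positioning error, and relative Gaussian device noise.  Fully seeded.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(true_series.times.min(), true_series.times.max(), n_points))
    t += np.arange(n_points) * 1e-9  # break ties, keep strict ordering
    truth = np.interp(t, true_series.times, true_series.values)
    dist = nominal_distance_cm + rng.normal(0.0, positioning_sd_cm, n_points)
    geom = (nominal_distance_cm / dist) ** 2
    noise = 1.0 + rng.normal(0.0, device_noise_rel, n_points)
    rates = truth * (1.0 + device_bias) * geom * np.clip(noise, 0.0, None)
    rates = rates * administered_activity_mbq
    return MeasurementSeries(
        patient_id=patient_id,
        pharmaceutical=pharmaceutical,
        administered_activity_mbq=administered_activity_mbq,
        times_min=t,
        h10_rate_usv_h=rates,
        device_id=device_id,
        first_void_min=first_void_min,
        meta={"seed": seed, "device_bias": device_bias,
              "positioning_sd_cm": positioning_sd_cm,
              "device_noise_rel": device_noise_rel},
    )


_CSV_COLUMNS = ["patient_id", "pharmaceutical", "activity_MBq", "time_min",
                "h10_uSv_per_h", "device_id", "first_void_min"]


def write_measurements_csv(series_list, path):
    rows = []
    for s in series_list:
        for t, y in zip(s.times_min, s.h10_rate_usv_h):
            rows.append([s.patient_id, s.pharmaceutical, s.administered_activity_mbq,
                         t, y, s.device_id, s.first_void_min])
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_measurements_csv(path):
    df = pd.read_csv(path)
    out = []
    for (pid, pharm, act, dev, fv), grp in df.groupby(
        ["patient_id", "pharmaceutical", "activity_MBq", "device_id", "first_void_min"],
        dropna=False, sort=False,
    ):
        grp = grp.sort_values("time_min")
        out.append(MeasurementSeries(
            patient_id=str(pid), pharmaceutical=str(pharm),
            administered_activity_mbq=float(act),
            times_min=grp["time_min"].to_numpy(),
            h10_rate_usv_h=grp["h10_uSv_per_h"].to_numpy(),
            device_id=str(dev),
            first_void_min=None if pd.isna(fv) else float(fv),
        ))
    return out
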