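"""Internal-standard calibration and full method-validation arithmetic.

Implements the validation workflow of a targeted LC-HRMS method:

* linear calibration of analyte/internal-standard area ratios against
  concentration, with automatic linear-range selection;
* instrument detection/quantification limits (IDL/IQL) from measured
  signal-to-noise ratios at S/N 3 and 10, with the IQL additionally
  floored at the lowest calibration level whose precision is < 20% RSD;
* corrected extraction recoveries
  ``R = 100 x (A_spiked - A_blank) / A_mobile_phase``;
* method limits ``ML = IL / F x 1 / RC`` where ``F`` is the SPE
  preconcentration factor (400 = 100 mL concentrated to 0.25 mL) and
  ``RC`` the fractional recovery, reported in ng/L;
* intra-/inter-day precision (%RSD) and accuracy (% of nominal);
* back-calculation of sample concentrations with <MDL / <MQL flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationLevel",
    "CalibrationCurve",
    "RecoveryExperiment",
    "SensitivityInputs",
    "PrecisionAccuracyReport",
    "fit_calibration",
    "estimate_idl_iql",
    "corrected_recovery",
    "method_limit",
    "mql_floor",
    "round_limit",
    "precision_accuracy",
    "quantify_sample",
]

#: The paper-of-record calibration series spans 0.01-100 ug/L in 13 levels.
DEFAULT_CALIBRATION_LEVELS = (
    0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0,
)
#: SPE preconcentration factor: 100 mL of sample into 0.25 mL of extract.
DEFAULT_CONCENTRATION_FACTOR = 400.0


@dataclass(frozen=True)
class CalibrationLevel:
    """One calibration measurement: nominal concentration and both areas."""

    concentration: float  # ug/L
    analyte_area: float
    is_area: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("calibration concentration must be positive")
        if self.analyte_area < 0 or self.is_area < 0:
            raise ValueError("areas must be non-negative")

    @property
    def ratio(self) -> float:
        if self.is_area <= 0:
            raise ValueError("internal-standard area is zero")
        return self.analyte_area / self.is_area


@dataclass
class CalibrationCurve:
    """OLS fit of mean area ratio vs concentration over the linear range."""

    slope: float
    intercept: float
    r_squared: float
    range_low: float
    range_high: float
    levels_used: tuple[float, ...]
    idl: Optional[float] = None  # ug/L
    iql: Optional[float] = None  # ug/L

    def concentration(self, ratio: float) -> float:
        """Invert the curve: area ratio -> concentration in ug/L."""
        if self.slope == 0:
            raise ValueError("degenerate calibration slope")
        return (ratio - self.intercept) / self.slope


def fit_calibration(
    levels: Sequence[CalibrationLevel],
    r2_target: float = 0.99,
    min_levels: int = 5,
    weighting: str = "none",
) -> CalibrationCurve:
    """Fit a calibration curve with automatic linear-range selection.

    Replicate ratios are averaged per concentration, then ordinary least
    squares is fit; while R^2 < ``r2_target`` and more than ``min_levels``
    concentrations remain, the extreme level (lowest or highest) whose
    removal improves R^2 most is dropped. ``weighting="1/x"`` weights each
    level by the inverse concentration instead of uniformly.
    """
    if weighting not in ("none", "1/x"):
        raise ValueError("weighting must be 'none' or '1/x'")
    by_conc: dict[float, list[float]] = {}
    for lv in levels:
        by_conc.setdefault(lv.concentration, []).append(lv.ratio)
    concs = np.array(sorted(by_conc))
    if concs.size < min_levels:
        raise ValueError(f"need at least {min_levels} distinct concentrations")
    ratios = np.array([np.mean(by_conc[c]) for c in concs])
    if not np.any(ratios > 0):
        raise ValueError("all area ratios are zero")

    def _fit(x: np.ndarray, y: np.ndarray):
        if weighting == "1/x":
            w = 1.0 / x
            slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
            yhat = slope * x + intercept
            ybar = np.average(y, weights=w)
            ss_res = np.sum(w * (y - yhat) ** 2)
            ss_tot = np.sum(w * (y - ybar) ** 2)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        else:
            res = stats.linregress(x, y)
            slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
        return float(slope), float(intercept), float(r2)

    lo, hi = 0, concs.size
    slope, intercept, r2 = _fit(concs, ratios)
    while r2 < r2_target and hi - lo > min_levels:
        drop_low = _fit(concs[lo + 1:hi], ratios[lo + 1:hi])
        drop_high = _fit(concs[lo:hi - 1], ratios[lo:hi - 1])
        if drop_high[2] >= drop_low[2]:
            hi -= 1
            slope, intercept, r2 = drop_high
        else:
            lo += 1
            slope, intercept, r2 = drop_low
    used = concs[lo:hi]
    return CalibrationCurve(
        slope=slope, intercept=intercept, r_squared=r2,
        range_low=float(used[0]), range_high=float(used[-1]),
        levels_used=tuple(float(c) for c in used),
    )


def estimate_idl_iql(
    curve: CalibrationCurve,
    snr_by_level: Mapping[float, float],
    precision_by_level: Mapping[float, float] | None = None,
    max_rsd: float = 20.0,
) -> tuple[float, float]:
    """Instrument detection/quantification limits from measured S/N.

    The IDL is the concentration giving S/N = 3, found by a straight line
    through S/N at the two lowest measured levels; the S/N = 10 point is
    found the same way and the IQL is the larger of that point and the
    lowest linear-range level whose replicate precision is below
    ``max_rsd`` %RSD. Raises when everything is below S/N 1 (undetectable).
    """
    if len(snr_by_level) < 2:
        raise ValueError("need S/N at two or more levels")
    if max(snr_by_level.values()) < 1.0:
        raise ValueError("analyte undetectable: all S/N below 1")
    concs = sorted(snr_by_level)
    c1, c2 = concs[0], concs[1]
    s1, s2 = snr_by_level[c1], snr_by_level[c2]
    if s2 == s1:
        raise ValueError("degenerate S/N response")
    slope = (s2 - s1) / (c2 - c1)
    intercept = s1 - slope * c1
    idl = (3.0 - intercept) / slope
    iql_snr = (10.0 - intercept) / slope
    if idl <= 0 or iql_snr <= 0:
        raise ValueError("S/N interpolation gives non-positive limit")
    iql = iql_snr
    if precision_by_level:
        precise = [
            c for c in curve.levels_used
            if c in precision_by_level and precision_by_level[c] < max_rsd
        ]
        if precise:
            iql = max(iql_snr, min(precise))
    return float(idl), float(iql)


@dataclass(frozen=True)
class RecoveryExperiment:
    """Measured concentrations of a spike-recovery experiment.

    All three inputs are internal-standard-corrected concentrations: the
    sample spiked before extraction, the unspiked matrix blank, and a
    standard at the spike level prepared directly in mobile phase.
    """

    a_spiked_before_spe: float
    a_blank: float
    a_mobile_phase: float
    spike_level: Optional[float] = None  # ng/L, bookkeeping only

    def __post_init__(self) -> None:
        if self.a_mobile_phase <= 0:
            raise ValueError("mobile-phase standard concentration must be positive")


def corrected_recovery(e: RecoveryExperiment) -> float:
    """Blank-subtracted, internal-standard-corrected extraction recovery in %.

    Values above 100% (matrix enhancement) are reported as-is, never
    clamped; callers may flag them.
    """
    return 100.0 * (e.a_spiked_before_spe - e.a_blank) / e.a_mobile_phase


@dataclass(frozen=True)
class SensitivityInputs:
    """Inputs of the instrument-to-method limit conversion."""

    il: float  # IDL or IQL, ug/L
    recovery: float  # fractional SPE recovery, e.g. 0.804
    factor: float = DEFAULT_CONCENTRATION_FACTOR

    def __post_init__(self) -> None:
        if self.recovery <= 0:
            raise ValueError("recovery must be positive")
        if self.factor <= 0:
            raise ValueError("concentration factor must be positive")


def method_limit(s: SensitivityInputs) -> float:
    """Method limit ``ML = IL / F x 1 / RC`` converted from ug/L to ng/L."""
    return s.il / s.factor / s.recovery * 1000.0


def mql_floor(
    calculated_mql: float,
    lowest_calibration_conc: float,
    factor: float = DEFAULT_CONCENTRATION_FACTOR,
    recovery: float = 1.0,
) -> float:
    """Floor the method quantification limit at the calibration range.

    A calculated MQL below the lowest calibration level cannot actually be
    quantified; the reported MQL is then the lowest level pushed through
    the same instrument-to-method scaling.
    """
    if calculated_mql <= 0 or lowest_calibration_conc <= 0:
        raise ValueError("inputs must be positive")
    floor = method_limit(SensitivityInputs(lowest_calibration_conc, recovery, factor))
    return max(calculated_mql, floor)


def round_limit(value: float) -> float:
    """Report-style rounding for method limits in ng/L.

    One decimal place when that still resolves the value (rounds to
    >= 0.1), two decimal places otherwise — the mixed precision used in
    method-performance tables. Raw values should always be retained
    alongside the rounded report.
    """
    at_1dp = round(value, 1)
    return at_1dp if at_1dp >= 0.1 else round(value, 2)


@dataclass
class PrecisionAccuracyReport:
    """Per-level accuracy and precision, intra- and inter-day."""

    nominal: float
    mean_measured: float
    accuracy_pct: float
    intra_day_rsd: float
    inter_day_rsd: Optional[float]
    n_replicates: int
    n_days: int


def _rsd(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        return 0.0
    return float(values.std(ddof=1) / m * 100.0)


def precision_accuracy(
    measurements: Mapping[float, Mapping[int, Sequence[float]]],
) -> list[PrecisionAccuracyReport]:
    """Accuracy and intra-/inter-day precision from replicate measurements.

    ``measurements`` maps nominal concentration -> day index -> replicate
    measured concentrations (>= 3 per day). Accuracy is the grand mean as a
    percentage of nominal; intra-day precision is the mean of the
    within-day %RSDs; inter-day precision is the %RSD of the day means
    (requires >= 2 days, otherwise None).
    """
    reports = []
    for nominal in sorted(measurements):
        days = measurements[nominal]
        per_day = []
        for day in sorted(days):
            values = np.asarray(days[day], dtype=float)
            if values.size < 3:
                raise ValueError(
                    f"level {nominal}: day {day} has {values.size} replicates (< 3)"
                )
            per_day.append(values)
        all_values = np.concatenate(per_day)
        day_means = np.array([v.mean() for v in per_day])
        reports.append(
            PrecisionAccuracyReport(
                nominal=nominal,
                mean_measured=float(all_values.mean()),
                accuracy_pct=float(all_values.mean() / nominal * 100.0),
                intra_day_rsd=float(np.mean([_rsd(v) for v in per_day])),
                inter_day_rsd=_rsd(day_means) if len(per_day) > 1 else None,
                n_replicates=int(all_values.size),
                n_days=len(per_day),
            )
        )
    return reports


@dataclass
class QuantResult:
    """Back-calculated sample concentration with detectability flags."""

    concentration: Optional[float]  # ng/L in the original sample
    flag: str  # "ok" | "<MDL" | "<MQL" | "no-internal-standard"
    instrument_concentration: Optional[float] = None  # ug/L in the extract


def quantify_sample(
    analyte_area: float,
    is_area: float,
    curve: CalibrationCurve,
    factor: float = DEFAULT_CONCENTRATION_FACTOR,
    mdl: Optional[float] = None,
    mql: Optional[float] = None,
) -> QuantResult:
    """Back-calculate a sample concentration from measured areas.

    The area ratio is inverted through the calibration curve to an
    instrument concentration (ug/L in the injected extract), then divided
    by the preconcentration factor and converted to ng/L in the original
    sample. Results below the MDL or MQL are flagged.
    """
    if is_area <= 0:
        return QuantResult(None, "no-internal-standard")
    instrument_conc = curve.concentration(analyte_area / is_area)
    sample_conc = instrument_conc / factor * 1000.0
    flag = "ok"
    if mdl is not None and sample_conc < mdl:
        flag = "<MDL"
    elif mql is not None and sample_conc < mql:
        flag = "<MQL"
    return QuantResult(float(sample_conc), flag, float(instrument_conc))
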