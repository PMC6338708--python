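"""Multi-criteria suspect screening and identification-confidence assignment.

A suspect (a target compound or an expected metabolite) is screened against
a run through a fixed evidence chain: predicted adduct m/z -> narrow-window
XIC -> chromatographic peak -> mass accuracy at the apex -> isotope-pattern
agreement -> optional retention-time, fragment and ion-ratio checks. The
evidence maps onto identification-confidence levels adapted from the
Schymanski scheme:

* ``1a`` — all applicable criteria pass and a commercial reference standard
  backs the structure (full quantification possible);
* ``1b`` — all criteria pass against an in-vitro-synthesised reference;
* ``2``  — mass accuracy, isotope pattern and (where applicable) the
  metabolite-before-parent retention rule pass without any reference
  (tentative identification);
* ``not-detected`` — no peak, or a failed applicable criterion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chem import (
    ElementalFormula,
    IsotopePattern,
    adduct_mz,
    get_adduct,
    isotope_pattern,
    parse_formula,
    pattern_deviation,
    ppm_error,
)
from .spectra import HIGH, LOW, CentroidRun, ChromPeak, detect_peaks, extract_xic

__all__ = [
    "Suspect",
    "IdentificationCriteria",
    "CriterionOutcome",
    "IdentificationResult",
    "screen_suspect",
    "rt_below_parent",
    "ion_ratio_check",
    "assign_confidence",
    "read_suspects",
]

REFERENCE_TYPES = ("commercial standard", "in-vitro synthesized", "none")


@dataclass
class Suspect:
    """One row of a suspect/target list."""

    name: str
    formula: ElementalFormula
    adduct: str = "[M-H]-"
    expected_rt: Optional[float] = None
    fragments: tuple[float, ...] = ()
    parent: Optional[str] = None
    reference_type: str = "none"
    internal_standard: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.reference_type not in REFERENCE_TYPES:
            raise ValueError(
                f"reference_type must be one of {REFERENCE_TYPES}, got {self.reference_type!r}"
            )

    @property
    def polarity(self) -> str:
        return get_adduct(self.adduct).polarity

    @property
    def mz(self) -> float:
        return adduct_mz(self.formula, self.adduct)


@dataclass
class IdentificationCriteria:
    """Thresholds of the screening criteria.

    The defaults follow common suspect-screening practice: 10 ppm mass
    accuracy, isotope-pattern agreement within 5 absolute percentage points
    on the base-100 scale, a 0.005-Da full mass window, +/-0.2 min to a
    reference retention time, +/-0.05 min low/high-energy co-elution and a
    +/-30% relative ion-ratio tolerance.
    """

    max_ppm: float = 10.0
    max_isotope_dev: float = 5.0
    mass_window: float = 0.005
    rt_tolerance: float = 0.2
    coelution_tolerance: float = 0.05
    ion_ratio_tolerance: float = 0.30
    min_snr: float = 3.0
    isotope_mode: str = "absolute"  # or "relative": tolerance scales per channel

    def __post_init__(self) -> None:
        for name in ("max_ppm", "max_isotope_dev", "mass_window", "rt_tolerance",
                     "coelution_tolerance", "ion_ratio_tolerance", "min_snr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CriterionOutcome:
    """Value and verdict of one criterion; ``passed=None`` means not applicable."""

    value: Optional[float]
    passed: Optional[bool]

    @property
    def applicable(self) -> bool:
        return self.passed is not None


@dataclass
class IdentificationResult:
    suspect: str
    peak: Optional[ChromPeak]
    mass_accuracy: CriterionOutcome
    isotope: CriterionOutcome
    rt_vs_parent: CriterionOutcome
    rt_vs_reference: CriterionOutcome
    fragments: CriterionOutcome
    ion_ratio: CriterionOutcome
    confidence: str = "not-detected"

    @property
    def detected(self) -> bool:
        return self.confidence != "not-detected"

    def criteria(self) -> dict[str, CriterionOutcome]:
        return {
            "mass_accuracy": self.mass_accuracy,
            "isotope": self.isotope,
            "rt_vs_parent": self.rt_vs_parent,
            "rt_vs_reference": self.rt_vs_reference,
            "fragments": self.fragments,
            "ion_ratio": self.ion_ratio,
        }


def rt_below_parent(metabolite_rt: float, parent_rt: float) -> bool:
    """Metabolite-before-parent retention rule for reverse-phase gradients.

    Phase-II conjugates are more polar than their parent, so on a
    reverse-phase column they must elute strictly earlier.
    """
    return metabolite_rt < parent_rt


def ion_ratio_check(
    quantifier_area: float,
    qualifier_area: float,
    reference_ratio: float,
    tolerance: float = 0.30,
) -> bool:
    """Qualifier/quantifier area ratio within a relative tolerance of the reference."""
    if reference_ratio <= 0:
        raise ValueError("reference ratio must be positive")
    if quantifier_area <= 0:
        raise ValueError("quantifier area must be positive")
    observed = qualifier_area / quantifier_area
    return abs(observed / reference_ratio - 1.0) <= tolerance


def assign_confidence(result: IdentificationResult, reference_type: str) -> str:
    """Map criterion evidence to a confidence level.

    Any failed applicable criterion demotes to ``not-detected``. With all
    applicable criteria passing: a commercial standard gives 1a, an
    in-vitro reference 1b, and no reference the tentative level 2.
    """
    if result.peak is None:
        return "not-detected"
    outcomes = result.criteria()
    if any(o.passed is not None and not o.passed for o in outcomes.values()):
        return "not-detected"
    core = (result.mass_accuracy, result.isotope)
    if any(o.passed is None or not o.passed for o in core):
        return "not-detected"
    if reference_type == "commercial standard":
        return "1a"
    if reference_type == "in-vitro synthesized":
        return "1b"
    return "2"


def _apex_scan(run: CentroidRun, rt_apex: float, channel: str):
    spectra = run.channel_spectra(channel)
    return min(spectra, key=lambda s: abs(s.rt - rt_apex))


def _weighted_mz_at_apex(run: CentroidRun, mz: float, window: float, rt_apex: float) -> Optional[float]:
    """Intensity-weighted mean in-window centroid m/z at the apex scan."""
    scan = _apex_scan(run, rt_apex, LOW)
    half = window / 2.0
    sel = (scan.mz >= mz - half) & (scan.mz <= mz + half)
    if not np.any(sel) or scan.intensity[sel].sum() <= 0:
        return None
    return float(np.average(scan.mz[sel], weights=scan.intensity[sel]))


def _observed_pattern_at_apex(
    run: CentroidRun, pattern: IsotopePattern, window: float, rt_apex: float
) -> list[tuple[float, float]]:
    """Intensities of companion XICs at each predicted channel, read at the apex."""
    observed = []
    for channel_mz in pattern.mz:
        xic = extract_xic(run, channel_mz, window, LOW)
        k = int(np.argmin(np.abs(xic.rt - rt_apex)))
        observed.append((channel_mz, float(xic.intensity[k])))
    return observed


def screen_suspect(
    run: CentroidRun,
    suspect: Suspect,
    criteria: IdentificationCriteria | None = None,
    parent_rt: Optional[float] = None,
) -> IdentificationResult:
    """Screen one suspect against one run and assign a confidence level.

    ``parent_rt`` is the retention time of the detected parent compound,
    used for the metabolite-before-parent rule; when the suspect names a
    parent but no parent retention time is supplied the rule is skipped
    (not applicable).
    """
    criteria = criteria or IdentificationCriteria()
    if suspect.polarity != run.polarity:
        raise ValueError(
            f"suspect {suspect.name!r} is {suspect.polarity} but run is {run.polarity}"
        )
    na = CriterionOutcome(None, None)
    result = IdentificationResult(
        suspect=suspect.name, peak=None,
        mass_accuracy=na, isotope=na, rt_vs_parent=na,
        rt_vs_reference=na, fragments=na, ion_ratio=na,
    )

    target_mz = suspect.mz
    xic = extract_xic(run, target_mz, criteria.mass_window, LOW)
    peaks = detect_peaks(xic, min_snr=criteria.min_snr)
    if not peaks:
        return result
    # deterministic best-peak choice: height, then S/N, then earliest rt
    peak = max(peaks, key=lambda p: (p.height, p.snr, -p.rt_apex))
    result.peak = peak

    # (ii) mass accuracy on the intensity-weighted apex-scan centroid
    observed_mz = _weighted_mz_at_apex(run, target_mz, criteria.mass_window, peak.rt_apex)
    if observed_mz is None:
        return result
    ppm = ppm_error(observed_mz, target_mz)
    result.mass_accuracy = CriterionOutcome(ppm, abs(ppm) <= criteria.max_ppm)

    # (iii) isotope pattern from companion XICs at the apex; neutral-pattern
    # channels shifted by the adduct mass delta
    predicted = isotope_pattern(suspect.formula).shifted(suspect.mz - suspect.formula.mass)
    observed = _observed_pattern_at_apex(run, predicted, criteria.mass_window, peak.rt_apex)
    try:
        dev = pattern_deviation(predicted, observed, match_tol=criteria.mass_window / 2)
    except ValueError:
        dev = float("inf")
    if criteria.isotope_mode == "relative":
        # per-channel relative tolerance: rescale worst absolute deviation
        passed = _relative_pattern_ok(predicted, observed, criteria)
        result.isotope = CriterionOutcome(dev, passed)
    else:
        result.isotope = CriterionOutcome(dev, dev <= criteria.max_isotope_dev)

    # (i) retention time below the parent, for metabolites with a known parent
    if suspect.parent is not None and parent_rt is not None:
        result.rt_vs_parent = CriterionOutcome(
            peak.rt_apex - parent_rt, rt_below_parent(peak.rt_apex, parent_rt)
        )

    # retention time against a reference standard, when one exists
    if suspect.expected_rt is not None and suspect.reference_type != "none":
        delta = peak.rt_apex - suspect.expected_rt
        result.rt_vs_reference = CriterionOutcome(delta, abs(delta) <= criteria.rt_tolerance)

    # qualifier fragments: co-eluting high-energy peaks at each listed m/z
    if suspect.fragments:
        worst = 0.0
        all_found = True
        for frag_mz in suspect.fragments:
            frag_xic = extract_xic(run, frag_mz, criteria.mass_window, HIGH)
            frag_peaks = detect_peaks(frag_xic, min_snr=criteria.min_snr)
            coeluting = [
                p for p in frag_peaks
                if abs(p.rt_apex - peak.rt_apex) <= criteria.coelution_tolerance
            ]
            if coeluting:
                worst = max(worst, min(abs(p.rt_apex - peak.rt_apex) for p in coeluting))
            else:
                all_found = False
        result.fragments = CriterionOutcome(worst if all_found else None, all_found)

    result.confidence = assign_confidence(result, suspect.reference_type)
    return result


def _relative_pattern_ok(
    predicted: IsotopePattern, observed, criteria: IdentificationCriteria
) -> bool:
    base_candidates = [
        i for m, i in observed
        if abs(m - predicted.mz[predicted.base_index]) <= criteria.mass_window / 2
    ]
    if not base_candidates or max(base_candidates) <= 0:
        return False
    base = max(base_candidates)
    for mz, pred_ab in zip(predicted.mz, predicted.abundance):
        candidates = [i for m, i in observed if abs(m - mz) <= criteria.mass_window / 2]
        obs_ab = max(candidates) / base * 100.0 if candidates else 0.0
        if abs(obs_ab - pred_ab) > criteria.max_isotope_dev / 100.0 * pred_ab:
            return False
    return True


def read_suspects(path: str | Path) -> list[Suspect]:
    """Read a suspect list CSV.

    Columns: name, formula, adduct, rt_min (blank allowed), fragments
    (semicolon-separated m/z), parent, reference_type, internal_standard.
    """
    suspects = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            fragments = tuple(
                float(x) for x in (row.get("fragments") or "").split(";") if x.strip()
            )
            suspects.append(
                Suspect(
                    name=row["name"],
                    formula=parse_formula(row["formula"]),
                    adduct=row.get("adduct") or "[M-H]-",
                    expected_rt=float(row["rt_min"]) if row.get("rt_min") else None,
                    fragments=fragments,
                    parent=row.get("parent") or None,
                    reference_type=row.get("reference_type") or "none",
                    internal_standard=row.get("internal_standard") or None,
                )
            )
    return suspects
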