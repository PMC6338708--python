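"""Pipeline configuration and the two top-level workflows.

The analytical protocol has two branches operating on the same acquired
data: the targeted branch (quantification of listed compounds against
internal-standard calibration curves) and the data-mining branch
(post-acquisition suspect screening with confidence levels). Both are
exposed here as functions returning pandas DataFrames; reports are written
as CSV with a JSON sidecar carrying full-precision values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .identify import IdentificationCriteria, Suspect, screen_suspect
from .quantify import (
    CalibrationCurve,
    QuantResult,
    quantify_sample,
)
from .spectra import LOW, CentroidRun, detect_peaks, extract_xic

__all__ = ["PipelineConfig", "run_targeted", "run_datamining", "write_report"]


@dataclass
class PipelineConfig:
    """Validated thresholds and settings of the whole pipeline.

    Defaults reproduce the protocol's stated settings: 10-ppm mass
    accuracy, 5-point isotope tolerance, 0.005-Da mass window,
    concentration factor 400 and S/N thresholds 3 (detection) / 10
    (quantification).
    """

    max_ppm: float = 10.0
    max_isotope_dev: float = 5.0
    mass_window: float = 0.005
    rt_tolerance: float = 0.2
    coelution_tolerance: float = 0.05
    ion_ratio_tolerance: float = 0.30
    detection_snr: float = 3.0
    quantification_snr: float = 10.0
    concentration_factor: float = 400.0
    polarity: str = "negative"
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "max_ppm", "max_isotope_dev", "mass_window", "rt_tolerance",
            "coelution_tolerance", "ion_ratio_tolerance", "detection_snr",
            "quantification_snr", "concentration_factor",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")

    def criteria(self) -> IdentificationCriteria:
        return IdentificationCriteria(
            max_ppm=self.max_ppm,
            max_isotope_dev=self.max_isotope_dev,
            mass_window=self.mass_window,
            rt_tolerance=self.rt_tolerance,
            coelution_tolerance=self.coelution_tolerance,
            ion_ratio_tolerance=self.ion_ratio_tolerance,
            min_snr=self.detection_snr,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _measure_is_area(run: CentroidRun, suspect: Suspect, config: PipelineConfig) -> Optional[float]:
    xic = extract_xic(run, suspect.mz, config.mass_window, LOW)
    peaks = detect_peaks(xic, min_snr=config.detection_snr)
    if not peaks:
        return None
    return max(peaks, key=lambda p: p.height).area


def run_targeted(
    config: PipelineConfig,
    runs: Mapping[str, CentroidRun],
    targets: Sequence[Suspect],
    curves: Mapping[str, CalibrationCurve],
    internal_standards: Mapping[str, Suspect],
    mdl: Mapping[str, float] | None = None,
    mql: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Targeted branch: detect, confirm and quantify every listed compound.

    ``curves`` and ``internal_standards`` are keyed by target name; a
    target whose internal standard is missing from the mapping raises a
    named error. One row per target x run with the criterion values, the
    confidence level and the concentration (ng/L) or its flag
    ("n.d." when not detected, "<MDL"/"<MQL" below the limits).
    """
    mdl = mdl or {}
    mql = mql or {}
    rows = []
    for run_name, run in runs.items():
        for target in targets:
            if target.internal_standard is None or target.internal_standard not in internal_standards:
                raise KeyError(
                    f"target {target.name!r} has no internal-standard mapping"
                )
            result = screen_suspect(run, target, config.criteria())
            row = {
                "run": run_name,
                "compound": target.name,
                "mz": target.mz,
                "detected": result.detected,
                "confidence": result.confidence,
                "rt": result.peak.rt_apex if result.peak else None,
                "snr": result.peak.snr if result.peak else None,
                "ppm": result.mass_accuracy.value,
                "isotope_dev": result.isotope.value,
                "concentration_ngl": None,
                "flag": "n.d.",
            }
            if result.detected and target.name in curves:
                is_suspect = internal_standards[target.internal_standard]
                is_area = _measure_is_area(run, is_suspect, config)
                if is_area is None:
                    row["flag"] = "no-internal-standard"
                else:
                    q: QuantResult = quantify_sample(
                        analyte_area=result.peak.area,
                        is_area=is_area,
                        curve=curves[target.name],
                        factor=config.concentration_factor,
                        mdl=mdl.get(target.name),
                        mql=mql.get(target.name),
                    )
                    row["concentration_ngl"] = q.concentration
                    row["flag"] = q.flag
            rows.append(row)
    return pd.DataFrame(rows)


def run_datamining(
    config: PipelineConfig,
    runs: Mapping[str, CentroidRun],
    suspects: Sequence[Suspect],
    curves: Mapping[str, CalibrationCurve] | None = None,
    internal_standards: Mapping[str, Suspect] | None = None,
) -> pd.DataFrame:
    """Data-mining branch: screen a suspect list and assign confidence levels.

    Metabolite suspects naming a parent require the parent to be in the
    suspect list too (named error otherwise); the parent's detected
    retention time feeds the elution-order rule. Level-1a suspects with a
    calibration curve are additionally quantified.
    """
    curves = curves or {}
    internal_standards = internal_standards or {}
    by_name = {s.name: s for s in suspects}
    for s in suspects:
        if s.parent is not None and s.parent not in by_name:
            raise KeyError(f"suspect {s.name!r} references unknown parent {s.parent!r}")
    rows = []
    for run_name, run in runs.items():
        parent_rts: dict[str, float] = {}
        ordered = [s for s in suspects if s.parent is None] + [
            s for s in suspects if s.parent is not None
        ]
        results = {}
        for s in ordered:
            result = screen_suspect(
                run, s, config.criteria(),
                parent_rt=parent_rts.get(s.parent) if s.parent else None,
            )
            results[s.name] = result
            if result.peak is not None:
                parent_rts[s.name] = result.peak.rt_apex
        for s in suspects:
            result = results[s.name]
            row = {
                "run": run_name,
                "suspect": s.name,
                "formula": s.formula.hill(),
                "mz": s.mz,
                "confidence": result.confidence,
                "rt": result.peak.rt_apex if result.peak else None,
                "ppm": result.mass_accuracy.value,
                "isotope_dev": result.isotope.value,
                "rt_vs_parent": result.rt_vs_parent.value,
                "fragments_found": result.fragments.passed,
                "concentration_ngl": None,
            }
            if (
                result.confidence == "1a"
                and s.name in curves
                and s.internal_standard in (internal_standards or {})
            ):
                is_area = _measure_is_area(run, internal_standards[s.internal_standard], config)
                if is_area is not None:
                    q = quantify_sample(
                        result.peak.area, is_area, curves[s.name],
                        factor=config.concentration_factor,
                    )
                    row["concentration_ngl"] = q.concentration
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path: str | Path, ndigits: int = 4) -> tuple[Path, Path]:
    """Write a report as rounded CSV plus a full-precision JSON sidecar."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    rounded = df.copy()
    for col in rounded.columns:
        if pd.api.types.is_float_dtype(rounded[col]):
            rounded[col] = rounded[col].round(ndigits)
    rounded.to_csv(csv_path, index=False)
    json_path.write_text(df.to_json(orient="records", indent=1))
    return csv_path, json_path
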