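"""Synthetic centroided dual-energy LC-HRMS runs with known ground truth.

The generator emulates what an alternating-energy QTOF acquisition of a
reverse-phase gradient run looks like after vendor centroiding:

* each planted compound contributes centroids at every channel of its
  predicted isotopologue envelope, with Gaussian-in-time elution profiles,
  ppm-scale mass jitter and multiplicative intensity noise;
* qualifier fragments appear only in high-energy scans, co-eluting with
  the precursor;
* a sparse baseline of random noise centroids covers the full mass range;
* complete validation studies (calibration series, matrix blanks,
  pre-extraction spikes, replicate days) are generated together with a
  manifest recording every planted truth value.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .chem import adduct_mz, get_adduct, isotope_pattern, parse_formula, ElementalFormula
from .spectra import HIGH, LOW, CentroidRun, CentroidSpectrum

__all__ = [
    "PlantedCompound",
    "NoiseModel",
    "StudyDesign",
    "ScanGrid",
    "generate_run",
    "generate_validation_study",
    "make_metabolite_case",
]

#: Sulfate-ester conjugation adds SO3 to the parent formula.
SULFATE = ElementalFormula({"S": 1, "O": 3})


@dataclass
class PlantedCompound:
    """Ground truth for one chromatographic peak."""

    name: str
    formula: ElementalFormula
    adduct: str = "[M-H]-"
    rt: float = 7.0  # min
    sigma: float = 0.05  # Gaussian elution width, min
    apex_intensity: float = 1e5  # base-isotopologue apex, counts
    fragments: tuple[tuple[float, float], ...] = ()  # (m/z, relative intensity 0-1)
    concentration: Optional[float] = None  # label, ug/L

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.sigma <= 0:
            raise ValueError("peak width sigma must be positive")
        if self.apex_intensity <= 0:
            raise ValueError("apex intensity must be positive")

    @property
    def mz(self) -> float:
        return adduct_mz(self.formula, self.adduct)

    @property
    def polarity(self) -> str:
        return get_adduct(self.adduct).polarity


@dataclass
class NoiseModel:
    """Stochastic imperfections of the simulated acquisition.

    ``baseline_density`` is the expected number of random noise centroids
    per Da per scan; their intensities are exponential with mean
    ``baseline_mean``. ``mass_jitter_ppm`` is the 1-sigma centroid mass
    error. ``intensity_cv`` is the multiplicative (lognormal) scan-to-scan
    intensity spread; it acts as a common factor on all channels of one
    compound in one scan (electrospray fluctuation), with an additional
    independent per-centroid term at a quarter of the CV (ion statistics),
    so isotopologue *ratios* are far more stable than raw intensities, as
    in real data. A zeroed model gives perfectly clean runs.
    """

    baseline_density: float = 0.02
    baseline_mean: float = 50.0
    mass_jitter_ppm: float = 2.0
    intensity_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("baseline_density", "baseline_mean", "mass_jitter_ppm", "intensity_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class ScanGrid:
    """Acquisition timing: alternating low/high-energy scans.

    The default emulates a 0.5-s cycle over a 20-min gradient; studies use
    narrower windows around the planted peaks to keep runs small.
    """

    rt_start: float = 0.0
    rt_end: float = 20.0
    cycle_s: float = 0.5
    mz_range: tuple[float, float] = (50.0, 1000.0)

    def cycle_times(self) -> np.ndarray:
        step = self.cycle_s / 60.0
        n = int(np.floor((self.rt_end - self.rt_start) / step)) + 1
        return self.rt_start + np.arange(n) * step


def _gaussian(t: np.ndarray | float, rt: float, sigma: float) -> np.ndarray | float:
    return np.exp(-0.5 * ((t - rt) / sigma) ** 2)


def _lognormal_unit(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal draw with the given coefficient of variation."""
    s2 = np.log(1.0 + cv * cv)
    return float(rng.lognormal(-0.5 * s2, np.sqrt(s2)))


def generate_run(
    compounds: Sequence[PlantedCompound],
    noise: NoiseModel | None = None,
    grid: ScanGrid | None = None,
    seed: int = 0,
    polarity: Optional[str] = None,
    isotope_floor: float = 0.005,
    min_intensity: float = 1.0,
) -> CentroidRun:
    """Simulate one centroided dual-energy run.

    Every compound must elute inside the scan grid (rt within the grid
    +/- 4 sigma). Precursor isotopologue envelopes appear in the
    low-energy channel, fragments only in the high-energy channel; both
    carry the same Gaussian elution profile. Centroids falling below
    ``min_intensity`` counts are dropped, as a centroiding threshold would.
    """
    noise = noise or NoiseModel()
    grid = grid or ScanGrid()
    if compounds:
        polarity = polarity or compounds[0].polarity
        for c in compounds:
            if c.polarity != polarity:
                raise ValueError(f"compound {c.name} polarity differs from run polarity")
            if not (grid.rt_start <= c.rt - 4 * c.sigma and c.rt + 4 * c.sigma <= grid.rt_end):
                raise ValueError(
                    f"scan grid [{grid.rt_start}, {grid.rt_end}] does not cover "
                    f"{c.name} at rt {c.rt} +/- 4 sigma"
                )
    polarity = polarity or "negative"
    rng = np.random.default_rng(seed)

    # per-compound ion channels: (mz, relative abundance fraction)
    channels = []
    for c in compounds:
        pattern = isotope_pattern(c.formula, abundance_floor=isotope_floor)
        delta = c.mz - c.formula.mass
        channels.append([(m + delta, a / 100.0) for m, a in zip(pattern.mz, pattern.abundance)])

    spectra: list[CentroidSpectrum] = []
    half_cycle = grid.cycle_s / 120.0  # high-energy scan offset, min
    for t in grid.cycle_times():
        for channel, rt in ((LOW, t), (HIGH, t + half_cycle)):
            mzs: list[float] = []
            ints: list[float] = []
            for c, chans in zip(compounds, channels):
                profile = float(_gaussian(rt, c.rt, c.sigma)) * c.apex_intensity
                if profile < min_intensity / 10.0:
                    continue
                if noise.intensity_cv > 0:
                    # spray fluctuation: one factor per compound per scan
                    profile *= _lognormal_unit(rng, noise.intensity_cv)
                if channel == LOW:
                    ions = [(m, profile * ab) for m, ab in chans]
                else:
                    ions = [(m, profile * rel) for m, rel in c.fragments]
                for m, i in ions:
                    if noise.intensity_cv > 0:
                        # residual per-centroid (ion-statistics) term
                        i *= _lognormal_unit(rng, noise.intensity_cv / 4.0)
                    if noise.mass_jitter_ppm > 0:
                        m += rng.normal(0.0, noise.mass_jitter_ppm * m / 1e6)
                    if i >= min_intensity:
                        mzs.append(m)
                        ints.append(i)
            if noise.baseline_density > 0:
                span = grid.mz_range[1] - grid.mz_range[0]
                n_noise = rng.poisson(noise.baseline_density * span)
                if n_noise:
                    mzs.extend(rng.uniform(*grid.mz_range, n_noise))
                    ints.extend(rng.exponential(noise.baseline_mean, n_noise))
            order = np.argsort(mzs) if mzs else []
            spectra.append(
                CentroidSpectrum(
                    rt=rt,
                    channel=channel,
                    mz=np.asarray(mzs, dtype=float)[order] if len(mzs) else np.empty(0),
                    intensity=np.asarray(ints, dtype=float)[order] if len(ints) else np.empty(0),
                )
            )
    return CentroidRun(
        polarity=polarity,
        spectra=spectra,
        metadata={
            "generator": "edcscreen.simulate",
            "seed": int(seed),
            "compounds": [c.name for c in compounds],
        },
    )


@dataclass
class StudyDesign:
    """Design of a complete synthetic validation study.

    Defaults mirror a standard validation campaign: a 13-level calibration
    series from 0.01 to 100 ug/L, triplicate spikes at 100 and 200 ng/L,
    three replicates over three days for precision, and an SPE
    preconcentration factor of 400.
    """

    calibration_levels: tuple[float, ...] = (
        0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0,
    )
    calibration_replicates: int = 1
    precision_levels: tuple[float, ...] = (0.1, 5.0, 100.0)
    precision_replicates: int = 5
    days: int = 3
    spike_levels_ngl: tuple[float, ...] = (100.0, 200.0)
    spike_replicates: int = 3
    recovery_truth: dict[str, float] = field(default_factory=dict)  # fraction per compound
    blank_background: dict[str, float] = field(default_factory=dict)  # ug/L equivalents
    concentration_factor: float = 400.0
    intra_day_cv: float = 0.05
    inter_day_cv: float = 0.03

    def __post_init__(self) -> None:
        if self.precision_replicates < 3 or self.spike_replicates < 3:
            raise ValueError("precision groups need at least 3 replicates")
        if self.concentration_factor <= 0:
            raise ValueError("concentration factor must be positive")


@dataclass
class ValidationStudy:
    """Bundle of generated runs plus the ground-truth manifest."""

    calibration: dict[tuple[float, int], CentroidRun]  # (ug/L level, replicate)
    precision: dict[tuple[float, int, int], CentroidRun]  # (level, day, replicate)
    blanks: list[CentroidRun]
    spiked: dict[tuple[float, int], CentroidRun]  # (ng/L spike, replicate)
    mobile_phase: dict[float, CentroidRun]  # ng/L spike -> standard run
    manifest: dict


def _scaled(compound: PlantedCompound, response: float, conc: float, factor_cv: float,
            rng: np.random.Generator) -> PlantedCompound:
    scale = 1.0
    if factor_cv > 0:
        scale = rng.lognormal(-0.5 * np.log(1 + factor_cv**2), np.sqrt(np.log(1 + factor_cv**2)))
    return replace(compound, apex_intensity=max(response * conc * scale, 1e-9),
                   concentration=conc)


def generate_validation_study(
    design: StudyDesign,
    compounds: Sequence[PlantedCompound],
    internal_standard: PlantedCompound,
    noise: NoiseModel | None = None,
    grid: ScanGrid | None = None,
    seed: int = 0,
    response_per_ugl: float = 2000.0,
) -> ValidationStudy:
    """Generate every run of a validation study with a truth manifest.

    Analyte apex intensity scales linearly with concentration at
    ``response_per_ugl`` counts per ug/L; the internal standard is planted
    at its fixed intensity in every run. Pre-extraction spikes are scaled
    by the per-compound truth recovery; blanks carry any configured matrix
    background. Day-to-day variation applies a common lognormal factor per
    day (the planted inter-day CV) on top of the per-replicate intra-day CV.
    """
    noise = noise or NoiseModel()
    grid = grid or ScanGrid()
    rng = np.random.default_rng(seed)
    run_seeds = iter(rng.integers(0, 2**31 - 1, size=100_000))

    def build(conc_by_name: dict[str, float], cv: float) -> CentroidRun:
        planted = [internal_standard]
        for c in compounds:
            conc = conc_by_name.get(c.name, 0.0)
            if conc > 0:
                planted.append(_scaled(c, response_per_ugl, conc, cv, rng))
        return generate_run(planted, noise, grid, seed=int(next(run_seeds)))

    calibration = {}
    for level in design.calibration_levels:
        for rep in range(design.calibration_replicates):
            calibration[(level, rep)] = build(
                {c.name: level for c in compounds}, design.intra_day_cv
            )

    precision = {}
    for level in design.precision_levels:
        for day in range(design.days):
            day_factor = 1.0
            if design.inter_day_cv > 0:
                day_factor = rng.lognormal(
                    -0.5 * np.log(1 + design.inter_day_cv**2),
                    np.sqrt(np.log(1 + design.inter_day_cv**2)),
                )
            for rep in range(design.precision_replicates):
                precision[(level, day, rep)] = build(
                    {c.name: level * day_factor for c in compounds},
                    design.intra_day_cv,
                )

    # recovery experiments: concentrations in the *extract* after SPE of a
    # spike at S ng/L are S / 1000 * factor ug/L, multiplied by the truth
    # recovery; blanks see only the matrix background.
    blanks = []
    for _ in range(design.spike_replicates):
        blanks.append(build(dict(design.blank_background), design.intra_day_cv))
    spiked = {}
    mobile_phase = {}
    for spike in design.spike_levels_ngl:
        extract_conc = spike / 1000.0 * design.concentration_factor
        mobile_phase[spike] = build(
            {c.name: extract_conc for c in compounds}, 0.0
        )
        for rep in range(design.spike_replicates):
            conc = {}
            for c in compounds:
                rc = design.recovery_truth.get(c.name, 1.0)
                conc[c.name] = extract_conc * rc + design.blank_background.get(c.name, 0.0)
            spiked[(spike, rep)] = build(conc, design.intra_day_cv)

    manifest = {
        "seed": int(seed),
        "response_per_ugl": response_per_ugl,
        "concentration_factor": design.concentration_factor,
        "compounds": {
            c.name: {
                "formula": c.formula.hill(),
                "adduct": c.adduct,
                "mz": c.mz,
                "rt": c.rt,
                "recovery_truth": design.recovery_truth.get(c.name, 1.0),
                "blank_background_ugl": design.blank_background.get(c.name, 0.0),
            }
            for c in compounds
        },
        "internal_standard": internal_standard.name,
        "calibration_levels_ugl": list(design.calibration_levels),
        "spike_levels_ngl": list(design.spike_levels_ngl),
        "intra_day_cv": design.intra_day_cv,
        "inter_day_cv": design.inter_day_cv,
    }
    return ValidationStudy(
        calibration=calibration,
        precision=precision,
        blanks=blanks,
        spiked=spiked,
        mobile_phase=mobile_phase,
        manifest=manifest,
    )


def make_metabolite_case(
    parent: PlantedCompound,
    formula_delta: ElementalFormula = SULFATE,
    rt_offset: float = -0.9,
    intensity_scale: float = 0.5,
) -> tuple[PlantedCompound, PlantedCompound]:
    """Build a (parent, phase-II metabolite) pair for screening tests.

    The metabolite formula is the parent plus ``formula_delta`` (sulfate
    ester by default) and it elutes strictly earlier than the parent, as a
    more polar conjugate does on a reverse-phase column.
    """
    if not formula_delta:
        raise ValueError("formula delta must add at least one atom")
    if rt_offset >= 0:
        raise ValueError("metabolite rt offset must be negative")
    metabolite = replace(
        parent,
        name=f"{parent.name} {'-'.join(formula_delta.counts)} conjugate"
        if formula_delta is not SULFATE else f"{parent.name} sulphate",
        formula=parent.formula + formula_delta,
        rt=parent.rt + rt_offset,
        apex_intensity=parent.apex_intensity * intensity_scale,
        fragments=(),
    )
    return parent, metabolite
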