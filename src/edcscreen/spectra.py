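"""Centroided dual-energy LC-HRMS runs: I/O, XIC extraction, peak picking.

A run is an ordered list of centroid spectra, each tagged with a retention
time and an energy channel. The "low" channel holds full-scan precursor
data and the "high" channel holds broadband collision-induced dissociation
(bbCID) fragment scans, mirroring alternating-energy QTOF acquisition.

Real data are read from centroided mzML (via pyteomics); synthetic data use
a plain-text fixture dialect — a JSON header plus a CSV of
``(rt, channel, mz, intensity)`` rows — that round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "CentroidSpectrum",
    "CentroidRun",
    "XIC",
    "ChromPeak",
    "read_run",
    "write_run",
    "extract_xic",
    "detect_peaks",
    "estimate_noise",
]

LOW, HIGH = "low", "high"


@dataclass
class CentroidSpectrum:
    """One centroided scan: retention time (min), energy channel, peak lists."""

    rt: float
    channel: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = float(self.rt)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.channel not in (LOW, HIGH):
            raise ValueError(f"unknown energy channel {self.channel!r}")
        if self.mz.size != self.intensity.size:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz)
            self.mz, self.intensity = self.mz[order], self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative centroid intensity")


@dataclass
class CentroidRun:
    """A time-ordered centroided LC-HRMS acquisition of one polarity."""

    polarity: str
    spectra: list[CentroidSpectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        self.spectra = sorted(self.spectra, key=lambda s: s.rt)

    def channel_spectra(self, channel: str) -> list[CentroidSpectrum]:
        return [s for s in self.spectra if s.channel == channel]

    @property
    def rt_range(self) -> tuple[float, float]:
        return self.spectra[0].rt, self.spectra[-1].rt


@dataclass
class XIC:
    """Extracted ion chromatogram at a fixed mass window."""

    target_mz: float
    window: float
    channel: str
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)


@dataclass
class ChromPeak:
    """A chromatographic peak on an XIC.

    Height is the raw trace at the apex, area the trapezoidal integral of
    the raw trace between the boundaries (intensity·min), and the
    signal-to-noise ratio uses the robust noise level of the peak-free trace.
    """

    rt_apex: float
    height: float
    area: float
    rt_left: float
    rt_right: float
    snr: float

    def __post_init__(self) -> None:
        if not self.rt_left < self.rt_apex < self.rt_right:
            # apex may sit on a boundary scan for 3-point peaks; tolerate ties
            if not self.rt_left <= self.rt_apex <= self.rt_right:
                raise ValueError("peak boundaries must bracket the apex")


# ---------------------------------------------------------------------------
# I/O


def write_run(run: CentroidRun, basepath: str | Path) -> tuple[Path, Path]:
    """Write a run in the fixture dialect: ``<base>.json`` + ``<base>.csv``.

    Floats are serialized with ``repr`` so the round-trip is bit-exact.
    """
    base = Path(basepath)
    header = {
        "polarity": run.polarity,
        "channels": sorted({s.channel for s in run.spectra}),
        "metadata": run.metadata,
        "n_spectra": len(run.spectra),
    }
    json_path = base.with_suffix(".json")
    csv_path = base.with_suffix(".csv")
    json_path.write_text(json.dumps(header, indent=1, sort_keys=True) + "\n")
    lines = ["rt,channel,mz,intensity"]
    for s in run.spectra:
        if s.mz.size == 0:
            lines.append(f"{float(s.rt)!r},{s.channel},,")
        for m, i in zip(s.mz, s.intensity):
            lines.append(f"{float(s.rt)!r},{s.channel},{float(m)!r},{float(i)!r}")
    csv_path.write_text("\n".join(lines) + "\n")
    return json_path, csv_path


def _read_fixture(base: Path) -> CentroidRun:
    header = json.loads(base.with_suffix(".json").read_text())
    spectra: dict[tuple[float, str], tuple[list[float], list[float]]] = {}
    with open(base.with_suffix(".csv")) as fh:
        next(fh)  # header row
        for line in fh:
            rt_s, channel, mz_s, int_s = line.rstrip("\n").split(",")
            key = (float(rt_s), channel)
            mzs, ints = spectra.setdefault(key, ([], []))
            if mz_s:
                mzs.append(float(mz_s))
                ints.append(float(int_s))
    return CentroidRun(
        polarity=header["polarity"],
        spectra=[
            CentroidSpectrum(rt, ch, np.array(mzs), np.array(ints))
            for (rt, ch), (mzs, ints) in spectra.items()
        ],
        metadata=header.get("metadata", {}),
    )


def _read_mzml(path: Path) -> CentroidRun:
    from pyteomics import mzml as pymzml_reader

    spectra = []
    polarity = None
    with pymzml_reader.MzML(str(path)) as reader:
        for scan in reader:
            if "profile spectrum" in scan:
                raise ValueError("profile-mode mzML is unsupported; centroid first")
            if "negative scan" in scan:
                pol = "negative"
            elif "positive scan" in scan:
                pol = "positive"
            else:
                raise ValueError("spectrum without polarity annotation")
            polarity = polarity or pol
            ms_level = scan.get("ms level", 1)
            channel = LOW if ms_level == 1 else HIGH
            rt = float(scan["scanList"]["scan"][0]["scan start time"])
            spectra.append(
                CentroidSpectrum(rt, channel, scan["m/z array"], scan["intensity array"])
            )
    if polarity is None:
        raise ValueError(f"no spectra found in {path}")
    return CentroidRun(polarity=polarity, spectra=spectra, metadata={"source": str(path)})


def read_run(path: str | Path, format: str | None = None) -> CentroidRun:
    """Read a centroided run from mzML or the fixture dialect.

    mzML MS1 scans map to the low-energy channel and all-ion-fragmentation
    (ms level 2 without isolation) scans to the high-energy channel.
    """
    path = Path(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "fixture"
    if format == "mzml":
        return _read_mzml(path)
    if format == "fixture":
        return _read_fixture(path.with_suffix(""))
    raise ValueError(f"unknown run format {format!r}")


# ---------------------------------------------------------------------------
# XIC extraction and peak detection


def extract_xic(
    run: CentroidRun, mz: float, window: float = 0.005, channel: str = LOW
) -> XIC:
    """Sum centroid intensities within ``|mz_i - mz| <= window/2`` per scan.

    ``window`` is the full mass-window width (the conventional 0.005-Da
    window means +/- 0.0025 Da). Spectra of the other energy channel are
    ignored entirely.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    spectra = run.channel_spectra(channel)
    if not spectra:
        raise ValueError(f"run has no spectra in channel {channel!r}")
    half = window / 2.0
    rt = np.array([s.rt for s in spectra])
    intensity = np.zeros(len(spectra))
    for k, s in enumerate(spectra):
        lo = np.searchsorted(s.mz, mz - half, side="left")
        hi = np.searchsorted(s.mz, mz + half, side="right")
        if hi > lo:
            intensity[k] = s.intensity[lo:hi].sum()
    return XIC(target_mz=mz, window=window, channel=channel, rt=rt, intensity=intensity)


def estimate_noise(xic: XIC, exclude: Sequence[ChromPeak] = ()) -> float:
    """Robust noise level of the peak-free trace.

    Uses 1.4826 x the median absolute deviation of intensities outside all
    excluded peak windows (the Gaussian-consistent MAD scale). Requires at
    least 10 peak-free scans.
    """
    mask = np.ones(xic.rt.size, dtype=bool)
    for p in exclude:
        mask &= ~((xic.rt >= p.rt_left) & (xic.rt <= p.rt_right))
    quiet = xic.intensity[mask]
    if quiet.size < 10:
        raise ValueError("fewer than 10 peak-free scans for noise estimation")
    return float(1.4826 * np.median(np.abs(quiet - np.median(quiet))))


def _robust_noise(y: np.ndarray) -> float:
    return float(1.4826 * np.median(np.abs(y - np.median(y))))


def detect_peaks(
    xic: XIC,
    min_snr: float = 3.0,
    min_points: int = 5,
    smooth_window: int = 5,
) -> list[ChromPeak]:
    """Detect chromatographic peaks on an XIC.

    Apexes are local maxima of a Savitzky-Golay-smoothed trace (2nd-order
    polynomial over ``smooth_window`` scans). Neighbouring maxima whose
    separating valley stays above half the lower apex are treated as one
    noisy peak. Each boundary is the nearer of the valley minimum toward
    the adjacent peak and the point where the smoothed trace falls to 1% of
    the apex; height and trapezoidal area come from the raw trace between
    the boundaries. Candidates are screened against a whole-trace robust
    noise estimate, then the final signal-to-noise ratio uses the
    peak-free trace only. Peaks never overlap; an empty list is returned
    when nothing reaches ``min_snr``.
    """
    y = xic.intensity
    if y.size < max(min_points, 3):
        return []
    if not np.any(y > 0):
        return []
    win = min(smooth_window, y.size if y.size % 2 else y.size - 1)
    smooth = savgol_filter(y, window_length=win, polyorder=2) if win >= 5 else y.astype(float)
    smooth = np.clip(smooth, 0.0, None)

    noise0 = _robust_noise(y)
    floor = min_snr * noise0 if noise0 > 0 else 0.0
    maxima = [
        k for k in range(1, y.size - 1)
        if smooth[k] > floor and smooth[k] > 0
        and smooth[k] >= smooth[k - 1] and smooth[k] > smooth[k + 1]
    ]
    if not maxima:
        return []
    # merge apexes separated by a shallow valley (> 50% of the lower apex)
    apexes = [maxima[0]]
    for k in maxima[1:]:
        valley = smooth[apexes[-1]:k + 1].min()
        if valley > 0.5 * min(smooth[apexes[-1]], smooth[k]):
            if smooth[k] > smooth[apexes[-1]]:
                apexes[-1] = k
        else:
            apexes.append(k)

    spans: list[tuple[int, int, int]] = []
    for i, apex in enumerate(apexes):
        tail = 0.01 * smooth[apex]
        lo_lim = 0 if i == 0 else int(apexes[i - 1] + np.argmin(smooth[apexes[i - 1]:apex + 1]))
        left = apex
        while left > lo_lim and smooth[left - 1] > tail:
            left -= 1
        hi_lim = y.size - 1 if i == len(apexes) - 1 else int(
            apex + np.argmin(smooth[apex:apexes[i + 1] + 1])
        )
        right = apex
        while right < hi_lim and smooth[right + 1] > tail:
            right += 1
        if right - left + 1 >= 3:
            raw_apex = int(left + np.argmax(y[left:right + 1]))
            if y[raw_apex] > 0:
                spans.append((left, raw_apex, right))

    prelim = [
        ChromPeak(
            rt_apex=float(xic.rt[a]),
            height=float(y[a]),
            area=float(np.trapezoid(y[l:r + 1], xic.rt[l:r + 1])),
            rt_left=float(xic.rt[l]),
            rt_right=float(xic.rt[r]),
            snr=float("inf"),
        )
        for l, a, r in spans
    ]
    if not prelim:
        return []
    try:
        noise = estimate_noise(xic, exclude=prelim)
    except ValueError:
        noise = noise0
    peaks = []
    for p in prelim:
        p.snr = float(p.height / noise) if noise > 0 else float("inf")
        if p.snr >= min_snr:
            peaks.append(p)
    return peaks
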