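"""Elemental-formula arithmetic, adduct m/z and isotope-pattern prediction.

This module is the mathematical core of suspect identification: given an
elemental formula (Hill notation, e.g. ``C15H16O5S``) it computes the
monoisotopic mass, the m/z of singly charged adducts ([M-H]-, [M+H]+),
signed ppm mass errors, and the isotopologue abundance envelope expected
for a 0.005-Da extraction window.

Isotope masses and abundances are pinned to a published table shipped as
package data (``data/isotopes.csv``); every derived number in the package
traces back to those constants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "Adduct",
    "ADDUCTS",
    "IsotopePattern",
    "isotope_table",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "isotope_pattern",
    "pattern_deviation",
]

#: Mass of a proton in Da (H atom minus one electron).
PROTON_MASS = 1.00727646688
#: Mass of an electron in Da.
ELECTRON_MASS = 0.00054857990907

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formulas or unknown element symbols."""


@lru_cache(maxsize=1)
def isotope_table() -> dict[str, list[tuple[float, float]]]:
    """Load the embedded isotope table.

    Returns a map element symbol -> list of ``(exact mass Da, abundance
    fraction)`` sorted by increasing mass. Abundances per element sum to 1.
    """
    table: dict[str, list[tuple[float, float]]] = {}
    text = resources.files("edcscreen.data").joinpath("isotopes.csv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element,"):
            continue
        element, _isotope, mass, abundance = line.split(",")
        table.setdefault(element, []).append((float(mass), float(abundance)))
    for element, isotopes in table.items():
        isotopes.sort()
        total = sum(a for _, a in isotopes)
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"abundances for {element} sum to {total}")
    return table


@dataclass(frozen=True)
class ElementalFormula:
    """A neutral molecular formula as an element -> count map.

    Counts are strictly positive; the empty formula has mass 0.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        table = isotope_table()
        clean = {}
        for element, count in self.counts.items():
            if element not in table:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(count, (int, np.integer)) or count < 1:
                raise FormulaError(f"invalid count for {element}: {count!r}")
            clean[element] = int(count)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalFormula(merged)

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Serialize in Hill order (C, H, then alphabetical)."""
        parts = []
        order = [e for e in ("C", "H") if e in self.counts]
        order += sorted(e for e in self.counts if e not in ("C", "H"))
        for element in order:
            n = self.counts[element]
            parts.append(element + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``C12H7Cl3O2``.

    Raises :class:`FormulaError` naming the offending token for unknown
    elements, explicit zero counts or any leftover characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed token at {text[pos:match.start()]!r}")
        if not match.group(0):
            continue
        element, digits = match.group(1), match.group(2)
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for element {element!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed token at {text[pos:]!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula in Da."""
    if isinstance(f, str):
        f = parse_formula(f)
    table = isotope_table()
    total = 0.0
    for element, count in f.counts.items():
        mass, _ = max(table[element], key=lambda ma: ma[1])
        total += count * mass
    return total


@dataclass(frozen=True)
class Adduct:
    """A singly charged ionisation adduct.

    ``mass_delta`` is added to the neutral monoisotopic mass; it carries the
    proton-mass convention, so electron bookkeeping is already included
    ([M-H]- loses an H atom and gains an electron = loses one proton mass).
    """

    name: str
    mass_delta: float
    charge: int
    polarity: str

    def mz(self, neutral_mass: float) -> float:
        return neutral_mass + self.mass_delta


ADDUCTS: dict[str, Adduct] = {
    "[M-H]-": Adduct("[M-H]-", -PROTON_MASS, -1, "negative"),
    "[M+H]+": Adduct("[M+H]+", +PROTON_MASS, +1, "positive"),
    "[M]-": Adduct("[M]-", +ELECTRON_MASS, -1, "negative"),
    "[M]+": Adduct("[M]+", -ELECTRON_MASS, +1, "positive"),
}


def get_adduct(name: str) -> Adduct:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise KeyError(
            f"unsupported adduct {name!r}; known: {sorted(ADDUCTS)}"
        ) from None


def adduct_mz(f: ElementalFormula | str, adduct: Adduct | str) -> float:
    """m/z of a singly charged adduct of formula ``f``."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return adduct.mz(monoisotopic_mass(f))


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue envelope as (mass, relative abundance % of base) channels.

    Masses are strictly increasing, the base channel has abundance exactly
    100 and all channels are in (0, 100].
    """

    mz: tuple[float, ...]
    abundance: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.abundance) or not self.mz:
            raise ValueError("pattern needs matching non-empty channels")
        if any(b <= a for a, b in zip(self.mz, self.mz[1:])):
            raise ValueError("channel masses must be strictly increasing")

    @property
    def base_index(self) -> int:
        return int(np.argmax(self.abundance))

    def shifted(self, delta: float) -> "IsotopePattern":
        """Pattern with every channel mass shifted by ``delta`` Da (adducts)."""
        return IsotopePattern(tuple(m + delta for m in self.mz), self.abundance)


def _merge_channels(
    masses: np.ndarray, probs: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge channels closer than ``tol`` Da, abundance-weighted."""
    order = np.argsort(masses)
    masses, probs = masses[order], probs[order]
    out_m: list[float] = []
    out_p: list[float] = []
    for m, p in zip(masses, probs):
        if out_m and m - out_m[-1] < tol:
            total = out_p[-1] + p
            out_m[-1] = (out_m[-1] * out_p[-1] + m * p) / total
            out_p[-1] = total
        else:
            out_m.append(m)
            out_p.append(p)
    return np.asarray(out_m), np.asarray(out_p)


def _convolve(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    tol: float,
    prune: float,
) -> tuple[np.ndarray, np.ndarray]:
    masses = (a[0][:, None] + b[0][None, :]).ravel()
    probs = (a[1][:, None] * b[1][None, :]).ravel()
    masses, probs = _merge_channels(masses, probs, tol)
    keep = probs > prune
    return masses[keep], probs[keep]


def _element_distribution(
    element: str, count: int, tol: float, prune: float
) -> tuple[np.ndarray, np.ndarray]:
    """Isotopologue distribution of ``count`` atoms of one element.

    Binary-exponentiation convolution keeps the channel count small even
    for dozens of atoms.
    """
    isotopes = isotope_table()[element]
    base = (
        np.array([m for m, _ in isotopes]),
        np.array([a for _, a in isotopes]),
    )
    result: tuple[np.ndarray, np.ndarray] | None = None
    power = base
    n = count
    while n:
        if n & 1:
            result = power if result is None else _convolve(result, power, tol, prune)
        n >>= 1
        if n:
            power = _convolve(power, power, tol, prune)
    assert result is not None
    return result


def isotope_pattern(
    f: ElementalFormula | str,
    abundance_floor: float = 0.005,
    merge_tol: float = 0.0025,
) -> IsotopePattern:
    """Predict the isotopologue envelope of a neutral formula.

    Per-element isotopologue distributions are convolved element-wise;
    channels whose masses differ by less than ``merge_tol`` Da (half the
    default 0.005-Da extraction window) are merged abundance-weighted, so
    the pattern is what a narrow-window XIC would actually resolve.
    Channels below ``abundance_floor`` (fraction of the base channel) are
    pruned and the envelope is normalized to base = 100.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if not f:
        raise FormulaError("isotope pattern of an empty formula")
    if not 0 <= abundance_floor < 1:
        raise ValueError("abundance_floor must be in [0, 1)")
    dist: tuple[np.ndarray, np.ndarray] | None = None
    for element, count in sorted(f.counts.items()):
        part = _element_distribution(element, count, merge_tol, prune=1e-12)
        dist = part if dist is None else _convolve(dist, part, merge_tol, prune=1e-12)
    assert dist is not None
    masses, probs = dist
    base = probs.max()
    keep = probs >= abundance_floor * base
    masses, probs = masses[keep], probs[keep]
    abundance = probs / base * 100.0
    return IsotopePattern(tuple(masses), tuple(abundance))


def pattern_deviation(
    predicted: IsotopePattern,
    observed: Sequence[tuple[float, float]] | Iterable[tuple[float, float]],
    match_tol: float = 0.0025,
) -> float:
    """Worst absolute isotope-abundance deviation, in percentage points.

    ``observed`` is a list of (m/z, intensity) channel measurements. Both
    envelopes are normalized so their base channel is 100; the deviation is
    the maximum |observed - predicted| over predicted channels, with a
    predicted channel that has no observed match counting as a deviation
    equal to its full predicted abundance. Raises ``ValueError`` when the
    predicted base channel itself has no observed counterpart.
    """
    observed = [(float(m), float(i)) for m, i in observed]
    if not observed:
        raise ValueError("no observed channels")
    matched: list[float | None] = []
    for target in predicted.mz:
        candidates = [i for m, i in observed if abs(m - target) <= match_tol]
        matched.append(max(candidates) if candidates else None)
    base_obs = matched[predicted.base_index]
    if base_obs is None or base_obs <= 0:
        raise ValueError("observed data has no channel matching the base peak")
    worst = 0.0
    for pred_ab, obs in zip(predicted.abundance, matched):
        if obs is None:
            worst = max(worst, pred_ab)
        else:
            worst = max(worst, abs(obs / base_obs * 100.0 - pred_ab))
    return worst
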