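"""Shared fixtures and the independent brute-force isotopologue oracle."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from edcscreen.chem import isotope_table, parse_formula
from edcscreen.simulate import NoiseModel, PlantedCompound, ScanGrid, generate_run


def brute_force_pattern(formula, merge_tol: float = 0.0025, floor: float = 0.005):
    """Exhaustive isotopologue enumeration, independent of the convolution path.

    Enumerates every multiset of isotopes per element with exact multinomial
    probabilities, merges channels within ``merge_tol`` Da abundance-weighted,
    prunes below ``floor`` of the base and normalizes the base to 100.
    Returns (masses, abundances) arrays. Only feasible for small formulas.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    table = isotope_table()
    element_states = []
    for element, count in sorted(formula.counts.items()):
        isotopes = table[element]
        states = []
        for combo in itertools.combinations_with_replacement(range(len(isotopes)), count):
            mass = sum(isotopes[i][0] for i in combo)
            prob = math.factorial(count)
            for i in set(combo):
                k = combo.count(i)
                prob //= math.factorial(k)
            p = float(prob)
            for i in combo:
                p *= isotopes[i][1]
            states.append((mass, p))
        element_states.append(states)
    channels: dict[float, float] = {}
    masses_list = []
    probs_list = []
    for combo in itertools.product(*element_states):
        masses_list.append(sum(m for m, _ in combo))
        probs_list.append(math.prod(p for _, p in combo))
    order = np.argsort(masses_list)
    masses = np.asarray(masses_list)[order]
    probs = np.asarray(probs_list)[order]
    out_m: list[float] = []
    out_p: list[float] = []
    for m, p in zip(masses, probs):
        if out_m and m - out_m[-1] < merge_tol:
            total = out_p[-1] + p
            out_m[-1] = (out_m[-1] * out_p[-1] + m * p) / total
            out_p[-1] = total
        else:
            out_m.append(float(m))
            out_p.append(float(p))
    out_m = np.asarray(out_m)
    out_p = np.asarray(out_p)
    base = out_p.max()
    keep = out_p >= floor * base
    return out_m[keep], out_p[keep] / base * 100.0


@pytest.fixture(scope="session")
def narrow_grid() -> ScanGrid:
    """A small scan grid around 1-2 min keeping test runs fast."""
    return ScanGrid(rt_start=0.3, rt_end=2.5, cycle_s=0.5, mz_range=(100.0, 400.0))


@pytest.fixture(scope="session")
def bpa_metabolite_run(narrow_grid):
    """Run with a BPA-like parent and its planted sulfate conjugate.

    Parent elutes at 1.7 min, the conjugate at 0.8 min, under default
    (mild) noise; the conjugate carries a qualifier fragment in the
    high-energy channel.
    """
    parent = PlantedCompound(
        "BPA", "C15H16O2", rt=1.7, sigma=0.05, apex_intensity=2e5,
    )
    metabolite = PlantedCompound(
        "BPA sulphate", "C15H16O5S", rt=0.8, sigma=0.05, apex_intensity=1e5,
        fragments=((227.1078, 0.4),),
    )
    return generate_run([parent, metabolite], NoiseModel(), narrow_grid, seed=11)
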