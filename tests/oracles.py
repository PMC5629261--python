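"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's convolution route: the distribution
of a formula is obtained by direct enumeration of isotope assignments,
either atom by atom (exponential, tiny formulas only) or per element over
isotope multisets with multinomial coefficients (feasible to tens of
atoms).  Both aggregate by total neutron excess with abundance-weighted
mean masses, the same convention the package documents.
"""

from __future__ import annotations

import itertools
import math

from micquant.chemistry import ChemicalFormula, ElementIsotopeTable


def enumerate_by_atom(formula: ChemicalFormula,
                      tables: ElementIsotopeTable | None = None) -> dict[int, tuple[float, float]]:
    """shift -> (mean mass, abundance) by per-atom cartesian product."""
    tables = tables or ElementIsotopeTable()
    atoms = []
    for key in sorted(formula):
        atoms.extend([tables[key]] * formula[key])
    agg: dict[int, list[float]] = {}
    for combo in itertools.product(*atoms):
        shift = sum(i.neutron_shift for i in combo)
        ab = math.prod(i.abundance for i in combo)
        mass = sum(i.mass for i in combo)
        cell = agg.setdefault(shift, [0.0, 0.0])
        cell[0] += ab
        cell[1] += ab * mass
    return {s: (w / p, p) for s, (p, w) in agg.items()}


def enumerate_by_multiset(formula: ChemicalFormula,
                          tables: ElementIsotopeTable | None = None) -> dict[int, tuple[float, float]]:
    """shift -> (mean mass, abundance) by per-element multiset enumeration.

    For each element the isotope assignments of its n atoms are enumerated
    as multisets weighted by multinomial coefficients; elements combine by
    a cartesian product over their aggregates.
    """
    tables = tables or ElementIsotopeTable()
    per_element: list[list[tuple[int, float, float]]] = []  # (shift, ab, mass)
    for key in sorted(formula):
        isotopes = tables[key]
        n = formula[key]
        entries: list[tuple[int, float, float]] = []
        for combo in itertools.combinations_with_replacement(range(len(isotopes)), n):
            counts = [combo.count(i) for i in range(len(isotopes))]
            coeff = math.factorial(n)
            for c in counts:
                coeff //= math.factorial(c)
            ab = coeff * math.prod(
                isotopes[i].abundance ** c for i, c in enumerate(counts))
            mass = sum(isotopes[i].mass * c for i, c in enumerate(counts))
            shift = sum(isotopes[i].neutron_shift * c for i, c in enumerate(counts))
            entries.append((shift, ab, mass))
        per_element.append(entries)
    agg: dict[int, list[float]] = {}
    for combo in itertools.product(*per_element):
        shift = sum(e[0] for e in combo)
        ab = math.prod(e[1] for e in combo)
        mass = sum(e[2] for e in combo)
        cell = agg.setdefault(shift, [0.0, 0.0])
        cell[0] += ab
        cell[1] += ab * mass
    return {s: (w / p, p) for s, (p, w) in agg.items()}
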