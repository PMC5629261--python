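"""Theoretical isotope patterns by exact multinomial convolution.

The isotopologue distribution of a formula is the convolution of the
per-atom isotope distributions of every atom, aggregated by total neutron
excess over the all-lightest (monoisotopic) species.  Aggregation carries
the abundance-weighted mean mass of each neutron-excess class exactly: for
two partial distributions the weighted mass sums combine linearly, so no
precision is lost by aggregating early.  Fine structure (distinct masses
within one neutron-excess class, e.g. 13C vs 15N substitutions) is not
resolved by default, matching the resolution regime of Orbitrap-class
instruments.

Charged patterns place each isotopologue at (M + z·m_proton)/z, rescale
intensities relative to the most intense peak (r_k, max = 1), and prune
peaks below the matching threshold (default 1 % of the maximum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .chemistry import (
    PROTON_MASS,
    ChemicalFormula,
    ElementIsotopeTable,
    Isotope,
    LabelPool,
    MoleculeSpec,
)

__all__ = [
    "IsotopologueDistribution",
    "IsotopePattern",
    "PatternLibrary",
    "convolve_distribution",
    "build_pattern",
    "build_library",
    "DEFAULT_MATCHING_THRESHOLD",
    "INTERMEDIATE_PRUNE",
]

DEFAULT_MATCHING_THRESHOLD = 0.01  # fraction of the most intense isotope peak
INTERMEDIATE_PRUNE = 1e-12  # absolute abundance cutoff during convolution


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Neutral isotopologue distribution aggregated by neutron excess.

    ``masses`` are abundance-weighted mean masses per neutron-excess class
    (strictly increasing); ``abundances`` sum to 1 (within 1e-9) before any
    pruning.
    """

    neutron_shifts: tuple[int, ...]
    masses: tuple[float, ...]
    abundances: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.masses)


# a partial distribution: neutron shift -> [abundance, abundance-weighted mass sum]
_Partial = dict[int, list[float]]


def _convolve(a: _Partial, b: _Partial) -> _Partial:
    out: _Partial = {}
    for s1, (p1, w1) in a.items():
        for s2, (p2, w2) in b.items():
            p = p1 * p2
            if p < INTERMEDIATE_PRUNE:
                continue
            # weighted mass sums combine exactly: sum a_i a_j (m_i + m_j)
            w = p1 * w2 + w1 * p2
            cell = out.setdefault(s1 + s2, [0.0, 0.0])
            cell[0] += p
            cell[1] += w
    return out


def _element_power(isotopes: Sequence[Isotope], n: int) -> _Partial:
    """Distribution of ``n`` atoms of one element, by binary powering."""
    base: _Partial = {
        i.neutron_shift: [i.abundance, i.abundance * i.mass] for i in isotopes
    }
    result: _Partial = {0: [1.0, 0.0]}
    while n:
        if n & 1:
            result = _convolve(result, base)
        n >>= 1
        if n:
            base = _convolve(base, base)
    return result


def convolve_distribution(
    formula: ChemicalFormula,
    tables: ElementIsotopeTable | None = None,
) -> IsotopologueDistribution:
    """Exact isotopologue distribution of ``formula``.

    Every key of the formula (element symbol or label-pool id) must resolve
    in ``tables``.  Raises ``ValueError`` on an empty formula.
    """
    if len(formula) == 0:
        raise ValueError("cannot compute a distribution for an empty formula")
    tables = tables or ElementIsotopeTable()
    total: _Partial = {0: [1.0, 0.0]}
    for key in sorted(formula):
        total = _convolve(total, _element_power(tables[key], formula[key]))
    shifts = sorted(total)
    masses, abundances = [], []
    for s in shifts:
        p, w = total[s]
        masses.append(w / p)
        abundances.append(p)
    return IsotopologueDistribution(
        neutron_shifts=tuple(shifts), masses=tuple(masses), abundances=tuple(abundances)
    )


@dataclass(frozen=True)
class IsotopePattern:
    """Charged, threshold-pruned theoretical pattern for one molecule state.

    ``rel_intensities`` (r_k) are scaled so the most intense retained peak is
    exactly 1; every retained peak satisfies r_k >= the matching threshold.
    """

    formula_key: str
    charge: int
    label_percentile: float
    mzs: tuple[float, ...]
    rel_intensities: tuple[float, ...]

    @property
    def key(self) -> tuple[str, int, float]:
        return (self.formula_key, self.charge, self.label_percentile)

    @property
    def most_intense_mz(self) -> float:
        return self.mzs[int(np.argmax(self.rel_intensities))]

    @property
    def monoisotopic_mz(self) -> float:
        return self.mzs[0]

    def __len__(self) -> int:
        return len(self.mzs)


def build_pattern(
    dist: IsotopologueDistribution,
    charge: int,
    threshold: float = DEFAULT_MATCHING_THRESHOLD,
    formula_key: str = "",
    label_percentile: float = 0.0,
) -> IsotopePattern:
    """Charged pattern from a neutral distribution.

    m/z = (M + z·m_proton)/z (positive mode, proton charge carrier only);
    intensities are rescaled to max = 1 before the threshold prune, so at
    least one peak always survives.
    """
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    if len(dist) == 0:
        raise ValueError("empty distribution")
    ab = np.asarray(dist.abundances, dtype=float)
    rel = ab / ab.max()
    keep = rel >= threshold
    assert keep.any(), "rescaling to max=1 guarantees one surviving peak"
    mz = (np.asarray(dist.masses, dtype=float)[keep] + charge * PROTON_MASS) / charge
    return IsotopePattern(
        formula_key=formula_key,
        charge=charge,
        label_percentile=label_percentile,
        mzs=tuple(mz),
        rel_intensities=tuple(rel[keep]),
    )


class PatternLibrary:
    """Deterministic mapping (formula key, charge, label percentile) → pattern.

    Maintains a sorted index over each pattern's most intense m/z so that,
    given one spectrum, candidate patterns are found by binary search rather
    than a scan of the whole library.
    """

    def __init__(self, patterns: Iterable[IsotopePattern] = ()):
        self._patterns: dict[tuple[str, int, float], IsotopePattern] = {}
        for p in patterns:
            self._patterns[p.key] = p
        self._index_dirty = True
        self._anchor_mzs: np.ndarray = np.empty(0)
        self._anchor_keys: list[tuple[str, int, float]] = []

    def add(self, pattern: IsotopePattern) -> None:
        self._patterns[pattern.key] = pattern
        self._index_dirty = True

    def _rebuild_index(self) -> None:
        items = sorted(self._patterns.values(), key=lambda p: p.most_intense_mz)
        self._anchor_mzs = np.array([p.most_intense_mz for p in items])
        self._anchor_keys = [p.key for p in items]
        self._index_dirty = False

    def candidates(self, spectrum_mzs: np.ndarray, alpha_ppm: float,
                   machine_offset_ppm: float = 0.0) -> list[IsotopePattern]:
        """Patterns whose most intense peak has a measured peak within α ppm."""
        if self._index_dirty:
            self._rebuild_index()
        if len(self._anchor_mzs) == 0 or len(spectrum_mzs) == 0:
            return []
        # measured m/z corrected for the machine offset before the tolerance check
        corrected = np.asarray(spectrum_mzs) * (1.0 - machine_offset_ppm * 1e-6)
        tol = self._anchor_mzs * alpha_ppm * 1e-6
        lo = np.searchsorted(corrected, self._anchor_mzs - tol, side="left")
        hi = np.searchsorted(corrected, self._anchor_mzs + tol, side="right")
        return [self._patterns[self._anchor_keys[i]] for i in np.nonzero(hi > lo)[0]]

    def __getitem__(self, key: tuple[str, int, float]) -> IsotopePattern:
        return self._patterns[key]

    def __contains__(self, key: tuple[str, int, float]) -> bool:
        return key in self._patterns

    def __len__(self) -> int:
        return len(self._patterns)

    def __iter__(self) -> Iterator[IsotopePattern]:
        return iter(sorted(self._patterns.values(), key=lambda p: p.key))

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for p in self:
                fh.write(json.dumps({
                    "formula": p.formula_key, "charge": p.charge,
                    "label_percentile": p.label_percentile,
                    "mzs": list(p.mzs), "rel_intensities": list(p.rel_intensities),
                }) + "\n")

    @classmethod
    def from_jsonl(cls, path: str) -> "PatternLibrary":
        lib = cls()
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                lib.add(IsotopePattern(
                    formula_key=d["formula"], charge=int(d["charge"]),
                    label_percentile=float(d["label_percentile"]),
                    mzs=tuple(d["mzs"]), rel_intensities=tuple(d["rel_intensities"]),
                ))
        return lib


def labeled_formula(molecule: MoleculeSpec, percentile: float,
                    zero_is_natural: bool = True) -> tuple[ChemicalFormula, ElementIsotopeTable]:
    """Formula and isotope tables for one labeling state of a molecule.

    At percentile 0 the unlabeled channel uses natural abundance by default
    (``zero_is_natural``); set False to model a pure-light-isotope pool
    instead — the two differ by the small natural heavy fraction.
    """
    tables = ElementIsotopeTable()
    element = molecule.label_element
    if element is None or (percentile == 0.0 and zero_is_natural):
        return molecule.formula, tables
    pool = LabelPool.enriched(element, percentile)
    if molecule.formula.get(element, 0) == 0:
        return molecule.formula, tables
    from .chemistry import apply_label

    return apply_label(molecule.formula, pool), tables.with_pool(pool)


def build_library(
    molecules: Sequence[MoleculeSpec],
    charges: Sequence[int],
    percentiles: Sequence[float] | None = None,
    threshold: float = DEFAULT_MATCHING_THRESHOLD,
    label_element: str | None = "N",
    zero_is_natural: bool = True,
) -> PatternLibrary:
    """Cartesian pattern library: molecules × charges × label percentiles.

    ``percentiles=None`` uses the full 0–100 grid in steps of 1, the default
    resolution for pulse/pulse-chase searches (two orders of magnitude more
    patterns than a label-free library).  Duplicate (formula, z, percentile)
    keys collapse silently — the pattern is identical by construction.
    """
    if not molecules or not charges:
        raise ValueError("molecules and charges must be non-empty")
    if percentiles is None:
        percentiles = list(range(0, 101))
    library = PatternLibrary()
    for mol in molecules:
        base = MoleculeSpec(
            identity=mol.identity, formula=mol.formula,
            label_element=mol.label_element or label_element,
        )
        key = mol.formula.to_string()
        for p in percentiles:
            formula, tables = labeled_formula(base, float(p), zero_is_natural)
            dist = convolve_distribution(formula, tables)
            for z in charges:
                library.add(build_pattern(
                    dist, z, threshold=threshold, formula_key=key,
                    label_percentile=float(p),
                ))
    return library
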