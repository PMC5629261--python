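"""Chemical formulas, peptide compositions, and isotope-labeled element pools.

Molecules are treated uniformly as chemical formulas: a peptide, a
ribonucleoside, or any other analyte reduces to a mapping from element
symbols (or label-pool ids) to atom counts.  Metabolic labels (e.g. growth
on :sup:`15`\\ N media) change the isotope distribution of an element's whole
cellular pool; fixed labels (chemical or amino-acid based) are independent of
the cellular pool.  Both are represented as :class:`LabelPool` objects — an
extra "element" whose isotope distribution is the enriched one — so that the
downstream convolution needs no special cases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "Isotope",
    "ElementIsotopeTable",
    "NATURAL_ISOTOPES",
    "LabelPool",
    "ChemicalFormula",
    "MoleculeSpec",
    "parse_formula",
    "peptide_to_formula",
    "parse_molecule",
    "apply_label",
    "monoisotopic_mass",
    "PROTON_MASS",
    "AMINO_ACID_COMPOSITIONS",
    "MODIFICATIONS",
    "WATER",
]

PROTON_MASS = 1.007276466  # Da, charge carrier in positive-mode ESI


@dataclass(frozen=True)
class Isotope:
    """One isotope of an element.

    ``neutron_shift`` is the neutron count relative to the lightest isotope
    of the same element; it indexes the isotopologue aggregation downstream.
    """

    mass: float  # Da
    abundance: float  # fraction in [0, 1]
    neutron_shift: int


def _iso(masses_abundances: list[tuple[float, float]]) -> tuple[Isotope, ...]:
    base = round(masses_abundances[0][0])
    return tuple(
        Isotope(mass=m, abundance=a, neutron_shift=round(m) - base)
        for m, a in masses_abundances
    )


# Static snapshot of IUPAC/NIST atomic masses and isotopic compositions
# (CIAAW 2021 values, truncated to the elements common in biomolecules and
# their labels).  Embedded so pattern calculation is reproducible offline.
NATURAL_ISOTOPES: dict[str, tuple[Isotope, ...]] = {
    "H": _iso([(1.0078250319, 0.999885), (2.0141017781, 0.000115)]),
    "C": _iso([(12.0, 0.9893), (13.0033548351, 0.0107)]),
    "N": _iso([(14.0030740052, 0.99636), (15.0001088984, 0.00364)]),
    "O": _iso([(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)]),
    "S": _iso([(31.97207069, 0.9499), (32.9714585, 0.0075), (33.96786683, 0.0425), (35.96708088, 0.0001)]),
    "P": _iso([(30.97376151, 1.0)]),
    "F": _iso([(18.99840322, 1.0)]),
    "Na": _iso([(22.98976928, 1.0)]),
    "Mg": _iso([(23.9850419, 0.7899), (24.98583702, 0.1000), (25.98259304, 0.1101)]),
    "Cl": _iso([(34.96885271, 0.7576), (36.9659026, 0.2424)]),
    "K": _iso([(38.9637069, 0.932581), (39.9639987, 0.000117), (40.961826, 0.067302)]),
    "Ca": _iso([(39.9625912, 0.96941), (41.9586183, 0.00647), (42.9587668, 0.00135),
                (43.9554811, 0.02086), (45.9536928, 0.00004), (47.952534, 0.00187)]),
    "Fe": _iso([(53.9396148, 0.05845), (55.9349421, 0.91754), (56.9353987, 0.02119), (57.9332805, 0.00282)]),
    "Zn": _iso([(63.9291466, 0.4863), (65.9260368, 0.2790), (66.9271309, 0.0410),
                (67.9248476, 0.1875), (69.925325, 0.0062)]),
    "Se": _iso([(73.9224766, 0.0089), (75.9192141, 0.0937), (76.9199146, 0.0763),
                (77.9173095, 0.2377), (79.9165218, 0.4961), (81.91670, 0.0873)]),
    "Br": _iso([(78.9183376, 0.5069), (80.9162906, 0.4931)]),
    "I": _iso([(126.904473, 1.0)]),
}


class ElementIsotopeTable:
    """Registry resolving element symbols and label-pool ids to isotope lists.

    Invariants checked at registration: abundances of each entry sum to 1
    (within 1e-9), masses strictly increase, abundances lie in [0, 1].
    """

    def __init__(self, elements: Mapping[str, tuple[Isotope, ...]] | None = None):
        self._tables: dict[str, tuple[Isotope, ...]] = {}
        for symbol, isotopes in (elements or NATURAL_ISOTOPES).items():
            self.register(symbol, isotopes)

    def register(self, key: str, isotopes: tuple[Isotope, ...]) -> None:
        total = sum(i.abundance for i in isotopes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances for {key!r} sum to {total}, not 1")
        masses = [i.mass for i in isotopes]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError(f"isotope masses for {key!r} not strictly increasing")
        if any(not (0.0 <= i.abundance <= 1.0) for i in isotopes):
            raise ValueError(f"abundance outside [0,1] for {key!r}")
        self._tables[key] = isotopes

    def __getitem__(self, key: str) -> tuple[Isotope, ...]:
        try:
            return self._tables[key]
        except KeyError:
            raise KeyError(f"no isotope table registered for {key!r}") from None

    def __contains__(self, key: str) -> bool:
        return key in self._tables

    def with_pool(self, pool: "LabelPool") -> "ElementIsotopeTable":
        """Return a copy with ``pool`` registered under its pool id."""
        if pool.pool_id in NATURAL_ISOTOPES:
            raise ValueError(f"pool id {pool.pool_id!r} collides with an element symbol")
        new = ElementIsotopeTable(self._tables)
        new.register(pool.pool_id, pool.isotopes())
        return new


@dataclass(frozen=True)
class LabelPool:
    """An isotope-labeled pool of one element.

    ``abundances`` maps neutron shift (relative to the element's lightest
    isotope) to fraction.  An enrichment of p% on a two-isotope element gives
    ``{heavy: p/100, light: 1 - p/100}``: the enriched distribution replaces
    the natural one (a 99.4% 15N medium means 99.4% of nitrogen atoms are
    15N, not 99.4% extra on top of natural abundance).  p = 0 is therefore
    the pure light isotope; the unlabeled (no-pool) channel uses natural
    abundance unless configured otherwise.
    """

    pool_id: str
    element: str
    abundances: Mapping[int, float]

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool abundances sum to {total}, not 1")

    @classmethod
    def enriched(cls, element: str, percentile: float, pool_id: str | None = None,
                 heavy_shift: int | None = None) -> "LabelPool":
        """Pool for a metabolic label at ``percentile`` % heavy enrichment."""
        if not 0.0 <= percentile <= 100.0:
            raise ValueError("enrichment percentile must be in [0, 100]")
        natural = NATURAL_ISOTOPES[element]
        if heavy_shift is None:
            heavy_shift = natural[1].neutron_shift if len(natural) > 1 else 1
        p = percentile / 100.0
        return cls(
            pool_id=pool_id or f"{element}[{percentile:g}]",
            element=element,
            abundances={0: 1.0 - p, heavy_shift: p},
        )

    def isotopes(self) -> tuple[Isotope, ...]:
        natural = {i.neutron_shift: i for i in NATURAL_ISOTOPES[self.element]}
        out = []
        for shift in sorted(self.abundances):
            if shift in natural:
                mass = natural[shift].mass
            else:
                # isotope absent from the natural table (e.g. 2H pool on H):
                # approximate by lightest mass + shift neutron masses
                mass = natural[0].mass + shift * 1.0086649
            out.append(Isotope(mass=mass, abundance=self.abundances[shift], neutron_shift=shift))
        return tuple(out)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula(Mapping):
    """Immutable mapping of element symbol (or pool id) to atom count."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {k: int(v) for k, v in self.counts.items() if v != 0}
        if any(v < 0 for v in clean.values()):
            raise ValueError("negative atom count")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, key: str) -> int:
        return self.counts[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) + v
        return ChemicalFormula(merged)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) - v
        return ChemicalFormula(merged)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def to_string(self) -> str:
        """Canonical Hill-order string: C, H, then other keys alphabetically."""
        keys = sorted(self.counts)
        ordered = [k for k in ("C", "H") if k in self.counts]
        ordered += [k for k in keys if k not in ("C", "H")]
        return "".join(f"{k}{self.counts[k]}" if self.counts[k] != 1 else k for k in ordered)

    def __str__(self) -> str:
        return self.to_string()

    def total_atoms(self) -> int:
        return sum(self.counts.values())


def parse_formula(text: str) -> ChemicalFormula:
    """Parse ``"C10O4N5H13"``-style formula strings.

    An omitted count means 1.  Unknown element symbols raise ``ValueError``
    naming the offending symbol.
    """
    counts: dict[str, int] = {}
    pos = 0
    stripped = text.strip()
    if not stripped:
        raise ValueError("empty formula string")
    for m in _FORMULA_TOKEN.finditer(stripped):
        if m.start() != pos:
            raise ValueError(f"malformed formula near {stripped[pos:]!r}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in NATURAL_ISOTOPES:
            raise ValueError(f"unknown element symbol {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(stripped):
        raise ValueError(f"malformed formula near {stripped[pos:]!r}")
    return ChemicalFormula(counts)


WATER = ChemicalFormula({"H": 2, "O": 1})

# Monoisotopic residue compositions of the 20 standard amino acids
# (residue = amino acid minus one water, as incorporated in a chain).
AMINO_ACID_COMPOSITIONS: dict[str, ChemicalFormula] = {
    "G": ChemicalFormula({"C": 2, "H": 3, "N": 1, "O": 1}),
    "A": ChemicalFormula({"C": 3, "H": 5, "N": 1, "O": 1}),
    "S": ChemicalFormula({"C": 3, "H": 5, "N": 1, "O": 2}),
    "P": ChemicalFormula({"C": 5, "H": 7, "N": 1, "O": 1}),
    "V": ChemicalFormula({"C": 5, "H": 9, "N": 1, "O": 1}),
    "T": ChemicalFormula({"C": 4, "H": 7, "N": 1, "O": 2}),
    "C": ChemicalFormula({"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}),
    "L": ChemicalFormula({"C": 6, "H": 11, "N": 1, "O": 1}),
    "I": ChemicalFormula({"C": 6, "H": 11, "N": 1, "O": 1}),
    "N": ChemicalFormula({"C": 4, "H": 6, "N": 2, "O": 2}),
    "D": ChemicalFormula({"C": 4, "H": 5, "N": 1, "O": 3}),
    "Q": ChemicalFormula({"C": 5, "H": 8, "N": 2, "O": 2}),
    "K": ChemicalFormula({"C": 6, "H": 12, "N": 2, "O": 1}),
    "E": ChemicalFormula({"C": 5, "H": 7, "N": 1, "O": 3}),
    "M": ChemicalFormula({"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}),
    "H": ChemicalFormula({"C": 6, "H": 7, "N": 3, "O": 1}),
    "F": ChemicalFormula({"C": 9, "H": 9, "N": 1, "O": 1}),
    "R": ChemicalFormula({"C": 6, "H": 12, "N": 4, "O": 1}),
    "Y": ChemicalFormula({"C": 9, "H": 9, "N": 1, "O": 2}),
    "W": ChemicalFormula({"C": 11, "H": 10, "N": 2, "O": 1}),
}

# Built-in modification vocabulary: the common proteomics trio.  Any other
# modification is accepted inline as a raw formula delta (e.g. "+H2O").
MODIFICATIONS: dict[str, ChemicalFormula] = {
    "oxidation": ChemicalFormula({"O": 1}),                      # +15.9949 Da
    "acetyl": ChemicalFormula({"C": 2, "H": 2, "O": 1}),         # +42.0106 Da
    "carbamidomethyl": ChemicalFormula({"C": 2, "H": 3, "N": 1, "O": 1}),  # +57.0215 Da
}


def _resolve_mod(name: str) -> ChemicalFormula:
    key = name.strip().lower()
    if key in MODIFICATIONS:
        return MODIFICATIONS[key]
    try:
        return parse_formula(name.lstrip("+"))
    except ValueError:
        raise ValueError(f"unknown modification {name!r}") from None


def peptide_to_formula(sequence: str,
                       mods: list[tuple[str, int]] | None = None) -> ChemicalFormula:
    """Elemental composition of a peptide with optional modifications.

    The formula is the sum of residue compositions plus one water (the chain
    termini) plus all modification deltas.  Modification positions are
    1-based residue indices; position 0 denotes the N terminus (e.g.
    N-terminal acetylation).
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty peptide sequence")
    formula = WATER
    for aa in sequence:
        try:
            formula = formula + AMINO_ACID_COMPOSITIONS[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid code {aa!r}") from None
    for name, pos in mods or []:
        if not 0 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside 0..{len(sequence)}")
        formula = formula + _resolve_mod(name)
    return formula


def parse_molecule(identity: str) -> ChemicalFormula:
    """Resolve a molecule identity string to a formula.

    Accepts raw formulas (``"C10O4N5H13"``) or peptide sequences with inline
    modifications in ``SEQ#mod:pos;mod:pos`` form (``"ELVISM#oxidation:6"``).
    Resolution is deterministic: a string of valid element tokens is tried as
    a formula first, otherwise as a peptide.
    """
    if "#" in identity:
        seq, _, modpart = identity.partition("#")
        mods = []
        for item in modpart.split(";"):
            if not item:
                continue
            name, _, pos = item.partition(":")
            mods.append((name, int(pos)))
        return peptide_to_formula(seq, mods)
    try:
        return parse_formula(identity)
    except ValueError:
        return peptide_to_formula(identity)


def apply_label(formula: ChemicalFormula, pool: LabelPool,
                n_atoms: int | None = None) -> ChemicalFormula:
    """Re-key atoms of the pool's base element to the pool id.

    Metabolic labels (default) move *all* atoms of the element into the pool;
    a fixed label moves exactly ``n_atoms`` of them, leaving the rest on the
    natural distribution.  Total atoms per base element are conserved.
    """
    if pool.pool_id in NATURAL_ISOTOPES:
        raise ValueError(f"pool id {pool.pool_id!r} collides with an element symbol")
    available = formula.get(pool.element, 0)
    if n_atoms is None:
        n_atoms = available
    if n_atoms > available:
        raise ValueError(
            f"cannot move {n_atoms} {pool.element} atoms; formula has {available}")
    counts = dict(formula.counts)
    counts[pool.element] = available - n_atoms
    if n_atoms:
        counts[pool.pool_id] = counts.get(pool.pool_id, 0) + n_atoms
    return ChemicalFormula(counts)


def monoisotopic_mass(formula: ChemicalFormula,
                      tables: ElementIsotopeTable | None = None) -> float:
    """Mass using the lightest isotope of every element/pool."""
    tables = tables or ElementIsotopeTable()
    return sum(tables[key][0].mass * n for key, n in formula.items())


@dataclass(frozen=True)
class MoleculeSpec:
    """A molecule to quantify: identity, resolved formula, and labeling.

    ``label_percentile`` is the heavy-isotope enrichment (0–100 %) of
    ``label_element``; ``None`` for ``label_element`` means unlabeled
    (natural abundance throughout).
    """

    identity: str
    formula: ChemicalFormula
    label_element: str | None = None
    label_percentile: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_percentile <= 100.0:
            raise ValueError("label percentile must be in [0, 100]")

    @classmethod
    def from_identity(cls, identity: str, label_element: str | None = None,
                      label_percentile: float = 0.0) -> "MoleculeSpec":
        return cls(identity=identity, formula=parse_molecule(identity),
                   label_element=label_element, label_percentile=label_percentile)
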