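"""Compute theoretical isotope patterns for labeled and unlabeled molecules.

Builds patterns for adenosine (as a raw formula) and a peptide at several
15N enrichment levels and prints the (m/z, relative intensity) peak lists.
Partial enrichment visibly broadens the pattern: more peaks survive the 1 %
matching threshold at 60 % than at 0 % or 100 %.
"""

from micquant import MoleculeSpec, build_library, parse_molecule

adenosine = MoleculeSpec.from_identity("C10O4N5H13")
peptide = MoleculeSpec.from_identity("PEPTIDEM#oxidation:8")

for molecule, charge in [(adenosine, 1), (peptide, 2)]:
    print(f"\n{molecule.identity}  ->  {molecule.formula}  (z={charge})")
    library = build_library([molecule], charges=[charge],
                            percentiles=[0, 60, 100])
    for pattern in library:
        n_n = parse_molecule(molecule.identity).get("N", 0)
        print(f"  15N enrichment {pattern.label_percentile:5.1f}%  "
              f"({len(pattern)} peaks above threshold, {n_n} N atoms)")
        for mz, r in zip(pattern.mzs, pattern.rel_intensities):
            print(f"    m/z {mz:10.4f}   r_k {r:.4f}")
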