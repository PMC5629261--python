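"""Score a theoretical pattern against measured spectra of varying quality.

Presents the adenosine pattern back to the scorer (i) exactly, scaled by
1000, (ii) shifted by 2.5 ppm, and (iii) with 10 % intensity error on the
top peak.  The mScore is 1 for the perfect match and decreases as m/z or
intensity agreement degrades; sigma is the fitted abundance (the intensity
of the pattern's most intense peak on the spectrum's scale).
"""

import numpy as np

from micquant import (
    CentroidedSpectrum,
    MoleculeSpec,
    build_library,
    match_pattern,
)

mol = MoleculeSpec.from_identity("C10O4N5H13")
pattern = next(iter(build_library([mol], charges=[1], percentiles=[0])))
mzs = np.array(pattern.mzs)
r = np.array(pattern.rel_intensities)

cases = {
    "perfect, scaled x1000": (mzs, 1000.0 * r),
    "uniform +2.5 ppm shift": (mzs * (1 + 2.5e-6), 1000.0 * r),
    "10% error on top peak": (mzs, 1000.0 * r * np.where(r == 1.0, 1.1, 1.0)),
}

for name, (m, i) in cases.items():
    spectrum = CentroidedSpectrum(1, 10.0, m, i)
    match = match_pattern(pattern, spectrum)
    print(f"{name:24s}  mScore {match.mscore:.4f}  "
          f"S_mz {match.score_mz:.4f}  S_int {match.score_intensity:.4f}  "
          f"sigma {match.sigma:.1f}")
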