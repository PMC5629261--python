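# Methods

## Isotopologue distributions

The distribution of a formula is the exact convolution of per-atom isotope
distributions. Per element, the n-atom distribution is computed by binary
powering with pairwise convolution; elements (and label pools) are then
convolved together. Terms below 1e-12 absolute abundance are pruned during
convolution — four orders of magnitude below anything the 1 % matching
threshold can see, so pruning never affects a retained peak.

Isotopologues are aggregated by integer neutron excess relative to the
all-lightest species, the regime in which Orbitrap-class instruments
operate; fine structure within one neutron-excess class (e.g. ¹³C vs ¹⁵N
substitutions) is not resolved. Each aggregate carries the
abundance-weighted mean mass, which is exact under convolution: for two
partial distributions the weighted mass sums combine linearly
(Σ a_i a_j (m_i+m_j) = A₁S₂ + S₁A₂), so aggregating early loses no
precision. The isotope masses and abundances are a static CIAAW/NIST
snapshot embedded in `chemistry.py` (17 elements common in biomolecules),
so results are reproducible without network access.

Charged patterns use the proton (1.007276466 Da) as the only charge
carrier, positive mode; peaks are rescaled so the most intense is exactly
1 (r_k) and peaks with r_k below the matching threshold (default 0.01) are
dropped.

## Labeling semantics

Enrichment p % for element E replaces E's natural distribution with
{heavy: p/100, light: 1 − p/100}. This matches how enriched media are
specified (a "99.4 % ¹⁵N" medium means 99.4 % of nitrogen atoms are ¹⁵N);
p = 0 therefore means the pure light isotope. The *unlabeled* channel of a
library uses natural abundance by default — the two differ by the 0.36 %
natural ¹⁵N fraction — and `zero_is_natural=False` switches to the
pure-light convention. Metabolic labels re-key all atoms of the element to
the pool; fixed labels move an explicit atom count, so both label kinds
(and combinations) reduce to the same convolution machinery.

## Matching and scoring

Candidate peaks are found by binary search over the sorted spectrum; the
ppm tolerance interval is closed, with 1e-9 ppm slack so the boundary is
robust to floating-point rounding of the ppm computation itself. The
signed machine offset is subtracted from the raw ppm error before the
tolerance test. Ties on |ppm| break toward the higher-intensity measured
peak, making output deterministic. One measured peak may serve several
overlapping patterns: every pattern is matched independently, with no peak
consumption.

A match is returned only if *every* pattern peak above the matching
threshold found a measured partner (`min_matched_fraction = 1.0`); this is
the conservative policy for patterns whose retained peaks are all, by
construction, above threshold. Lowering `min_matched_fraction` permits
partial-pattern matches for workflows that tolerate missing minor
isotopologues.

Per-peak scores are clamped to [0, 1]; the linear forms can otherwise go
negative for errors near the edge of the windows.

Two numerical choices in the intensity score deserve note. First, the
intensity-error normalization is a dimensionless constant `alpha_intensity`
(default 1, plain relative error) rather than the ppm range α: a ppm
quantity in an intensity denominator is dimensionally incoherent, and the
default reproduces all worked examples; setting `alpha_intensity = 5`
restores the literal equation form. Second, the relative error is taken
against the σ-scaled theoretical intensity, δ^int = |I_ik − σI_jk| /
(α_int·σ·I_jk). Normalizing by I_jk alone (the pattern-scale theoretical
intensity, ≤ 1) would make the error grow with the detector's count scale
— a spectrum scaled by 10⁶ would score 0 on intensities it fits perfectly
in relative terms — and would break the invariant that scaling a
spectrum's intensity axis by c multiplies σ by c while leaving both scores
unchanged. The σ-normalized form preserves that invariance and reduces to
the plain form when σ = 1.

## Parameters

| name | meaning | default | why |
|---|---|---|---|
| `alpha_ppm` | ppm window over which s^mz falls 1 → 0 | 5 | precision of modern Orbitrap MS¹ |
| `epsilon` | relative intensity error allowed at r_k = 1 | 0.2 | most conservative error on the best-measured peak |
| `xi` | weight of S^mz in the mScore | 0.4 | m/z is measured more accurately than intensity |
| `matching_threshold` | minimum r_k for a required peak | 0.01 | 1 % of the maximum-intensity peak |
| `machine_offset_ppm` | signed systematic calibration error | 0 | per-instrument; subtracted before tolerance checks |
| `alpha_intensity` | intensity-error normalization | 1 | plain relative error (see above) |
| `min_matched_fraction` | fraction of required peaks that must match | 1.0 | conservative required-peak policy |
| reporting threshold | minimum mScore stored by `quantify_run` | 0.5 | evaluation-grade cuts (0.7/0.8/0.9) applied downstream |

Library percentile grids default to 0–100 in steps of 1 (101 labeling
states per formula and charge), the resolution needed for pulse/pulse-chase
searches; tests and examples use coarser grids.

## Quantification and evaluation

Spectra are streamed one at a time; the library keeps a sorted index of
each pattern's most intense m/z, so per spectrum only patterns whose
anchor peak has a measured counterpart within α are fully scored
(binary search, sublinear in library size; `prefilter=False` restores
exhaustive pairing, and a test asserts both routes agree). Retention-time
windows from evidence files are closed intervals in minutes (mzML scan
times in seconds are converted on read); formulas without evidence rows
pass unfiltered by default.

A MIC reduces to its best-mScore match (ties toward higher σ); the
reported abundance is the maximum σ inside the RT window. Since
theoretical intensities are normalized to max = 1, σ is the
max-peak-equivalent intensity — directly comparable across label states of
the same formula.

Evaluation groups reduced MICs per (formula, charge, run) into the 11
percentile bins and, one ground truth at a time, counts: TP (expected bin
fires, no other bin does), FP (expected silent, another bin fires), FN
(expected silent), TN (no unexpected bin fires). These rules are applied
literally, so one unit can increment both FP and FN, or both FN and TN;
`mode="exclusive"` instead partitions units into TP / FP (any unexpected
match) / FN (fully silent). In a mixed sample the bins of the *other* true
percentiles are excluded from the unexpected set (an 11-bin unit becomes a
10-bin decision for a two-channel mix) — without this exclusion the second
true channel of every molecule would annihilate the TP count. Undefined
ratios (0/0) are reported as missing, never as 0. ROC tables run over
thresholds 0.00–1.00 in steps of 0.01, with specificity = 1 − FPR.

## Synthetic data

The generator emulates a two-channel partially-labeled gold-standard
design: molecules planted at chosen enrichment percentiles and abundances,
Gaussian elution profiles (default σ = 0.25 min) over an RT grid, and
evidence windows of 2.5 min (the stringent setting) centred on each apex.
The noise model is deliberately simple and fully parameterized: Normal m/z
jitter in ppm (default 1 ppm), log-normal multiplicative intensity noise
(default 2 %), and Poisson-count contaminant peaks at uniform random m/z
(default off). Defaults are realistic for a well-calibrated Orbitrap
acquisition; tests that require exactness set the noise scales to zero
explicitly.

What the generator does *not* emulate: chromatographic peak asymmetry,
co-eluting isobaric interference, detector saturation, charge-state
envelopes from a single species, or MS² spectra. Passing tests on
synthetic runs therefore demonstrate the correctness of the pattern
arithmetic, matching, scoring, and evaluation bookkeeping — not robustness
to every artifact of real LC-MS data.

mzML is written as a minimal standards-conformant document (one run,
centroided MS¹ spectra, uncompressed 64-bit little-endian arrays, scan
times in seconds) and read back with a compact streaming reader (plain or
zlib-compressed, 32/64-bit floats). The writer is validated by
round-tripping through the package's own reader and, independently, by
Bioconductor's mzR in an integration test.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
libraries of tens of patterns, runs of ~40 spectra, 100-molecule
perfect-match sweeps, 40 random formulas for the enumeration oracle, and
five-peptide two-channel mixes for recovery checks. The enumeration oracle
is direct per-element multiset enumeration with multinomial coefficients —
a different algorithm from the production convolution — and agrees with a
per-atom cartesian-product enumeration on very small formulas.

## Known limitations

* Positive mode, proton adducts only; no isotope fine structure.
* No deconvolution of overlapping isotope clusters into mixtures; a
  coeluting interferent either lowers the mScore or (rarely) inflates σ.
* No RT or intensity alignment across runs; evidence windows are taken as
  given.
* Peptide parsing covers the 20 standard residues and formula-delta
  modifications; no glycan/lipid nomenclature (raw formulas cover those).
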