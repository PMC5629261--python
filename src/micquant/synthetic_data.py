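"""Synthetic centroided MS¹ runs with known labeling ground truth.

Emulates the design of a partially labeled two-channel gold standard:
molecules are planted at chosen enrichment percentiles and abundances, each
eluting as a Gaussian over retention time, and every spectrum receives the
molecules' theoretical isotope patterns scaled by the elution profile.
Noise is parameterized and off by default per component: Normal m/z jitter
(in ppm), log-normal multiplicative intensity noise, and Poisson-count
contaminant peaks at uniform random m/z.  A fixed seed makes the whole
output stream — spectra, mzML bytes, manifest — reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chemistry import MoleculeSpec, parse_molecule
from .isotope_pattern import (
    DEFAULT_MATCHING_THRESHOLD,
    IsotopePattern,
    build_library,
)
from .quantification import EvidenceEntry, write_evidence
from .scoring import CentroidedSpectrum
from .mzml_io import write_mzml

__all__ = ["PlantedMolecule", "SimulationConfig", "simulate_spectrum", "simulate_run"]


@dataclass(frozen=True)
class PlantedMolecule:
    """One molecule channel planted in a simulated run."""

    identity: str
    label_percentile: float = 0.0
    abundance: float = 1e6       # apex intensity of the pattern's max peak
    apex_rt: float = 10.0        # minutes
    elution_width: float = 0.25  # Gaussian sigma, minutes
    charges: tuple[int, ...] = (2,)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated LC-MS run.

    Defaults emulate a short two-channel metabolic-labeling experiment:
    15N as the labeled element, 1 ppm m/z jitter and 2 % multiplicative
    intensity noise (Orbitrap-regime values), and no contaminant peaks
    unless requested.  ``seed`` fixes every random draw.
    """

    molecules: tuple[PlantedMolecule, ...]
    rt_start: float = 8.0        # minutes
    rt_stop: float = 12.0
    n_spectra: int = 41
    ppm_jitter: float = 1.0      # sigma of Normal m/z jitter, ppm
    intensity_noise: float = 0.02  # sigma of log-normal multiplicative noise
    contaminant_rate: float = 0.0  # Poisson mean contaminant peaks per spectrum
    contaminant_mz_range: tuple[float, float] = (300.0, 1600.0)
    contaminant_intensity: float = 1e5
    label_element: str = "N"
    matching_threshold: float = DEFAULT_MATCHING_THRESHOLD
    elution_floor: float = 1e-3  # drop channel when profile < floor × abundance
    evidence_window: float = 2.5  # minutes, full window width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_jitter < 0 or self.intensity_noise < 0 or self.contaminant_rate < 0:
            raise ValueError("noise scales must be non-negative")
        if self.n_spectra < 1 or not self.rt_start < self.rt_stop:
            raise ValueError("invalid RT grid")

    def rt_grid(self) -> np.ndarray:
        return np.linspace(self.rt_start, self.rt_stop, self.n_spectra)


def _planted_patterns(config: SimulationConfig) -> list[tuple[PlantedMolecule, IsotopePattern]]:
    out = []
    for mol in config.molecules:
        spec = MoleculeSpec(identity=mol.identity, formula=parse_molecule(mol.identity),
                            label_element=config.label_element)
        library = build_library(
            [spec], charges=list(mol.charges),
            percentiles=[mol.label_percentile],
            threshold=config.matching_threshold,
            label_element=config.label_element,
        )
        for pattern in library:
            out.append((mol, pattern))
    return out


def simulate_spectrum(
    config: SimulationConfig,
    rt: float,
    spectrum_id: int = 1,
    rng: np.random.Generator | None = None,
    patterns: Sequence[tuple[PlantedMolecule, IsotopePattern]] | None = None,
) -> CentroidedSpectrum:
    """One centroided MS¹ spectrum at retention time ``rt`` (minutes).

    Without an explicit ``rng`` the generator is seeded from the config
    seed, so repeated calls with identical arguments return identical
    spectra.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if patterns is None:
        patterns = _planted_patterns(config)
    mzs: list[float] = []
    intensities: list[float] = []
    for mol, pattern in patterns:
        profile = math.exp(-0.5 * ((rt - mol.apex_rt) / mol.elution_width) ** 2)
        if profile < config.elution_floor:
            continue
        scale = mol.abundance * profile
        for mz, r in zip(pattern.mzs, pattern.rel_intensities):
            jitter = rng.normal(0.0, config.ppm_jitter) if config.ppm_jitter else 0.0
            noise = (math.exp(rng.normal(0.0, config.intensity_noise))
                     if config.intensity_noise else 1.0)
            mzs.append(mz * (1.0 + jitter * 1e-6))
            intensities.append(scale * r * noise)
    if config.contaminant_rate:
        n = rng.poisson(config.contaminant_rate)
        lo, hi = config.contaminant_mz_range
        for _ in range(n):
            mzs.append(rng.uniform(lo, hi))
            intensities.append(rng.uniform(0.0, config.contaminant_intensity))
    order = np.argsort(mzs, kind="stable")
    mz_arr = np.asarray(mzs, dtype=float)[order]
    int_arr = np.asarray(intensities, dtype=float)[order]
    # centroiding: coincident apexes (within 1e-9 Th) merge into one peak
    if len(mz_arr) > 1:
        keep_mz, keep_int = [mz_arr[0]], [int_arr[0]]
        for mz, inten in zip(mz_arr[1:], int_arr[1:]):
            if mz - keep_mz[-1] <= 1e-9:
                keep_int[-1] += inten
            else:
                keep_mz.append(mz)
                keep_int.append(inten)
        mz_arr, int_arr = np.asarray(keep_mz), np.asarray(keep_int)
    return CentroidedSpectrum(spectrum_id=spectrum_id, retention_time=rt,
                              mzs=mz_arr, intensities=int_arr, ms_level=1)


def simulate_run(
    config: SimulationConfig,
    out_dir: str | Path,
    run_id: str = "synthetic_run",
) -> dict[str, Path]:
    """Simulate a full run and write mzML + manifest + evidence files.

    Returns paths under ``out_dir``: ``mzml`` (centroided MS¹ spectra over
    the RT grid), ``manifest`` (every planted channel with its formula,
    charge, percentile, apex RT and abundance — the ground truth), and
    ``evidence`` (RT windows of the configured width centred on each apex,
    default 2.5 min, the stringent setting).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    patterns = _planted_patterns(config)

    spectra = [
        simulate_spectrum(config, float(rt), spectrum_id=i + 1, rng=rng,
                          patterns=patterns)
        for i, rt in enumerate(config.rt_grid())
    ]
    mzml_path = out_dir / f"{run_id}.mzML"
    write_mzml(str(mzml_path), spectra, run_id=run_id)

    manifest_rows = []
    evidence_entries = []
    half = config.evidence_window / 2.0
    for mol, pattern in patterns:
        manifest_rows.append({
            "identity": mol.identity, "formula": pattern.formula_key,
            "charge": pattern.charge, "label_percentile": pattern.label_percentile,
            "apex_rt_min": mol.apex_rt, "abundance": mol.abundance,
            "run_id": run_id,
        })
        evidence_entries.append(EvidenceEntry(
            identity=mol.identity, formula_key=pattern.formula_key,
            charge=pattern.charge, rt_start=mol.apex_rt - half,
            rt_stop=mol.apex_rt + half, run_id=run_id,
        ))
    manifest_path = out_dir / f"{run_id}.manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    evidence_path = out_dir / f"{run_id}.evidence.tsv"
    # one evidence row per (molecule, charge); duplicates collapse
    write_evidence(str(evidence_path), evidence_entries)
    return {"mzml": mzml_path, "manifest": manifest_path, "evidence": evidence_path}
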