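import numpy as np
import pytest
from hypothesis import settings

from micquant import CentroidedSpectrum, ScoringParams
from micquant.synthetic_data import PlantedMolecule, SimulationConfig

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def params() -> ScoringParams:
    return ScoringParams()


def spectrum_from_pattern(pattern, scale: float = 1.0, ppm_shift: float = 0.0,
                          spectrum_id: int = 1, rt: float = 10.0,
                          drop: tuple[int, ...] = ()) -> CentroidedSpectrum:
    """Measured spectrum presenting a pattern's peaks, optionally perturbed."""
    mzs, intensities = [], []
    for k, (mz, r) in enumerate(zip(pattern.mzs, pattern.rel_intensities)):
        if k in drop:
            continue
        mzs.append(mz * (1.0 + ppm_shift * 1e-6))
        intensities.append(scale * r)
    return CentroidedSpectrum(spectrum_id=spectrum_id, retention_time=rt,
                              mzs=np.array(mzs), intensities=np.array(intensities))


@pytest.fixture
def two_channel_config() -> SimulationConfig:
    """Noiseless 0/60-style mix: three peptides, two label channels each."""
    molecules = []
    for pep, apex in [("ELVISLK", 9.0), ("PEPTIDE", 10.0), ("GASPVTK", 11.0)]:
        for p in (0.0, 60.0):
            molecules.append(PlantedMolecule(
                identity=pep, label_percentile=p, abundance=1e6,
                apex_rt=apex, charges=(2,)))
    return SimulationConfig(molecules=tuple(molecules), ppm_jitter=0.0,
                            intensity_noise=0.0, seed=11)
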