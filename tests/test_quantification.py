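"""Run-level matching, MIC assembly, RT windows, and result tables."""

import numpy as np
import pandas as pd
import pytest

from micquant import (
    CentroidedSpectrum,
    EvidenceEntry,
    MoleculeSpec,
    PatternLibrary,
    ScoringParams,
    apply_rt_windows,
    assemble_mics,
    build_library,
    matches_to_table,
    quantify_run,
    reduce_mic,
)
from micquant.quantification import MIC, read_evidence, write_evidence
from micquant.scoring import PatternMatch

from conftest import spectrum_from_pattern


@pytest.fixture(scope="module")
def peptide_library():
    mol = MoleculeSpec.from_identity("PEPTIDE")
    return build_library([mol], charges=[2], percentiles=[0, 100])


@pytest.fixture(scope="module")
def peptide_pattern(peptide_library):
    return peptide_library[(MoleculeSpec.from_identity("PEPTIDE").formula.to_string(),
                            2, 0.0)]


def blank_spectrum(spectrum_id, rt):
    return CentroidedSpectrum(spectrum_id, rt, np.array([400.0]), np.array([1.0]))


def fake_match(formula="F", z=2, percentile=0.0, rt=10.0, mscore=0.9,
               sigma=100.0, spectrum_id=1):
    return PatternMatch(pattern_key=(formula, z, percentile),
                        spectrum_id=spectrum_id, retention_time=rt,
                        sigma=sigma, score_mz=1.0, score_intensity=1.0,
                        mscore=mscore)


def test_pattern_found_only_where_planted(peptide_library, peptide_pattern):
    spectra = [blank_spectrum(1, 9.0),
               spectrum_from_pattern(peptide_pattern, scale=500.0,
                                     spectrum_id=2, rt=10.0),
               blank_spectrum(3, 11.0)]
    matches = quantify_run(spectra, peptide_library)
    assert len(matches) == 1
    assert matches[0].spectrum_id == 2
    assert matches[0].label_percentile == 0.0


def test_empty_library_yields_no_matches(peptide_pattern):
    spectra = [spectrum_from_pattern(peptide_pattern)]
    assert quantify_run(spectra, PatternLibrary()) == []


def test_only_the_planted_percentile_matches(peptide_library):
    """A fully labeled spectrum matches the 100% pattern, not the 0% one."""
    key100 = next(k.key for k in peptide_library if k.label_percentile == 100.0)
    spectrum = spectrum_from_pattern(peptide_library[key100], scale=300.0)
    matched_keys = {m.pattern_key for m in quantify_run([spectrum], peptide_library)}
    assert matched_keys == {key100}


def test_ms2_spectra_are_skipped(peptide_library, peptide_pattern):
    s = spectrum_from_pattern(peptide_pattern)
    ms2 = CentroidedSpectrum(2, 10.0, s.mzs, s.intensities, ms_level=2)
    assert quantify_run([ms2], peptide_library) == []


def test_prefilter_agrees_with_exhaustive_matching(peptide_library, peptide_pattern):
    spectra = [spectrum_from_pattern(peptide_pattern, scale=50.0, spectrum_id=i,
                                     rt=float(i)) for i in (1, 2, 3)]
    fast = quantify_run(spectra, peptide_library, prefilter=True)
    slow = quantify_run(spectra, peptide_library, prefilter=False)
    assert fast == slow


def test_evidence_restricts_matching_to_rt_window(peptide_library, peptide_pattern):
    spectra = [spectrum_from_pattern(peptide_pattern, spectrum_id=i, rt=rt)
               for i, rt in enumerate([5.0, 10.0, 15.0], start=1)]
    evidence = [EvidenceEntry(identity="PEPTIDE",
                              formula_key=peptide_pattern.formula_key,
                              charge=2, rt_start=9.0, rt_stop=11.0)]
    matches = quantify_run(spectra, peptide_library, evidence=evidence)
    assert [m.retention_time for m in matches] == [10.0]


class TestMicAssembly:
    def test_partition_by_key(self):
        matches = [fake_match("A", rt=1.0), fake_match("A", rt=2.0),
                   fake_match("A", rt=3.0), fake_match("B", rt=1.0),
                   fake_match("B", rt=2.0)]
        mics = assemble_mics(matches)
        assert sorted((m.formula_key, len(m)) for m in mics) == [("A", 3), ("B", 2)]

    def test_single_match_mic(self):
        assert len(assemble_mics([fake_match()])[0]) == 1

    def test_charge_states_are_never_mixed(self):
        matches = [fake_match("A", z=2), fake_match("A", z=3)]
        mics = assemble_mics(matches)
        assert len(mics) == 2

    def test_matches_ordered_by_retention_time(self):
        matches = [fake_match("A", rt=3.0), fake_match("A", rt=1.0),
                   fake_match("A", rt=2.0)]
        (mic,) = assemble_mics(matches)
        assert [m.retention_time for m in mic.matches] == [1.0, 2.0, 3.0]


class TestMicReduction:
    def _mic(self, entries):
        matches = tuple(fake_match("A", rt=rt, mscore=s, sigma=g)
                        for rt, s, g in entries)
        return MIC("A", 2, 0.0, "run", matches)

    def test_best_mscore_selected(self):
        mic = self._mic([(1.0, 0.6, 10), (2.0, 0.9, 20), (3.0, 0.7, 30)])
        assert reduce_mic(mic).best_mscore == 0.9

    def test_mscore_tie_breaks_toward_higher_intensity(self):
        mic = self._mic([(1.0, 0.9, 10), (2.0, 0.9, 50)])
        r = reduce_mic(mic)
        assert r.abundance == 50 and r.rt_of_max == 2.0

    def test_abundance_is_window_restricted_maximum(self):
        mic = self._mic([(9.5, 0.9, 1000), (11.0, 0.8, 200)])
        r = reduce_mic(mic, window=(10.0, 12.0))
        assert r.abundance == 200
        assert r.rt_of_max == 11.0
        assert r.n_matches == 1

    def test_all_matches_outside_window_is_empty(self):
        mic = self._mic([(5.0, 0.9, 10)])
        assert reduce_mic(mic, window=(10.0, 12.0)) is None


class TestRtWindows:
    def _matches(self, rts, formula="A"):
        return [fake_match(formula, rt=rt) for rt in rts]

    def _evidence(self, start, stop, formula="A"):
        return [EvidenceEntry(identity=formula, formula_key=formula, charge=2,
                              rt_start=start, rt_stop=stop)]

    def test_window_filtering(self):
        matches = self._matches([8.0, 9.0, 9.5, 10.0, 10.5, 11.0, 12.0,
                                 13.0, 14.0, 15.0])
        kept = apply_rt_windows(matches, self._evidence(9.5, 11.0))
        assert len(kept) == 4

    def test_unlisted_formulas_pass_by_default(self):
        matches = self._matches([1.0], formula="B")
        assert apply_rt_windows(matches, self._evidence(9.0, 10.0)) == matches
        assert apply_rt_windows(matches, self._evidence(9.0, 10.0),
                                pass_unlisted=False) == []

    def test_boundary_rt_is_retained(self):
        matches = self._matches([9.0, 11.0])
        assert len(apply_rt_windows(matches, self._evidence(9.0, 11.0))) == 2

    def test_tightening_window_never_adds_matches(self):
        matches = self._matches(np.linspace(5, 15, 21))
        widths = [(5.0, 15.0), (8.0, 12.0), (9.0, 11.0), (9.9, 10.1)]
        counts = [len(apply_rt_windows(matches, self._evidence(*w)))
                  for w in widths]
        assert counts == sorted(counts, reverse=True)


def test_completeness_of_pair_evaluation(peptide_library, peptide_pattern, monkeypatch):
    """Without RT restriction every (pattern, spectrum) pair is evaluated."""
    import micquant.quantification as q

    calls = []
    original = q.match_pattern

    def counting(pattern, spectrum, params):
        calls.append((pattern.key, spectrum.spectrum_id))
        return original(pattern, spectrum, params)

    monkeypatch.setattr(q, "match_pattern", counting)
    spectra = [spectrum_from_pattern(peptide_pattern, spectrum_id=i, rt=float(i))
               for i in (1, 2, 3)]
    quantify_run(spectra, peptide_library, prefilter=False)
    assert len(calls) == len(peptide_library) * len(spectra)
    assert len(set(calls)) == len(calls)


def test_result_tables_are_deterministic(peptide_library, peptide_pattern):
    spectra = [spectrum_from_pattern(peptide_pattern, scale=10.0, spectrum_id=i,
                                     rt=float(i)) for i in (1, 2)]
    t1 = matches_to_table(quantify_run(spectra, peptide_library))
    t2 = matches_to_table(quantify_run(spectra, peptide_library))
    pd.testing.assert_frame_equal(t1, t2)
    assert t1.to_csv() == t2.to_csv()


def test_evidence_file_round_trip(tmp_path):
    entries = [EvidenceEntry("PEPTIDE", "C34H53N7O15", 9.0, 11.5, charge=2,
                             run_id="r1"),
               EvidenceEntry("C10O4N5H13", "C10H13N5O4", 1.0, 3.0, run_id="r2")]
    path = tmp_path / "evidence.tsv"
    write_evidence(str(path), entries)
    assert read_evidence(str(path)) == entries


def test_raising_mscore_threshold_never_adds_matches(peptide_library,
                                                     peptide_pattern):
    rng = np.random.default_rng(3)
    spectra = []
    for i in range(5):
        base = spectrum_from_pattern(peptide_pattern, scale=100.0,
                                     spectrum_id=i + 1, rt=float(i),
                                     ppm_shift=float(rng.uniform(-4, 4)))
        noisy = CentroidedSpectrum(
            base.spectrum_id, base.retention_time, base.mzs,
            base.intensities * rng.lognormal(0, 0.15, len(base)))
        spectra.append(noisy)
    counts = [len(quantify_run(spectra, peptide_library, mscore_threshold=t))
              for t in (0.0, 0.5, 0.7, 0.9)]
    assert counts == sorted(counts, reverse=True)
    assert counts[0] > 0
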