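"""Run-level quantification: match a library against a run, assemble MICs.

A matched isotope pattern chromatogram (MIC) collects every scored match of
one (formula, charge, label percentile) across the MS¹ spectra of one run —
the isotope-pattern analogue of an XIC, with the match quality (mScore) as
an extra dimension.  Each MIC reduces to a single best-mScore match; the
reported abundance is the maximum σ (max-peak-equivalent intensity) over
the matches inside the evidence retention-time window.

Spectra are processed one at a time; per spectrum the library's m/z index
restricts full scoring to patterns whose most intense peak has a measured
counterpart, so matching stays sublinear in library size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .chemistry import MoleculeSpec
from .isotope_pattern import PatternLibrary
from .scoring import CentroidedSpectrum, PatternMatch, ScoringParams, match_pattern

__all__ = [
    "EvidenceEntry",
    "MIC",
    "QuantResult",
    "quantify_run",
    "assemble_mics",
    "reduce_mic",
    "apply_rt_windows",
    "read_evidence",
    "write_evidence",
    "read_molecule_list",
    "matches_to_table",
    "results_to_table",
    "DEFAULT_REPORTING_THRESHOLD",
]

logger = logging.getLogger(__name__)

# matches below this mScore are not reported; evaluation-grade thresholds
# (0.7, 0.8, 0.9) are applied downstream, not at matching time
DEFAULT_REPORTING_THRESHOLD = 0.5


@dataclass(frozen=True)
class EvidenceEntry:
    """Identification evidence: a molecule expected in an RT window of a run."""

    identity: str
    formula_key: str
    rt_start: float  # minutes
    rt_stop: float   # minutes
    charge: int | None = None
    run_id: str = "run"

    def __post_init__(self) -> None:
        if not self.rt_start < self.rt_stop:
            raise ValueError("evidence window requires rt_start < rt_stop")

    def covers(self, formula_key: str, charge: int, rt: float) -> bool:
        # closed interval: a match exactly on the boundary is retained
        return (self.formula_key == formula_key
                and (self.charge is None or self.charge == charge)
                and self.rt_start <= rt <= self.rt_stop)


@dataclass(frozen=True)
class MIC:
    """All matches of one (formula, z, label percentile) in one run, by RT."""

    formula_key: str
    charge: int
    label_percentile: float
    run_id: str
    matches: tuple[PatternMatch, ...]

    @property
    def key(self) -> tuple[str, int, float, str]:
        return (self.formula_key, self.charge, self.label_percentile, self.run_id)

    def __len__(self) -> int:
        return len(self.matches)


@dataclass(frozen=True)
class QuantResult:
    """Reduced quantification of one MIC."""

    formula_key: str
    charge: int
    label_percentile: float
    run_id: str
    best_mscore: float
    abundance: float
    rt_of_max: float
    n_matches: int


def _evidence_index(evidence: Sequence[EvidenceEntry]) -> dict[str, list[EvidenceEntry]]:
    index: dict[str, list[EvidenceEntry]] = {}
    for e in evidence:
        index.setdefault(e.formula_key, []).append(e)
    return index


def quantify_run(
    spectra: Iterable[CentroidedSpectrum],
    library: PatternLibrary,
    evidence: Sequence[EvidenceEntry] | None = None,
    params: ScoringParams | None = None,
    mscore_threshold: float = DEFAULT_REPORTING_THRESHOLD,
    pass_unlisted: bool = True,
    prefilter: bool = True,
) -> list[PatternMatch]:
    """Match every library pattern against every MS¹ spectrum of a run.

    With ``evidence`` given, matching is restricted to the identified RT
    windows; formulas without any evidence row pass unfiltered when
    ``pass_unlisted`` (the default).  Matches below ``mscore_threshold``
    are discarded.  Non-MS¹ spectra are skipped with a warning.
    ``prefilter=False`` disables the anchor-peak index and scores every
    (pattern, spectrum) pair exhaustively.
    """
    params = params or ScoringParams()
    ev_index = _evidence_index(evidence) if evidence else None
    out: list[PatternMatch] = []
    for spectrum in spectra:
        if spectrum.ms_level != 1:
            logger.warning("skipping spectrum %s: MS level %d",
                           spectrum.spectrum_id, spectrum.ms_level)
            continue
        if prefilter:
            patterns = library.candidates(
                spectrum.mzs, params.alpha_ppm, params.machine_offset_ppm)
        else:
            patterns = list(library)
        for pattern in patterns:
            if ev_index is not None:
                entries = ev_index.get(pattern.formula_key)
                if entries is None:
                    if not pass_unlisted:
                        continue
                elif not any(e.covers(pattern.formula_key, pattern.charge,
                                      spectrum.retention_time) for e in entries):
                    continue
            m = match_pattern(pattern, spectrum, params)
            if m is not None and m.mscore >= mscore_threshold:
                out.append(m)
    return out


def apply_rt_windows(
    matches: Iterable[PatternMatch],
    evidence: Sequence[EvidenceEntry],
    pass_unlisted: bool = True,
) -> list[PatternMatch]:
    """Keep matches whose RT falls inside a (closed) evidence window.

    Formulas with no evidence row pass through unfiltered by default.
    """
    ev_index = _evidence_index(evidence)
    kept = []
    for m in matches:
        entries = ev_index.get(m.formula)
        if entries is None:
            if pass_unlisted:
                kept.append(m)
        elif any(e.covers(m.formula, m.charge, m.retention_time) for e in entries):
            kept.append(m)
    return kept


def assemble_mics(matches: Iterable[PatternMatch], run_id: str = "run") -> list[MIC]:
    """Partition matches into MICs, ordered by retention time within each."""
    groups: dict[tuple[str, int, float], list[PatternMatch]] = {}
    for m in matches:
        groups.setdefault(m.pattern_key, []).append(m)
    mics = []
    for (formula, z, percentile) in sorted(groups):
        ms = sorted(groups[(formula, z, percentile)],
                    key=lambda m: (m.retention_time, m.spectrum_id))
        mics.append(MIC(formula_key=formula, charge=z, label_percentile=percentile,
                        run_id=run_id, matches=tuple(ms)))
    return mics


def reduce_mic(mic: MIC, window: tuple[float, float] | None = None) -> QuantResult | None:
    """Reduce a MIC to one best match plus an abundance.

    The selected match has the highest mScore (ties break toward higher σ);
    the abundance is the maximum σ over the matches inside ``window`` (all
    matches when no window is given).  Returns ``None`` when every match
    falls outside the window.
    """
    if window is not None:
        in_window = [m for m in mic.matches
                     if window[0] <= m.retention_time <= window[1]]
    else:
        in_window = list(mic.matches)
    if not in_window:
        return None
    best = max(in_window, key=lambda m: (m.mscore, m.sigma))
    peak = max(in_window, key=lambda m: m.sigma)
    return QuantResult(
        formula_key=mic.formula_key, charge=mic.charge,
        label_percentile=mic.label_percentile, run_id=mic.run_id,
        best_mscore=best.mscore, abundance=peak.sigma,
        rt_of_max=peak.retention_time, n_matches=len(in_window),
    )


# ---------------------------------------------------------------------------
# delimited-text interfaces

_EVIDENCE_COLUMNS = ["identity", "formula", "charge", "rt_start_min",
                     "rt_stop_min", "run_id"]


def read_evidence(path: str) -> list[EvidenceEntry]:
    """Read evidence rows from a tab-separated file with the standard header
    ``identity, formula, charge, rt_start_min, rt_stop_min, run_id``."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        charge = getattr(row, "charge", None)
        charge = None if pd.isna(charge) else int(charge)
        out.append(EvidenceEntry(
            identity=str(row.identity), formula_key=str(row.formula),
            charge=charge, rt_start=float(row.rt_start_min),
            rt_stop=float(row.rt_stop_min), run_id=str(row.run_id),
        ))
    return out


def write_evidence(path: str, entries: Sequence[EvidenceEntry]) -> None:
    pd.DataFrame([{
        "identity": e.identity, "formula": e.formula_key,
        "charge": e.charge, "rt_start_min": e.rt_start,
        "rt_stop_min": e.rt_stop, "run_id": e.run_id,
    } for e in entries], columns=_EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_molecule_list(path: str) -> list[tuple[MoleculeSpec, tuple[int, ...], tuple[float, ...]]]:
    """Read a molecule list: columns ``identity``, optional ``formula``,
    ``charges`` and ``label_percentiles`` as ``;``-separated lists.

    Peptide identities may carry inline modifications (``SEQ#mod:pos``).
    """
    from .chemistry import parse_formula, parse_molecule

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        identity = str(row.identity)
        raw_formula = getattr(row, "formula", None)
        if raw_formula is not None and not pd.isna(raw_formula):
            formula = parse_formula(str(raw_formula))
        else:
            formula = parse_molecule(identity)
        charges = tuple(int(c) for c in str(row.charges).split(";"))
        raw_p = getattr(row, "label_percentiles", "0")
        percentiles = tuple(float(p) for p in str(raw_p).split(";"))
        out.append((MoleculeSpec(identity=identity, formula=formula),
                    charges, percentiles))
    return out


_MATCH_COLUMNS = ["formula", "charge", "label_percentile", "run_id",
                  "spectrum_id", "rt_min", "mscore", "s_mz", "s_intensity",
                  "sigma", "abundance"]


def matches_to_table(matches: Iterable[PatternMatch], run_id: str = "run") -> pd.DataFrame:
    """One row per retained match, deterministic order."""
    rows = [{
        "formula": m.formula, "charge": m.charge,
        "label_percentile": m.label_percentile, "run_id": run_id,
        "spectrum_id": m.spectrum_id, "rt_min": m.retention_time,
        "mscore": m.mscore, "s_mz": m.score_mz, "s_intensity": m.score_intensity,
        "sigma": m.sigma, "abundance": m.abundance,
    } for m in matches]
    df = pd.DataFrame(rows, columns=_MATCH_COLUMNS)
    return df.sort_values(
        ["formula", "charge", "label_percentile", "spectrum_id"],
        kind="mergesort").reset_index(drop=True)


def results_to_table(results: Iterable[QuantResult]) -> pd.DataFrame:
    """Per-MIC summary table."""
    rows = [{
        "formula": r.formula_key, "charge": r.charge,
        "label_percentile": r.label_percentile, "run_id": r.run_id,
        "best_mscore": r.best_mscore, "abundance": r.abundance,
        "rt_of_max_min": r.rt_of_max, "n_matches": r.n_matches,
    } for r in results]
    df = pd.DataFrame(rows, columns=["formula", "charge", "label_percentile",
                                     "run_id", "best_mscore", "abundance",
                                     "rt_of_max_min", "n_matches"])
    return df.sort_values(["formula", "charge", "label_percentile"],
                          kind="mergesort").reset_index(drop=True)
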