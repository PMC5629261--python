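"""Gold-standard style statistical evaluation of labeled quantifications.

Against a known ground-truth enrichment (e.g. a 0 %/60 % two-channel mix),
quantifications are evaluated per (formula, charge, run) unit: each MIC is
first reduced to its best match, the reduced MICs are grouped into 11 label
percentile bins (0–5, 6–15, 16–25, …, 96–100 %), and each bin keeps only
its max-mScore entry.  One ground-truth percentile is considered at a time;
at a given mScore threshold the unit contributes to the confusion counts as:

* TP — the expected bin has matches and no other bin has;
* FP — the expected bin has no matches but another bin has;
* FN — the expected bin has no match at all;
* TN — no unexpected bin has a match.

These rules are applied literally, so a unit whose expected bin is empty
while another bin fires counts as both FP and FN, and a fully silent unit
as both FN and TN; an ``exclusive`` mode assigns each unit to at most one
category instead.  FDR = FP/(FP+TP), TPR = TP/(TP+FN), FPR = FP/(FP+TN);
ratios with zero denominators are reported as missing, not as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quantification import MIC, QuantResult, reduce_mic

__all__ = [
    "LABEL_BINS",
    "bin_index",
    "bin_label",
    "GroundTruth",
    "ConfusionCounts",
    "ThresholdPoint",
    "EvaluationResult",
    "group_and_reduce",
    "confusion_counts",
    "roc_and_fdr",
    "heatmap_table",
]

# (low, high) inclusive percentile ranges of the 11 label bins
LABEL_BINS: tuple[tuple[int, int], ...] = (
    (0, 5), (6, 15), (16, 25), (26, 35), (36, 45), (46, 55),
    (56, 65), (66, 75), (76, 85), (86, 95), (96, 100),
)


def bin_index(percentile: float) -> int:
    """Index of the label bin containing ``percentile``."""
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile outside [0, 100]")
    for i, (lo, hi) in enumerate(LABEL_BINS):
        if lo <= percentile <= hi:
            return i
    # non-integer percentile in a gap (e.g. 5.5): closest bin by midpoint
    mids = [(lo + hi) / 2 for lo, hi in LABEL_BINS]
    return int(np.argmin([abs(percentile - m) for m in mids]))


def bin_label(index: int) -> str:
    lo, hi = LABEL_BINS[index]
    return f"{lo}-{hi}"


@dataclass(frozen=True)
class GroundTruth:
    """True enrichment percentiles of one mixed sample (e.g. {0, 60})."""

    sample_id: str
    percentiles: frozenset[float]

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 100.0 for p in self.percentiles):
            raise ValueError("ground-truth percentile outside [0, 100]")

    @classmethod
    def from_mix(cls, sample_id: str, *percentiles: float) -> "GroundTruth":
        return cls(sample_id=sample_id, percentiles=frozenset(percentiles))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def fdr(self) -> float | None:
        return self.fp / (self.fp + self.tp) if self.fp + self.tp else None

    @property
    def tpr(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def fpr(self) -> float | None:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else None


GroupedUnit = Mapping[int, QuantResult]  # bin index -> best reduced match


def group_and_reduce(
    mics: Iterable[MIC],
    windows: Mapping[tuple[str, int], tuple[float, float]] | None = None,
) -> dict[tuple[str, int, str], dict[int, QuantResult]]:
    """Reduce MICs and group them per (formula, charge, run) into label bins.

    Each MIC reduces to its best match; within a unit each of the 11 bins
    keeps the entry with the highest mScore.  ``windows`` optionally maps
    (formula, charge) to an RT window applied during MIC reduction.
    """
    units: dict[tuple[str, int, str], dict[int, QuantResult]] = {}
    for mic in mics:
        window = None
        if windows is not None:
            window = windows.get((mic.formula_key, mic.charge))
        reduced = reduce_mic(mic, window)
        if reduced is None:
            continue
        unit = units.setdefault((mic.formula_key, mic.charge, mic.run_id), {})
        b = bin_index(reduced.label_percentile)
        prev = unit.get(b)
        if prev is None or (reduced.best_mscore, reduced.abundance) > (
                prev.best_mscore, prev.abundance):
            unit[b] = reduced
    return units


def confusion_counts(
    units: Mapping[tuple, GroupedUnit],
    truth_percentile: float,
    threshold: float,
    mode: str = "literal",
    other_truths: Sequence[float] = (),
) -> ConfusionCounts:
    """Confusion counts over grouped units for one ground-truth percentile.

    One ground truth is considered at a time: in a mixed sample the bins of
    the *other* true percentiles (``other_truths``) are neither expected nor
    unexpected and are ignored, reducing an 11-bin unit to ten bins for a
    two-channel mix.  Only bin entries with mScore >= ``threshold`` count
    as matches.  The default ``literal`` mode applies the TP/FP/FN/TN rules
    independently (one unit may increment both FP and FN, or both FN and
    TN); ``exclusive`` mode keeps TP/FP/FN mutually exclusive.
    """
    if mode not in ("literal", "exclusive"):
        raise ValueError("mode must be 'literal' or 'exclusive'")
    expected_bin = bin_index(truth_percentile)
    ignored = {bin_index(p) for p in other_truths} - {expected_bin}
    tp = fp = fn = tn = 0
    for unit in units.values():
        fired = {b for b, r in unit.items() if r.best_mscore >= threshold}
        fired -= ignored
        expected = expected_bin in fired
        unexpected = bool(fired - {expected_bin})
        if mode == "literal":
            if expected and not unexpected:
                tp += 1
            if not expected and unexpected:
                fp += 1
            if not expected:
                fn += 1
            if not unexpected:
                tn += 1
        else:
            # TP/FP/FN partition the units; TN counted as in literal mode
            if expected and not unexpected:
                tp += 1
            elif unexpected:  # any unexpected match is a false positive
                fp += 1
            else:  # silent unit
                fn += 1
            if not unexpected:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class ThresholdPoint:
    threshold: float
    counts: ConfusionCounts

    @property
    def specificity(self) -> float | None:
        fpr = self.counts.fpr
        return None if fpr is None else 1.0 - fpr


@dataclass(frozen=True)
class EvaluationResult:
    """Per-threshold confusion counts and rates plus ROC points."""

    truth_percentile: float
    points: tuple[ThresholdPoint, ...]

    def roc_points(self) -> list[tuple[float, float]]:
        """(specificity, TPR) pairs, omitting undefined ratios."""
        out = []
        for p in self.points:
            spec, tpr = p.specificity, p.counts.tpr
            if spec is not None and tpr is not None:
                out.append((spec, tpr))
        return out

    def to_table(self) -> pd.DataFrame:
        rows = [{
            "threshold": p.threshold,
            "tp": p.counts.tp, "fp": p.counts.fp,
            "fn": p.counts.fn, "tn": p.counts.tn,
            "fdr": p.counts.fdr, "tpr": p.counts.tpr, "fpr": p.counts.fpr,
            "specificity": p.specificity,
        } for p in self.points]
        return pd.DataFrame(rows)


def roc_and_fdr(
    units: Mapping[tuple, GroupedUnit],
    truth_percentile: float,
    thresholds: Sequence[float] | None = None,
    mode: str = "literal",
    other_truths: Sequence[float] = (),
) -> EvaluationResult:
    """Evaluate one ground truth over an mScore-threshold grid.

    ``other_truths`` lists the remaining true percentiles of the mixed
    sample, whose bins are excluded from the unexpected set (one ground
    truth at a time).  The default grid is 0.00–1.00 in steps of 0.01.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    points = tuple(
        ThresholdPoint(threshold=float(t),
                       counts=confusion_counts(units, truth_percentile, float(t),
                                               mode, other_truths))
        for t in thresholds
    )
    return EvaluationResult(truth_percentile=truth_percentile, points=points)


def heatmap_table(
    matches: Iterable,
    mscore_bin_width: float = 0.05,
) -> pd.DataFrame:
    """2-D histogram of summed match abundance: label bin × mScore bin.

    Accepts anything carrying ``label_percentile``, ``mscore``/``best_mscore``
    and ``abundance`` attributes (raw matches or reduced results).  Rows are
    the 11 label bins, columns the mScore bins; the table total equals the
    total abundance of the input.
    """
    n_score_bins = int(round(1.0 / mscore_bin_width))
    grid = np.zeros((len(LABEL_BINS), n_score_bins))
    for m in matches:
        score = getattr(m, "mscore", None)
        if score is None:
            score = m.best_mscore
        row = bin_index(m.label_percentile)
        col = min(int(score / mscore_bin_width + 1e-9), n_score_bins - 1)
        grid[row, col] += m.abundance
    cols = [f"{i * mscore_bin_width:.2f}" for i in range(n_score_bins)]
    return pd.DataFrame(grid, index=[bin_label(i) for i in range(len(LABEL_BINS))],
                        columns=cols)
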