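"""Threshold training, exon calling and nucleotide-level evaluation.

Every measure here is computed per nucleotide: a position is predicted
exonic when its track score is >= the threshold, and the prediction is
tallied against the truth intervals.  Sensitivity Sn = TP/(TP+FN) and
specificity Sp = TP/(TP+FP) follow the gene-finding convention (Sp is
what classification texts call precision).  The approximate correlation

    ACP = mean of { TP/(TP+FN), TP/(TP+FP), TN/(TN+FN), TN/(TN+FP) }
    AC  = (ACP - 0.5) * 2

summarises both error directions in [-1, 1]; terms with a zero
denominator are omitted from the mean (Burset–Guigo convention).

The training threshold is derived from the per-label score statistics:

    T = (sd_e * mean_i + sd_i * mean_e) / (sd_e + sd_i)

which places T between the intron mean and the exon mean, closer to the
label whose scores are tighter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ExonAnnotation, ScoreTrack


@dataclass
class ConfusionCounts:
    """Nucleotide-level confusion counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


@dataclass
class MetricsResult:
    """Sn, Sp and the approximate-correlation pair (ACP, AC)."""

    sn: float
    sp: float
    acp: float
    ac: float


@dataclass
class ThresholdModel:
    """Training statistics of exon/intron scores and the derived threshold."""

    mean_exon: float
    sd_exon: float
    mean_intron: float
    sd_intron: float
    threshold: float


@dataclass
class RocCurve:
    """Threshold-swept ROC curve with trapezoidal AUC."""

    thresholds: np.ndarray  # descending; starts at +inf
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _scores_labels(track: ScoreTrack, truth: ExonAnnotation) -> tuple[np.ndarray, np.ndarray]:
    if track.sequence_id != truth.sequence_id:
        raise ValueError(
            f"sequence id mismatch: track {track.sequence_id!r} vs truth {truth.sequence_id!r}"
        )
    labels = truth.mask(len(track.values) + track.offset - 1)[track.offset - 1 :]
    return track.values, labels


def pooled_scores_labels(
    tracks: list[ScoreTrack], truths: list[ExonAnnotation]
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-position scores and truth labels across sequences.

    Dataset-level metrics pool nucleotides (one confusion table per
    dataset) rather than averaging per-sequence metrics.
    """
    truth_by_id = {t.sequence_id: t for t in truths}
    scores, labels = [], []
    for track in tracks:
        # a sequence absent from the truth file simply has no exons
        truth = truth_by_id.get(
            track.sequence_id, ExonAnnotation(track.sequence_id, [])
        )
        s, l = _scores_labels(track, truth)
        scores.append(s)
        labels.append(l)
    return np.concatenate(scores), np.concatenate(labels)


def confusion_from_arrays(scores: np.ndarray, labels: np.ndarray, t: float) -> ConfusionCounts:
    pred = scores >= t
    labels = labels.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(pred & labels)),
        TN=int(np.sum(~pred & ~labels)),
        FP=int(np.sum(pred & ~labels)),
        FN=int(np.sum(~pred & labels)),
    )


def confusion_at_threshold(track: ScoreTrack, truth: ExonAnnotation, t: float) -> ConfusionCounts:
    """Tally per-nucleotide predictions (score >= t is exon) against truth."""
    scores, labels = _scores_labels(track, truth)
    return confusion_from_arrays(scores, labels, t)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is zero; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    """Sn = TP/(TP+FN): fraction of exon nucleotides recovered."""
    return _ratio(c.TP, c.TP + c.FN, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """Sp = TP/(TP+FP): fraction of predicted exon nucleotides that are exonic."""
    return _ratio(c.TP, c.TP + c.FP, "specificity")


def approximate_correlation(c: ConfusionCounts) -> MetricsResult:
    """ACP/AC with zero-denominator terms omitted from the four-term mean."""
    terms = []
    for num, den in (
        (c.TP, c.TP + c.FN),
        (c.TP, c.TP + c.FP),
        (c.TN, c.TN + c.FN),
        (c.TN, c.TN + c.FP),
    ):
        if den > 0:
            terms.append(num / den)
    if not terms:
        raise ValueError("all four ACP terms are undefined (empty confusion table)")
    acp = float(np.mean(terms))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sn, sp = sensitivity(c), specificity(c)
    return MetricsResult(sn=sn, sp=sp, acp=acp, ac=(acp - 0.5) * 2.0)


def roc_from_arrays(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate truth: need both exon and intron positions")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels)
    cum_fp = np.cumsum(~sorted_labels)
    # last index of each unique score value
    boundary = np.nonzero(np.diff(sorted_scores) != 0)[0]
    idx = np.concatenate([boundary, [scores.size - 1]])
    thresholds = np.concatenate([[np.inf], sorted_scores[idx]])
    tpr = np.concatenate([[0.0], cum_tp[idx] / n_pos])
    fpr = np.concatenate([[0.0], cum_fp[idx] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def roc_curve(track: ScoreTrack, truth: ExonAnnotation) -> RocCurve:
    """ROC over all unique score thresholds (descending, +inf sentinel first)."""
    scores, labels = _scores_labels(track, truth)
    return roc_from_arrays(scores, labels)


def fp_at_sensitivity_arrays(
    scores: np.ndarray, labels: np.ndarray, target_sn: float
) -> tuple[int, float, float]:
    if not 0.0 < target_sn <= 1.0:
        raise ValueError("target sensitivity must lie in (0, 1]")
    curve = roc_from_arrays(scores, labels)
    reachable = curve.tpr >= target_sn
    if not reachable.any():
        raise ValueError(f"maximum sensitivity {curve.tpr.max():.3f} < target {target_sn}")
    t = float(curve.thresholds[int(np.argmax(reachable))])
    c = confusion_from_arrays(scores, labels, t)
    res = approximate_correlation(c)
    return c.FP, res.sp, res.ac


def fp_at_sensitivity(
    track: ScoreTrack, truth: ExonAnnotation, target_sn: float
) -> tuple[int, float, float]:
    """FP count, Sp and AC at the largest threshold reaching Sn >= target_sn."""
    scores, labels = _scores_labels(track, truth)
    return fp_at_sensitivity_arrays(scores, labels, target_sn)


def train_threshold(exon_scores, intron_scores) -> ThresholdModel:
    """Derive the calling threshold from per-label training score statistics.

    T = (sd_e * mean_i + sd_i * mean_e) / (sd_e + sd_i); standard
    deviations are sample (ddof=1) statistics.
    """
    exon_scores = np.asarray(exon_scores, dtype=np.float64)
    intron_scores = np.asarray(intron_scores, dtype=np.float64)
    if exon_scores.size < 2 or intron_scores.size < 2:
        raise ValueError("need at least two scores per label to estimate a spread")
    mean_e, sd_e = float(exon_scores.mean()), float(exon_scores.std(ddof=1))
    mean_i, sd_i = float(intron_scores.mean()), float(intron_scores.std(ddof=1))
    if sd_e + sd_i == 0.0:
        raise ValueError("both score spreads are zero; threshold undefined")
    t = (sd_e * mean_i + sd_i * mean_e) / (sd_e + sd_i)
    return ThresholdModel(
        mean_exon=mean_e, sd_exon=sd_e, mean_intron=mean_i, sd_intron=sd_i, threshold=t
    )


def call_exons(
    track: ScoreTrack, t: float, min_length: int = 0, merge_gap: int = 0
) -> ExonAnnotation:
    """Extract predicted exon intervals as maximal runs of score >= t.

    Runs separated by a gap of at most ``merge_gap`` bases are merged;
    merged runs shorter than ``min_length`` are dropped.  Intervals are
    1-based inclusive in sequence coordinates.
    """
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    above = track.values >= t
    intervals: list[tuple[int, int]] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            start = track.offset + i
            end = track.offset + j
            if intervals and start - intervals[-1][1] - 1 <= merge_gap:
                intervals[-1] = (intervals[-1][0], end)
            else:
                intervals.append((start, end))
            i = j + 1
        else:
            i += 1
    intervals = [iv for iv in intervals if iv[1] - iv[0] + 1 >= min_length]
    return ExonAnnotation(sequence_id=track.sequence_id, intervals=intervals)
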