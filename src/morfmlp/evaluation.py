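"""ROC construction, AUC, and FPR-at-fixed-TPR operating points.

TPR = TP / N_MoRF and FPR = FP / N_non. Residues sharing a score enter the
confusion matrix together: the threshold set is the distinct scores plus a
+inf sentinel, swept in descending order, and the AUC is the trapezoidal
area under the resulting curve (equal to the tie-aware Mann-Whitney pair
statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlignmentError, EvaluationError
from .seq_io import PredictionTrack, RegionAnnotation, labels_from_regions

DEFAULT_TPR_TARGETS = (0.2, 0.3, 0.4)

#: MoRF regions up to this many residues count as "short" in stratified runs.
SHORT_REGION_MAX = 30


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending; leading +inf sentinel
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_morf: int
    n_non: int


def roc(scores, labels) -> ROCResult:
    """Sweep every distinct score as a threshold (call = score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be 1-D and equal length")
    n_morf = int((labels == 1).sum())
    n_non = int((labels == 0).sum())
    if n_morf == 0 or n_non == 0:
        raise EvaluationError(
            f"ROC needs both classes (got {n_morf} positives, {n_non} negatives)"
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.flatnonzero(np.diff(s) != 0)
    block_ends = np.concatenate([distinct, [s.size - 1]])  # last index per tie block
    tp = np.cumsum(y == 1)[block_ends]
    fp = np.cumsum(y == 0)[block_ends]
    thresholds = np.concatenate([[np.inf], s[block_ends]])
    tpr = np.concatenate([[0.0], tp / n_morf])
    fpr = np.concatenate([[0.0], fp / n_non])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds, tpr, fpr, auc, n_morf, n_non)


def fpr_at_tpr(result: ROCResult,
               tpr_targets: Sequence[float] = DEFAULT_TPR_TARGETS) -> dict[float, float]:
    """Smallest FPR among operating points reaching each TPR target."""
    out: dict[float, float] = {}
    for target in tpr_targets:
        ok = result.tpr >= target
        out[float(target)] = float(result.fpr[ok].min()) if ok.any() else 1.0
    return out


def _region_lengths_per_position(regions: Iterable[RegionAnnotation],
                                 length: int) -> np.ndarray:
    """For each position, the length of the longest annotated region covering it."""
    lens = np.zeros(length, dtype=int)
    for r in regions:
        rlen = r.end - r.start + 1
        span = slice(r.start - 1, r.end)
        lens[span] = np.maximum(lens[span], rlen)
    return lens


def evaluate_run(tracks: Sequence[PredictionTrack],
                 regions: Iterable[RegionAnnotation],
                 strata: bool = False,
                 tpr_targets: Sequence[float] = DEFAULT_TPR_TARGETS) -> dict[str, dict]:
    """Pool residues across sequences and report AUC + FPR-at-TPR.

    With ``strata=True``, positives are additionally split by containing-
    region length (short <= 30 residues, long > 30); each stratum's positives
    are scored against all pooled negatives. Empty strata are omitted.
    """
    by_id: dict[str, list[RegionAnnotation]] = {}
    for r in regions:
        by_id.setdefault(r.sequence_id, []).append(r)
    track_ids = {t.sequence_id for t in tracks}
    unknown = set(by_id) - track_ids
    if unknown:
        raise AlignmentError(
            f"regions reference sequences with no predictions: {sorted(unknown)}"
        )
    all_scores, all_labels, all_region_lens = [], [], []
    for t in tracks:
        length = t.scores.size
        regs = by_id.get(t.sequence_id, [])
        all_scores.append(t.scores)
        all_labels.append(labels_from_regions(regs, length, t.sequence_id))
        all_region_lens.append(_region_lengths_per_position(regs, length))
    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    region_lens = np.concatenate(all_region_lens)

    def stratum_report(mask: np.ndarray) -> dict:
        r = roc(scores[mask], labels[mask])
        return {
            "auc": r.auc,
            "fpr_at_tpr": fpr_at_tpr(r, tpr_targets),
            "n_morf": r.n_morf,
            "n_non": r.n_non,
        }

    report = {"all": stratum_report(np.ones_like(labels, dtype=bool))}
    if strata:
        negatives = labels == 0
        short_pos = (labels == 1) & (region_lens <= SHORT_REGION_MAX)
        long_pos = (labels == 1) & (region_lens > SHORT_REGION_MAX)
        if short_pos.any():
            report["short"] = stratum_report(short_pos | negatives)
        if long_pos.any():
            report["long"] = stratum_report(long_pos | negatives)
    return report


def report_to_rows(report: Mapping[str, dict]) -> list[dict]:
    """Flatten an evaluate_run report into table rows (one per stratum)."""
    rows = []
    for stratum, metrics in report.items():
        row = {
            "stratum": stratum,
            "auc": metrics["auc"],
            "n_morf": metrics["n_morf"],
            "n_non": metrics["n_non"],
        }
        for target, value in metrics["fpr_at_tpr"].items():
            row[f"fpr_at_tpr_{target:g}"] = value
        rows.append(row)
    return rows
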