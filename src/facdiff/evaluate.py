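"""Scoring detections against simulation truth: TPR, FDR and AUROC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class EvalReport:
    """Detection-quality summary for one analysis of one simulated dataset."""

    tpr: float
    fdr: float
    auroc: float
    n_detected: int
    n_true: int


def confusion_metrics(detected: set, truth: set) -> tuple[float, float, int]:
    """True-positive rate and false-discovery rate of a detected edge set.

    FDR of an empty detection set is defined as 0 so metric tables aggregate
    cleanly.
    """
    if not truth:
        raise ValueError("truth set is empty; TPR undefined")
    detected = set(detected)
    tp = len(detected & set(truth))
    tpr = tp / len(truth)
    fdr = (len(detected) - tp) / len(detected) if detected else 0.0
    return tpr, fdr, len(detected)


def auroc(scores: np.ndarray, truth_flags: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUROC of per-edge scores against truth flags.

    Ties get average ranks, so any strictly monotone transform of the scores
    (e.g. 1/p versus -p) yields the same value.
    """
    scores = np.asarray(scores, dtype=float)
    truth_flags = np.asarray(truth_flags, dtype=bool)
    n_pos = int(truth_flags.sum())
    n_neg = len(truth_flags) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one true and one false edge")
    ranks = rankdata(scores)
    return float((ranks[truth_flags].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def evaluate_detection(detected: set, scores: np.ndarray,
                       truth_flags: np.ndarray,
                       edge_pairs: tuple[np.ndarray, np.ndarray]) -> EvalReport:
    """Full report: confusion metrics of the detected set plus score AUROC.

    ``scores`` ranks edges (larger = more differential; typically the inverse
    approximate p-value); ``edge_pairs`` gives the (gene1, gene2) indices of
    the lexicographic edge vector the flags and scores follow.
    """
    truth_flags = np.asarray(truth_flags, dtype=bool)
    ii, jj = edge_pairs
    truth = {(int(a), int(b)) for a, b, f in zip(ii, jj, truth_flags) if f}
    tpr, fdr, n_detected = confusion_metrics(detected, truth)
    return EvalReport(tpr=tpr, fdr=fdr, auroc=auroc(scores, truth_flags),
                      n_detected=n_detected, n_true=len(truth))
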