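"""Scoring of mapper output against simulation truth.

A detected QTL within 5 cM of a simulated QTL counts as that QTL
(greedy nearest-distance assignment, each detection consumed at most
once). Power per QTL is the fraction of replicates with a match; effect
accuracy is summarized by the mean absolute deviation and mean squared
error of the matched estimates; the false positive rate divides unmatched
detections by the number of zero-effect positions considered (scan-grid
loci farther than the window from every simulated QTL) times replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationMetrics",
    "match_detections",
    "compute_metrics",
    "count_zero_effect_positions",
    "MATCH_WINDOW_CM",
]

MATCH_WINDOW_CM = 5.0


@dataclass
class EvaluationMetrics:
    """Power / FPR / accuracy summary over simulation replicates."""

    per_qtl: pd.DataFrame     # position, power, mad, mse, n_detected
    average_power: float
    fpr: float
    n_replicates: int
    n_false_positives: int


def match_detections(detected_positions, truth_positions,
                     window: float = MATCH_WINDOW_CM):
    """Greedy nearest-distance assignment of detections to true QTL.

    Returns ``(assignment, false_positive_mask)`` where ``assignment[t]``
    is the detection index matched to truth ``t`` or -1, and the mask flags
    detections matched to no truth. Pairs farther apart than ``window`` cM
    never match.
    """
    det = np.asarray(detected_positions, dtype=float)
    tru = np.asarray(truth_positions, dtype=float)
    assignment = np.full(tru.size, -1, dtype=int)
    used = np.zeros(det.size, dtype=bool)
    if det.size and tru.size:
        dist = np.abs(det[:, None] - tru[None, :])
        pairs = [
            (dist[i, j], i, j)
            for i in range(det.size)
            for j in range(tru.size)
            if dist[i, j] <= window
        ]
        for _, i, j in sorted(pairs):
            if not used[i] and assignment[j] < 0:
                used[i] = True
                assignment[j] = i
    return assignment, ~used


def count_zero_effect_positions(scan_positions, truth_positions,
                                window: float = MATCH_WINDOW_CM) -> int:
    """Scan-grid loci farther than ``window`` cM from every simulated QTL."""
    pos = np.asarray(scan_positions, dtype=float)
    tru = np.asarray(truth_positions, dtype=float)
    if tru.size == 0:
        return int(pos.size)
    near = np.abs(pos[:, None] - tru[None, :]).min(axis=1) <= window
    return int(np.sum(~near))


def compute_metrics(reports, truth: pd.DataFrame, n_zero_positions: int,
                    window: float = MATCH_WINDOW_CM) -> EvaluationMetrics:
    """Score a list of per-replicate QTL reports against the truth table.

    ``reports`` holds one QTL-report DataFrame per replicate (columns
    ``position_cM`` and ``effect``); ``truth`` has ``position_cM`` and
    ``effect``. MAD and MSE average over matched detections only; a QTL
    never detected reports NaN there rather than zero.
    """
    if len(reports) == 0:
        raise ValueError("need at least one replicate")
    tru_pos = truth["position_cM"].to_numpy(dtype=float)
    tru_eff = truth["effect"].to_numpy(dtype=float)
    T = tru_pos.size
    hits = np.zeros(T, dtype=int)
    errors = [[] for _ in range(T)]
    n_fp = 0
    for rep in reports:
        det_pos = rep["position_cM"].to_numpy(dtype=float)
        det_eff = rep["effect"].to_numpy(dtype=float)
        assignment, fp_mask = match_detections(det_pos, tru_pos, window=window)
        n_fp += int(fp_mask.sum())
        for t, i in enumerate(assignment):
            if i >= 0:
                hits[t] += 1
                errors[t].append(det_eff[i] - tru_eff[t])
    R = len(reports)
    power = hits / R
    mad = np.array([np.mean(np.abs(e)) if e else np.nan for e in errors])
    mse = np.array([np.mean(np.square(e)) if e else np.nan for e in errors])
    per_qtl = pd.DataFrame(
        {
            "position_cM": tru_pos,
            "effect": tru_eff,
            "power": power,
            "mad": mad,
            "mse": mse,
            "n_detected": hits,
        }
    )
    fpr = n_fp / (R * n_zero_positions) if n_zero_positions > 0 else np.nan
    return EvaluationMetrics(
        per_qtl=per_qtl,
        average_power=float(power.mean()) if T else np.nan,
        fpr=float(fpr) if np.isfinite(fpr) else np.nan,
        n_replicates=R,
        n_false_positives=int(n_fp),
    )
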