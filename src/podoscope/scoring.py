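"""Detection scoring against ground truth by proximity matching.

A detection within the match radius (0.4 um by default) of an unmatched
ground-truth podosome is a true positive; matching is one-to-one and
greedy by ascending pair distance.  The false discovery rate is
FP / (TP + FP) and the recall TP / (TP + FN), the validation metrics of
the original pipeline comparison against manual annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["MatchResult", "match_detections"]


@dataclass
class MatchResult:
    """Outcome of one-to-one proximity matching."""

    pairs: list  # (detected_idx, truth_idx, distance_um)
    false_positives: np.ndarray  # unmatched detection indices
    false_negatives: np.ndarray  # unmatched truth indices
    match_radius: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)

    @property
    def fdr(self) -> float:
        total = self.tp + self.fp
        return self.fp / total if total else 0.0

    @property
    def recall(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else 1.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "fdr": self.fdr,
            "recall": self.recall,
            "match_radius": self.match_radius,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def match_detections(
    detected,
    truth,
    match_radius: float = 0.4,
    method: str = "greedy",
) -> MatchResult:
    """Match detections to ground-truth positions within ``match_radius``.

    ``method='greedy'`` (default) accepts candidate pairs in ascending
    distance order; ``method='hungarian'`` uses an optimal assignment and
    exists for sensitivity checks.  Both enforce one-to-one matching and
    reject pairs beyond the radius.
    """
    if match_radius < 0:
        raise ValueError("match radius must be non-negative")
    if method not in ("greedy", "hungarian"):
        raise ValueError(f"unknown matching method {method!r}")
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(det) == 0 or len(tru) == 0:
        return MatchResult(
            pairs=[],
            false_positives=np.arange(len(det)),
            false_negatives=np.arange(len(tru)),
            match_radius=match_radius,
        )
    d = cdist(det, tru)
    pairs: list[tuple[int, int, float]] = []
    if method == "greedy":
        ii, jj = np.nonzero(d <= match_radius)
        order = sorted(range(len(ii)), key=lambda k: (d[ii[k], jj[k]], ii[k], jj[k]))
        used_det = np.zeros(len(det), dtype=bool)
        used_tru = np.zeros(len(tru), dtype=bool)
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            if used_det[i] or used_tru[j]:
                continue
            used_det[i] = used_tru[j] = True
            pairs.append((i, j, float(d[i, j])))
    else:
        penalty = max(match_radius, d.max()) * 10 + 1.0
        cost = np.where(d <= match_radius, d, penalty)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if d[i, j] <= match_radius:
                pairs.append((int(i), int(j), float(d[i, j])))
    matched_det = {i for i, _, _ in pairs}
    matched_tru = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        false_positives=np.array(
            [i for i in range(len(det)) if i not in matched_det], dtype=int
        ),
        false_negatives=np.array(
            [j for j in range(len(tru)) if j not in matched_tru], dtype=int
        ),
        match_radius=match_radius,
    )
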