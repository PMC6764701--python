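"""Evaluation surfaces: accuracy, F1, top-fraction FP ratio, score histograms,
and the hit ratio on an all-positive independent link set.

The score histogram uses the five fixed bins [0,0.2), [0.2,0.4), [0.4,0.6),
[0.6,0.8), [0.8,1.0] (the last bin closed), each split into true and false
predictions.  The top-fraction false-positive ratio ranks predictions by
score and reports the fraction of actual negatives among the top
``ceil(fraction * n)`` — a false-discovery view of the most confident calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalReport", "evaluate", "hit_ratio", "BIN_EDGES"]

BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
_BIN_LABELS = ("[0.0,0.2)", "[0.2,0.4)", "[0.4,0.6)", "[0.6,0.8)", "[0.8,1.0]")


@dataclass
class EvalReport:
    accuracy: float
    f1: float
    precision: float
    recall: float
    top_fraction_fp_ratio: float
    top_fraction: float
    histogram: dict[str, dict[str, int]]  # bin label -> {"true": n, "false": n}
    n_scorable: int
    n_unscorable: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "f1": self.f1,
            "precision": self.precision, "recall": self.recall,
            "top_fraction_fp_ratio": self.top_fraction_fp_ratio,
            "top_fraction": self.top_fraction,
            "histogram": self.histogram,
            "n_scorable": self.n_scorable, "n_unscorable": self.n_unscorable,
            "notes": list(self.notes),
        }

    def histogram_frame(self):
        import pandas as pd
        rows = [{"bin": b, "true": v["true"], "false": v["false"]}
                for b, v in self.histogram.items()]
        return pd.DataFrame(rows)


def _bin_index(score: float) -> int:
    # half-open bins; a score at an interior edge falls in the upper bin,
    # and 1.0 closes the last bin
    return min(int(score / 0.2), 4)


def evaluate(predictions, labels: dict[tuple[str, str], int],
             top_fraction: float = 0.10) -> EvalReport:
    """Score predictions against labels.

    ``labels`` maps (tf_id, target_id) to the true 0/1 label.  Unscorable
    predictions are excluded from every denominator and counted separately.
    Raises if no prediction is scorable.
    """
    scorable = [p for p in predictions if p.scorable]
    n_unscorable = len(predictions) - len(scorable)
    if not scorable:
        raise ValueError("no scorable predictions to evaluate")
    y = np.array([labels[p.key] for p in scorable], dtype=int)
    yhat = np.array([int(p.decision) for p in scorable], dtype=int)
    scores = np.array([p.score for p in scorable], dtype=float)

    notes = []
    accuracy = float(np.mean(y == yhat))
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    if tp + fp == 0:
        precision = 0.0
        f1 = 0.0
        notes.append("no predicted positives; F1 defined as 0")
    else:
        precision = tp / (tp + fp)
        recall_ = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = (2 * precision * recall_ / (precision + recall_)
              if precision + recall_ > 0 else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else 0.0

    # top-fraction FP ratio: stable ordering by (score desc, tf_id, target_id)
    order = sorted(range(len(scorable)),
                   key=lambda i: (-scores[i], scorable[i].tf_id,
                                  scorable[i].target_id))
    m = int(np.ceil(top_fraction * len(scorable)))
    top = order[:m]
    top_fp = float(np.mean([y[i] == 0 for i in top])) if m else 0.0

    hist = {b: {"true": 0, "false": 0} for b in _BIN_LABELS}
    for i, p in enumerate(scorable):
        key = _BIN_LABELS[_bin_index(p.score)]
        hist[key]["true" if y[i] == yhat[i] else "false"] += 1

    if n_unscorable:
        notes.append(f"{n_unscorable} pair(s) unscorable (no shared orientation)")
    notes.append("accuracy may be underestimated: unrevealed true links can "
                 "be sampled as negatives")
    return EvalReport(accuracy=accuracy, f1=f1, precision=precision,
                      recall=recall, top_fraction_fp_ratio=top_fp,
                      top_fraction=top_fraction, histogram=hist,
                      n_scorable=len(scorable), n_unscorable=n_unscorable,
                      notes=notes)


def hit_ratio(predictions) -> dict:
    """Hit ratio of an all-positive link set, with high-score bands.

    Hit = decision positive at the prediction's threshold.  The bands
    report, among the hits, the fraction with score strictly > 0.8 and
    strictly > 0.6.
    """
    scorable = [p for p in predictions if p.scorable]
    if not scorable:
        raise ValueError("hit_ratio needs at least one scorable prediction")
    hits = [p for p in scorable if p.decision]
    ratio = len(hits) / len(scorable)
    band = {"gt_0.8": 0.0, "gt_0.6": 0.0}
    if hits:
        band["gt_0.8"] = float(np.mean([p.score > 0.8 for p in hits]))
        band["gt_0.6"] = float(np.mean([p.score > 0.6 for p in hits]))
    return {"hit_ratio": ratio, "n_links": len(scorable), "n_hits": len(hits),
            "hits_gt_0.8": band["gt_0.8"], "hits_gt_0.6": band["gt_0.6"]}
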