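"""Link-score aggregation: from per-image-pair probabilities to TF->target scores.

The link score for a gene pair is the arithmetic mean of the classifier's
probabilities over *all* orientation-matched image-pair instances,

    score(i, j) = sum_o sum_p sum_q f(x_i,o^(p) (+) x_j,o^(q))
                  / sum_o |X_i,o| * |X_j,o|,

and the decision applies a threshold (default 0.5, with score >= threshold
called positive).  Pairs with no shared non-empty orientation cannot be
scored; they are flagged explicitly, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import GenePairLabel, enumerate_instances

__all__ = ["LinkPrediction", "aggregate", "predict_links", "write_predictions"]

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class LinkPrediction:
    tf_id: str
    target_id: str
    score: float            # nan when unscorable
    decision: bool | None   # None when unscorable
    n_instances: int
    scorable: bool
    threshold_used: float
    per_instance_scores: tuple[float, ...] | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.tf_id, self.target_id)


def aggregate(pair: GenePairLabel, instance_scores,
              threshold: float = DEFAULT_THRESHOLD,
              keep_instance_scores: bool = True) -> LinkPrediction:
    """Mean-aggregate per-instance probabilities into one link prediction.

    ``instance_scores`` is a sequence of (orientation, probability); an
    empty sequence yields an unscorable prediction with ``scorable=False``.
    """
    probs = np.asarray([p for _, p in instance_scores], dtype=np.float64)
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValueError("instance scores must lie in [0,1]")
    if probs.size == 0:
        return LinkPrediction(pair.tf_id, pair.target_id, float("nan"), None,
                              0, False, threshold,
                              per_instance_scores=() if keep_instance_scores else None)
    score = float(probs.mean())
    return LinkPrediction(
        pair.tf_id, pair.target_id, score, bool(score >= threshold),
        int(probs.size), True, threshold,
        per_instance_scores=tuple(float(p) for p in probs)
        if keep_instance_scores else None)


def predict_links(net, pairs, image_sets, threshold: float = DEFAULT_THRESHOLD,
                  batch_size: int = 64,
                  keep_instance_scores: bool = False) -> list[LinkPrediction]:
    """One LinkPrediction per pair (unscorable pairs flagged, not dropped).

    All instances across pairs are scored in one batched pass; the result
    is deterministic in eval mode.
    """
    from .model import score_instances

    all_instances = []
    slices = []
    for pair in pairs:
        for gid in (pair.tf_id, pair.target_id):
            if gid not in image_sets:
                raise KeyError(f"pair ({pair.tf_id}, {pair.target_id}) references "
                               f"unknown gene {gid!r}")
        ins = enumerate_instances(pair, image_sets[pair.tf_id],
                                  image_sets[pair.target_id])
        slices.append((pair, len(all_instances), len(ins)))
        all_instances.extend(ins)

    scores = score_instances(net, all_instances, image_sets, batch_size)
    out = []
    for pair, start, n in slices:
        chunk = [(all_instances[start + k].orientation, float(scores[start + k]))
                 for k in range(n)]
        out.append(aggregate(pair, chunk, threshold,
                             keep_instance_scores=keep_instance_scores))
    return out


def write_predictions(predictions, path) -> None:
    """TSV: tf_id, target_id, score, decision, n_instances (stable format)."""
    lines = ["tf_id\ttarget_id\tscore\tdecision\tn_instances"]
    for p in predictions:
        score = "NA" if not p.scorable else repr(p.score)
        dec = "NA" if p.decision is None else int(p.decision)
        lines.append(f"{p.tf_id}\t{p.target_id}\t{score}\t{dec}\t{p.n_instances}")
    Path(path).write_text("\n".join(lines) + "\n")
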