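"""Classification metrics, overlap analysis and attention export."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence, Set

import numpy as np
from scipy import stats

__all__ = [
    "MetricReport",
    "compute_metrics",
    "overlap_analysis",
    "export_attention",
]


@dataclass(frozen=True)
class MetricReport:
    auroc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float
    n_positive: int
    n_negative: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _rank_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: mean rank of positives, ties averaged."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float | None = None,
) -> MetricReport:
    """AUROC plus thresholded accuracy/precision/recall/F1.

    The default threshold is the score median; precision and recall fall back
    to 0 when undefined (no predicted / no true positives).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: labels contain a single class")
    if threshold is None:
        threshold = float(np.median(scores))
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return MetricReport(
        auroc=_rank_auroc(scores, labels),
        accuracy=(tp + tn) / len(labels),
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=float(threshold),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def overlap_analysis(correct_sets: Mapping[str, Set]) -> dict[str, int]:
    """Exclusive-region counts for the Venn diagram of 2-3 models' hits.

    Keys are '&'-joined sorted model names; each id is counted once, in the
    region of exactly the models that contain it.
    """
    names = sorted(correct_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("overlap analysis requires 2 or 3 sets")
    universe = set().union(*correct_sets.values())
    regions: dict[str, int] = {}
    for item in universe:
        members = tuple(n for n in names if item in correct_sets[n])
        key = "&".join(members)
        regions[key] = regions.get(key, 0) + 1
    # make every region explicit, including empty ones
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions.setdefault("&".join(combo), 0)
    return regions


def export_attention(state, seq, vocab, out_path=None) -> dict:
    """Per-layer, per-head post-softmax attention for one sequence.

    Returns (and optionally writes as JSON) a payload with the sequence's
    code labels and one L x L matrix per layer/head, rows normalized over
    visible positions, zero strictly above the diagonal.
    """
    from .transformer import forward_with_attention

    keep = min(len(seq), state.config.max_len)
    ids = vocab.encode_sequence(seq)[-keep:]
    times = seq.times[-keep:]
    _, attn = forward_with_attention(ids[None, :], times[None, :], state)
    payload = {
        "sample_id": seq.sample_id,
        "codes": seq.codes[-keep:],
        "layers": [
            [np.asarray(head[0]).tolist() for head in layer] for layer in attn
        ],
    }
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(payload, fh)
    return payload
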