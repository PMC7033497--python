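"""Closed-set identification: averaged distances, rank-k rates, CMC curve.

Identification compares a probe window against the enrolled template of
every subject for the probed gesture.  Instead of voting binary
decisions, the Mahalanobis distances themselves are smoothed by a
trailing moving average over m points (within the repetition; shorter
history during warm-up), and subjects are ranked by ascending averaged
distance.  Rank-k is the fraction of test windows whose true subject
appears among the k nearest templates; the CMC curve plots rank-k
against k.  Ties place the true subject at its worst tied position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import FoldScores

__all__ = [
    "CMCCurve",
    "trailing_mean",
    "averaged_distance_stream",
    "rank_of_true_identity",
    "ranks_for_gesture",
    "compute_cmc",
    "evaluate_identification",
]


def trailing_mean(
    values: np.ndarray,
    m: int,
    segment_bounds: Iterable[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Moving average over each point and its m-1 predecessors.

    Works along axis 0 (values may be a matrix of streams); never crosses
    a segment boundary; at warm-up the available shorter history is used.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    v = np.asarray(values, dtype=float)
    if v.shape[0] == 0 or m == 1:
        return v.copy()
    bounds = list(segment_bounds) if segment_bounds is not None else [(0, v.shape[0])]
    out = np.empty_like(v)
    for a, b in bounds:
        block = v[a:b]
        n = block.shape[0]
        c = np.concatenate(
            [np.zeros((1,) + block.shape[1:]), np.cumsum(block, axis=0)], axis=0
        )
        k = np.arange(n)
        e = np.minimum(k + 1, m)
        out[a:b] = (c[k + 1] - c[k + 1 - e]) / e.reshape((-1,) + (1,) * (block.ndim - 1))
    return out


def averaged_distance_stream(
    scores: pd.DataFrame,
    m: int,
    segment_bounds: Iterable[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Moving-average every template column of a stream-ordered score table."""
    avg = trailing_mean(scores.to_numpy(), m, segment_bounds)
    return pd.DataFrame(avg, index=scores.index, columns=scores.columns)


def rank_of_true_identity(distances: Mapping[int, float], true_subject: int) -> int:
    """1-based rank of the true subject among ascending distances.

    Pessimistic tie rule: the true subject takes the worst position among
    its ties, so all-tied distances give rank N.
    """
    if true_subject not in distances:
        raise KeyError(f"true subject {true_subject} is not enrolled")
    d_true = distances[true_subject]
    d = np.array(list(distances.values()), dtype=float)
    return int(np.sum(d < d_true) + np.sum(d == d_true))


def _segment_bounds_of(probes: pd.DataFrame) -> list[tuple[int, int]]:
    ids = probes[["subject", "gesture", "repetition"]].to_numpy()
    if len(ids) == 0:
        return []
    change = np.any(ids[1:] != ids[:-1], axis=1)
    starts = np.concatenate([[0], np.flatnonzero(change) + 1])
    stops = np.concatenate([starts[1:], [len(ids)]])
    return list(zip(starts.tolist(), stops.tolist()))


def ranks_for_gesture(fs: FoldScores, gesture: int, m: int) -> np.ndarray:
    """Rank of the true identity for every test window of one gesture.

    Uses the fold's scores of the gesture's probes against every
    subject's template for that gesture, averaged over m trailing points
    within each repetition.
    """
    mask = (fs.probes["gesture"] == gesture).to_numpy()
    probes = fs.probes.loc[mask].reset_index(drop=True)
    subjects = sorted({s for s, g in fs.scores.columns if g == gesture})
    missing = [s for s in subjects if (s, gesture) not in fs.scores.columns]
    if missing:
        raise KeyError(f"missing templates for subjects {missing}, gesture {gesture}")
    cols = [(s, gesture) for s in subjects]
    D = fs.scores.loc[mask, cols].to_numpy()
    D = trailing_mean(D, m, _segment_bounds_of(probes))
    true_idx = np.searchsorted(subjects, probes["subject"].to_numpy())
    d_true = D[np.arange(len(D)), true_idx]
    ranks = (D < d_true[:, None]).sum(axis=1) + (D == d_true[:, None]).sum(axis=1)
    return ranks


@dataclass
class CMCCurve:
    """Cumulative match characteristic: identification rate per rank."""

    ranks: np.ndarray  # 1 .. N enrolled subjects
    rate: np.ndarray
    gesture_id: int
    vote_size: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.rate) < -1e-12):
            raise ValueError("CMC rate must be nondecreasing in rank")
        if self.rate.min() < -1e-12 or self.rate.max() > 1 + 1e-12:
            raise ValueError("CMC rate must lie in [0, 1]")

    def rank_k(self, k: int) -> float:
        k = min(k, len(self.ranks))
        return float(self.rate[k - 1])


def compute_cmc(
    fold_scores: Mapping[int, FoldScores], gesture: int, m: int
) -> CMCCurve:
    """CMC curve for one gesture pooled over CV folds."""
    all_ranks = []
    n_subjects = None
    for fold in sorted(fold_scores):
        fs = fold_scores[fold]
        subjects = sorted({s for s, g in fs.scores.columns if g == gesture})
        n_subjects = len(subjects)
        all_ranks.append(ranks_for_gesture(fs, gesture, m))
    ranks = np.concatenate(all_ranks)
    ks = np.arange(1, n_subjects + 1)
    rate = np.array([(ranks <= k).mean() for k in ks])
    return CMCCurve(ranks=ks, rate=rate, gesture_id=gesture, vote_size=m)


def evaluate_identification(
    fold_scores: Mapping[int, FoldScores],
    vote_sizes: Sequence[int] = (1, 5, 9, 13),
) -> tuple[pd.DataFrame, dict[tuple[int, int], CMCCurve]]:
    """Per-(gesture, fold, m) rank-1/rank-5 records plus pooled CMC curves."""
    records = []
    curves: dict[tuple[int, int], CMCCurve] = {}
    gestures = None
    for fold in sorted(fold_scores):
        fs = fold_scores[fold]
        gestures = sorted({g for _, g in fs.scores.columns})
        for g in gestures:
            for m in vote_sizes:
                r = ranks_for_gesture(fs, g, m)
                records.append(
                    dict(gesture=g, fold=fold, m=m,
                         rank1=float((r <= 1).mean()), rank5=float((r <= 5).mean()))
                )
    for g in gestures or []:
        for m in vote_sizes:
            curves[(g, m)] = compute_cmc(fold_scores, g, m)
    return pd.DataFrame.from_records(records), curves
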