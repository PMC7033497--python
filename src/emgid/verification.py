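"""Verification-mode evaluation: DET curves, EER and AUC under three
attack scenarios, with majority-vote postprocessing.

A verification attempt claims one identity with one code gesture.  The
genuine stream is always the claimed subject's own test data for the
code gesture.  The imposter stream depends on the scenario:

- ``normal``: the code is secret -- every gesture of every other subject;
- ``leaked``: the code is compromised -- the code gesture of every other
  subject;
- ``self``: the true subject forgot the code -- their own non-code
  gestures.

Each window's score is compared with a threshold (accept iff score <=
threshold, scores being distances), and the per-window decision stream
is postprocessed by a trailing majority vote over m points (m odd; the
vote never crosses a repetition boundary, and during warm-up the
available shorter history is used with an odd effective count).  FRR and
FAR as functions of the threshold give the DET curve, summarized by the
equal error rate (EER, linear interpolation at the FRR-FAR crossing) and
the area under the DET curve (AUC, trapezoidal; lower is better for
both).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import FoldScores

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "DETCurve",
    "imposter_classes",
    "build_scenario_streams",
    "majority_vote",
    "compute_det",
    "evaluate_verification",
]

SCENARIOS = ("normal", "leaked", "self")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    code_gesture: int
    claimed_subject: int

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario '{self.name}'; expected one of {SCENARIOS}")


def imposter_classes(
    name: str,
    claimed_subject: int,
    code_gesture: int,
    subjects: Sequence[int],
    gestures: Sequence[int],
) -> list[tuple[int, int]]:
    """(subject, gesture) classes whose windows act as imposter attempts."""
    if name == "normal":
        return [(s, g) for s in subjects if s != claimed_subject for g in gestures]
    if name == "leaked":
        return [(s, code_gesture) for s in subjects if s != claimed_subject]
    if name == "self":
        return [(claimed_subject, g) for g in gestures if g != code_gesture]
    raise ValueError(f"unknown scenario '{name}'")


def _segment_bounds(probes: pd.DataFrame, mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous (start, stop) runs of one (subject, gesture, repetition)
    among the selected rows, preserving stream order."""
    sel = probes.loc[mask, ["subject", "gesture", "repetition"]].to_numpy()
    if len(sel) == 0:
        return []
    change = np.any(sel[1:] != sel[:-1], axis=1)
    starts = np.concatenate([[0], np.flatnonzero(change) + 1])
    stops = np.concatenate([starts[1:], [len(sel)]])
    return list(zip(starts.tolist(), stops.tolist()))


def build_scenario_streams(
    probes: pd.DataFrame,
    scores: np.ndarray,
    spec: ScenarioSpec,
    subjects: Sequence[int],
    gestures: Sequence[int],
):
    """Split a fold's scores against the claimed template into streams.

    ``scores`` is the column of the fold's score table for the
    (claimed_subject, code_gesture) template, aligned row-by-row with
    ``probes``.  Returns ``(genuine, genuine_bounds, imposter,
    imposter_bounds)`` with within-stream window order preserved and
    bounds marking repetition segments (votes never cross them).
    """
    scores = np.asarray(scores, dtype=float)
    subj = probes["subject"].to_numpy()
    gest = probes["gesture"].to_numpy()
    genuine_mask = (subj == spec.claimed_subject) & (gest == spec.code_gesture)
    imp_classes = set(
        imposter_classes(spec.name, spec.claimed_subject, spec.code_gesture, subjects, gestures)
    )
    pair = list(zip(subj.tolist(), gest.tolist()))
    imposter_mask = np.fromiter((p in imp_classes for p in pair), bool, len(pair))
    if not genuine_mask.any():
        raise ValueError(
            f"scenario '{spec.name}': empty genuine stream for subject "
            f"{spec.claimed_subject}, gesture {spec.code_gesture}"
        )
    if not imposter_mask.any():
        raise ValueError(
            f"scenario '{spec.name}': empty imposter stream for subject "
            f"{spec.claimed_subject}, gesture {spec.code_gesture}"
        )
    return (
        scores[genuine_mask],
        _segment_bounds(probes, genuine_mask),
        scores[imposter_mask],
        _segment_bounds(probes, imposter_mask),
    )


def _vote_block(D: np.ndarray, m: int) -> np.ndarray:
    """Trailing majority vote along axis 0 of a boolean block.

    Effective count at row k is min(k+1, m), reduced by one when even so
    ties cannot occur (m itself must be odd).
    """
    n = D.shape[0]
    if m == 1 or n == 1:
        return D
    c = np.concatenate(
        [np.zeros((1,) + D.shape[1:], dtype=np.int64), np.cumsum(D, axis=0)], axis=0
    )
    k = np.arange(n)
    e = np.minimum(k + 1, m)
    e = e - (e % 2 == 0)
    sums = c[k + 1] - c[k + 1 - e]
    return (2 * sums) > e.reshape((-1,) + (1,) * (D.ndim - 1))


def majority_vote(
    stream: Sequence[bool] | np.ndarray,
    m: int,
    segment_bounds: Iterable[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Postprocess a decision stream by a trailing m-point majority vote."""
    if m < 1 or m % 2 == 0:
        raise ValueError("vote size m must be odd and >= 1")
    d = np.asarray(stream, dtype=bool)
    if d.size == 0:
        return d.copy()
    out = np.empty_like(d)
    bounds = list(segment_bounds) if segment_bounds is not None else [(0, d.size)]
    for a, b in bounds:
        out[a:b] = _vote_block(d[a:b], m)
    return out


@dataclass
class DETCurve:
    """Threshold-indexed (FAR, FRR) pairs with derived EER and AUC."""

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray
    eer: float
    auc: float
    degenerate: bool = False  # identical genuine/imposter score multisets

    def __post_init__(self) -> None:
        if np.any(np.diff(self.far) < -1e-12) or np.any(np.diff(self.frr) > 1e-12):
            raise ValueError("DET rates must be monotone in the threshold")
        for r in (self.far, self.frr):
            if r.min() < -1e-12 or r.max() > 1 + 1e-12:
                raise ValueError("DET rates must lie in [0, 1]")


def _eer_interpolate(far: np.ndarray, frr: np.ndarray) -> float:
    d = frr - far  # nonincreasing, d[0] = 1, d[-1] = -1
    idx = int(np.argmax(d <= 0))
    if d[idx] == 0:
        return float(0.5 * (far[idx] + frr[idx]))
    d1, d2 = d[idx - 1], d[idx]
    alpha = d1 / (d1 - d2)
    return float(frr[idx - 1] + alpha * (frr[idx] - frr[idx - 1]))


def compute_det(
    genuine: np.ndarray,
    imposter: np.ndarray,
    m: int = 1,
    genuine_bounds: Iterable[tuple[int, int]] | None = None,
    imposter_bounds: Iterable[tuple[int, int]] | None = None,
) -> DETCurve:
    """Sweep every observed score as a threshold and derive EER and AUC.

    Decisions (accept iff score <= threshold) are majority-voted per
    repetition segment before counting errors.  EER uses linear
    interpolation between the bracketing thresholds (midpoint at an exact
    crossing); AUC is the trapezoidal area under FRR as a function of FAR
    with the +-inf sentinels pinning the (0, 1) and (1, 0) endpoints.
    """
    genuine = np.asarray(genuine, dtype=float)
    imposter = np.asarray(imposter, dtype=float)
    if genuine.size == 0 or imposter.size == 0:
        raise ValueError("genuine and imposter streams must be nonempty")
    if m < 1 or m % 2 == 0:
        raise ValueError("vote size m must be odd and >= 1")
    gb = list(genuine_bounds) if genuine_bounds is not None else [(0, genuine.size)]
    ib = list(imposter_bounds) if imposter_bounds is not None else [(0, imposter.size)]

    thr = np.concatenate([[-np.inf], np.unique(np.concatenate([genuine, imposter])), [np.inf]])
    Dg = genuine[:, None] <= thr[None, :]
    Di = imposter[:, None] <= thr[None, :]
    if m > 1:
        Vg = np.empty_like(Dg)
        for a, b in gb:
            Vg[a:b] = _vote_block(Dg[a:b], m)
        Vi = np.empty_like(Di)
        for a, b in ib:
            Vi[a:b] = _vote_block(Di[a:b], m)
    else:
        Vg, Vi = Dg, Di
    frr = 1.0 - Vg.mean(axis=0)
    far = Vi.mean(axis=0)

    eer = _eer_interpolate(far, frr)
    auc = float(np.trapezoid(frr, far))
    degenerate = genuine.size == imposter.size and np.array_equal(
        np.sort(genuine), np.sort(imposter)
    )
    return DETCurve(thr, far, frr, eer=eer, auc=auc, degenerate=degenerate)


def evaluate_verification(
    fold_scores: Mapping[int, FoldScores],
    scenarios: Sequence[str] = SCENARIOS,
    vote_sizes: Sequence[int] = (1, 5, 9, 13),
) -> pd.DataFrame:
    """Full factorial sweep: every gesture as code, every subject as the
    claimed identity, every fold, scenario and vote size.

    Returns tidy records (gesture, subject, fold, scenario, m, eer, auc).
    """
    records = []
    for fold in sorted(fold_scores):
        fs = fold_scores[fold]
        keys = list(fs.scores.columns)
        subjects = sorted({s for s, _ in keys})
        gestures = sorted({g for _, g in keys})
        score_arr = fs.scores.to_numpy()
        for j, (s, g) in enumerate(keys):
            col = score_arr[:, j]
            for name in scenarios:
                spec = ScenarioSpec(name, code_gesture=g, claimed_subject=s)
                gen, gb, imp, ib = build_scenario_streams(
                    fs.probes, col, spec, subjects, gestures
                )
                for m in vote_sizes:
                    det = compute_det(gen, imp, m, gb, ib)
                    records.append(
                        dict(gesture=g, subject=s, fold=fold, scenario=name,
                             m=m, eer=det.eer, auc=det.auc)
                    )
    return pd.DataFrame.from_records(records)
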