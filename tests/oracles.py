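"""Independent brute-force oracles used only by the tests.

Each function re-derives a pipeline quantity by direct enumeration,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def brute_idft_feature(window, low, high, n_segments, fs, log_floor=1e-12):
    """Explicit DFT sum + explicit bin partition, one channel at a time."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    C, L = window.shape
    edges = [low + (high - low) * i / n_segments for i in range(n_segments + 1)]
    out = []
    for c in range(C):
        mags = []
        for k in range(L // 2 + 1):
            s = sum(window[c, n] * cmath.exp(-2j * math.pi * k * n / L) for n in range(L))
            mags.append((k * fs / L, abs(s)))
        for i in range(n_segments):
            sel = [
                m for f, m in mags
                if (edges[i] <= f < edges[i + 1]) or (i == n_segments - 1 and f == edges[-1])
            ]
            out.append(math.log(max(sum(sel) / len(sel), log_floor)))
    return np.array(out)


def naive_vote(stream, m):
    """Trailing majority vote over one repetition segment."""
    out = []
    for k in range(len(stream)):
        e = min(k + 1, m)
        if e % 2 == 0:
            e -= 1
        votes = stream[k - e + 1 : k + 1]
        out.append(sum(bool(v) for v in votes) > e / 2)
    return np.array(out, dtype=bool)


def naive_trailing_mean(values, m):
    out = []
    for k in range(len(values)):
        e = min(k + 1, m)
        out.append(sum(values[k - e + 1 : k + 1]) / e)
    return np.array(out)


def brute_eer(genuine, imposter, m=1, genuine_bounds=None, imposter_bounds=None):
    """Exhaustive threshold enumeration; linear interpolation only between
    the bracketing pair where FRR - FAR changes sign."""
    genuine = list(map(float, genuine))
    imposter = list(map(float, imposter))
    gb = genuine_bounds or [(0, len(genuine))]
    ib = imposter_bounds or [(0, len(imposter))]
    thresholds = [-math.inf] + sorted(set(genuine + imposter)) + [math.inf]

    def rates(t):
        acc_g = []
        for a, b in gb:
            acc_g.extend(naive_vote([s <= t for s in genuine[a:b]], m))
        acc_i = []
        for a, b in ib:
            acc_i.extend(naive_vote([s <= t for s in imposter[a:b]], m))
        frr = 1.0 - sum(acc_g) / len(acc_g)
        far = sum(acc_i) / len(acc_i)
        return far, frr

    pts = [rates(t) for t in thresholds]
    for idx in range(len(pts)):
        far, frr = pts[idx]
        d = frr - far
        if d == 0:
            return 0.5 * (far + frr)
        if d < 0:
            far0, frr0 = pts[idx - 1]
            d0 = frr0 - far0
            alpha = d0 / (d0 - d)
            return frr0 + alpha * (frr - frr0)
    raise AssertionError("no EER crossing found")


def naive_ranks(distance_rows, true_subjects, subjects):
    """Pessimistic 1-based rank of the true subject per row, by pairwise
    comparison."""
    ranks = []
    for row, true_s in zip(distance_rows, true_subjects):
        d = dict(zip(subjects, row))
        d_true = d[true_s]
        # worst position among ties: everything <= d_true counts (incl. self)
        ranks.append(sum(1 for s in subjects if d[s] <= d_true))
    return np.array(ranks)


def sorted_quartiles(values):
    """Median / quartiles by linear interpolation between closest ranks."""
    x = sorted(values)
    n = len(x)

    def q(p):
        h = (n - 1) * p
        lo = math.floor(h)
        hi = math.ceil(h)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    return q(0.25), q(0.5), q(0.75)
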