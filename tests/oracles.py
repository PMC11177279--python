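"""Independent brute-force oracles used by the test suite.

Each oracle evaluates its statistic straight from the definition with
explicit loops and no shared code with the package implementation.
"""

import itertools
import math

import numpy as np


def wsmi_oracle(x, y, k, tau):
    """wSMI of two 1-D sequences by exhaustive pattern enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_pat = len(x) - (k - 1) * tau
    perms = list(itertools.permutations(range(k)))

    def pattern(v, t):
        vals = [v[t + i * tau] for i in range(k)]
        # earlier sample ranks lower on ties
        order = sorted(range(k), key=lambda i: (vals[i], i))
        return perms.index(tuple(order))

    nk = math.factorial(k)
    joint = np.zeros((nk, nk))
    for t in range(n_pat):
        joint[pattern(x, t), pattern(y, t)] += 1
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    opposite = {i: perms.index(p[::-1]) for i, p in enumerate(perms)}
    total = 0.0
    for a in range(nk):
        for b in range(nk):
            if a == b or opposite[a] == b:
                continue  # identical / sign-flipped pairs weighted out
            if joint[a, b] > 0:
                total += joint[a, b] * math.log(joint[a, b] / (px[a] * py[b]))
    return total / math.log(nk)


def dcfa_oracle(series, window, step):
    """SD over sliding windows of the window-mean Fisher-z pair correlation."""
    series = np.asarray(series, dtype=float)
    m, T = series.shape
    zs = []
    for start in range(0, T - window + 1, step):
        win = series[:, start:start + window]
        rs = []
        for i in range(m):
            for j in range(i + 1, m):
                r = np.corrcoef(win[i], win[j])[0, 1]
                r = min(max(r, -1 + 1e-12), 1 - 1e-12)
                rs.append(np.arctanh(r))
        zs.append(np.mean(rs))
    return float(np.std(zs, ddof=0))


def bootstrap_auc_enumeration(y, scores, quantiles):
    """Exact bootstrap-AUC quantiles over all class-valid resamples.

    Enumerates every resample (n^n index tuples) of a small test set, keeps
    those containing both classes, computes the Mann–Whitney AUC of each,
    and returns the requested percentiles of that population.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n = len(y)
    idx = np.array(list(itertools.product(range(n), repeat=n)))
    yb, sb = y[idx], scores[idx]
    valid = (yb.min(axis=1) == 0) & (yb.max(axis=1) == 1)
    yb, sb = yb[valid], sb[valid]
    greater = (sb[:, :, None] > sb[:, None, :]).astype(float)
    ties = 0.5 * (sb[:, :, None] == sb[:, None, :])
    pair = (yb[:, :, None] == 1) & (yb[:, None, :] == 0)
    n_pos = yb.sum(axis=1)
    aucs = ((greater + ties) * pair).sum(axis=(1, 2)) / (n_pos * (n - n_pos))
    return np.percentile(aucs, quantiles)
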