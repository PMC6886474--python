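"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is deliberately naive (explicit pair enumeration, literal
formula transcription) and shares no code with the implementation.
"""

import math

import numpy as np


def tau_a_pair_count(x, y):
    """Kendall tau-a by explicit O(n^2) pair enumeration."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = (x[i] > x[j]) - (x[i] < x[j])
            dy = (y[i] > y[j]) - (y[i] < y[j])
            prod = dx * dy
            if prod > 0:
                conc += 1
            elif prod < 0:
                disc += 1
    return (conc - disc) / (n * (n - 1) / 2)


def pearson(u, v):
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    su = u.std()
    sv = v.std()
    if su == 0 or sv == 0:
        return 0.0
    return float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))


def merit_literal(X, y, idx):
    """Literal transcription of the subset-merit formula.

    merit = k * rcf_bar / sqrt(k + k (k - 1) * rff_bar), with correlation
    magnitudes, rff_bar = 0 for singletons.
    """
    idx = list(idx)
    k = len(idx)
    rcf_bar = sum(abs(pearson(X[:, j], y)) for j in idx) / k
    if k > 1:
        pairs = [
            abs(pearson(X[:, a], X[:, b]))
            for i, a in enumerate(idx)
            for b in idx[i + 1 :]
        ]
        rff_bar = sum(pairs) / len(pairs)
    else:
        rff_bar = 0.0
    return k * rcf_bar / math.sqrt(k + k * (k - 1) * rff_bar)


def auc_pair_count(scores, labels):
    """AUC by all-pairs concordance counting (ties count 1/2)."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def mcc_literal(tp, tn, fp, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def tanimoto_popcount(a, b):
    """Bit-counting Tanimoto over python ints."""
    ai = int("".join(str(int(v)) for v in a), 2) if len(a) else 0
    bi = int("".join(str(int(v)) for v in b), 2) if len(b) else 0
    union = bin(ai | bi).count("1")
    if union == 0:
        return 0.0
    return bin(ai & bi).count("1") / union


def nn_scan(query, actives, ids):
    """Nearest neighbor by exhaustive scan, first-row tie-breaking."""
    best_id, best_sim = None, -1.0
    for row, rid in zip(actives, ids):
        sim = tanimoto_popcount(query, row)
        if sim > best_sim:
            best_id, best_sim = rid, sim
    return best_id, best_sim
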