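"""Independent brute-force oracles used by the metric tests.

These deliberately avoid the contingency-table shortcuts of the
implementation: agreement is counted over explicit item pairs and the
accuracy mapping is found by exhaustive permutation search.
"""

import itertools
import math

import numpy as np


def all_partitions(n):
    """Every partition of range(n) as a label vector (restricted growth)."""
    out = []

    def grow(prefix, next_label):
        if len(prefix) == n:
            out.append(list(prefix))
            return
        for lab in range(next_label + 1):
            grow(prefix + [lab], max(next_label, lab + 1))

    grow([], 0)
    return [np.array(p) for p in out]


def pair_sets(labels):
    same = set()
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                same.add((i, j))
    return same


def brute_ari(t, p):
    n = len(t)
    st_, sp_ = pair_sets(t), pair_sets(p)
    total = n * (n - 1) // 2
    a = len(st_ & sp_)                      # same in both
    b = total - len(st_ | sp_)              # different in both
    ri = (a + b) / total
    exp = (len(st_) * len(sp_) + (total - len(st_)) * (total - len(sp_))) / total**2
    if exp == 1.0:
        return 1.0
    return (ri - exp) / (1.0 - exp)


def brute_fmi(t, p):
    st_, sp_ = pair_sets(t), pair_sets(p)
    if not st_ or not sp_:
        return 0.0
    tp = len(st_ & sp_)
    return tp / math.sqrt(len(st_) * len(sp_))


def brute_acc(t, p):
    k = max(max(t), max(p)) + 1
    best = 0
    for perm in itertools.permutations(range(k)):
        agree = sum(1 for ti, pi in zip(t, p) if perm[pi] == ti)
        best = max(best, agree)
    return best / len(t)


def brute_nmi(t, p):
    n = len(t)
    kt, kp = max(t) + 1, max(p) + 1
    table = np.zeros((kt, kp))
    for ti, pi in zip(t, p):
        table[ti, pi] += 1
    pt = table.sum(axis=1) / n
    pp = table.sum(axis=0) / n
    mi = 0.0
    for i in range(kt):
        for j in range(kp):
            if table[i, j]:
                pij = table[i, j] / n
                mi += pij * math.log(pij / (pt[i] * pp[j]))
    ht = -sum(q * math.log(q) for q in pt if q > 0)
    hp = -sum(q * math.log(q) for q in pp if q > 0)
    if ht == 0.0 and hp == 0.0:
        return 1.0
    denom = (ht + hp) / 2
    return 0.0 if denom == 0.0 else min(max(mi / denom, 0.0), 1.0)
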