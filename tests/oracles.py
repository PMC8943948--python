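"""Independent brute-force oracles shared by the unit and acceptance tests.

Each function recomputes a quantity from first principles, avoiding the code
paths it is used to check.
"""

import math

import numpy as np


def brute_force_modularity(W, labels, gamma=1.0, scheme="negative_asym"):
    """Direct double-sum over ordered node pairs, one sign part at a time."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    Wp = np.where(W > 0, W, 0.0)
    Wm = np.where(W < 0, -W, 0.0)

    def part(Wx):
        v = Wx.sum()
        if v == 0:
            return 0.0, 0.0
        s = Wx.sum(axis=1)
        q = 0.0
        n = len(labels)
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    q += Wx[i, j] - gamma * s[i] * s[j] / v
        return q / v, v

    qp, vp = part(Wp)
    qm, vm = part(Wm)
    q = qp
    if scheme == "negative_asym" and vp + vm > 0:
        q -= vm / (vp + vm) * qm
    return q


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def labels_from_blocks(blocks, n):
    lab = np.empty(n, dtype=int)
    for k, block in enumerate(blocks):
        for i in block:
            lab[i] = k
    return lab


def brute_force_ami(l1, l2):
    """AMI with the exact hypergeometric E[MI], in plain Python floats."""
    n = len(l1)
    cont = {}
    for a, b in zip(l1, l2):
        cont[(a, b)] = cont.get((a, b), 0) + 1
    arow = {a: sum(v for (x, _), v in cont.items() if x == a) for a in set(l1)}
    bcol = {b: sum(v for (_, y), v in cont.items() if y == b) for b in set(l2)}
    mi = sum(v / n * math.log(v * n / (arow[a] * bcol[b]))
             for (a, b), v in cont.items())
    emi = 0.0
    for a in arow.values():
        for b in bcol.values():
            for nij in range(max(1, a + b - n), min(a, b) + 1):
                hyp = (math.comb(b, nij) * math.comb(n - b, a - nij)
                       / math.comb(n, a))
                emi += hyp * (nij / n) * math.log(n * nij / (a * b))
    h1 = -sum(v / n * math.log(v / n) for v in arow.values())
    h2 = -sum(v / n * math.log(v / n) for v in bcol.values())
    return (mi - emi) / (0.5 * (h1 + h2) - emi)


def brute_upgma_heights(d0, n):
    """UPGMA merge heights recomputing all cross-pair means each step."""
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs = [d0[a][b] for a in clusters[i] for b in clusters[j]]
                m = sum(pairs) / len(pairs)
                if best is None or m < best[0] - 1e-15:
                    best = (m, i, j)
        m, i, j = best
        heights.append(m)
        clusters = ([c for k, c in enumerate(clusters) if k not in (i, j)]
                    + [clusters[i] | clusters[j]])
    return heights
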