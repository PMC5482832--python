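"""Independent brute-force replay of the CCS search and merge.

Everything here is written with plain Python loops and a textbook Pearson
formula on explicitly subset vectors — deliberately sharing no code with the
package's vectorized implementation — so that agreement between the two is a
meaningful check.
"""

from __future__ import annotations

import math
from itertools import combinations

CLASS_LABELS = ("up-positive", "down-positive", "negative")


def pearson_subset(x, y, samples):
    """Textbook Pearson on the explicit sample subset; None if degenerate."""
    xs = [x[s] for s in samples]
    ys = [y[s] for s in samples]
    n = len(xs)
    if n < 3:
        return None
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((v - mx) ** 2 for v in xs)
    syy = sum((v - my) ** 2 for v in ys)
    if sxx == 0 or syy == 0:
        return None
    sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    return sxy / math.sqrt(sxx * syy)


def split_oracle(x_i, x_j, mean_i, mean_j):
    """Per-sample sign enumeration of the three selection rules."""
    j1, j2, j3 = [], [], []
    for s in range(len(x_i)):
        di = x_i[s] - mean_i
        dj = x_j[s] - mean_j
        if di > 0 and dj > 0:
            j1.append(s)
        elif di < 0 and dj < 0:
            j2.append(s)
        elif di * dj < 0:
            j3.append(s)
    return j1, j2, j3


def grow_oracle(values, i, j, samples, theta):
    """Greedy growth replay: scan every gene in row order."""
    members = [i, j]
    for p in range(len(values)):
        if p in members:
            continue
        ok = True
        for q in members:
            r = pearson_subset(values[p], values[q], samples)
            if r is None or abs(r) <= theta:
                ok = False
                break
        if ok:
            members.append(p)
    return sorted(members)


def correlated_pairs_oracle(values, rows, samples, theta):
    out = set()
    for a, b in combinations(rows, 2):
        r = pearson_subset(values[a], values[b], samples)
        if r is not None and abs(r) > theta:
            out.add((min(a, b), max(a, b)))
    return out


def bscore_oracle(values, rows, samples, theta):
    m = len(values[0])
    comp = [s for s in range(m) if s not in set(samples)]
    n_set = correlated_pairs_oracle(values, rows, samples, theta)
    m_set = correlated_pairs_oracle(values, rows, comp, theta)
    union = n_set | m_set
    if not union:
        return 0.0
    return len(n_set & m_set) / len(union)


def find_bicluster_oracle(values, means, i, theta, min_samples=3, min_genes=3,
                          bscore_threshold=0.01):
    """Literal replay of the per-base search (partner loop, three rule-derived
    sample sets, growth, BScore, smallest-score-then-largest-set selection).

    ``values`` must already be in variability-sorted row order.  Returns
    (member rows, sample list, class index, bscore) or None.
    """
    n = len(values)
    best = None
    for j in range(i + 1, n):
        for k, samples in enumerate(split_oracle(values[i], values[j],
                                                 means[i], means[j])):
            if len(samples) < min_samples:
                continue
            r = pearson_subset(values[i], values[j], samples)
            if r is None or abs(r) <= theta:
                continue
            rows = grow_oracle(values, i, j, samples, theta)
            if len(rows) < min_genes:
                continue
            score = bscore_oracle(values, rows, samples, theta)
            if score >= bscore_threshold:
                continue
            if (best is None or score < best[3]
                    or (score == best[3] and len(rows) > len(best[0]))):
                best = (rows, samples, k, score)
    return best


def merge_oracle(values, biclusters, theta, bscore_threshold=0.01):
    """Literal replay of the merge pass on (rows, samples) pairs.

    ``biclusters`` is a list of (row set, sample set); the function returns
    the surviving list in order, with BScores recomputed on the final sets.
    """
    live = [(set(r), set(s)) for r, s in biclusters]
    dead = [False] * len(live)
    for a in range(len(live)):
        if dead[a]:
            continue
        for b in range(len(live)):
            if b == a or dead[b] or dead[a]:
                continue
            ia, ja = live[a]
            ib, jb = live[b]
            if not (ia & ib):
                continue
            rows = sorted(ia | ib)
            samples = sorted(ja | jb)
            if bscore_oracle(values, rows, samples, theta) < bscore_threshold:
                live[a] = (set(rows), set(samples))
                dead[b] = True
    out = []
    for alive, (rows, samples) in zip((not d for d in dead), live):
        if alive:
            score = bscore_oracle(values, sorted(rows), sorted(samples), theta)
            out.append((sorted(rows), sorted(samples), score))
    return out
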