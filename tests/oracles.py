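"""Independent brute-force reference implementations used as test oracles.

Everything here is written as directly as possible from the definitions —
explicit loops, no vectorization, no reuse of package code — so that
agreement with the package is evidence of correctness, not of shared bugs.
"""

from itertools import combinations

import numpy as np


def brute_consensus(label_vectors):
    """Co-assignment proportions by explicit double loop over pairs/vectors."""
    n = len(label_vectors[0])
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                c[i, j] = 1.0
                continue
            together = sum(1 for v in label_vectors if v[i] == v[j])
            c[i, j] = together / len(label_vectors)
    return c


def brute_silhouette(distance, labels):
    """Per-point silhouette by direct evaluation of a, b and (b-a)/max."""
    n = len(labels)
    scores = np.zeros(n)
    clusters = sorted(set(labels))
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores[i] = 0.0
            continue
        a = sum(distance[i, j] for j in own) / len(own)
        b = np.inf
        for k in clusters:
            if k == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == k]
            b = min(b, sum(distance[i, j] for j in members) / len(members))
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return scores, scores.sum()


def brute_stability(consensus_values, labels):
    """Per-species within-group consensus share by direct summation."""
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        num = sum(consensus_values[i, j] for j in range(n)
                  if j != i and labels[j] == labels[i])
        den = sum(consensus_values[i, j] for j in range(n) if j != i)
        out[i] = np.nan if den == 0 else num / den
    return out


def brute_ari(labels_a, labels_b):
    """ARI from explicit pair counting (no contingency table)."""
    n = len(labels_a)
    n11 = n00 = n10 = n01 = 0
    for i, j in combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


def brute_fgr(present, group_map):
    return len({group_map[s] for s in set(present) if s in group_map})


def brute_fredund(present, group_map):
    groups = [group_map[s] for s in sorted(set(present)) if s in group_map]
    n = len(groups)
    if n < 2:
        return float("nan")
    same = sum(1 for a in groups for b in groups if a == b)
    return same / (n * n)


def naive_ward(distance):
    """Greedy Lance-Williams Ward agglomeration.

    Returns (merge heights, cophenetic matrix). The cophenetic matrix fully
    encodes the dendrogram, so it is the comparison object against other
    Ward implementations whose merge-row ordering may differ.
    """
    distance = np.asarray(distance, dtype=float)
    n = distance.shape[0]
    sizes = {i: 1 for i in range(n)}
    members = {i: [i] for i in range(n)}
    active = list(range(n))
    dist = {(i, j): distance[i, j] for i in range(n) for j in range(i + 1, n)}

    def get(a, b):
        return dist[(min(a, b), max(a, b))]

    coph = np.zeros((n, n))
    next_id = n
    heights = []
    while len(active) > 1:
        best, best_d = None, np.inf
        for x in range(len(active)):
            for y in range(x + 1, len(active)):
                d = get(active[x], active[y])
                if d < best_d:
                    best_d, best = d, (active[x], active[y])
        a, b = best
        heights.append(best_d)
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = best_d
        new = next_id
        next_id += 1
        sa, sb = sizes[a], sizes[b]
        for k in active:
            if k in (a, b):
                continue
            sk = sizes[k]
            dist[(min(k, new), max(k, new))] = np.sqrt(
                ((sk + sa) * get(k, a) ** 2 + (sk + sb) * get(k, b) ** 2
                 - sk * best_d ** 2) / (sk + sa + sb)
            )
        active.remove(a)
        active.remove(b)
        active.append(new)
        sizes[new] = sa + sb
        members[new] = members[a] + members[b]
    return heights, coph
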