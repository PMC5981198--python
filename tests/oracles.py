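"""Independent brute-force oracles used to verify the greedy algorithms.

Everything here is deliberately written from the definitions — direct
summation for mutual information, exhaustive per-step evaluation for the
MID ranking, and re-scoring of every candidate at every step for the
wrapper feature-selection algorithms — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def plug_in_mi(x, y) -> float:
    """Plug-in MI in nats by direct summation over the joint counts."""
    x = list(x)
    y = list(y)
    n = len(x)
    joint: dict[tuple, int] = {}
    mx: dict = {}
    my: dict = {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        mx[a] = mx.get(a, 0) + 1
        my[b] = my.get(b, 0) + 1
    total = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        total += pab * math.log(pab / ((mx[a] / n) * (my[b] / n)))
    return total


def mid_rank_oracle(rows: np.ndarray, genes: list[str], y, n_select: int):
    """Exhaustive MID selection: at every step, evaluate the MID objective
    for every remaining candidate from freshly computed MI values.  Ties:
    higher relevance, then lexicographically smaller symbol."""
    y = list(y)
    relevance = {g: plug_in_mi(rows[i], y) for i, g in enumerate(genes)}
    row_of = {g: rows[i] for i, g in enumerate(genes)}
    selected: list[str] = []
    remaining = list(genes)
    while len(selected) < n_select:
        scored = []
        for g in remaining:
            if selected:
                red = sum(plug_in_mi(row_of[g], row_of[s]) for s in selected)
                red /= len(selected)
            else:
                red = 0.0
            scored.append((round(relevance[g] - red, 12), round(relevance[g], 12), g))
        # max MID, then max relevance, then min symbol; scores compared at
        # 1e-12 resolution (mathematical ties must not depend on float
        # summation order)
        best = min(scored, key=lambda t: (-t[0], -t[1], t[2]))
        selected.append(best[2])
        remaining.remove(best[2])
    return selected


def csfs_oracle(ranked: list[str], score_fn):
    """Best prefix by exhaustive evaluation of every prefix length; ties to
    the shorter prefix."""
    best_score, best_len = math.inf, 0
    for size in range(1, len(ranked) + 1):
        s = score_fn(ranked[:size])
        if s < best_score:
            best_score, best_len = s, size
    return ranked[:best_len], best_score


def fsfs_oracle(pool: list[str], score_fn):
    """Greedy forward selection re-evaluating every candidate each step;
    score ties resolve to the earlier-ranked candidate; additions must
    strictly improve (first gene always accepted)."""
    selected: list[str] = []
    current = math.inf
    trajectory = []
    while True:
        candidates = [g for g in pool if g not in selected]
        if not candidates:
            break
        scored = [(score_fn(selected + [g]), pool.index(g), g) for g in candidates]
        score, _, gene = min(scored, key=lambda t: (t[0], t[1]))
        if score < current:
            selected.append(gene)
            trajectory.append((gene, score))
            current = score
        else:
            break
    return selected, trajectory


def bsfs_oracle(pool: list[str], score_fn):
    """Greedy backward elimination re-evaluating every single removal each
    step; removal ties resolve to dropping the worse-ranked gene; removals
    must strictly improve; never empties the set."""
    selected = list(pool)
    current = score_fn(selected)
    trajectory = [("", current)]
    while len(selected) > 1:
        scored = []
        for pos, g in enumerate(selected):
            reduced = selected[:pos] + selected[pos + 1 :]
            scored.append((score_fn(reduced), -pos, g, reduced))
        score, _, gene, reduced = min(scored, key=lambda t: (t[0], t[1]))
        if score < current:
            selected = reduced
            trajectory.append((gene, score))
            current = score
        else:
            break
    return selected, trajectory
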