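"""Independent brute-force oracles: explicit enumeration of every legal
pair-state path, written from the state-machine definition rather than the
dynamic-programming recursions they are used to check.

A path is a sequence of pair states; it must start and end in MM.  MM
consumes one column of each profile and contributes the match score of its
cell; MI/DG consume a query column, IM/GD a template column, and contribute
transition weights only.  Local mode allows any start/end MM cell; global
(semi-global) mode restricts starts to the first row/column and ends to the
last row/column.
"""

from __future__ import annotations

import numpy as np

# transition slots, mirroring the profile layout (deliberately re-declared)
MM_, MI_, MD_, IM_, II_, DM_, DD_ = range(7)


def _lg(p: float) -> float:
    return float(np.log2(max(p, 1e-30)))


def enumerate_paths(S, q_tr, t_tr, mode):
    """Yield (mm_cells, log2_score) for every legal alignment path.

    S: (Lq, Lt) match-score matrix (0-based).  q_tr/t_tr: raw (L, 7)
    transition probabilities; row c-1 holds transitions out of 1-based
    column c.  mm_cells are 1-based (i, j) tuples.
    """
    Lq, Lt = S.shape
    out = []

    def end_ok(i, j):
        return mode == "local" or i == Lq or j == Lt

    def walk(state, i, j, score, cells):
        if state == "MM":
            score = score + S[i - 1, j - 1]
            cells = cells + ((i, j),)
            if end_ok(i, j):
                out.append((cells, score))
            if i < Lq and j < Lt:
                walk("MM", i + 1, j + 1,
                     score + _lg(q_tr[i - 1, MM_]) + _lg(t_tr[j - 1, MM_]), cells)
            if i < Lq:
                walk("MI", i + 1, j,
                     score + _lg(q_tr[i - 1, MM_]) + _lg(t_tr[j - 1, MI_]), cells)
                walk("DG", i + 1, j, score + _lg(q_tr[i - 1, MD_]), cells)
            if j < Lt:
                walk("IM", i, j + 1,
                     score + _lg(q_tr[i - 1, MI_]) + _lg(t_tr[j - 1, MM_]), cells)
                walk("GD", i, j + 1, score + _lg(t_tr[j - 1, MD_]), cells)
        elif state == "MI":  # query advanced to i, template insert after j
            if i < Lq and j < Lt:
                walk("MM", i + 1, j + 1,
                     score + _lg(q_tr[i - 1, MM_]) + _lg(t_tr[j - 1, IM_]), cells)
            if i < Lq:
                walk("MI", i + 1, j,
                     score + _lg(q_tr[i - 1, MM_]) + _lg(t_tr[j - 1, II_]), cells)
        elif state == "DG":  # query column i deleted against nothing
            if i < Lq and j < Lt:
                walk("MM", i + 1, j + 1,
                     score + _lg(q_tr[i - 1, DM_]) + _lg(t_tr[j - 1, MM_]), cells)
            if i < Lq:
                walk("DG", i + 1, j, score + _lg(q_tr[i - 1, DD_]), cells)
        elif state == "IM":  # query insert after i, template advanced to j
            if i < Lq and j < Lt:
                walk("MM", i + 1, j + 1,
                     score + _lg(q_tr[i - 1, IM_]) + _lg(t_tr[j - 1, MM_]), cells)
            if j < Lt:
                walk("IM", i, j + 1,
                     score + _lg(q_tr[i - 1, II_]) + _lg(t_tr[j - 1, MM_]), cells)
        else:  # GD: template column j deleted against nothing
            if i < Lq and j < Lt:
                walk("MM", i + 1, j + 1,
                     score + _lg(q_tr[i - 1, MM_]) + _lg(t_tr[j - 1, DM_]), cells)
            if j < Lt:
                walk("GD", i, j + 1, score + _lg(t_tr[j - 1, DD_]), cells)

    if mode == "local":
        starts = [(i, j) for i in range(1, Lq + 1) for j in range(1, Lt + 1)]
    else:
        starts = [(i, j) for i in range(1, Lq + 1) for j in range(1, Lt + 1)
                  if i == 1 or j == 1]
    for (i, j) in starts:
        walk("MM", i, j, 0.0, ())
    return out


def brute_force_viterbi(S, q_tr, t_tr, mode):
    """Best log2 score over all legal paths (0 floor in local mode)."""
    paths = enumerate_paths(S, q_tr, t_tr, mode)
    best = max(score for _, score in paths) if paths else -np.inf
    if mode == "local":
        return max(best, 0.0)
    return best


def brute_force_posteriors(S, q_tr, t_tr, mode):
    """Exact posteriors and partition value by summing path weights.

    Returns (posterior matrix, log2 Z).  Weights are 2**score; Z sums over
    all paths (every path contains at least one MM cell).
    """
    Lq, Lt = S.shape
    paths = enumerate_paths(S, q_tr, t_tr, mode)
    scores = np.array([s for _, s in paths])
    shift = scores.max() if scores.size else 0.0  # stabilize the sums
    weights = np.exp2(scores - shift)
    num = np.zeros((Lq, Lt))
    for (cells, _), w in zip(paths, weights):
        for (i, j) in cells:
            num[i - 1, j - 1] += w
    z = weights.sum()
    return num / z, float(np.log2(z) + shift)
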