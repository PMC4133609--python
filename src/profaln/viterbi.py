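"""Five-matrix Viterbi dynamic programming over two profile HMMs.

Pair states: MM (both emit), MI / DG (query column consumed), IM / GD
(template column consumed).  Gap states carry transition log-probabilities
only; match-state cells add the augmented match score.  Everything is in
log2 space.

Local mode allows a path to start and end at any MM cell (max with 0 inside
the MM recursion).  Global mode is semi-global: paths start at any MM cell
on the first row/column and end on the last row/column, so terminal
overhangs are unpenalized.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .alignment import AlignedColumn, PairwiseAlignment
from .profile_model import (T_DD, T_DM, T_II, T_IM, T_MD, T_MI, T_MM,
                            BackgroundModel, ProfileHMM)
from .scoring import ScoringWeights, match_score_matrix

#: Transition probabilities are floored here before the log so that zero
#: transitions yield a large finite penalty instead of -inf.
TRANSITION_FLOOR = 1e-30

NEG = -np.inf

# Pointer codes for the MM matrix, in tie-break preference order.
_P_MM, _P_MI, _P_IM, _P_DG, _P_GD, _P_START = range(6)


@dataclasses.dataclass
class ViterbiResult:
    score: float
    alignment: PairwiseAlignment
    matrices: Optional[dict] = None


def _log_transitions(profile: ProfileHMM) -> np.ndarray:
    """(L+1, 7) log2 transition table; row c holds transitions out of
    1-based column c, row 0 is an unused zero pad."""
    out = np.zeros((profile.length + 1, 7))
    out[1:] = np.log2(np.maximum(profile.transitions, TRANSITION_FLOOR))
    return out


def viterbi_align(
    q: ProfileHMM,
    t: ProfileHMM,
    weights: ScoringWeights | None = None,
    background: BackgroundModel | None = None,
    ss_matrix: np.ndarray | None = None,
    keep_matrices: bool = False,
) -> ViterbiResult:
    """Best augmented log-sum-odds alignment of two profiles.

    Tie-breaking is deterministic: MM > MI > IM > DG > GD > fresh start, and
    the first-best end cell in row-major order.
    """
    w = weights or ScoringWeights()
    Lq, Lt = q.length, t.length
    S = match_score_matrix(q, t, w, background, ss_matrix)
    qtr = _log_transitions(q)
    ttr = _log_transitions(t)

    MM = np.full((Lq + 1, Lt + 1), NEG)
    MI = np.full((Lq + 1, Lt + 1), NEG)
    IM = np.full((Lq + 1, Lt + 1), NEG)
    DG = np.full((Lq + 1, Lt + 1), NEG)
    GD = np.full((Lq + 1, Lt + 1), NEG)
    ptr_MM = np.zeros((Lq + 1, Lt + 1), dtype=np.int8)
    ptr_MI = np.zeros((Lq + 1, Lt + 1), dtype=np.int8)  # 0: open from MM, 1: extend
    ptr_IM = np.zeros((Lq + 1, Lt + 1), dtype=np.int8)
    ptr_DG = np.zeros((Lq + 1, Lt + 1), dtype=np.int8)
    ptr_GD = np.zeros((Lq + 1, Lt + 1), dtype=np.int8)

    local = w.mode == "local"
    jcols = np.arange(1, Lt + 1)

    for i in range(1, Lq + 1):
        # MM: all predecessors are at (i-1, j-1); vectorized over j.
        via = np.empty((6, Lt))
        via[_P_MM] = MM[i - 1, :-1] + qtr[i - 1, T_MM] + ttr[:-1, T_MM]
        via[_P_MI] = MI[i - 1, :-1] + qtr[i - 1, T_MM] + ttr[:-1, T_IM]
        via[_P_IM] = IM[i - 1, :-1] + qtr[i - 1, T_IM] + ttr[:-1, T_MM]
        via[_P_DG] = DG[i - 1, :-1] + qtr[i - 1, T_DM] + ttr[:-1, T_MM]
        via[_P_GD] = GD[i - 1, :-1] + qtr[i - 1, T_MM] + ttr[:-1, T_DM]
        if local:
            via[_P_START] = 0.0
        else:
            via[_P_START] = np.where((i == 1) | (jcols == 1), 0.0, NEG)
        best = via.max(axis=0)
        ptr_MM[i, 1:] = via.argmax(axis=0)
        MM[i, 1:] = S[i - 1, :] + best

        # MI / DG: predecessors in the previous row, same column.
        open_mi = MM[i - 1, 1:] + qtr[i - 1, T_MM] + ttr[1:, T_MI]
        ext_mi = MI[i - 1, 1:] + qtr[i - 1, T_MM] + ttr[1:, T_II]
        MI[i, 1:] = np.maximum(open_mi, ext_mi)
        ptr_MI[i, 1:] = (ext_mi > open_mi).astype(np.int8)

        open_dg = MM[i - 1, 1:] + qtr[i - 1, T_MD]
        ext_dg = DG[i - 1, 1:] + qtr[i - 1, T_DD]
        DG[i, 1:] = np.maximum(open_dg, ext_dg)
        ptr_DG[i, 1:] = (ext_dg > open_dg).astype(np.int8)

        # IM / GD: predecessors in the same row, previous column (sequential).
        for j in range(1, Lt + 1):
            open_im = MM[i, j - 1] + qtr[i, T_MI] + ttr[j - 1, T_MM]
            ext_im = IM[i, j - 1] + qtr[i, T_II] + ttr[j - 1, T_MM]
            if open_im >= ext_im:
                IM[i, j] = open_im
            else:
                IM[i, j] = ext_im
                ptr_IM[i, j] = 1
            open_gd = MM[i, j - 1] + ttr[j - 1, T_MD]
            ext_gd = GD[i, j - 1] + ttr[j - 1, T_DD]
            if open_gd >= ext_gd:
                GD[i, j] = open_gd
            else:
                GD[i, j] = ext_gd
                ptr_GD[i, j] = 1

    # Choose the end cell (paths always end in MM).
    if local:
        flat = int(np.argmax(MM[1:, 1:]))
        ei, ej = flat // Lt + 1, flat % Lt + 1
        best_score = float(MM[ei, ej])
        if best_score < 0.0:
            alignment = PairwiseAlignment([], q.name, t.name)
            result_score = 0.0
            return ViterbiResult(result_score, alignment,
                                 _pack(MM, MI, IM, DG, GD) if keep_matrices else None)
        result_score = best_score
    else:
        boundary = np.full((Lq + 1, Lt + 1), NEG)
        boundary[Lq, 1:] = MM[Lq, 1:]
        boundary[1:, Lt] = MM[1:, Lt]
        flat = int(np.argmax(boundary))
        ei, ej = divmod(flat, Lt + 1)
        result_score = float(MM[ei, ej])

    columns: list[AlignedColumn] = []
    state, i, j = "MM", ei, ej
    while True:
        if state == "MM":
            columns.append(AlignedColumn(i, j, "MM", float(S[i - 1, j - 1])))
            p = ptr_MM[i, j]
            if p == _P_START:
                break
            state = ("MM", "MI", "IM", "DG", "GD")[p]
            i, j = i - 1, j - 1
        elif state == "MI":
            columns.append(AlignedColumn(i, None, "MI", None))
            state = "MI" if ptr_MI[i, j] else "MM"
            i -= 1
        elif state == "DG":
            columns.append(AlignedColumn(i, None, "DG", None))
            state = "DG" if ptr_DG[i, j] else "MM"
            i -= 1
        elif state == "IM":
            columns.append(AlignedColumn(None, j, "IM", None))
            state = "IM" if ptr_IM[i, j] else "MM"
            j -= 1
        else:  # GD
            columns.append(AlignedColumn(None, j, "GD", None))
            state = "GD" if ptr_GD[i, j] else "MM"
            j -= 1
    columns.reverse()
    alignment = PairwiseAlignment(columns, q.name, t.name)
    return ViterbiResult(result_score, alignment,
                         _pack(MM, MI, IM, DG, GD) if keep_matrices else None)


def _pack(MM, MI, IM, DG, GD):
    return {"MM": MM, "MI": MI, "IM": IM, "DG": DG, "GD": GD}


def alignment_score(
    alignment: PairwiseAlignment,
    q: ProfileHMM,
    t: ProfileHMM,
    weights: ScoringWeights | None = None,
    background: BackgroundModel | None = None,
    ss_matrix: np.ndarray | None = None,
) -> float:
    """Recompute the log-sum-odds score of an alignment path from scratch.

    Used to verify that the Viterbi score equals the score of its own path.
    """
    w = weights or ScoringWeights()
    S = match_score_matrix(q, t, w, background, ss_matrix)
    qtr = _log_transitions(q)
    ttr = _log_transitions(t)
    total = 0.0
    prev: Optional[AlignedColumn] = None
    pi, pj = 0, 0  # last consumed columns
    for col in alignment.columns:
        if prev is not None:
            a, b = prev.state, col.state
            if b == "MM":
                key = {"MM": (T_MM, T_MM), "MI": (T_MM, T_IM), "IM": (T_IM, T_MM),
                       "DG": (T_DM, T_MM), "GD": (T_MM, T_DM)}[a]
                total += qtr[pi, key[0]] + ttr[pj, key[1]]
            elif b == "MI":
                total += qtr[pi, T_MM] + (ttr[pj, T_II] if a == "MI" else ttr[pj, T_MI])
            elif b == "DG":
                total += qtr[pi, T_DD] if a == "DG" else qtr[pi, T_MD]
            elif b == "IM":
                total += ttr[pj, T_MM] + (qtr[pi, T_II] if a == "IM" else qtr[pi, T_MI])
            else:  # GD
                total += ttr[pj, T_DD] if a == "GD" else ttr[pj, T_MD]
        if col.state == "MM":
            total += S[col.query - 1, col.template - 1]
        if col.query is not None:
            pi = col.query
        if col.template is not None:
            pj = col.template
        prev = col
    return total
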