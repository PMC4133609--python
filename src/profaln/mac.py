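"""Forward/Backward partition functions, posterior match probabilities and
maximum-accuracy (MAC) alignment.

The Forward recursion accumulates, in linear space, the total odds of all
partial alignment paths; match cells contribute the odds factor
``2**match_score(i, j)`` so the structural terms enter exactly as in the
Viterbi scores.  Rows are multiplicatively rescaled with the log2 offsets
tracked, so posteriors are exact (scale-free).

``p_min`` follows the published convention: 1 = local mode (a path may start
and end at any cell), 0 = global mode (paths start/end on the matrix
boundary, in line with the semi-global Viterbi).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .alignment import AlignedColumn, PairwiseAlignment
from .errors import NumericError, ValidationError
from .profile_model import (T_DD, T_DM, T_II, T_IM, T_MD, T_MI, T_MM,
                            BackgroundModel, ProfileHMM)
from .scoring import ScoringWeights, match_score_matrix
from .viterbi import TRANSITION_FLOOR


def _logsumexp2(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return -np.inf
    m = finite.max()
    return float(m + np.log2(np.exp2(finite - m).sum()))


@dataclasses.dataclass
class PosteriorMatrix:
    """Posterior probabilities p(i~j) that match column i of the query aligns
    to match column j of the template, plus the total partition value."""

    post: np.ndarray
    log2_z_forward: float
    log2_z_backward: float

    def __post_init__(self):
        self.post = np.asarray(self.post, dtype=float)
        if np.any(self.post < -1e-12) or np.any(self.post > 1.0 + 1e-6):
            raise ValidationError("posterior entries outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.post.shape

    @property
    def log2_z(self) -> float:
        return self.log2_z_forward


def _linear_transitions(profile: ProfileHMM) -> np.ndarray:
    out = np.zeros((profile.length + 1, 7))
    out[1:] = np.maximum(profile.transitions, TRANSITION_FLOOR)
    return out


def forward_backward(
    q: ProfileHMM,
    t: ProfileHMM,
    weights: ScoringWeights | None = None,
    background: BackgroundModel | None = None,
    p_min: int | None = None,
    ss_matrix: np.ndarray | None = None,
) -> PosteriorMatrix:
    """Posterior match probabilities via the five-matrix Forward-Backward
    algorithm with structural odds factors.

    ``p_min`` defaults from ``weights.mode`` (local -> 1, global -> 0).
    """
    w = weights or ScoringWeights()
    if p_min is None:
        p_min = 1 if w.mode == "local" else 0
    if p_min not in (0, 1):
        raise ValidationError("p_min must be 0 (global) or 1 (local)")
    Lq, Lt = q.length, t.length
    S = match_score_matrix(q, t, w, background, ss_matrix)
    P = np.zeros((Lq + 1, Lt + 1))
    P[1:, 1:] = np.exp2(S)
    qtr = _linear_transitions(q)
    ttr = _linear_transitions(t)
    local = p_min == 1
    jcols = np.arange(1, Lt + 1)

    # ---- Forward ----
    # Stored row i equals the true row divided by 2**offF[i]; a row is
    # computed from stored row i-1 (scale offF[i-1]), so constant "start"
    # contributions (true value 1) enter as 2**-offF[i-1].
    F_MM = np.zeros((Lq + 1, Lt + 1))
    F_MI = np.zeros((Lq + 1, Lt + 1))
    F_IM = np.zeros((Lq + 1, Lt + 1))
    F_DG = np.zeros((Lq + 1, Lt + 1))
    F_GD = np.zeros((Lq + 1, Lt + 1))
    offF = np.zeros(Lq + 1)

    for i in range(1, Lq + 1):
        unit = np.exp2(-offF[i - 1])
        if not np.isfinite(unit):
            raise NumericError(f"forward underflow before row {i}")
        if local:
            start = np.full(Lt, unit)
        else:
            start = np.where((i == 1) | (jcols == 1), unit, 0.0)
        F_MM[i, 1:] = P[i, 1:] * (
            start
            + F_MM[i - 1, :-1] * qtr[i - 1, T_MM] * ttr[:-1, T_MM]
            + F_MI[i - 1, :-1] * qtr[i - 1, T_MM] * ttr[:-1, T_IM]
            + F_IM[i - 1, :-1] * qtr[i - 1, T_IM] * ttr[:-1, T_MM]
            + F_DG[i - 1, :-1] * qtr[i - 1, T_DM] * ttr[:-1, T_MM]
            + F_GD[i - 1, :-1] * qtr[i - 1, T_MM] * ttr[:-1, T_DM]
        )
        F_MI[i, 1:] = (F_MM[i - 1, 1:] * qtr[i - 1, T_MM] * ttr[1:, T_MI]
                       + F_MI[i - 1, 1:] * qtr[i - 1, T_MM] * ttr[1:, T_II])
        F_DG[i, 1:] = (F_MM[i - 1, 1:] * qtr[i - 1, T_MD]
                       + F_DG[i - 1, 1:] * qtr[i - 1, T_DD])
        for j in range(1, Lt + 1):
            F_IM[i, j] = (F_MM[i, j - 1] * qtr[i, T_MI] * ttr[j - 1, T_MM]
                          + F_IM[i, j - 1] * qtr[i, T_II] * ttr[j - 1, T_MM])
            F_GD[i, j] = (F_MM[i, j - 1] * ttr[j - 1, T_MD]
                          + F_GD[i, j - 1] * ttr[j - 1, T_DD])
        c = max(F_MM[i, 1:].max(), F_MI[i, 1:].max(), F_IM[i, 1:].max(),
                F_DG[i, 1:].max(), F_GD[i, 1:].max())
        if not np.isfinite(c):
            raise NumericError(f"forward overflow in row {i}")
        if c > 0.0:
            for M in (F_MM, F_MI, F_IM, F_DG, F_GD):
                M[i, 1:] /= c
            offF[i] = offF[i - 1] + np.log2(c)
        else:
            offF[i] = offF[i - 1]

    with np.errstate(divide="ignore"):
        logF = np.log2(F_MM[1:, 1:]) + offF[1:, None]
    if local:
        log2_z_f = _logsumexp2(logF.ravel())
    else:
        ends = np.concatenate([logF[-1, :], logF[:-1, -1]])
        log2_z_f = _logsumexp2(ends)

    # ---- Backward ----
    # B_MM(i, j) sums the weights of all path suffixes that continue after a
    # match at (i, j); the match odds P(i, j) itself is carried by F only.
    B_MM = np.zeros((Lq + 2, Lt + 2))
    B_MI = np.zeros((Lq + 2, Lt + 2))
    B_IM = np.zeros((Lq + 2, Lt + 2))
    B_DG = np.zeros((Lq + 2, Lt + 2))
    B_GD = np.zeros((Lq + 2, Lt + 2))
    offB = np.zeros(Lq + 2)
    Ppad = np.zeros((Lq + 2, Lt + 2))
    Ppad[1:Lq + 1, 1:Lt + 1] = P[1:, 1:]

    for i in range(Lq, 0, -1):
        unit = np.exp2(-offB[i + 1])
        if not np.isfinite(unit):
            raise NumericError(f"backward underflow before row {i}")
        for j in range(Lt, 0, -1):
            end = unit if (local or i == Lq or j == Lt) else 0.0
            close = B_MM[i + 1, j + 1] * Ppad[i + 1, j + 1]
            B_MI[i, j] = (close * qtr[i, T_MM] * ttr[j, T_IM]
                          + B_MI[i + 1, j] * qtr[i, T_MM] * ttr[j, T_II])
            B_DG[i, j] = (close * qtr[i, T_DM] * ttr[j, T_MM]
                          + B_DG[i + 1, j] * qtr[i, T_DD])
            B_IM[i, j] = (close * qtr[i, T_IM] * ttr[j, T_MM]
                          + B_IM[i, j + 1] * qtr[i, T_II] * ttr[j, T_MM])
            B_GD[i, j] = (close * qtr[i, T_MM] * ttr[j, T_DM]
                          + B_GD[i, j + 1] * ttr[j, T_DD])
            B_MM[i, j] = (end
                          + close * qtr[i, T_MM] * ttr[j, T_MM]
                          + B_MI[i + 1, j] * qtr[i, T_MM] * ttr[j, T_MI]
                          + B_IM[i, j + 1] * qtr[i, T_MI] * ttr[j, T_MM]
                          + B_DG[i + 1, j] * qtr[i, T_MD]
                          + B_GD[i, j + 1] * ttr[j, T_MD])
        c = max(B_MM[i, 1:-1].max(), B_MI[i, 1:-1].max(), B_IM[i, 1:-1].max(),
                B_DG[i, 1:-1].max(), B_GD[i, 1:-1].max())
        if not np.isfinite(c):
            raise NumericError(f"backward overflow in row {i}")
        if c > 0.0:
            for M in (B_MM, B_MI, B_IM, B_DG, B_GD):
                M[i, 1:-1] /= c
            offB[i] = offB[i + 1] + np.log2(c)
        else:
            offB[i] = offB[i + 1]

    with np.errstate(divide="ignore"):
        logB = np.log2(B_MM[1:-1, 1:-1]) + offB[1:-1, None]
        logP = np.log2(P[1:, 1:])
    if local:
        log2_z_b = _logsumexp2((logP + logB).ravel())
    else:
        starts = np.full((Lq, Lt), -np.inf)
        starts[0, :] = logP[0, :] + logB[0, :]
        starts[:, 0] = logP[:, 0] + logB[:, 0]
        log2_z_b = _logsumexp2(starts.ravel())

    log_post = logF + logB - log2_z_f
    post = np.exp2(log_post)
    if not np.all(np.isfinite(post)):
        bad = np.argwhere(~np.isfinite(post))[0]
        raise NumericError(f"posterior overflow at cell ({bad[0] + 1}, {bad[1] + 1})")
    post = np.clip(post, 0.0, 1.0)
    return PosteriorMatrix(post=post, log2_z_forward=log2_z_f,
                           log2_z_backward=log2_z_b)


# ---------------------------------------------------------------------------
# Maximum-accuracy alignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MacMatrix:
    """Optimal sub-alignment score matrix AS, shape (L_q+1, L_t+1) with a
    zero boundary row/column; best cell is 1-based."""

    AS: np.ndarray
    best_cell: tuple[int, int]
    mact: float


def _traceback(AS: np.ndarray, post: np.ndarray, mact: float,
               start: tuple[int, int]) -> list[AlignedColumn]:
    """Shared MAC traceback.

    Moves are re-derived at each cell by comparing candidate values in AS
    (diagonal > up > left on ties, stop when no candidate is positive), so
    the same code path serves both the plain and the coupling-augmented
    matrices.
    """
    i, j = start
    cols: list[AlignedColumn] = []
    half = mact / 2.0
    while i > 0 and j > 0:
        diag = AS[i - 1, j - 1] + post[i - 1, j - 1] - mact
        up = AS[i - 1, j] - half
        left = AS[i, j - 1] - half
        best = max(diag, up, left)
        if best <= 0.0:
            break
        if diag == best:
            cols.append(AlignedColumn(i, j, "MM", float(post[i - 1, j - 1])))
            i, j = i - 1, j - 1
        elif up == best:
            cols.append(AlignedColumn(i, None, "MI", None))
            i -= 1
        else:
            cols.append(AlignedColumn(None, j, "IM", None))
            j -= 1
    cols.reverse()
    return cols


def mac_align(
    posterior: PosteriorMatrix | np.ndarray,
    mact: float,
    query_name: str = "query",
    template_name: str = "template",
) -> tuple[MacMatrix, PairwiseAlignment]:
    """Maximum-accuracy alignment from a posterior matrix.

    AS(i,j) = max(AS(i-1,j-1) + p(i~j) - mact,
                  AS(i-1,j) - mact/2, AS(i,j-1) - mact/2, 0);
    traceback runs from the global maximum cell until a zero cell.
    """
    if not 0.0 <= mact < 1.0:
        raise ValidationError("mact must be in [0, 1)")
    post = posterior.post if isinstance(posterior, PosteriorMatrix) else \
        np.asarray(posterior, dtype=float)
    Lq, Lt = post.shape
    AS = np.zeros((Lq + 1, Lt + 1))
    half = mact / 2.0
    for i in range(1, Lq + 1):
        row = AS[i]
        prev = AS[i - 1]
        pr = post[i - 1]
        for j in range(1, Lt + 1):
            v = prev[j - 1] + pr[j - 1] - mact
            u = prev[j] - half
            if u > v:
                v = u
            u = row[j - 1] - half
            if u > v:
                v = u
            row[j] = v if v > 0.0 else 0.0
    flat = int(np.argmax(AS[1:, 1:]))
    bi, bj = flat // Lt + 1, flat % Lt + 1
    mat = MacMatrix(AS=AS, best_cell=(bi, bj), mact=mact)
    if AS[bi, bj] <= 0.0:
        return mat, PairwiseAlignment([], query_name, template_name)
    cols = _traceback(AS, post, mact, (bi, bj))
    return mat, PairwiseAlignment(cols, query_name, template_name)
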