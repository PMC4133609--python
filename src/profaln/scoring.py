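"""Match-state scoring: amino-acid column log-odds plus weighted secondary
structure, solvent accessibility and torsion-angle agreement terms.

All scores are in bits (log base 2).  The full match score is

    S(i, j) = S_aa(q_i, t_j) + w_ss * S_ss + w_sa * S_sa + w_tors * S_tors + S_shift

Unknown structural states contribute 0 (neutral) to their term.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np

from .annotations import SA_STATES, SS_STATES, UNKNOWN, StructuralAnnotation
from .errors import ValidationError
from .profile_model import BackgroundModel, ProfileHMM

logger = logging.getLogger(__name__)

#: Floor applied to the column co-emission odds sum before taking the log.
SCORE_FLOOR = 1e-6

#: Simplified secondary-structure score table (H/E/C x H/E/C):
#: +1 for matching states, -1 for mismatching ones.  Replaceable by any
#: 3x3 table; unknown states always score 0.
DEFAULT_SS_MATRIX = np.array([
    [1.0, -1.0, -1.0],
    [-1.0, 1.0, -1.0],
    [-1.0, -1.0, 1.0],
])


@dataclasses.dataclass
class ScoringWeights:
    """All tunable alignment parameters, with the published defaults."""

    w_ss: float = 0.11
    w_sa: float = 0.72
    w_tors: float = 0.4
    w_ec: float = 0.1
    shift: float = -0.03
    mact: float = 0.3501
    mode: str = "local"

    def __post_init__(self):
        for field in ("w_ss", "w_sa", "w_tors", "w_ec"):
            if getattr(self, field) < 0:
                raise ValidationError(f"{field} must be non-negative")
        if not 0.0 <= self.mact < 1.0:
            raise ValidationError("mact must be in [0, 1)")
        if self.mode not in ("local", "global"):
            raise ValidationError(f"mode must be 'local' or 'global', got {self.mode!r}")


def column_amino_score(q_col: np.ndarray, t_col: np.ndarray,
                       background: BackgroundModel) -> float:
    """log2 sum_a q_i(a) * t_j(a) / f(a), floored at SCORE_FLOOR."""
    q_col = np.asarray(q_col, dtype=float)
    t_col = np.asarray(t_col, dtype=float)
    odds = float(np.sum(q_col * t_col / background.frequencies))
    return float(np.log2(max(odds, SCORE_FLOOR)))


def ss_score(ss_q: str, ss_t: str, matrix: np.ndarray | None = None) -> float:
    """Secondary-structure agreement from a 3x3 table; unknowns score 0."""
    if ss_q not in SS_STATES or ss_t not in SS_STATES:
        return 0.0
    table = DEFAULT_SS_MATRIX if matrix is None else np.asarray(matrix, dtype=float)
    return float(table[SS_STATES.index(ss_q), SS_STATES.index(ss_t)])


def sa_score(sa_q: str, sa_t: str) -> float:
    """Kronecker delta on two-state solvent accessibility; unknowns score 0."""
    if sa_q not in SA_STATES or sa_t not in SA_STATES:
        return 0.0
    return 1.0 if sa_q == sa_t else 0.0


def torsion_score(phi_q: float, psi_q: float, phi_t: float, psi_t: float) -> float:
    """Mean of cosines of the two torsion-angle differences, in [-1, 1].

    Periodic in 360 degrees in every argument; any unknown (NaN) angle makes
    the score 0.
    """
    angles = np.array([phi_q, psi_q, phi_t, psi_t], dtype=float)
    if np.any(np.isnan(angles)):
        return 0.0
    dphi = np.deg2rad(phi_q - phi_t)
    dpsi = np.deg2rad(psi_q - psi_t)
    return float(0.5 * (np.cos(dphi) + np.cos(dpsi)))


_SS_PAD = 3  # index used for the unknown state in padded lookup tables


def _ss_codes(ann: Optional[StructuralAnnotation], L: int) -> np.ndarray:
    if ann is None:
        return np.full(L, _SS_PAD, dtype=np.int8)
    codes = np.full(L, _SS_PAD, dtype=np.int8)
    for k, s in enumerate(SS_STATES):
        codes[ann.ss == s] = k
    return codes


def _sa_codes(ann: Optional[StructuralAnnotation], L: int) -> np.ndarray:
    if ann is None:
        return np.full(L, 2, dtype=np.int8)
    codes = np.full(L, 2, dtype=np.int8)
    for k, s in enumerate(SA_STATES):
        codes[ann.sa == s] = k
    return codes


def match_score_matrix(
    q: ProfileHMM,
    t: ProfileHMM,
    weights: ScoringWeights,
    background: BackgroundModel | None = None,
    ss_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Full (L_q, L_t) match-score matrix (amino + structural terms + shift).

    A structural weight > 0 with the corresponding annotation missing makes
    that term contribute 0 everywhere, with a logged warning.
    """
    bg = background or BackgroundModel.default()
    odds = q.emissions @ (t.emissions / bg.frequencies).T
    S = np.log2(np.maximum(odds, SCORE_FLOOR))

    any_struct = weights.w_ss > 0 or weights.w_sa > 0 or weights.w_tors > 0
    if any_struct and (q.annotation is None or t.annotation is None):
        logger.warning(
            "structural weights > 0 but annotation missing on %s; "
            "structural terms contribute 0",
            "both profiles" if q.annotation is None and t.annotation is None
            else (q.name if q.annotation is None else t.name),
        )

    if weights.w_ss > 0:
        table = DEFAULT_SS_MATRIX if ss_matrix is None else np.asarray(ss_matrix, float)
        padded = np.zeros((4, 4))
        padded[:3, :3] = table
        cq = _ss_codes(q.annotation, q.length)
        ct = _ss_codes(t.annotation, t.length)
        S = S + weights.w_ss * padded[np.ix_(cq, ct)]

    if weights.w_sa > 0:
        cq = _sa_codes(q.annotation, q.length)
        ct = _sa_codes(t.annotation, t.length)
        delta = (cq[:, None] == ct[None, :]) & (cq[:, None] != 2) & (ct[None, :] != 2)
        S = S + weights.w_sa * delta.astype(float)

    if weights.w_tors > 0 and q.annotation is not None and t.annotation is not None:
        phi_q, psi_q = q.annotation.phi, q.annotation.psi
        phi_t, psi_t = t.annotation.phi, t.annotation.psi
        dphi = np.deg2rad(phi_q[:, None] - phi_t[None, :])
        dpsi = np.deg2rad(psi_q[:, None] - psi_t[None, :])
        tors = 0.5 * (np.cos(dphi) + np.cos(dpsi))
        known = (~np.isnan(phi_q) & ~np.isnan(psi_q))[:, None] & \
                (~np.isnan(phi_t) & ~np.isnan(psi_t))[None, :]
        S = S + weights.w_tors * np.where(known, np.nan_to_num(tors), 0.0)

    return S + weights.shift


def match_score(
    q: ProfileHMM,
    i: int,
    t: ProfileHMM,
    j: int,
    weights: ScoringWeights,
    background: BackgroundModel | None = None,
    ss_matrix: np.ndarray | None = None,
) -> float:
    """Single match score for 1-based columns i of q and j of t."""
    if not 1 <= i <= q.length or not 1 <= j <= t.length:
        raise ValidationError(f"column indices ({i}, {j}) out of range")
    bg = background or BackgroundModel.default()
    s = column_amino_score(q.emissions[i - 1], t.emissions[j - 1], bg)
    qa, ta = q.annotation, t.annotation
    if weights.w_ss > 0 and qa is not None and ta is not None:
        s += weights.w_ss * ss_score(qa.ss[i - 1], ta.ss[j - 1], ss_matrix)
    if weights.w_sa > 0 and qa is not None and ta is not None:
        s += weights.w_sa * sa_score(qa.sa[i - 1], ta.sa[j - 1])
    if weights.w_tors > 0 and qa is not None and ta is not None:
        s += weights.w_tors * torsion_score(
            qa.phi[i - 1], qa.psi[i - 1], ta.phi[j - 1], ta.psi[j - 1]
        )
    return s + weights.shift
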