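"""Mutual-information evolutionary-coupling matrices, partner selection and
the coupling-augmented MAC traceback.

The coupling signal between two columns of an MSA is their mutual
information over 21 symbols (20 amino acids + gap), in nats.  The top
high-MI pairs define a partner map k(.) per profile; during the final MAC
traceback, cells whose partner positions were matched consistently in a
first, standard traceback receive a bonus of w_ec per satisfied partner
constraint, and the traceback is repeated on the augmented matrix.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np

from .alignment import PairwiseAlignment
from .errors import ValidationError
from .mac import MacMatrix, PosteriorMatrix, _traceback
from .profile_model import MSA

logger = logging.getLogger(__name__)

N_SYMBOLS = 21  # 20 amino acids + gap

DEFAULT_MIN_SEPARATION = 5


def default_n_pairs(length: int) -> int:
    return math.ceil(length / 10)


def mutual_information_matrix(msa: MSA, pseudocount: float | None = None) -> np.ndarray:
    """Column-pair mutual information (natural log) over 21 symbols.

    ``pseudocount`` is an additive count per joint cell (default
    1 / n_sequences); marginals are derived from the smoothed joint, which
    keeps every MI value non-negative.  Unknown residues are counted as gap.
    A single-sequence MSA yields an all-zero matrix with a warning.
    """
    if pseudocount is None:
        pseudocount = 1.0 / msa.n_seqs
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    L = msa.n_cols
    mi = np.zeros((L, L))
    if msa.n_seqs < 2:
        logger.warning("MSA has a single sequence; MI matrix is all zero")
        return mi
    codes = msa.to_codes()
    codes = np.where(codes > 20, 20, codes).astype(np.int64)  # unknown -> gap
    n = codes.shape[0]
    denom = n + pseudocount * N_SYMBOLS * N_SYMBOLS
    for i in range(L):
        ci = codes[:, i]
        for j in range(i + 1, L):
            joint = np.bincount(ci * N_SYMBOLS + codes[:, j],
                                minlength=N_SYMBOLS * N_SYMBOLS).astype(float)
            joint += pseudocount
            joint /= denom
            joint = joint.reshape(N_SYMBOLS, N_SYMBOLS)
            fi = joint.sum(axis=1)
            fj = joint.sum(axis=0)
            mask = joint > 0
            ratio = joint[mask] / np.outer(fi, fj)[mask]
            val = float(np.sum(joint[mask] * np.log(ratio)))
            mi[i, j] = mi[j, i] = val
    return mi


def select_partners(mi: np.ndarray, n_pairs: int | None = None,
                    min_separation: int = DEFAULT_MIN_SEPARATION) -> dict[int, int]:
    """Greedy top-MI partner map (1-based columns).

    The ``n_pairs`` highest-MI pairs with |i - j| >= min_separation are taken
    in decreasing MI order (ties to the lexicographically smaller pair), each
    column used at most once; pairs with MI <= 0 are never selected.  The map
    is symmetric: k(i)=j implies k(j)=i.
    """
    mi = np.asarray(mi, dtype=float)
    if mi.ndim != 2 or mi.shape[0] != mi.shape[1]:
        raise ValidationError("MI matrix must be square")
    if not np.allclose(mi, mi.T, atol=1e-12):
        raise ValidationError("MI matrix must be symmetric")
    if min_separation < 1:
        raise ValidationError("min_separation must be >= 1")
    L = mi.shape[0]
    if n_pairs is None:
        n_pairs = default_n_pairs(L)
    if n_pairs < 0:
        raise ValidationError("n_pairs must be >= 0")
    candidates = [
        (-mi[i, j], i, j)
        for i in range(L) for j in range(i + min_separation, L)
    ]
    candidates.sort()
    partners: dict[int, int] = {}
    taken = 0
    for negval, i, j in candidates:
        if taken >= n_pairs or -negval <= 0.0:
            break  # never select pairs without a positive coupling signal
        pi, pj = i + 1, j + 1
        if pi in partners or pj in partners:
            continue
        partners[pi] = pj
        partners[pj] = pi
        taken += 1
    return partners


def write_partner_map(partners: dict[int, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tpartner\n")
        for i in sorted(partners):
            fh.write(f"{i}\t{partners[i]}\n")


def read_partner_map(path: str | Path) -> dict[int, int]:
    partners: dict[int, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("position"):
            raise ValidationError(f"{path}: missing 'position\\tpartner' header")
        for line in fh:
            if not line.strip():
                continue
            a, b = line.split()
            partners[int(a)] = int(b)
    for i, j in partners.items():
        if partners.get(j) != i:
            raise ValidationError(f"{path}: partner map not symmetric at {i}<->{j}")
    return partners


def ec_traceback(
    mac: MacMatrix,
    posterior: PosteriorMatrix | np.ndarray,
    k_q: dict[int, int],
    k_t: dict[int, int],
    w_ec: float,
    query_name: str = "query",
    template_name: str = "template",
) -> PairwiseAlignment:
    """Coupling-augmented MAC traceback (two passes).

    Pass 1 runs the standard traceback and records the matched-position maps
    M_q (query -> template) and M_t (template -> query).  Pass 2 repeats the
    traceback on AS' where cell (i, j) gains
    ``w_ec * [M_q(k_q(i)) == k_t(j)] + w_ec * [M_t(k_t(j)) == k_q(i)]``
    for positions with defined partners; move comparisons and tie rules are
    identical to the plain MAC traceback.  With w_ec = 0 or empty partner
    maps the result is bitwise-identical to pass 1.
    """
    if w_ec < 0:
        raise ValidationError("w_ec must be >= 0")
    post = posterior.post if isinstance(posterior, PosteriorMatrix) else \
        np.asarray(posterior, dtype=float)
    if mac.AS[mac.best_cell] <= 0.0:
        return PairwiseAlignment([], query_name, template_name)
    pass1 = _traceback(mac.AS, post, mac.mact, mac.best_cell)
    base = PairwiseAlignment(pass1, query_name, template_name)
    if w_ec == 0.0 or not k_q or not k_t:
        return base

    m_q = base.query_to_template()
    m_t = base.template_to_query()
    bonus = np.zeros_like(mac.AS)
    for i, ki in k_q.items():
        for j, kj in k_t.items():
            b = 0.0
            if m_q.get(ki) == kj:
                b += w_ec
            if m_t.get(kj) == ki:
                b += w_ec
            if b:
                bonus[i, j] += b
    if not bonus.any():
        return base
    pass2 = _traceback(mac.AS + bonus, post, mac.mact, mac.best_cell)
    return PairwiseAlignment(pass2, query_name, template_name)
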