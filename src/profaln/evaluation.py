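"""Alignment-quality metrics against a reference alignment with core blocks.

SP score: percentage of reference core residue pairs recovered by the
predicted alignment.  TC score: percentage of core columns correctly
aligned.  For strictly pairwise alignments the two coincide (a correctly
aligned column is exactly a correctly aligned residue pair); both are kept
as separate operations for reporting parity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .alignment import PairwiseAlignment
from .errors import MetricError, ValidationError
from .profile_model import read_msa


@dataclasses.dataclass
class ReferenceAlignment:
    """Reference aligned pairs (1-based) with a core-block subset."""

    pairs: list[tuple[int, int]]
    core: set[tuple[int, int]]

    def __post_init__(self):
        last_q, last_t = 0, 0
        for qi, tj in self.pairs:
            if qi <= last_q or tj <= last_t:
                raise ValidationError("reference pairs must be strictly increasing")
            last_q, last_t = qi, tj
        extra = self.core - set(self.pairs)
        if extra:
            raise ValidationError(f"core pairs not in reference: {sorted(extra)[:3]}")

    @classmethod
    def from_pairs(cls, pairs, core=None) -> "ReferenceAlignment":
        pairs = [tuple(p) for p in pairs]
        core = set(pairs) if core is None else {tuple(p) for p in core}
        return cls(pairs=pairs, core=core)


def read_reference(path: str | Path, core_mask: str | None = None) -> ReferenceAlignment:
    """Read a two-row aligned FASTA reference.

    ``core_mask``, when given, is a string over alignment columns ('*' =
    core, anything else = non-core); without it every aligned pair is core.
    """
    msa = read_msa(path, format="fasta")
    if msa.n_seqs != 2:
        raise ValidationError(
            f"{path}: reference must contain exactly 2 records, found {msa.n_seqs}"
        )
    top, bottom = msa.rows
    if core_mask is not None and len(core_mask) != len(top):
        raise ValidationError("core mask length differs from alignment length")
    pairs, core = [], set()
    qi = tj = 0
    for col, (a, b) in enumerate(zip(top, bottom)):
        if a != "-":
            qi += 1
        if b != "-":
            tj += 1
        if a != "-" and b != "-":
            pairs.append((qi, tj))
            if core_mask is None or core_mask[col] == "*":
                core.add((qi, tj))
    return ReferenceAlignment(pairs=pairs, core=core)


def sp_score(predicted: PairwiseAlignment, reference: ReferenceAlignment) -> float:
    """100 * |predicted MM pairs  ∩  core pairs| / |core pairs|."""
    if not reference.core:
        raise MetricError("reference has no core pairs; SP score undefined")
    hits = sum(1 for p in predicted.matched_pairs if p in reference.core)
    return 100.0 * hits / len(reference.core)


def tc_score(predicted: PairwiseAlignment, reference: ReferenceAlignment) -> float:
    """Percentage of core columns correctly aligned.

    For pairwise alignments a core column is correct iff its residue pair is
    recovered, so this equals :func:`sp_score`; kept separate for reporting.
    """
    if not reference.core:
        raise MetricError("reference has no core pairs; TC score undefined")
    predicted_pairs = set(predicted.matched_pairs)
    correct = sum(1 for p in reference.core if p in predicted_pairs)
    return 100.0 * correct / len(reference.core)


def report_tsv(rows: list[tuple[str, float, float]]) -> str:
    """TSV report of (pair id, SP, TC) rows."""
    out = ["pair\tsp\ttc"]
    for pair_id, sp, tc in rows:
        out.append(f"{pair_id}\t{sp:.4f}\t{tc:.4f}")
    return "\n".join(out) + "\n"
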