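"""Pairwise alignment container shared by the Viterbi and MAC decoders."""

from __future__ import annotations

import dataclasses
from typing import Optional

from .errors import ValidationError

STATES = ("MM", "MI", "IM", "DG", "GD")


@dataclasses.dataclass(frozen=True)
class AlignedColumn:
    """One alignment step: 1-based column indices (None = gap on that side),
    the pair-state label, and the per-pair score or posterior (MM only)."""

    query: Optional[int]
    template: Optional[int]
    state: str
    score: Optional[float] = None


@dataclasses.dataclass
class PairwiseAlignment:
    columns: list[AlignedColumn]
    query_name: str = "query"
    template_name: str = "template"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        last_q, last_t = 0, 0
        for col in self.columns:
            if col.state not in STATES:
                raise ValidationError(f"unknown pair state {col.state!r}")
            if col.query is None and col.template is None:
                raise ValidationError("(gap, gap) column is not allowed")
            if col.state == "MM" and (col.query is None or col.template is None):
                raise ValidationError("MM column must have both indices")
            if col.query is not None:
                if col.query <= last_q:
                    raise ValidationError(
                        f"query columns not strictly increasing at {col.query}"
                    )
                last_q = col.query
            if col.template is not None:
                if col.template <= last_t:
                    raise ValidationError(
                        f"template columns not strictly increasing at {col.template}"
                    )
                last_t = col.template

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def matched_pairs(self) -> list[tuple[int, int]]:
        """The (query, template) pairs of MM columns, in order."""
        return [(c.query, c.template) for c in self.columns if c.state == "MM"]

    def query_to_template(self) -> dict[int, int]:
        return {q: t for q, t in self.matched_pairs}

    def template_to_query(self) -> dict[int, int]:
        return {t: q for q, t in self.matched_pairs}

    def to_tsv(self) -> str:
        """TSV rendering: query pos, template pos, state, score/posterior."""
        lines = ["query\ttemplate\tstate\tscore"]
        for c in self.columns:
            lines.append("\t".join([
                "-" if c.query is None else str(c.query),
                "-" if c.template is None else str(c.template),
                c.state,
                "" if c.score is None else f"{c.score:.6g}",
            ]))
        return "\n".join(lines) + "\n"

    def to_fasta(self, query_seq: str, template_seq: str) -> str:
        """Two-row aligned FASTA given the full (unaligned) residue strings,
        e.g. profile consensus sequences.  Only the aligned span is shown."""
        top, bottom = [], []
        for c in self.columns:
            top.append("-" if c.query is None else query_seq[c.query - 1])
            bottom.append("-" if c.template is None else template_seq[c.template - 1])
        return (f">{self.query_name}\n{''.join(top)}\n"
                f">{self.template_name}\n{''.join(bottom)}\n")
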