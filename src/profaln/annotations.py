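"""Per-residue structural annotations: secondary structure, solvent
accessibility and backbone torsion angles.

The canonical input is a tab-separated table with header
``position  ss  sa  phi  psi``; missing cells ('' or '.') become unknowns.
Numeric solvent-accessibility cells are relative exposures in [0, 1] and are
discretized to exposed/buried at the 25% threshold.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ParseError, ValidationError

SS_STATES = ("H", "E", "C")
SA_STATES = ("e", "b")
UNKNOWN = "."

# 8-state DSSP codes collapsed to 3 states.
_DSSP_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E",
                  "T": "C", "S": "C", "C": "C", "-": "C", " ": "C"}

#: Exposure fraction at or above which a residue counts as exposed.
SA_EXPOSED_THRESHOLD = 0.25


def discretize_sa(relative_exposure: float) -> str:
    """Two-state solvent accessibility: 'e' if >= 25% of the maximum area is
    exposed, 'b' (buried) below."""
    x = float(relative_exposure)
    if not 0.0 <= x <= 1.0:
        raise ValidationError(f"relative exposure {x!r} outside [0, 1]")
    return "e" if x >= SA_EXPOSED_THRESHOLD else "b"


@dataclasses.dataclass
class StructuralAnnotation:
    """Per-column structural states; any field may be unknown.

    ss/sa are arrays of single characters ('.' = unknown); phi/psi are
    degree arrays with NaN for unknown, all values in [-180, 180].
    """

    ss: np.ndarray
    sa: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.ss = np.asarray(self.ss, dtype="U1")
        self.sa = np.asarray(self.sa, dtype="U1")
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.validate()

    @property
    def length(self) -> int:
        return self.ss.shape[0]

    def validate(self) -> None:
        L = self.ss.shape[0]
        for field in ("sa", "phi", "psi"):
            if getattr(self, field).shape[0] != L:
                raise ValidationError(f"annotation field {field} has wrong length")
        bad_ss = ~np.isin(self.ss, SS_STATES + (UNKNOWN,))
        if bad_ss.any():
            raise ValidationError(
                f"invalid secondary-structure state {self.ss[bad_ss][0]!r}"
            )
        bad_sa = ~np.isin(self.sa, SA_STATES + (UNKNOWN,))
        if bad_sa.any():
            raise ValidationError(
                f"invalid solvent-accessibility state {self.sa[bad_sa][0]!r}"
            )
        for label, ang in (("phi", self.phi), ("psi", self.psi)):
            vals = ang[~np.isnan(ang)]
            if vals.size and (vals.min() < -180.0 or vals.max() > 180.0):
                raise ValidationError(f"{label} angle outside [-180, 180]")

    @classmethod
    def empty(cls, length: int) -> "StructuralAnnotation":
        return cls(
            ss=np.full(length, UNKNOWN, dtype="U1"),
            sa=np.full(length, UNKNOWN, dtype="U1"),
            phi=np.full(length, np.nan),
            psi=np.full(length, np.nan),
        )


_HEADER = ("position", "ss", "sa", "phi", "psi")


def _parse_cell(cell: str) -> str:
    return cell.strip()


def read_annotation_table(path: str | Path) -> StructuralAnnotation:
    """Parse the canonical annotation table.

    Rules: 8-state DSSP secondary-structure codes are collapsed to H/E/C;
    an 'sa' cell may be a state letter or a numeric relative exposure;
    positions must be contiguous starting at 1.
    """
    path = Path(path)
    ss, sa, phi, psi = [], [], [], []
    with open(path) as fh:
        header = fh.readline()
        cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
        if tuple(cols[:5]) != _HEADER:
            raise ParseError(
                f"{path}: expected header {' '.join(_HEADER)!r}, got {header.strip()!r}"
            )
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cells = [_parse_cell(c) for c in line.rstrip("\n").split("\t")]
            if len(cells) < 5:
                cells += [""] * (5 - len(cells))
            try:
                pos = int(cells[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {cells[0]!r}") from exc
            if pos != len(ss) + 1:
                raise ValidationError(
                    f"{path}:{lineno}: non-contiguous position {pos} "
                    f"(expected {len(ss) + 1})"
                )
            ss_cell = cells[1].upper()
            if ss_cell in ("", UNKNOWN):
                ss.append(UNKNOWN)
            elif ss_cell in _DSSP_COLLAPSE:
                ss.append(_DSSP_COLLAPSE[ss_cell])
            else:
                raise ValidationError(
                    f"{path}:{lineno}: unknown secondary-structure code {cells[1]!r}"
                )
            sa_cell = cells[2]
            if sa_cell in ("", UNKNOWN):
                sa.append(UNKNOWN)
            elif sa_cell.lower() in SA_STATES:
                sa.append(sa_cell.lower())
            else:
                try:
                    rsa = float(sa_cell)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: bad solvent-accessibility cell {sa_cell!r}"
                    ) from exc
                try:
                    sa.append(discretize_sa(rsa))
                except ValidationError as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            for cell, dest, label in ((cells[3], phi, "phi"), (cells[4], psi, "psi")):
                if cell in ("", UNKNOWN):
                    dest.append(np.nan)
                else:
                    try:
                        ang = float(cell)
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: bad {label} angle {cell!r}"
                        ) from exc
                    if not -180.0 <= ang <= 180.0:
                        raise ValidationError(
                            f"{path}:{lineno}: {label} angle {ang} outside [-180, 180]"
                        )
                    dest.append(ang)
    if not ss:
        raise ParseError(f"{path}: no annotation rows")
    return StructuralAnnotation(ss=np.array(ss), sa=np.array(sa),
                                phi=np.array(phi), psi=np.array(psi))


def write_annotation_table(annotation: StructuralAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for i in range(annotation.length):
            phi = annotation.phi[i]
            psi = annotation.psi[i]
            fh.write("\t".join([
                str(i + 1),
                annotation.ss[i],
                annotation.sa[i],
                UNKNOWN if np.isnan(phi) else f"{phi:.17g}",
                UNKNOWN if np.isnan(psi) else f"{psi:.17g}",
            ]) + "\n")
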