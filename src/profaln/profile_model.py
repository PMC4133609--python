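"""Profile hidden Markov models: construction from MSAs, validation, text I/O.

A profile is a per-column emission distribution over the 20 amino acids plus
seven per-column transition probabilities (M->M, M->I, M->D, I->M, I->I,
D->M, D->D).  Column indices are 1-based in every public interface; numpy
arrays are 0-based internally.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from .errors import DimensionError, ParseError, ValidationError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: k for k, a in enumerate(AMINO_ACIDS)}
GAP = "-"
UNKNOWN = "X"

# Transition slot order, used everywhere including the native profile format.
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)
TRANSITION_LABELS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")

#: Fallback transition row used when a transition cannot be estimated from
#: the alignment (configurable via ``build_profile`` arguments).
DEFAULT_TRANSITIONS = np.array([0.97, 0.015, 0.015, 0.5, 0.5, 0.5, 0.5])

#: Emission probability floor applied after pseudocount admixture so that
#: log-odds column scores never hit log(0).
EMISSION_FLOOR = 1e-6

# Robinson & Robinson (1991) amino-acid frequencies (normalized below),
# in AMINO_ACIDS order.  Overridable: pass any BackgroundModel.
_ROBINSON = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
    0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
    0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03219,
])

_PROB_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class BackgroundModel:
    """Background amino-acid frequencies f(a)."""

    frequencies: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.shape != (20,):
            raise ValidationError(f"background must have 20 entries, got {f.shape}")
        if not np.all(f > 0):
            raise ValidationError("background frequencies must be strictly positive")
        if abs(f.sum() - 1.0) > _PROB_TOL:
            raise ValidationError(f"background frequencies sum to {f.sum():.12g}, not 1")

    @classmethod
    def default(cls) -> "BackgroundModel":
        return cls(_ROBINSON / _ROBINSON.sum())


@dataclasses.dataclass
class MSA:
    """A rectangular multiple sequence alignment over the 20 amino acids,
    gap '-' and unknown 'X'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise DimensionError("ids and rows differ in length")
        if not self.rows:
            raise ValidationError("MSA must contain at least one sequence")
        ncol = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise DimensionError(
                    f"ragged alignment: sequence {sid!r} has {len(row)} columns, "
                    f"expected {ncol}"
                )

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        """Character matrix of shape (n_seqs, n_cols)."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def to_codes(self) -> np.ndarray:
        """Integer matrix: 0..19 residues, 20 gap, 21 unknown."""
        arr = self.to_array()
        codes = np.full(arr.shape, 21, dtype=np.int8)
        for a, k in AA_INDEX.items():
            codes[arr == a] = k
        codes[arr == GAP] = 20
        return codes


def _normalise_residues(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in AA_INDEX:
            out.append(ch)
        elif ch in ("-", "."):
            out.append(GAP)
        else:
            out.append(UNKNOWN)
    return "".join(out)


def read_msa(path: str | Path, format: str = "fasta") -> MSA:
    """Read a FASTA or A3M alignment.

    For A3M, lower-case residues mark insert columns and are removed, leaving
    only match columns; '.' gap fillers are dropped along with them.
    """
    path = Path(path)
    if format not in ("fasta", "a3m"):
        raise ValueError(f"unknown MSA format {format!r}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: expected a '>' header, found {line.strip()[:30]!r}"
                )
            break
        else:
            raise ParseError(f"{path}: empty file")

    ids, rows = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if format == "a3m":
            # a3m convention: lower-case letters and '.' are insert states.
            seq = "".join(ch for ch in seq if not ch.islower() and ch != ".")
        rows.append(_normalise_residues(seq))
        ids.append(record.id)
    if not rows:
        raise ParseError(f"{path}: no sequence records found")
    ncol = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != ncol:
            raise DimensionError(
                f"{path}: ragged alignment at record {sid!r} "
                f"({len(row)} columns, expected {ncol})"
            )
    return MSA(ids=ids, rows=rows)


def write_msa(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


@dataclasses.dataclass
class ProfileHMM:
    """A profile HMM of length L.

    emissions: (L, 20) row-stochastic matrix q_i(a).
    transitions: (L, 7) matrix, slots ordered per TRANSITION_LABELS; the
        M row (MM, MI, MD), I row (IM, II) and D row (DM, DD) each sum to 1.
    annotation: optional per-column structural annotation of matching length.
    """

    name: str
    emissions: np.ndarray
    transitions: np.ndarray
    annotation: Optional["StructuralAnnotation"] = None  # noqa: F821

    def __post_init__(self):
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.validate()

    @property
    def length(self) -> int:
        return self.emissions.shape[0]

    def validate(self) -> None:
        if self.emissions.ndim != 2 or self.emissions.shape[1] != 20:
            raise ValidationError("emissions must be an L x 20 matrix")
        L = self.emissions.shape[0]
        if L < 1:
            raise ValidationError("profile length must be >= 1")
        if self.transitions.shape != (L, 7):
            raise DimensionError(
                f"transitions must be {L} x 7, got {self.transitions.shape}"
            )
        if np.any(self.emissions < 0):
            raise ValidationError("negative emission probability")
        sums = self.emissions.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _PROB_TOL)
        if bad.size:
            raise ValidationError(
                f"emission row(s) {[int(b) + 1 for b in bad[:5]]} sum to "
                f"{sums[bad[0]]:.12g}, not 1"
            )
        for lo, hi, label in ((T_MM, T_MD, "M"), (T_IM, T_II, "I"), (T_DM, T_DD, "D")):
            rowsum = self.transitions[:, lo:hi + 1].sum(axis=1)
            bad = np.flatnonzero(np.abs(rowsum - 1.0) > _PROB_TOL)
            if bad.size:
                raise ValidationError(
                    f"transition probabilities out of state {label} at column "
                    f"{int(bad[0]) + 1} sum to {rowsum[bad[0]]:.12g}, not 1"
                )
        if np.any(self.transitions < 0):
            raise ValidationError("negative transition probability")
        if self.annotation is not None and self.annotation.length != L:
            raise DimensionError(
                f"annotation has {self.annotation.length} columns, profile has {L}"
            )

    def attach_annotation(self, annotation) -> None:
        if annotation is not None and annotation.length != self.length:
            raise DimensionError(
                f"annotation has {annotation.length} columns, profile has {self.length}"
            )
        self.annotation = annotation

    def consensus(self) -> str:
        """Highest-probability residue per column (for rendering alignments)."""
        return "".join(AMINO_ACIDS[k] for k in self.emissions.argmax(axis=1))


def _henikoff_weights(codes: np.ndarray) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff 1994)."""
    n, L = codes.shape
    w = np.zeros(n)
    for j in range(L):
        col = codes[:, j]
        obs = col[col < 20]
        if obs.size == 0:
            continue
        symbols, counts = np.unique(obs, return_counts=True)
        r = symbols.size
        share = {int(s): 1.0 / (r * c) for s, c in zip(symbols, counts)}
        for k in range(n):
            if col[k] < 20:
                w[k] += share[int(col[k])]
    if w.sum() == 0:
        return np.full(n, 1.0 / n)
    return w / w.sum()


def build_profile(
    msa: MSA,
    background: BackgroundModel | None = None,
    pseudocount_admixture: float = 0.0,
    weighting: str = "uniform",
    name: str = "profile",
    default_transitions: np.ndarray | None = None,
    emission_floor: float = EMISSION_FLOOR,
) -> ProfileHMM:
    """Estimate a profile HMM from an MSA.

    Emissions are ``(1 - tau) * observed + tau * f(a)`` (tau =
    ``pseudocount_admixture``), floored at ``emission_floor`` and
    renormalized.  Transitions are estimated from the match/delete structure
    of consecutive columns with a Laplace pseudocount of 1; insert
    transitions (unobservable from match columns) use the defaults.
    All-gap columns are dropped with a warning.
    """
    if not 0.0 <= pseudocount_admixture <= 1.0:
        raise ValidationError("pseudocount_admixture must be in [0, 1]")
    if weighting not in ("uniform", "position-based"):
        raise ValueError(f"unknown weighting scheme {weighting!r}")
    bg = background or BackgroundModel.default()
    defaults = DEFAULT_TRANSITIONS if default_transitions is None else np.asarray(
        default_transitions, dtype=float
    )

    codes = msa.to_codes()
    n, ncol = codes.shape
    if weighting == "uniform":
        weights = np.full(n, 1.0 / n)
    else:
        weights = _henikoff_weights(codes)

    # Drop columns with no residue observations (all gap/unknown).
    keep = []
    for j in range(ncol):
        if np.any(codes[:, j] < 20):
            keep.append(j)
        else:
            logger.warning("dropping all-gap column %d while building %s", j + 1, name)
    if not keep:
        raise ValidationError("MSA has no columns with residue observations")
    codes = codes[:, keep]
    L = codes.shape[1]

    tau = pseudocount_admixture
    emissions = np.zeros((L, 20))
    for j in range(L):
        col = codes[:, j]
        mask = col < 20
        wsum = weights[mask].sum()
        freq = np.zeros(20)
        if wsum > 0:
            np.add.at(freq, col[mask], weights[mask])
            freq /= wsum
        emissions[j] = (1.0 - tau) * freq + tau * bg.frequencies
    emissions = np.maximum(emissions, emission_floor)
    emissions /= emissions.sum(axis=1, keepdims=True)

    # Match/delete transition estimation: state per (sequence, column) is
    # M if a residue (incl. unknown) is present, D if gap.
    transitions = np.tile(defaults, (L, 1))
    is_m = codes != 20  # unknown residues (code 21) still occupy a match state
    if np.any(codes == 20):
        alpha = 1.0  # Laplace pseudocount per observed category
        mi_default = defaults[T_MI]
        for j in range(L - 1):
            a, b = is_m[:, j], is_m[:, j + 1]
            m2m = float(np.sum(a & b)) + alpha
            m2d = float(np.sum(a & ~b)) + alpha
            d2m = float(np.sum(~a & b)) + alpha
            d2d = float(np.sum(~a & ~b)) + alpha
            transitions[j, T_MM] = (1.0 - mi_default) * m2m / (m2m + m2d)
            transitions[j, T_MI] = mi_default
            transitions[j, T_MD] = (1.0 - mi_default) * m2d / (m2m + m2d)
            transitions[j, T_DM] = d2m / (d2m + d2d)
            transitions[j, T_DD] = d2d / (d2m + d2d)

    return ProfileHMM(name=name, emissions=emissions, transitions=transitions)


_FORMAT_HEADER = "# profaln profile format 1"


def write_profile(profile: ProfileHMM, path: str | Path,
                  background: BackgroundModel | None = None) -> None:
    """Write the native column-oriented text dialect (full float precision,
    so that read(write(p)) reproduces every probability exactly)."""
    bg = background or BackgroundModel.default()
    with open(path, "w") as fh:
        fh.write(_FORMAT_HEADER + "\n")
        fh.write(f"name\t{profile.name}\n")
        fh.write(f"length\t{profile.length}\n")
        fh.write("alphabet\t" + AMINO_ACIDS + "\n")
        fh.write("background\t" + "\t".join(f"{v:.17g}" for v in bg.frequencies) + "\n")
        fh.write("# column\t20 emissions\t7 transitions (" +
                 " ".join(TRANSITION_LABELS) + ")\n")
        for i in range(profile.length):
            vals = [f"{v:.17g}" for v in profile.emissions[i]]
            vals += [f"{v:.17g}" for v in profile.transitions[i]]
            fh.write(f"{i + 1}\t" + "\t".join(vals) + "\n")


def read_profile(path: str | Path) -> tuple[ProfileHMM, BackgroundModel]:
    """Read the native profile dialect written by :func:`write_profile`."""
    path = Path(path)
    name, length, bg = None, None, None
    rows: list[list[float]] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# profaln profile"):
            raise ParseError(f"{path}: not a profaln profile file")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            key = fields[0]
            if key == "name":
                name = fields[1] if len(fields) > 1 else ""
            elif key == "length":
                length = int(fields[1])
            elif key == "alphabet":
                if fields[1] != AMINO_ACIDS:
                    raise ParseError(f"{path}:{lineno}: unsupported alphabet")
            elif key == "background":
                bg = BackgroundModel(np.array([float(v) for v in fields[1:21]]))
            else:
                try:
                    int(key)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: unexpected line {key!r}") from exc
                if len(fields) != 28:
                    raise ParseError(
                        f"{path}:{lineno}: expected 27 values per column, got "
                        f"{len(fields) - 1}"
                    )
                rows.append([float(v) for v in fields[1:]])
    if name is None or length is None or bg is None:
        raise ParseError(f"{path}: missing header line(s)")
    if length < 1:
        raise ValidationError(f"{path}: profile length must be >= 1, got {length}")
    if len(rows) != length:
        raise DimensionError(
            f"{path}: header says {length} columns, found {len(rows)}"
        )
    data = np.array(rows)
    profile = ProfileHMM(name=name, emissions=data[:, :20], transitions=data[:, 20:])
    return profile, bg
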