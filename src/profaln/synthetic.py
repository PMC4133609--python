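"""Seeded generator of homologous protein-pair fixtures.

Produces, deterministically from a seed: two related sequence families (as
MSAs), per-column structural annotations whose agreement on truly aligned
columns is controlled, the true pairwise alignment implied by the indel
history, and planted covarying column pairs with partner maps.  Everything
every other module consumes can be generated here, so no external data is
needed for testing.

The substitution process draws replacement residues from the background
distribution (not from a substitution matrix) -- deliberately
non-biological, but it keeps closed-form oracles simple.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alignment import AlignedColumn, PairwiseAlignment
from .annotations import StructuralAnnotation
from .errors import GenerationError, ValidationError
from .profile_model import AMINO_ACIDS, MSA, BackgroundModel, ProfileHMM

# Representative (phi, psi) centres per secondary-structure class, degrees.
_SS_ANGLES = {"H": (-60.0, -45.0), "E": (-120.0, 130.0), "C": (-70.0, 140.0)}
_SS_CLASSES = ("H", "E", "C")
_ANGLE_NOISE = 12.0  # uniform +- degrees around the class centre


@dataclasses.dataclass(frozen=True)
class SyntheticParams:
    seed: int = 0
    length: int = 40
    n_sequences: int = 8
    divergence: float = 0.2
    indel_rate: float = 0.05
    family_mutation: float = 0.05
    annotation_agreement: float = 0.9
    coupling_strength: float = 0.0
    coupled_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.length < 5:
            raise ValidationError("length must be >= 5")
        if self.n_sequences < 2:
            raise ValidationError("n_sequences must be >= 2")
        for field in ("divergence", "indel_rate", "family_mutation",
                      "annotation_agreement", "coupling_strength"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{field} must be in [0, 1], got {v}")


@dataclasses.dataclass
class SyntheticPair:
    params: SyntheticParams
    msa_q: MSA
    msa_t: MSA
    annotation_q: StructuralAnnotation
    annotation_t: StructuralAnnotation
    true_alignment: PairwiseAlignment
    partners_q: dict[int, int]
    partners_t: dict[int, int]


def _mutate(seq: np.ndarray, rate: float, bg: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    if hit.any():
        out[hit] = rng.choice(20, size=int(hit.sum()), p=bg)
    return out


def _wrap(angle: np.ndarray) -> np.ndarray:
    return (angle + 180.0) % 360.0 - 180.0


def _annotation_for(classes: list[str], sa: list[str],
                    rng: np.random.Generator) -> StructuralAnnotation:
    phi = np.empty(len(classes))
    psi = np.empty(len(classes))
    for k, cls in enumerate(classes):
        c_phi, c_psi = _SS_ANGLES[cls]
        phi[k] = c_phi + rng.uniform(-_ANGLE_NOISE, _ANGLE_NOISE)
        psi[k] = c_psi + rng.uniform(-_ANGLE_NOISE, _ANGLE_NOISE)
    return StructuralAnnotation(ss=np.array(classes), sa=np.array(sa),
                                phi=_wrap(phi), psi=_wrap(psi))


def generate_pair(params: SyntheticParams) -> SyntheticPair:
    """Generate a homologous pair fixture; bit-identical for equal params."""
    rng = np.random.default_rng(params.seed)
    bg = BackgroundModel.default().frequencies
    L = params.length

    ancestral = rng.choice(20, size=L, p=bg)

    # Indel history: each ancestral column survives in q, in t, or in both.
    u = rng.random(L)
    in_q = u >= params.indel_rate / 2.0
    in_t = (u < params.indel_rate / 2.0) | (u >= params.indel_rate)
    if not in_q.any() or not in_t.any():
        raise GenerationError("all columns deleted; lower indel_rate")
    q_index = np.cumsum(in_q)  # ancestral column -> 1-based q position
    t_index = np.cumsum(in_t)
    true_cols = [
        AlignedColumn(int(q_index[k]), int(t_index[k]), "MM", None)
        if in_q[k] and in_t[k] else
        AlignedColumn(int(q_index[k]), None, "DG", None)
        if in_q[k] else
        AlignedColumn(None, int(t_index[k]), "GD", None)
        for k in range(L)
    ]
    if not any(c.state == "MM" for c in true_cols):
        raise GenerationError("no aligned columns survived; lower the rates")

    seq_q = _mutate(ancestral[in_q], params.divergence, bg, rng)
    seq_t = _mutate(ancestral[in_t], params.divergence, bg, rng)
    Lq, Lt = seq_q.size, seq_t.size

    def family(descendant: np.ndarray, tag: str) -> list[np.ndarray]:
        return [
            _mutate(descendant, params.family_mutation, bg, rng)
            for _ in range(params.n_sequences)
        ]

    fam_q = family(seq_q, "q")
    fam_t = family(seq_t, "t")

    # Plant covarying column pairs (1-based positions in the query family);
    # the corresponding template positions, where both survive, are planted
    # too so that each profile carries its own coupling signal.
    q_to_t = {c.query: c.template for c in true_cols if c.state == "MM"}
    partners_q: dict[int, int] = {}
    partners_t: dict[int, int] = {}
    for (pi, pj) in params.coupled_pairs:
        if not (1 <= pi <= Lq and 1 <= pj <= Lq and pi != pj):
            raise ValidationError(f"coupled pair ({pi}, {pj}) out of range")
        symbols = rng.choice(20, size=4, replace=False)
        states = rng.integers(0, 2, size=params.n_sequences)
        covary = rng.random(params.n_sequences) < params.coupling_strength
        for fam, a, b in ((fam_q, pi, pj),
                          (fam_t, q_to_t.get(pi), q_to_t.get(pj))):
            if a is None or b is None:
                continue
            for s, z, cv in zip(fam, states, covary):
                if cv:
                    s[a - 1] = symbols[z]
                    s[b - 1] = symbols[2 + z]
        partners_q[pi] = pj
        partners_q[pj] = pi
        ti, tj = q_to_t.get(pi), q_to_t.get(pj)
        if ti is not None and tj is not None:
            partners_t[ti] = tj
            partners_t[tj] = ti

    def to_msa(fam: list[np.ndarray], tag: str) -> MSA:
        rows = ["".join(AMINO_ACIDS[r] for r in s) for s in fam]
        ids = [f"{tag}{k + 1}" for k in range(len(fam))]
        return MSA(ids=ids, rows=rows)

    msa_q = to_msa(fam_q, "q")
    msa_t = to_msa(fam_t, "t")

    # Structural annotations: each query position draws a class; truly
    # aligned template positions copy it with the agreement probability.
    cls_q = [str(rng.choice(_SS_CLASSES)) for _ in range(Lq)]
    sa_q = [str(rng.choice(("e", "b"))) for _ in range(Lq)]
    cls_t = [str(rng.choice(_SS_CLASSES)) for _ in range(Lt)]
    sa_t = [str(rng.choice(("e", "b"))) for _ in range(Lt)]
    for c in true_cols:
        if c.state == "MM" and rng.random() < params.annotation_agreement:
            cls_t[c.template - 1] = cls_q[c.query - 1]
            sa_t[c.template - 1] = sa_q[c.query - 1]
    ann_q = _annotation_for(cls_q, sa_q, rng)
    ann_t = _annotation_for(cls_t, sa_t, rng)

    true_alignment = PairwiseAlignment(true_cols, "query", "template")
    return SyntheticPair(
        params=params, msa_q=msa_q, msa_t=msa_t,
        annotation_q=ann_q, annotation_t=ann_t,
        true_alignment=true_alignment,
        partners_q=partners_q, partners_t=partners_t,
    )


def write_pair_files(pair: SyntheticPair, directory: str | Path) -> dict[str, Path]:
    """Write every fixture file in the formats the other modules read."""
    from .annotations import write_annotation_table
    from .coupling import write_partner_map
    from .profile_model import write_msa

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "msa_q": directory / "query.fasta",
        "msa_t": directory / "template.fasta",
        "ann_q": directory / "query.ann.tsv",
        "ann_t": directory / "template.ann.tsv",
        "reference": directory / "reference.fasta",
        "partners_q": directory / "query.partners.tsv",
        "partners_t": directory / "template.partners.tsv",
    }
    write_msa(pair.msa_q, paths["msa_q"])
    write_msa(pair.msa_t, paths["msa_t"])
    write_annotation_table(pair.annotation_q, paths["ann_q"])
    write_annotation_table(pair.annotation_t, paths["ann_t"])
    with open(paths["reference"], "w") as fh:
        fh.write(pair.true_alignment.to_fasta(pair.msa_q.rows[0], pair.msa_t.rows[0]))
    write_partner_map(pair.partners_q, paths["partners_q"])
    write_partner_map(pair.partners_t, paths["partners_t"])
    return paths


# ---------------------------------------------------------------------------
# Random model fixtures (used heavily by tests and the acceptance report)
# ---------------------------------------------------------------------------

def random_profile(rng: np.random.Generator, length: int,
                   name: str = "random", with_annotation: bool = True,
                   annotation: Optional[StructuralAnnotation] = None) -> ProfileHMM:
    """A random valid profile: Dirichlet emissions, Dirichlet transition
    rows, optional random annotation."""
    emissions = rng.dirichlet(np.full(20, 0.5), size=length)
    m_row = rng.dirichlet(np.array([8.0, 1.0, 1.0]), size=length)
    i_row = rng.dirichlet(np.array([1.0, 1.0]), size=length)
    d_row = rng.dirichlet(np.array([1.0, 1.0]), size=length)
    transitions = np.hstack([m_row, i_row, d_row])
    profile = ProfileHMM(name=name, emissions=emissions, transitions=transitions)
    if annotation is not None:
        profile.attach_annotation(annotation)
    elif with_annotation:
        profile.attach_annotation(random_annotation(rng, length))
    return profile


def random_annotation(rng: np.random.Generator, length: int,
                      unknown_fraction: float = 0.1) -> StructuralAnnotation:
    ss = rng.choice(_SS_CLASSES, size=length).astype("U1")
    sa = rng.choice(("e", "b"), size=length).astype("U1")
    phi = rng.uniform(-180.0, 180.0, size=length)
    psi = rng.uniform(-180.0, 180.0, size=length)
    mask = rng.random(length) < unknown_fraction
    ss[mask] = "."
    mask = rng.random(length) < unknown_fraction
    sa[mask] = "."
    mask = rng.random(length) < unknown_fraction
    phi[mask] = np.nan
    psi[mask] = np.nan
    return StructuralAnnotation(ss=ss, sa=sa, phi=phi, psi=psi)
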