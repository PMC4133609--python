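# profaln

Pairwise profile-HMM alignment with structure-augmented scoring and
evolutionary-coupling-guided traceback.

`profaln` aligns two protein profile hidden Markov models (built from
multiple sequence alignments or read from its native profile format). The
match-state score combines the classic column log-odds term with weighted
agreement terms for 3-state secondary structure, 2-state solvent
accessibility (exposed/buried at the 25% relative-exposure threshold) and
backbone torsion angles. Decoding is either:

- **Viterbi** — five-matrix (MM/MI/IM/DG/GD) dynamic programming maximizing
  the augmented log-sum-of-odds score, or
- **MAC** (default) — Forward-Backward posterior match probabilities
  followed by a maximum-accuracy alignment whose greediness is set by
  `mact` (0 ≈ global, →1 short precise local), optionally finished by a
  traceback pass that rewards residue pairs whose mutual-information
  coupling partners were aligned consistently.

Also included: mutual-information coupling matrices and partner selection
from MSAs, SP/TC alignment evaluation against a core-block reference, and a
fully seeded synthetic homolog-pair generator so that everything is testable
without external data.

## Command line

```bash
# simulate a homologous pair fixture (MSAs, annotations, reference, partners)
profaln simulate --seed 3 --length 40 --out fixtures/

# align two MSAs end to end (Viterbi score + MAC alignment)
profaln align --query fixtures/query.fasta --template fixtures/template.fasta \
    --query-ann fixtures/query.ann.tsv --template-ann fixtures/template.ann.tsv \
    --query-partners fixtures/query.partners.tsv \
    --template-partners fixtures/template.partners.tsv \
    --out result

# weights (defaults): --w-ss 0.11 --w-sa 0.72 --w-tors 0.4 --w-ec 0.1
#                     --shift -0.03 --mact 0.3501 --mode local --realign mac

# coupling matrix / partner map from an MSA
profaln mi --msa fixtures/query.fasta --partners-out partners.tsv

# evaluate a predicted two-row aligned FASTA against a reference
profaln evaluate --predicted result.fasta --reference fixtures/reference.fasta
```

`--config FILE` reads `key = value` lines for any of the weight flags;
explicit flags override the config. `align` writes a two-row aligned FASTA
(profile consensus residues) and a TSV of (query pos, template pos, state,
posterior).

## File formats

- **MSA**: FASTA (rectangular) or A3M (lower-case insert columns removed).
- **Profile**: native column-oriented text (`write_profile`/`read_profile`),
  one line per column with 20 emissions and 7 transitions; round-trips
  exactly.
- **Annotations**: TSV with header `position ss sa phi psi`; `sa` accepts
  `e`/`b` or a numeric relative exposure; missing cells (`.` or empty) are
  neutral in scoring; 8-state DSSP codes are collapsed to H/E/C.
- **Partner maps**: two-column `position partner` TSV.
- **Reference alignments**: two-row aligned FASTA, optional core mask.

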