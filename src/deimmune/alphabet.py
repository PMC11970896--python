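"""Amino-acid alphabet constants shared across the package.

The 20 canonical residues are kept in the fixed row order used by every
position weight matrix in this package; ``X`` denotes an unknown residue and
is an input-only symbol (it is never designed, and peptides containing it
cannot be classified).
"""

from __future__ import annotations

import numpy as np

#: Canonical amino acids, fixed PWM row order.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

#: Unknown-residue symbol.
UNKNOWN: str = "X"

#: Model vocabulary: 20 amino acids plus the unknown symbol (input only).
VOCAB: str = AA_ORDER + UNKNOWN

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}
VOCAB_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(VOCAB)}

#: Peptide lengths presented by MHC class I that this package scans for.
PEPTIDE_LENGTHS: tuple[int, ...] = (8, 9, 10)

# Approximate background amino-acid composition of natural proteins
# (Swiss-Prot bulk frequencies), used when synthesizing "native" template
# sequences for toy backbones.
_NATURAL = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.63, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
}

#: Natural amino-acid frequencies in AA_ORDER, normalized to sum to 1.
NATURAL_FREQUENCIES: np.ndarray = np.array(
    [_NATURAL[aa] for aa in AA_ORDER], dtype=float
)
NATURAL_FREQUENCIES /= NATURAL_FREQUENCIES.sum()


class _Unclear:
    """Sentinel for peptides whose presentation cannot be assessed.

    Returned by predictors for peptides containing ``X``.  It is falsy so
    that naive boolean use never counts an unclear call as presented, but
    callers should compare with ``is UNCLEAR`` (or ``is True``) explicitly.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return "UNCLEAR"


#: Singleton "unclear" presentation call.
UNCLEAR = _Unclear()


def validate_peptide(peptide: str, lengths: tuple[int, ...] = PEPTIDE_LENGTHS) -> str:
    """Validate a peptide string and return it unchanged.

    Raises ``ValueError`` if the length is not in *lengths* or the sequence
    contains a character outside the 20 canonical residues plus ``X``.
    """
    if len(peptide) not in lengths:
        raise ValueError(
            f"peptide length {len(peptide)} not in supported lengths {lengths}: "
            f"{peptide!r}"
        )
    bad = set(peptide) - set(VOCAB)
    if bad:
        raise ValueError(f"invalid residue letters {sorted(bad)} in {peptide!r}")
    return peptide


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an amino-acid string to integer token indices over :data:`VOCAB`."""
    try:
        return np.array([VOCAB_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid residue letter {exc.args[0]!r}") from exc


def decode_tokens(tokens: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    return "".join(VOCAB[t] for t in np.asarray(tokens, dtype=int))
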