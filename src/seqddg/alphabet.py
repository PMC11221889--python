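"""Canonical amino-acid alphabet shared by every module.

The 20 canonical residues are kept in a single fixed alphabetical order,
``ACDEFGHIKLMNPQRSTVWY``; both the one-hot block and the PSSM block of the
feature matrix use this ordering, and PSI-BLAST profiles are re-ordered to it
at parse time.  ``X`` marks an unknown residue: it is legal in sequences
(encoded as an all-zero row) but never as a mutation target.
"""

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
UNKNOWN = "X"

#: PSI-BLAST's native column ordering in ASCII PSSM output.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def is_canonical(residue: str) -> bool:
    """True for one of the 20 canonical one-letter residue codes."""
    return residue in ALPHABET_INDEX


def validate_sequence(seq: str, *, allow_unknown: bool = True) -> None:
    """Raise ``ValueError`` naming the first illegal character in ``seq``."""
    if not seq:
        raise ValueError("empty sequence")
    legal = set(ALPHABET) | ({UNKNOWN} if allow_unknown else set())
    for pos, ch in enumerate(seq, start=1):
        if ch not in legal:
            raise ValueError(
                f"illegal residue {ch!r} at position {pos} "
                f"(expected one of {ALPHABET}{UNKNOWN if allow_unknown else ''})"
            )
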