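"""Sequence featurization: one-hot ∥ PSSM matrices of shape (n, 40).

Each protein sequence of length ``n`` is encoded as the horizontal
concatenation of a one-hot matrix (n, 20) and a position-specific scoring
matrix (n, 20), both over the fixed alphabet ``ACDEFGHIKLMNPQRSTVWY``.
PSSMs come from PSI-BLAST ASCII output (parsed, columns re-ordered to the
model alphabet) or, when no profile is available — synthetic data in
particular — from a deterministic per-residue fallback built from BLOSUM62
substitution scores.  PSSM values are used as raw log-odds; optional
per-matrix z-scaling is available for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import ALPHABET, ALPHABET_INDEX, PSIBLAST_ORDER, UNKNOWN, validate_sequence


@dataclass
class FeatureMatrix:
    """(n, 40) per-residue features: columns 0–19 one-hot, 20–39 PSSM."""

    values: np.ndarray
    seq: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 40:
            raise ValueError(f"feature matrix must be (n, 40), got {self.values.shape}")
        if self.values.shape[0] != len(self.seq):
            raise ValueError("feature row count does not match sequence length")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def one_hot(self) -> np.ndarray:
        return self.values[:, :20]

    @property
    def pssm(self) -> np.ndarray:
        return self.values[:, 20:]


def one_hot_encode(seq: str) -> np.ndarray:
    """Indicator encoding (n, 20); an ``X`` row is all zeros."""
    validate_sequence(seq)
    out = np.zeros((len(seq), 20), dtype=np.float64)
    for i, aa in enumerate(seq):
        if aa != UNKNOWN:
            out[i, ALPHABET_INDEX[aa]] = 1.0
    return out


# -- PSI-BLAST ASCII PSSM -----------------------------------------------------


def parse_pssm(text: str, expected_seq: str | None = None) -> np.ndarray:
    """Parse the log-odds block of a PSI-BLAST ``-out_ascii_pssm`` file.

    Returns an (n, 20) float matrix with columns re-ordered from PSI-BLAST's
    native ``ARNDCQEGHILKMFPSTWYV`` to the model alphabet.  When
    ``expected_seq`` is given, the residue column must match it.
    """
    lines = text.splitlines()
    order = None
    rows: list[np.ndarray] = []
    residues: list[str] = []
    for line in lines:
        fields = line.split()
        if order is None:
            # Header: 20 or 40 single-letter columns (log-odds + frequencies).
            if len(fields) in (20, 40) and all(len(f) == 1 and f.isalpha() for f in fields):
                order = "".join(fields[:20])
            continue
        if len(fields) >= 22 and fields[0].isdigit() and len(fields[1]) == 1:
            try:
                values = [float(v) for v in fields[2:22]]
            except ValueError as exc:
                raise ValueError(f"non-numeric PSSM cell in line {line!r}") from exc
            rows.append(np.array(values))
            residues.append(fields[1].upper())
    if order is None or not rows:
        raise ValueError("truncated or malformed PSSM: no header/data rows found")
    matrix = np.vstack(rows)
    # Re-order columns to the model alphabet.
    col = [order.index(aa) for aa in ALPHABET]
    matrix = matrix[:, col]
    if expected_seq is not None:
        found = "".join(residues)
        if found != expected_seq.upper():
            raise ValueError(
                f"PSSM residue column {found!r} does not match expected sequence "
                f"{expected_seq.upper()!r}"
            )
    return matrix


def read_pssm(path: str | Path, expected_seq: str | None = None) -> np.ndarray:
    return parse_pssm(Path(path).read_text(), expected_seq=expected_seq)


def format_pssm(seq: str, matrix: np.ndarray) -> str:
    """Render an (n, 20) matrix in PSI-BLAST ASCII layout (native column
    order); inverse of :func:`parse_pssm` on the numeric block.  Used to
    persist profiles for synthetic complexes."""
    matrix = np.asarray(matrix)
    if matrix.shape != (len(seq), 20):
        raise ValueError(f"matrix shape {matrix.shape} does not match sequence length {len(seq)}")
    inv = [ALPHABET.index(aa) for aa in PSIBLAST_ORDER]
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed percentages rounded down",
        "            " + "  ".join(PSIBLAST_ORDER) + "   " + "  ".join(PSIBLAST_ORDER),
    ]
    for i, aa in enumerate(seq):
        vals = "".join(f"{matrix[i, j]:6.0f}" if float(matrix[i, j]).is_integer() else f"{matrix[i, j]:6.2f}" for j in inv)
        pct = "".join("     0" for _ in range(20))
        lines.append(f"{i + 1:5d} {aa} {vals}{pct}  0.00 0.00")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1337     0.3157"]
    return "\n".join(lines) + "\n"


# -- BLOSUM62 fallback profile ------------------------------------------------

_BLOSUM62 = None


def _blosum_rows() -> np.ndarray:
    """(21, 20) table: for each alphabet residue (+X), its BLOSUM62 scores
    against the 20 alphabet residues; the X row is all zeros."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        table = substitution_matrices.load("BLOSUM62")
        rows = np.zeros((21, 20), dtype=np.float64)
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                rows[i, j] = table[a, b]
        _BLOSUM62 = rows
    return _BLOSUM62


def pseudo_pssm(seq: str) -> np.ndarray:
    """Deterministic (n, 20) profile: row r is residue r's BLOSUM62 log-odds
    row over the model alphabet ('X' rows are zero).

    A single-sequence stand-in for an alignment-derived profile: it carries
    residue-identity and substitution-preference information but no true
    positional conservation signal.
    """
    validate_sequence(seq)
    rows = _blosum_rows()  # row 20 (for 'X') is all zeros
    idx = np.array([20 if aa == UNKNOWN else ALPHABET_INDEX[aa] for aa in seq], dtype=int)
    return rows[idx]


def featurize(seq: str, pssm: np.ndarray | None = None, *, z_scale: bool = False) -> FeatureMatrix:
    """Concatenate one-hot and PSSM blocks into the (n, 40) model input.

    Falls back to :func:`pseudo_pssm` when no profile is supplied.  With
    ``z_scale`` the PSSM block is standardized per matrix (mean 0, sd 1).
    """
    oh = one_hot_encode(seq)
    if pssm is None:
        pssm = pseudo_pssm(seq)
    pssm = np.asarray(pssm, dtype=np.float64)
    if pssm.shape != (len(seq), 20):
        raise ValueError(
            f"PSSM shape {pssm.shape} does not match sequence of length {len(seq)}"
        )
    if z_scale:
        sd = pssm.std()
        pssm = (pssm - pssm.mean()) / sd if sd > 0 else pssm - pssm.mean()
    return FeatureMatrix(values=np.hstack([oh, pssm]), seq=seq)
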