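"""Wild-vs-mutant attention-difference maps for residue-level heatmaps.

The antigen→antibody mutual-attention map of a complex is a
(len_antigen, len_antibody) interaction map: entry (i, j) scores how much
antigen residue i attends to antibody residue j.  To visualize what a
mutation changed, both the wild-type and mutant maps are min-max normalized
over the whole matrix, subtracted (mutant − wild), and the difference is
min-max normalized again so every value lands in [0, 1].  A constant matrix
normalizes to all zeros rather than raising, so a heatmap renders for any
input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import MutationRecord
from .network import AttentionMaps


def minmax_norm(w: np.ndarray) -> np.ndarray:
    """(x − min)/(max − min) over the whole matrix; a constant matrix maps
    to all zeros (declared policy for the degenerate case)."""
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty matrix")
    if not np.isfinite(w).all():
        raise ValueError("non-finite entries")
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.zeros_like(w)
    return (w - lo) / (hi - lo)


@dataclass
class DeltaMap:
    """Normalized wild→mutant attention change; values in [0, 1]."""

    values: np.ndarray  # (len_ag, len_ab)
    row_labels: list[str]  # antigen residues, e.g. "K7"
    col_labels: list[str]  # antibody residues, e.g. "Y32"
    source: tuple[str, str] = ("", "")  # (complex_id, mutation string)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match matrix shape")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("delta map values must lie in [0, 1]")


def _residue_labels(seq: str) -> list[str]:
    return [f"{aa}{i}" for i, aa in enumerate(seq, start=1)]


def attention_delta(
    w_wt: np.ndarray,
    w_mt: np.ndarray,
    *,
    row_seq: str | None = None,
    col_seq: str | None = None,
    source: tuple[str, str] = ("", ""),
) -> DeltaMap:
    """Normalize, difference (mutant − wild) and renormalize two attention
    maps of equal shape into a :class:`DeltaMap`."""
    w_wt = np.asarray(w_wt, dtype=float)
    w_mt = np.asarray(w_mt, dtype=float)
    if w_wt.shape != w_mt.shape:
        raise ValueError(f"shape mismatch: {w_wt.shape} vs {w_mt.shape}")
    distance = minmax_norm(w_mt) - minmax_norm(w_wt)
    values = minmax_norm(distance)
    rows = _residue_labels(row_seq) if row_seq else [str(i + 1) for i in range(w_wt.shape[0])]
    cols = _residue_labels(col_seq) if col_seq else [str(j + 1) for j in range(w_wt.shape[1])]
    return DeltaMap(values=values, row_labels=rows, col_labels=cols, source=source)


def delta_map_for_record(record: MutationRecord, maps: AttentionMaps) -> DeltaMap:
    """Convenience wrapper labelling axes with the record's sequences."""
    return attention_delta(
        maps.w_ag_ab_wt,
        maps.w_ag_ab_mt,
        row_seq=record.antigen_seq,
        col_seq=record.antibody_seq,
        source=(record.complex_id, record.mutation_string),
    )


def mutated_column_enrichment(record: MutationRecord, delta: DeltaMap) -> float:
    """Diagnostic: mean delta-map value over the mutated antibody columns
    divided by the global matrix mean (>1 means the map highlights the
    mutated sites).  Returns NaN for an all-zero map."""
    cols = [
        record.concatenated_position(m)[1] - 1
        for m in record.mutations
        if record.concatenated_position(m)[0] == "antibody"
    ]
    global_mean = delta.values.mean()
    if not cols or global_mean == 0:
        return float("nan")
    return float(delta.values[:, cols].mean() / global_mean)


def export_heatmap(delta: DeltaMap, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.tsv`` (labelled values) and ``<path>.png``.

    Per the interaction-map convention, the PNG puts the antigen sequence on
    the x-axis and the antibody sequence on the y-axis (the stored matrix is
    antigen × antibody, so it is transposed for display).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tsv = path.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        fh.write("antigen\\antibody\t" + "\t".join(delta.col_labels) + "\n")
        for label, row in zip(delta.row_labels, delta.values):
            fh.write(label + "\t" + "\t".join(f"{v:.9g}" for v in row) + "\n")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    png = path.with_suffix(".png")
    fig, ax = plt.subplots(figsize=(max(4, len(delta.row_labels) / 8), max(3, len(delta.col_labels) / 8)))
    im = ax.imshow(delta.values.T, aspect="auto", cmap="viridis", vmin=0, vmax=1, origin="upper")
    ax.set_xlabel("antigen sequence")
    ax.set_ylabel("antibody sequence")
    title = ":".join(s for s in delta.source if s)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalized attention change")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return tsv, png


def read_heatmap_tsv(path: str | Path) -> DeltaMap:
    """Re-read an exported TSV (round-trip partner of :func:`export_heatmap`)."""
    lines = Path(path).read_text().strip("\n").split("\n")
    cols = lines[0].split("\t")[1:]
    rows, values = [], []
    for line in lines[1:]:
        fields = line.split("\t")
        rows.append(fields[0])
        values.append([float(v) for v in fields[1:]])
    return DeltaMap(values=np.array(values), row_labels=rows, col_labels=cols)
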