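"""Mutation tables, FASTA sequences and wild/mutant complex construction.

A *mutation record* pairs one antigen-antibody complex (as raw chain
sequences) with a set of point mutations and the experimentally measured
binding free-energy change ΔΔG = ΔG_mutant − ΔG_wild in kcal/mol.  Tables in
the AB-Bind / SKEMPI 2.0 family differ only in column naming and mutation
syntax, so loading is driven by small dialect configurations; every loaded
table is normalized to one canonical in-memory form (and one canonical CSV on
disk).

Positions in mutation strings are 1-based indices into the named chain's
sequence.  Tables numbered against author/PDB coordinates must declare a
per-chain offset column; without it, sequential numbering is assumed and a
wild-type residue mismatch raises rather than silently mis-indexing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .alphabet import ALPHABET, UNKNOWN, is_canonical, validate_sequence

log = logging.getLogger(__name__)

Chain = tuple[str, str]  # (chain_id, sequence)


class ParseError(ValueError):
    """Malformed input text (mutation token, table cell, FASTA record)."""


@dataclass(frozen=True)
class Mutation:
    """A single residue substitution on one chain, 1-based position."""

    chain_id: str
    wt_residue: str
    position: int
    mt_residue: str

    def __post_init__(self) -> None:
        if len(self.chain_id) != 1:
            raise ParseError(f"chain id must be one character, got {self.chain_id!r}")
        for res, role in ((self.wt_residue, "wild-type"), (self.mt_residue, "mutant")):
            if not is_canonical(res):
                raise ParseError(f"invalid {role} residue {res!r}")
        if self.position < 1:
            raise ParseError(f"position must be >= 1, got {self.position}")
        if self.wt_residue == self.mt_residue:
            raise ValueError(
                f"mutation {self} is a no-op: wild-type and mutant residue are equal"
            )

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.wt_residue}{self.position}{self.mt_residue}"

    def reversed(self) -> "Mutation":
        """The back-mutation (wt and mt residues swapped)."""
        return replace(self, wt_residue=self.mt_residue, mt_residue=self.wt_residue)


_TOKEN_COLON = re.compile(r"^(?P<chain>.):(?P<wt>[A-Za-z])(?P<pos>\d+)(?P<mt>[A-Za-z])$")
# SKEMPI-style token: wild-type residue, chain, position, mutant residue.
_TOKEN_SKEMPI = re.compile(r"^(?P<wt>[A-Za-z])(?P<chain>.)(?P<pos>\d+)(?P<mt>[A-Za-z])$")


def parse_mutation_string(s: str, *, style: str = "colon") -> list[Mutation]:
    """Parse a comma-separated mutation list such as ``"A:Y32W,A:S56M"``.

    ``style="colon"`` expects ``CHAIN:WT POS MT`` tokens (``A:Y32W``);
    ``style="skempi"`` expects ``WT CHAIN POS MT`` tokens (``YA32W``).
    Order is preserved; whitespace around commas is tolerated.
    """
    pattern = {"colon": _TOKEN_COLON, "skempi": _TOKEN_SKEMPI}.get(style)
    if pattern is None:
        raise ValueError(f"unknown mutation style {style!r}")
    tokens = [t.strip() for t in s.split(",")]
    if not any(tokens):
        raise ParseError(f"empty mutation string {s!r}")
    mutations = []
    for token in tokens:
        m = pattern.match(token)
        if m is None:
            raise ParseError(f"malformed mutation token {token!r} in {s!r}")
        mutations.append(
            Mutation(
                chain_id=m["chain"],
                wt_residue=m["wt"].upper(),
                position=int(m["pos"]),
                mt_residue=m["mt"].upper(),
            )
        )
    return mutations


def apply_mutations(chains: Sequence[Chain], mutations: Iterable[Mutation]) -> list[Chain]:
    """Return new chains with each mutation applied; inputs are untouched.

    Raises if a mutation names an absent chain, falls outside the chain, or
    disagrees with the wild-type residue found at its position.
    """
    out = {cid: list(seq) for cid, seq in chains}
    order = [cid for cid, _ in chains]
    for mut in mutations:
        if mut.chain_id not in out:
            raise ValueError(f"mutation {mut} names unknown chain {mut.chain_id!r}")
        seq = out[mut.chain_id]
        if mut.position > len(seq):
            raise ValueError(
                f"mutation {mut}: position {mut.position} outside chain "
                f"{mut.chain_id} of length {len(seq)}"
            )
        found = seq[mut.position - 1]
        if found != mut.wt_residue:
            raise ValueError(
                f"wild-type mismatch for {mut}: chain {mut.chain_id} position "
                f"{mut.position} holds {found!r}, expected {mut.wt_residue!r}"
            )
        seq[mut.position - 1] = mut.mt_residue
    return [(cid, "".join(out[cid])) for cid in order]


@dataclass
class MutationRecord:
    """One labeled wild/mutant complex pair."""

    complex_id: str
    antibody_chains: list[Chain]
    antigen_chains: list[Chain]
    mutations: list[Mutation]
    ddg: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.mutations:
            raise ValueError(f"record {self.complex_id}: no mutations")
        chain_ids = {cid for cid, _ in self.antibody_chains + self.antigen_chains}
        if len(chain_ids) != len(self.antibody_chains) + len(self.antigen_chains):
            raise ValueError(f"record {self.complex_id}: duplicate chain ids")
        for _, seq in self.antibody_chains + self.antigen_chains:
            validate_sequence(seq)
        # Applying the mutations checks chain membership, range and wt identity.
        apply_mutations(self.antibody_chains + self.antigen_chains, self.mutations)
        for mut in self.mutations:
            if mut.mt_residue == UNKNOWN:
                raise ValueError(f"record {self.complex_id}: mutation to 'X' forbidden")

    # -- concatenated per-role sequences (the model consumes one sequence per role) --

    @property
    def antibody_seq(self) -> str:
        return "".join(seq for _, seq in self.antibody_chains)

    @property
    def antigen_seq(self) -> str:
        return "".join(seq for _, seq in self.antigen_chains)

    def mutant_chains(self) -> tuple[list[Chain], list[Chain]]:
        """(antibody_chains, antigen_chains) with mutations applied."""
        ab_ids = {cid for cid, _ in self.antibody_chains}
        ab_muts = [m for m in self.mutations if m.chain_id in ab_ids]
        ag_muts = [m for m in self.mutations if m.chain_id not in ab_ids]
        return (
            apply_mutations(self.antibody_chains, ab_muts),
            apply_mutations(self.antigen_chains, ag_muts),
        )

    @property
    def mutant_antibody_seq(self) -> str:
        return "".join(seq for _, seq in self.mutant_chains()[0])

    @property
    def mutant_antigen_seq(self) -> str:
        return "".join(seq for _, seq in self.mutant_chains()[1])

    def concatenated_position(self, mut: Mutation) -> tuple[str, int]:
        """Map a mutation to ("antibody"|"antigen", 1-based index in the
        concatenated role sequence); chain boundaries are table order."""
        for role, chains in (("antibody", self.antibody_chains), ("antigen", self.antigen_chains)):
            offset = 0
            for cid, seq in chains:
                if cid == mut.chain_id:
                    return role, offset + mut.position
                offset += len(seq)
        raise ValueError(f"mutation {mut} not on a chain of {self.complex_id}")

    @property
    def mutation_string(self) -> str:
        return ",".join(str(m) for m in self.mutations)


@dataclass
class MutationDataset:
    records: list[MutationRecord]
    name: str = "dataset"
    provenance: str = "synthetic"  # abbind | skempi | synthetic

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("dataset has no records")
        if self.provenance not in ("abbind", "skempi", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def complex_ids(self) -> list[str]:
        return sorted({r.complex_id for r in self.records})

    def subset(self, indices: Sequence[int], name: str | None = None) -> "MutationDataset":
        return MutationDataset(
            records=[self.records[i] for i in indices],
            name=name or f"{self.name}[{len(indices)}]",
            provenance=self.provenance,
        )

    def summary(self) -> dict:
        single = sum(1 for r in self.records if len(r.mutations) == 1)
        return {
            "name": self.name,
            "n_records": len(self.records),
            "n_complexes": len(self.complex_ids),
            "n_single_point": single,
            "n_multi_point": len(self.records) - single,
        }


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs in file order.

    Duplicate ids, empty files and gap/stop characters are rejected.
    """
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for ch in seq:
            if ch not in ALPHABET and ch != UNKNOWN:
                raise ParseError(f"illegal character {ch!r} in FASTA record {rec.id!r}")
        if not seq:
            raise ParseError(f"empty sequence for FASTA id {rec.id!r}")
        entries.append((rec.id, seq))
    if not entries:
        raise ParseError(f"no FASTA records in {path}")
    return entries


# ---------------------------------------------------------------------------
# Table dialects


@dataclass(frozen=True)
class Dialect:
    """Column mapping + mutation syntax for one mutation-table flavour.

    ``seq_mode`` is ``inline`` (per-role sequence columns, chains ';'-joined
    in chain-id order) or ``fasta`` (a column holding a FASTA path relative
    to the table, record ids = chain ids).  ``offsets`` optionally names a
    column like ``"A:2;B:0"`` whose per-chain value is subtracted from table
    residue numbers to recover 1-based sequence positions.
    """

    name: str
    complex_id: str
    mutations: str
    ddg: str
    ab_chains: str
    ag_chains: str
    mutation_style: str = "colon"
    seq_mode: str = "inline"
    ab_seq: str | None = None
    ag_seq: str | None = None
    fasta: str | None = None
    offsets: str | None = None

    def required_columns(self) -> list[str]:
        cols = [self.complex_id, self.mutations, self.ddg, self.ab_chains, self.ag_chains]
        if self.seq_mode == "inline":
            cols += [self.ab_seq, self.ag_seq]
        else:
            cols.append(self.fasta)
        return [c for c in cols if c]


#: The canonical dialect is also what `write_dataset` emits.
CANONICAL = Dialect(
    name="synthetic",
    complex_id="complex_id",
    mutations="mutations",
    ddg="ddg",
    ab_chains="ab_chains",
    ag_chains="ag_chains",
    ab_seq="ab_seq",
    ag_seq="ag_seq",
)

DIALECTS: dict[str, Dialect] = {
    "synthetic": CANONICAL,
    "abbind": Dialect(
        name="abbind",
        complex_id="#PDB",
        mutations="Mutation",
        ddg="ddG(kcal/mol)",
        ab_chains="AbChains",
        ag_chains="AgChains",
        mutation_style="colon",
        seq_mode="fasta",
        fasta="Fasta",
        offsets="Offsets",
    ),
    "skempi": Dialect(
        name="skempi",
        complex_id="#Pdb",
        mutations="Mutation(s)",
        ddg="ddG",
        ab_chains="AbChains",
        ag_chains="AgChains",
        mutation_style="skempi",
        seq_mode="fasta",
        fasta="Fasta",
        offsets="Offsets",
    ),
}


def _split_chain_ids(cell: str) -> list[str]:
    ids = [c for c in str(cell).replace(";", "").replace("|", "") if not c.isspace()]
    if not ids:
        raise ParseError(f"no chain ids in cell {cell!r}")
    return ids


def _parse_offsets(cell) -> dict[str, int]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return {}
    out = {}
    for item in str(cell).split(";"):
        chain, _, off = item.partition(":")
        out[chain.strip()] = int(off)
    return out


def load_dataset(
    path: str | Path,
    dialect: str | Dialect = "synthetic",
    *,
    name: str | None = None,
) -> MutationDataset:
    """Load a mutation table into a validated :class:`MutationDataset`.

    Rows violating record invariants are rejected with row-numbered
    diagnostics collected into a single error.  A short summary (record,
    complex and single/multi-point counts) is logged.
    """
    path = Path(path)
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(
                f"unknown dialect {dialect!r}; built-ins: {sorted(DIALECTS)}"
            ) from None
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ParseError(f"empty table {path}")
    missing = [c for c in dialect.required_columns() if c not in df.columns]
    if missing:
        raise ParseError(f"table {path} lacks required columns {missing} for dialect {dialect.name}")

    fasta_cache: dict[str, dict[str, str]] = {}

    def chains_for(row, ids: list[str], seq_cell) -> list[Chain]:
        if dialect.seq_mode == "inline":
            seqs = str(seq_cell).split(";")
            if len(seqs) != len(ids):
                raise ParseError(f"{len(ids)} chain ids but {len(seqs)} sequences")
            return list(zip(ids, (s.strip().upper() for s in seqs)))
        fasta_path = str((path.parent / str(row[dialect.fasta])).resolve())
        if fasta_path not in fasta_cache:
            fasta_cache[fasta_path] = dict(read_fasta(fasta_path))
        by_id = fasta_cache[fasta_path]
        try:
            return [(cid, by_id[cid]) for cid in ids]
        except KeyError as exc:
            raise ParseError(f"chain {exc.args[0]!r} absent from {fasta_path}") from None

    records, errors = [], []
    for i, row in df.iterrows():
        try:
            ab_ids = _split_chain_ids(row[dialect.ab_chains])
            ag_ids = _split_chain_ids(row[dialect.ag_chains])
            muts = parse_mutation_string(str(row[dialect.mutations]), style=dialect.mutation_style)
            offsets = _parse_offsets(row[dialect.offsets]) if dialect.offsets in df.columns else {}
            if offsets:
                muts = [replace(m, position=m.position - offsets.get(m.chain_id, 0)) for m in muts]
            records.append(
                MutationRecord(
                    complex_id=str(row[dialect.complex_id]),
                    antibody_chains=chains_for(row, ab_ids, row.get(dialect.ab_seq)),
                    antigen_chains=chains_for(row, ag_ids, row.get(dialect.ag_seq)),
                    mutations=muts,
                    ddg=float(row[dialect.ddg]),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header line + 1-based
    if errors:
        raise ParseError(
            f"{len(errors)} invalid row(s) in {path}:\n  " + "\n  ".join(errors[:20])
        )
    dataset = MutationDataset(
        records=records, name=name or path.stem, provenance=dialect.name if dialect.name in ("abbind", "skempi") else "synthetic"
    )
    log.info("loaded %s: %s", path, dataset.summary())
    return dataset


def write_dataset(dataset: MutationDataset, path: str | Path) -> None:
    """Write the canonical CSV form (the ``synthetic`` dialect)."""
    rows = [
        {
            "complex_id": r.complex_id,
            "ab_chains": ";".join(cid for cid, _ in r.antibody_chains),
            "ag_chains": ";".join(cid for cid, _ in r.antigen_chains),
            "ab_seq": ";".join(seq for _, seq in r.antibody_chains),
            "ag_seq": ";".join(seq for _, seq in r.antigen_chains),
            "mutations": r.mutation_string,
            "ddg": repr(r.ddg),
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
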