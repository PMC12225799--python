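"""Readers and writers for the external formats the pipeline touches.

Formats handled here:

* a PDB-format subset (``ATOM`` records, Cα atoms only) for toy structures;
* aligned FASTA for multiple sequence alignments;
* the Foldseek tabular dialect with the exact column order
  ``target, qlen, alnlen, rmsd, taxname, taxlineage``;
* the DALI summary-table dialect, where field 3 is the rmsd and field 4
  the aligned length, with ``#``/``Job:``/``Query:`` header lines skipped.

Parsers are strict: malformed rows are rejected with a message naming the
offending line or row rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqUtils import seq1, seq3

from .errors import (
    DuplicateLabelError,
    EmptyStructureError,
    RaggedAlignmentError,
    StructureParseError,
    TableDialectError,
    TableParseError,
)

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Gap symbol used in every alignment this package reads or writes.
GAP = "-"

#: Kingdom vocabulary used throughout (query taxa plus "unknown" fallback).
KINGDOMS = ("bacteria", "fungi", "metazoa", "plantae", "protozoa")

# Lineage rank names mapped onto the five-kingdom vocabulary.  Protozoa is
# not a monophyletic rank, so the common protist phyla are matched instead.
_KINGDOM_RANKS = (
    ("bacteria", ("bacteria",)),
    ("fungi", ("fungi",)),
    ("metazoa", ("metazoa",)),
    ("plantae", ("viridiplantae", "plantae", "plants", "streptophyta")),
    (
        "protozoa",
        ("protozoa", "apicomplexa", "euglenozoa", "amoebozoa", "ciliophora",
         "alveolata", "parabasalia"),
    ),
)


def kingdom_from_lineage(lineage: Sequence[str]) -> str:
    """Map an ordered taxonomic lineage onto the five-kingdom vocabulary.

    Ranks are scanned outermost-first; the first rank matching the
    vocabulary decides the kingdom.  Unmatched lineages map to "unknown"
    so the function is total.
    """
    for rank in lineage:
        token = rank.strip().lower()
        for kingdom, names in _KINGDOM_RANKS:
            if token in names:
                return kingdom
    return "unknown"


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    """One residue of a Cα trace: source numbering, identity, coordinates."""

    number: int
    aa: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class StructureRecord:
    """An ordered Cα trace for one chain; the unit of superposition."""

    id: str
    residues: tuple[Residue, ...]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """Cα coordinates as an (n, 3) float array in Å."""
        return np.array([r.xyz for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


def read_structure(path: str | Path, chain: str | None = None) -> StructureRecord:
    """Read the Cα trace of one chain from a PDB-format file.

    Only ``ATOM`` records are considered (``HETATM`` skipped); alternate
    locations other than blank or ``A`` are skipped; residue numbers are
    taken verbatim from the record.  With ``chain=None`` the first chain
    encountered is used.
    """
    path = Path(path)
    residues: list[Residue] = []
    picked_chain: str | None = chain
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith("ATOM"):
                continue
            atom_name = line[12:16].strip()
            if atom_name != "CA":
                continue
            altloc = line[16:17].strip()
            if altloc not in ("", "A"):
                continue
            chain_id = line[21:22]
            if picked_chain is None:
                picked_chain = chain_id
            if chain_id != picked_chain:
                continue
            try:
                resnum = int(line[22:26])
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise StructureParseError(
                    f"{path.name}, line {lineno}: malformed ATOM record ({exc})"
                ) from None
            if not all(math.isfinite(v) for v in xyz):
                raise StructureParseError(
                    f"{path.name}, line {lineno}: non-finite coordinate"
                )
            aa = seq1(line[17:20].strip().capitalize())
            residues.append(Residue(resnum, aa if aa != "" else "X", xyz))
    if not residues:
        raise EmptyStructureError(f"{path.name}: no Cα ATOM records found")
    return StructureRecord(id=path.stem, residues=tuple(residues))


def write_structure(record: StructureRecord, path: str | Path, chain: str = "A") -> None:
    """Write a Cα-only trace as PDB ATOM records (coordinates to 0.001 Å)."""
    with open(path, "w") as handle:
        for serial, res in enumerate(record.residues, start=1):
            resname = seq3(res.aa).upper()
            x, y, z = res.xyz
            handle.write(
                f"ATOM  {serial:5d}  CA  {resname:>3s} {chain}{res.number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C\n"
            )
        handle.write("END\n")


# ---------------------------------------------------------------------------
# Search-result tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchHit:
    """One row of a structure-search result table; the unit of filtering."""

    query_id: str
    target_id: str
    query_length: int
    aligned_length: int
    rmsd: float
    identity: float | None = None
    taxon_name: str | None = None
    tax_lineage: tuple[str, ...] = ()
    kingdom: str = "unknown"

    @property
    def coverage(self) -> float:
        """Aligned length over query length (> 1 possible, flagged)."""
        return self.aligned_length / self.query_length

    @property
    def coverage_flagged(self) -> bool:
        return self.query_length > 0 and self.coverage > 1.0


def parse_foldseek_table(path: str | Path, query_id: str = "query") -> list[SearchHit]:
    """Parse a Foldseek tabular file.

    Expects exactly six tab-separated fields per row, in the order
    ``target, qlen, alnlen, rmsd, taxname, taxlineage``.  A row with a
    different field count raises :class:`TableDialectError`; a row whose
    numeric fields fail to parse raises :class:`TableParseError` naming
    the row.
    """
    hits: list[SearchHit] = []
    with open(path) as handle:
        for row_idx, raw in enumerate(handle):
            line = raw.rstrip("\n")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise TableDialectError(
                    f"row {row_idx}: expected 6 tab-separated fields "
                    f"(target,qlen,alnlen,rmsd,taxname,taxlineage), got {len(fields)}"
                )
            target, qlen_s, alnlen_s, rmsd_s, taxname, lineage_s = fields
            try:
                qlen = int(qlen_s)
                alnlen = int(alnlen_s)
                rmsd = float(rmsd_s)
            except ValueError as exc:
                raise TableParseError(f"row {row_idx}: {exc}") from None
            lineage = tuple(t.strip() for t in lineage_s.split(";") if t.strip())
            hits.append(
                SearchHit(
                    query_id=query_id,
                    target_id=target,
                    query_length=qlen,
                    aligned_length=alnlen,
                    rmsd=rmsd,
                    taxon_name=taxname or None,
                    tax_lineage=lineage,
                    kingdom=kingdom_from_lineage(lineage),
                )
            )
    return hits


def write_foldseek_table(hits: Iterable[SearchHit], path: str | Path) -> None:
    """Write hits in the six-column Foldseek tabular dialect."""
    with open(path, "w") as handle:
        for h in hits:
            handle.write(
                f"{h.target_id}\t{h.query_length}\t{h.aligned_length}\t"
                f"{h.rmsd:.3f}\t{h.taxon_name or ''}\t{';'.join(h.tax_lineage)}\n"
            )


def parse_dali_table(
    path: str | Path, query_length: int, query_id: str = "query"
) -> list[SearchHit]:
    """Parse a whitespace-separated DALI summary block.

    Blank lines, comment lines and lines whose first token begins with
    ``Job:`` or ``Query:`` are skipped.  Field 3 maps to the rmsd and
    field 4 to the aligned length; the query length is supplied by the
    caller because the table does not carry it.  A file of only headers
    yields an empty list.
    """
    if query_length <= 0:
        raise TableParseError("query_length must be positive")
    hits: list[SearchHit] = []
    with open(path) as handle:
        for row_idx, raw in enumerate(handle):
            tokens = raw.split()
            if not tokens:
                continue
            first = tokens[0]
            if first.startswith("#") or first.startswith("Job:") or first.startswith("Query:"):
                continue
            if len(tokens) < 4:
                raise TableParseError(
                    f"row {row_idx}: expected at least 4 whitespace-separated fields"
                )
            try:
                rmsd = float(tokens[2])
                alnlen = int(float(tokens[3]))
            except ValueError as exc:
                raise TableParseError(f"row {row_idx}: {exc}") from None
            identity = None
            if len(tokens) >= 6:
                try:
                    identity = float(tokens[5]) / 100.0
                except ValueError:
                    identity = None
            hits.append(
                SearchHit(
                    query_id=query_id,
                    target_id=first,
                    query_length=query_length,
                    aligned_length=alnlen,
                    rmsd=rmsd,
                    identity=identity,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Msa:
    """Aligned sequences over the 20 amino acids plus the gap symbol."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise RaggedAlignmentError("taxa and rows differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateLabelError("alignment labels are not unique")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise RaggedAlignmentError(
                f"aligned rows have unequal lengths: {sorted(widths)}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def to_array(self) -> np.ndarray:
        """(n_taxa, width) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")


def read_fasta_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    Unequal record lengths raise :class:`RaggedAlignmentError`; duplicate
    labels raise :class:`DuplicateLabelError`.
    """
    taxa: list[str] = []
    rows: list[str] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise DuplicateLabelError(f"duplicate alignment label {record.id!r}")
        seen.add(record.id)
        taxa.append(record.id)
        rows.append(str(record.seq))
    return Msa(taxa=tuple(taxa), rows=tuple(rows))


def write_fasta_msa(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as handle:
        for taxon, row in zip(msa.taxa, msa.rows):
            handle.write(f">{taxon}\n{row}\n")
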