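"""Domain-architecture novelty classification for trefoil-plus proteins.

A protein carrying a trefoil domain next to an extra domain is binned by
how the extra domain relates to a catalog of structures with known
architectures:

* category 1 — the extra domain appears in no catalog structure: it is
  structurally uncharacterized;
* category 2 — some catalog structure contains the extra domain, but no
  such structure (even as its full-length protein) also carries the
  trefoil: the domain is known, the combination is new;
* category 3 — some catalog structure already pairs the extra domain
  with the trefoil: the combination exists and was merely missed by
  stricter upstream filters;
* "known" — single-domain trefoils, and proteins whose full signature is
  already in the catalog.

Smaller category numbers are more novel; a protein with several extra
domains takes the minimum category across them.  Domain identity is by
name equality on annotation tables: domain scanning happens upstream and
its output is consumed here as data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InvalidParameterError

#: Category values, ordered from most novel to already-known.
CATEGORIES = (1, 2, 3, "known")


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered named domain intervals (1-based inclusive) on one protein."""

    protein_id: str
    domains: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        for name, start, end in self.domains:
            if not name:
                raise InvalidParameterError(f"{self.protein_id}: empty domain name")
            if start > end:
                raise InvalidParameterError(
                    f"{self.protein_id}: domain {name} has start {start} > end {end}"
                )
        ordered = sorted(self.domains, key=lambda d: (d[1], d[2]))
        for (n1, _, e1), (n2, s2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise InvalidParameterError(
                    f"{self.protein_id}: domains {n1} and {n2} overlap"
                )

    @property
    def names(self) -> tuple[str, ...]:
        """Domain names in sequence order (positions discarded)."""
        return tuple(n for n, _, _ in sorted(self.domains, key=lambda d: d[1]))


def architecture_signature(arch: DomainArchitecture) -> tuple[str, ...]:
    """Equality key for "distinct domain architecture": ordered names."""
    return arch.names


@dataclass(frozen=True)
class CatalogEntry:
    """A known structure and the architecture of its full-length protein."""

    architecture: DomainArchitecture
    full_length_architecture: DomainArchitecture


@dataclass(frozen=True)
class ArchitectureCatalog:
    """Reference architectures keyed by structure id."""

    entries: dict[str, CatalogEntry]

    def signatures(self) -> set[tuple[str, ...]]:
        return {architecture_signature(e.architecture) for e in self.entries.values()}

    def entries_with_domain(self, name: str) -> list[CatalogEntry]:
        return [e for e in self.entries.values() if name in e.architecture.names]


def classify_category(
    arch: DomainArchitecture,
    trefoil_name: str,
    catalog: ArchitectureCatalog,
) -> int | str:
    """Novelty category of one trefoil-containing protein.

    Each extra domain is classified against the catalog; the protein
    takes the minimum (most novel) category.  Single-domain trefoils are
    "known".  Category never depends on coordinates, only on the name
    signature and the catalog.
    """
    cat, _ = classify_category_detailed(arch, trefoil_name, catalog)
    return cat


def classify_category_detailed(
    arch: DomainArchitecture,
    trefoil_name: str,
    catalog: ArchitectureCatalog,
) -> tuple[int | str, dict[str, int]]:
    """Like :func:`classify_category` but also reports per-domain categories."""
    names = arch.names
    if trefoil_name not in names:
        raise InvalidParameterError(
            f"{arch.protein_id}: trefoil domain {trefoil_name!r} absent"
        )
    extras = [n for n in names if n != trefoil_name]
    per_domain: dict[str, int] = {}
    if not extras:
        return "known", per_domain
    for extra in extras:
        with_extra = catalog.entries_with_domain(extra)
        if not with_extra:
            per_domain[extra] = 1
        elif any(
            trefoil_name in e.architecture.names
            or trefoil_name in e.full_length_architecture.names
            for e in with_extra
        ):
            per_domain[extra] = 3
        else:
            per_domain[extra] = 2
    return min(per_domain.values()), per_domain


def find_novel_architectures(
    archs: Sequence[DomainArchitecture],
    catalog: ArchitectureCatalog,
    trefoil_name: str = "trefoil",
) -> list[tuple[str, tuple[str, ...], int | str]]:
    """Trefoil proteins whose signature matches no catalog signature.

    Returns (protein_id, signature, category) triples, ordered by
    signature then id.  Proteins without the trefoil domain are ignored.
    """
    known = catalog.signatures()
    out: list[tuple[str, tuple[str, ...], int | str]] = []
    for arch in archs:
        if trefoil_name not in arch.names:
            continue
        sig = architecture_signature(arch)
        if sig in known:
            continue
        out.append((arch.protein_id, sig, classify_category(arch, trefoil_name, catalog)))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# Annotation-table I/O (TSV: protein_id, domain_name, start, end[, full_length])
# ---------------------------------------------------------------------------

def read_domain_table(path: str | Path) -> dict[str, DomainArchitecture]:
    """Read domain annotations; intervals are 1-based inclusive."""
    rows: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InvalidParameterError(
                    f"{path}, line {lineno}: expected protein_id, domain_name, start, end"
                )
            pid, name, start_s, end_s = fields[:4]
            rows.setdefault(pid, []).append((name, int(start_s), int(end_s)))
    return {
        pid: DomainArchitecture(protein_id=pid, domains=tuple(doms))
        for pid, doms in rows.items()
    }


def write_domain_table(
    archs: Iterable[DomainArchitecture], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for arch in archs:
            for name, start, end in arch.domains:
                handle.write(f"{arch.protein_id}\t{name}\t{start}\t{end}\n")


def read_catalog(path: str | Path) -> ArchitectureCatalog:
    """Catalog TSV: protein_id, domain_name, start, end, full_length(0/1).

    Rows flagged 0 describe the deposited structure's architecture; rows
    flagged 1 the full-length protein's.  A structure with no flagged-1
    rows uses its own architecture as the full-length one.
    """
    structural: dict[str, list[tuple[str, int, int]]] = {}
    full: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise InvalidParameterError(
                    f"{path}, line {lineno}: expected 5 columns "
                    "(protein_id, domain_name, start, end, full_length)"
                )
            pid, name, start_s, end_s, flag = fields
            target = full if flag.strip() == "1" else structural
            target.setdefault(pid, []).append((name, int(start_s), int(end_s)))
    entries: dict[str, CatalogEntry] = {}
    for pid, doms in structural.items():
        arch = DomainArchitecture(protein_id=pid, domains=tuple(doms))
        fdoms = full.get(pid)
        farch = (
            DomainArchitecture(protein_id=pid, domains=tuple(fdoms)) if fdoms else arch
        )
        entries[pid] = CatalogEntry(architecture=arch, full_length_architecture=farch)
    return ArchitectureCatalog(entries=entries)


def write_catalog(catalog: ArchitectureCatalog, path: str | Path) -> None:
    with open(path, "w") as handle:
        for pid, entry in catalog.entries.items():
            for name, start, end in entry.architecture.domains:
                handle.write(f"{pid}\t{name}\t{start}\t{end}\t0\n")
            if entry.full_length_architecture is not entry.architecture:
                for name, start, end in entry.full_length_architecture.domains:
                    handle.write(f"{pid}\t{name}\t{start}\t{end}\t1\n")
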