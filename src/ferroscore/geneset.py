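"""Gene-set ingest and signature hygiene.

Ferroptosis scoring starts from two curated signatures: *driver* genes that
promote ferroptosis and *suppressor* genes that prevent it (FerrDb
nomenclature).  Before scoring, the two lists must be made disjoint — a gene
annotated as both a driver and a suppressor carries no directional
information and is excluded from both — and may be restricted to a
protein-coding whitelist.  All exclusions are recorded so the provenance of
the final signature pair is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


class GmtParseError(ValueError):
    """Raised when a GMT file is empty or a line has fewer than 3 fields."""


def _normalize(gene: str) -> str:
    return gene.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers.

    Identifiers are case-normalized (upper-cased, whitespace-trimmed) so that
    mixed-case symbols from different GMT sources compare equal.
    """

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetPair:
    """Disjoint driver/suppressor signatures plus the exclusion record."""

    drivers: GeneSet
    suppressors: GeneSet
    excluded_overlap: frozenset[str] = field(default_factory=frozenset)
    excluded_noncoding: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.drivers.genes & self.suppressors.genes:
            raise ValueError("driver and suppressor sets must be disjoint")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, gene, gene, ...).

    Duplicate genes within a line are collapsed; empty gene tokens are
    dropped; the order of sets follows file order.

    Raises
    ------
    GmtParseError
        If the file is empty or any line has fewer than 3 tab-separated
        fields (the line number is named in the message).
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0].strip()
            genes = frozenset(
                _normalize(g) for g in fields[2:] if _normalize(g)
            )
            if not genes:
                raise GmtParseError(
                    f"{path}: line {lineno}: gene set {name!r} has no genes"
                )
            sets.append(GeneSet(name=name, genes=genes))
    if not sets:
        raise GmtParseError(f"{path}: no gene sets found (empty file)")
    return sets


def read_whitelist(path: str | Path) -> frozenset[str]:
    """Read a one-gene-per-line whitelist (e.g. protein-coding symbols)."""
    with Path(path).open() as fh:
        genes = frozenset(_normalize(line) for line in fh if _normalize(line))
    if not genes:
        raise ValueError(f"{path}: whitelist is empty")
    return genes


def build_pair(
    drivers: GeneSet,
    suppressors: GeneSet,
    whitelist: frozenset[str] | set[str] | None = None,
) -> GeneSetPair:
    """Apply signature hygiene and return the disjoint driver/suppressor pair.

    Genes present in both lists are removed from *both* (they are excluded,
    not reassigned) and recorded in ``excluded_overlap``.  When a whitelist
    is given, genes outside it are removed and recorded in
    ``excluded_noncoding``.

    Raises
    ------
    ValueError
        If either resulting set is empty (nothing left to score).
    """
    overlap = drivers.genes & suppressors.genes
    d = drivers.genes - overlap
    s = suppressors.genes - overlap
    noncoding: frozenset[str] = frozenset()
    if whitelist is not None:
        wl = frozenset(_normalize(g) for g in whitelist)
        noncoding = frozenset((d | s) - wl)
        d &= wl
        s &= wl
    if not d or not s:
        which = "driver" if not d else "suppressor"
        raise ValueError(
            f"{which} set is empty after hygiene filters "
            f"(overlap removed: {len(overlap)}, non-whitelist removed: "
            f"{len(noncoding)})"
        )
    return GeneSetPair(
        drivers=GeneSet(drivers.name, frozenset(d)),
        suppressors=GeneSet(suppressors.name, frozenset(s)),
        excluded_overlap=frozenset(overlap),
        excluded_noncoding=noncoding,
    )


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    """Write gene sets to GMT, gene identifiers sorted for determinism."""
    with Path(path).open("w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")
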