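"""Gene sets: drug targets, endophenotype modules, pathway catalogs.

A :class:`GeneSet` is a named collection of gene identifiers — a drug's
experimentally supported protein targets, one endophenotype module (a gene
set standing in for an intermediate disease mechanism such as
neuroinflammation or tauopathy), or one pathway.  A :class:`ModuleCatalog`
bundles the modules of one source file (GMT format, Broad dialect).

Gene identifiers are opaque case-sensitive strings compared by exact
equality after whitespace trimming; no symbol/accession reconciliation is
attempted here (an ID-mapping table can be applied when the interactome is
loaded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .interactome import InteractomeGraph

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "ModuleCatalog",
    "CoverageReport",
    "load_gmt",
    "write_gmt",
    "load_target_set",
    "restrict_to_graph",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated, non-empty set of gene identifiers."""

    name: str
    genes: frozenset[str]
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class ModuleCatalog:
    """An ordered catalog of uniquely named gene sets from one source."""

    modules: list[GeneSet]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            if m.name in seen:
                raise ValueError(f"duplicate module name {m.name!r} in catalog")
            seen.add(m.name)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.modules)

    def __getitem__(self, name: str) -> GeneSet:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.modules]

    @property
    def sizes(self) -> dict[str, int]:
        return {m.name: len(m) for m in self.modules}

    def gene_union(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m.genes
        return frozenset(out)


def load_gmt(path: str | Path) -> ModuleCatalog:
    """Parse a GMT file (tab-separated: name, description, genes...).

    The description field carries the module's category label (e.g. one of
    the endophenotype classifications).  Genes are deduplicated per module;
    a module left empty, a row with fewer than three fields, or a repeated
    module name is an error.
    """
    path = Path(path)
    modules: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need >=3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name = fields[0].strip()
            category = fields[1].strip() or None
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(
                    f"{path}: line {lineno}: module {name!r} has no genes"
                )
            modules.append(GeneSet(name=name, genes=genes, category=category))
    if not modules:
        raise ValueError(f"{path}: no modules found")
    catalog = ModuleCatalog(modules=modules, source=str(path))
    logger.info(
        "loaded %d modules (%d distinct genes) from %s",
        len(catalog),
        len(catalog.gene_union()),
        path,
    )
    return catalog


def write_gmt(catalog: ModuleCatalog, path: str | Path) -> None:
    """Write a catalog as GMT; genes sorted so load/write round-trips."""
    with open(path, "w") as fh:
        for m in catalog.modules:
            genes = "\t".join(sorted(m.genes))
            fh.write(f"{m.name}\t{m.category or ''}\t{genes}\n")


def load_target_set(path: str | Path, name: str = "targets") -> GeneSet:
    """Load a drug-target set: one gene per line, or the first TSV column.

    Blank lines and ``#`` comments are skipped; duplicates collapse.
    """
    path = Path(path)
    genes: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split("\t")[0].strip())
    genes.discard("")
    if not genes:
        raise ValueError(f"{path}: target set is empty after deduplication")
    logger.info("loaded target set %r: %d genes from %s", name, len(genes), path)
    return GeneSet(name=name, genes=frozenset(genes))


@dataclass(frozen=True)
class CoverageReport:
    """What survived mapping a gene set onto the interactome."""

    set_name: str
    n_input: int
    n_kept: int
    dropped: tuple[str, ...]

    @property
    def coverage(self) -> float:
        return self.n_kept / self.n_input if self.n_input else 0.0


def restrict_to_graph(
    s: GeneSet, g: InteractomeGraph
) -> tuple[GeneSet, CoverageReport]:
    """Intersect a gene set with the graph's node set.

    Returns the restricted set plus a report naming every dropped identifier.
    An empty intersection is an error — a set with no network representation
    cannot enter any distance computation.  Idempotent.
    """
    nodes = g.node_set
    kept = s.genes & nodes
    dropped = tuple(sorted(s.genes - nodes))
    if not kept:
        raise ValueError(
            f"gene set {s.name!r} has no members in graph {g.name!r}"
        )
    report = CoverageReport(
        set_name=s.name,
        n_input=len(s.genes),
        n_kept=len(kept),
        dropped=dropped,
    )
    if dropped:
        logger.info(
            "set %r: %d/%d genes in graph (coverage %.2f); dropped: %s",
            s.name,
            report.n_kept,
            report.n_input,
            report.coverage,
            ", ".join(dropped),
        )
    return GeneSet(name=s.name, genes=frozenset(kept), category=s.category), report
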