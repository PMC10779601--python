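"""Target-module bipartite membership network and pathway overlays.

The two-mode network links each gene to every endophenotype module that
contains it; "degree" counts memberships.  On the gene side a high degree
means one protein participates in many pathological processes; on the
module side it is simply module size.  The overlay maps a drug's targets
onto pathway gene sets by plain intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genesets import GeneSet, ModuleCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "build_bipartite",
    "top_by_degree",
    "pathway_overlay",
]


@dataclass
class BipartiteNetwork:
    """Gene <-> module membership pairs with marginal degree counts.

    Invariant: ``|pairs| == sum(module sizes) == sum of gene degrees ==
    sum of module degrees``.
    """

    pairs: frozenset[tuple[str, str]]  # (gene, module name)
    gene_degree: dict[str, int]
    module_degree: dict[str, int]
    module_category: dict[str, str | None]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_genes(self) -> int:
        return len(self.gene_degree)

    @property
    def n_modules(self) -> int:
        return len(self.module_degree)

    def pairs_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(
            {
                "gene": [g for g, _ in rows],
                "module": [m for _, m in rows],
                "category": [self.module_category.get(m) or "" for _, m in rows],
            }
        )

    def degree_frame(self, side: str) -> pd.DataFrame:
        if side == "gene":
            items = sorted(self.gene_degree.items(), key=lambda kv: (-kv[1], kv[0]))
            return pd.DataFrame(items, columns=["gene", "degree"])
        if side == "module":
            items = sorted(self.module_degree.items(), key=lambda kv: (-kv[1], kv[0]))
            return pd.DataFrame(items, columns=["module", "degree"])
        raise ValueError(f"side must be 'gene' or 'module', got {side!r}")

    def write_tsvs(self, out_dir: str | Path, prefix: str = "bipartite") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pairs": out_dir / f"{prefix}_pairs.tsv",
            "gene_degree": out_dir / f"{prefix}_gene_degree.tsv",
            "module_degree": out_dir / f"{prefix}_module_degree.tsv",
        }
        self.pairs_frame().to_csv(paths["pairs"], sep="\t", index=False)
        self.degree_frame("gene").to_csv(paths["gene_degree"], sep="\t", index=False)
        self.degree_frame("module").to_csv(paths["module_degree"], sep="\t", index=False)
        return paths


def build_bipartite(catalog: ModuleCatalog) -> BipartiteNetwork:
    """One pair per (gene, module) membership across the catalog."""
    if len(catalog) == 0:
        raise ValueError("module catalog is empty")
    pairs: set[tuple[str, str]] = set()
    gene_degree: dict[str, int] = {}
    module_degree: dict[str, int] = {}
    category: dict[str, str | None] = {}
    for m in catalog:
        category[m.name] = m.category
        module_degree[m.name] = len(m.genes)
        for gene in m.genes:
            pairs.add((gene, m.name))
            gene_degree[gene] = gene_degree.get(gene, 0) + 1
    net = BipartiteNetwork(
        pairs=frozenset(pairs),
        gene_degree=gene_degree,
        module_degree=module_degree,
        module_category=category,
    )
    logger.info(
        "bipartite network: %d pairs, %d genes, %d modules",
        net.n_pairs,
        net.n_genes,
        net.n_modules,
    )
    return net


def top_by_degree(
    b: BipartiteNetwork,
    side: str,
    k: int | None = None,
    min_degree: int | None = None,
) -> list[tuple[str, int]]:
    """Rank genes or modules by membership degree.

    Descending by degree, ties broken lexicographically; an optional
    ``min_degree`` filter is applied before truncating to the top ``k``.
    """
    if side == "gene":
        items = b.gene_degree.items()
    elif side == "module":
        items = b.module_degree.items()
    else:
        raise ValueError(f"side must be 'gene' or 'module', got {side!r}")
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    if min_degree is not None:
        ranked = [kv for kv in ranked if kv[1] >= min_degree]
    return ranked[:k] if k is not None else ranked


def pathway_overlay(targets: GeneSet, pathways: ModuleCatalog) -> pd.DataFrame:
    """Intersect the drug-target set with each pathway gene set.

    Returns one row per pathway (zero-hit rows retained): pathway name,
    category, pathway size, hit count, and the sorted hit genes.
    """
    if len(pathways) == 0:
        raise ValueError("pathway catalog is empty")
    rows = []
    for p in pathways:
        hits = sorted(targets.genes & p.genes)
        rows.append(
            {
                "pathway": p.name,
                "category": p.category or "",
                "pathway_size": len(p.genes),
                "n_hits": len(hits),
                "hit_genes": ",".join(hits),
            }
        )
    df = pd.DataFrame(
        rows, columns=["pathway", "category", "pathway_size", "n_hits", "hit_genes"]
    )
    return df.sort_values(
        ["n_hits", "pathway"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
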