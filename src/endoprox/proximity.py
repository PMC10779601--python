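"""Closest network distance, degree-preserving permutation null, screening.

The proximity between a drug-target set B and a disease module A on the
interactome G is the *closest* distance

    d_AB = ( sum_{a in A} min_{b in B} d(a,b)
           + sum_{b in B} min_{a in A} d(a,b) ) / (|A| + |B|)

with d(a,b) the unweighted shortest-path (hop) length.  Significance comes
from a degree-preserving permutation null: each replicate replaces every
member of a set with a node drawn uniformly from the same degree bin
(without replacement within the set), recomputes d, and the observed value
is standardised against the replicate distribution:

    z = (d_obs - mean_null) / sd_null,      sd with ddof=1

together with a one-sided empirical p-value toward small distances,
p = (r + 1) / (n + 1) where r counts null distances <= d_obs.  Large
negative z means the targets sit unexpectedly close to the module.

A module screen applies this per catalog module and flags modules passing
both a z threshold (default -1.8) and a p threshold (default 0.05).

Two null modes are provided: ``"both"`` resamples degree-matched stand-ins
for A and B each replicate (the default), ``"B-only"`` resamples only the
target set and keeps the module fixed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path
from scipy.stats import norm

from .genesets import GeneSet, ModuleCatalog, restrict_to_graph
from .interactome import (
    DegreeBins,
    InteractomeGraph,
    build_degree_bins,
    shortest_path_from_set,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "ProximityResult",
    "ScreenTable",
    "closest_distance",
    "sample_degree_matched",
    "proximity_z",
    "screen_modules",
    "SCREEN_COLUMNS",
]

#: default permutation depth for the null distribution
DEFAULT_N_PERMUTATIONS = 10_000
#: default screening thresholds (z upper bound, p upper bound)
DEFAULT_Z_THRESHOLD = -1.8
DEFAULT_P_THRESHOLD = 0.05

_PERM_BLOCK = 2048  # replicates per vectorised block; bounds peak memory


@dataclass
class DistanceMatrix:
    """All-pairs hop distances for one graph, indexed by node name.

    Memory is 8 bytes per node pair, so this is intended for graphs up to a
    few tens of thousands of nodes; the permutation loop amortises the one-
    time BFS cost over all modules and replicates.
    """

    nodes: tuple[str, ...]
    d: np.ndarray  # (n, n) float64, np.inf across components
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {node: i for i, node in enumerate(self.nodes)}

    @classmethod
    def from_graph(cls, g: InteractomeGraph) -> "DistanceMatrix":
        nodelist = sorted(g.graph.nodes)
        adj = nx_to_csr(g, nodelist)
        d = _csgraph_shortest_path(adj, method="D", directed=False, unweighted=True)
        return cls(nodes=tuple(nodelist), d=d)

    def indices_of(self, genes: Iterable[str]) -> np.ndarray:
        try:
            return np.array(sorted(self._index[x] for x in genes), dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise ValueError(f"gene {exc.args[0]!r} not in distance matrix") from exc


def nx_to_csr(g: InteractomeGraph, nodelist: Sequence[str]) -> sparse.csr_array:
    return nx.to_scipy_sparse_array(g.graph, nodelist=list(nodelist), format="csr")


def closest_distance(g: InteractomeGraph, A: GeneSet, B: GeneSet) -> float:
    """Evaluate the closest distance d_AB with two multi-source BFS passes.

    Both sets must already be restricted to the graph.  On a connected graph
    every term is finite; any member of one set unreachable from the whole
    other set raises.
    """
    for s in (A, B):
        missing = s.genes - g.node_set
        if missing:
            raise ValueError(
                f"set {s.name!r} has members outside the graph: "
                + ", ".join(sorted(missing))
            )
    dist_to_B = shortest_path_from_set(g, B.genes)
    dist_to_A = shortest_path_from_set(g, A.genes)
    try:
        total = sum(dist_to_B[a] for a in A.genes)
        total += sum(dist_to_A[b] for b in B.genes)
    except KeyError as exc:
        raise ValueError(
            f"node {exc.args[0]!r} has no path to the opposite set; restrict "
            "both sets to the largest connected component first"
        ) from exc
    return total / (len(A) + len(B))


def _closest_from_matrix(dm: DistanceMatrix, ia: np.ndarray, ib: np.ndarray) -> float:
    sub = dm.d[np.ix_(ia, ib)]
    val = (sub.min(axis=1).sum() + sub.min(axis=0).sum()) / (len(ia) + len(ib))
    if not np.isfinite(val):
        raise ValueError(
            "infinite distance between sets; restrict inputs to the largest "
            "connected component"
        )
    return float(val)


def sample_degree_matched(
    g: InteractomeGraph,
    bins: DegreeBins,
    template: GeneSet | Iterable[str],
    rng: np.random.Generator | int,
) -> frozenset[str]:
    """Draw one degree-matched random stand-in for ``template``.

    For each template node one node is drawn uniformly from that node's
    degree bin; draws are without replacement within the result, so the
    sample has exactly ``|template|`` distinct members with the template's
    degree-bin profile.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    members = template.genes if isinstance(template, GeneSet) else set(template)
    missing = set(members) - set(g.graph.nodes)
    if missing:
        raise ValueError(
            "template nodes not in graph: " + ", ".join(sorted(missing))
        )
    per_bin: dict[int, int] = {}
    for node in sorted(members):
        per_bin[bins.bin_index_of(node)] = per_bin.get(bins.bin_index_of(node), 0) + 1
    out: list[str] = []
    for bin_idx in sorted(per_bin):
        b = bins.bins[bin_idx]
        k = per_bin[bin_idx]
        if k > len(b):
            raise ValueError(
                f"degree bin [{b.degree_min},{b.degree_max}] holds {len(b)} "
                f"nodes but the template needs {k}; rebuild bins with a "
                "smaller min_bin_size"
            )
        out.extend(rng.choice(np.array(b.nodes, dtype=object), size=k, replace=False))
    return frozenset(out)


class _IndexedBins:
    """Degree bins re-expressed as node-index arrays of a DistanceMatrix."""

    def __init__(self, bins: DegreeBins, dm: DistanceMatrix) -> None:
        self.bin_nodes: list[np.ndarray] = [
            dm.indices_of(b.nodes) for b in bins.bins
        ]
        self.node_bin = np.empty(len(dm.nodes), dtype=np.intp)
        for bi, idx in enumerate(self.bin_nodes):
            self.node_bin[idx] = bi


def _sample_block(
    ibins: _IndexedBins,
    template_idx: np.ndarray,
    n_rows: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_rows`` degree-matched samples of a template, vectorised.

    Returns an (n_rows, len(template)) array of node indices; each row is an
    independent without-replacement draw per degree bin.
    """
    out = np.empty((n_rows, len(template_idx)), dtype=np.intp)
    owner = ibins.node_bin[template_idx]
    for bi in np.unique(owner):
        cols = np.flatnonzero(owner == bi)
        pool = ibins.bin_nodes[bi]
        k = len(cols)
        if k > len(pool):
            raise ValueError(
                f"degree bin {bi} holds {len(pool)} nodes but the template "
                f"needs {k}; rebuild bins with a smaller min_bin_size"
            )
        if k == len(pool):
            out[:, cols] = np.broadcast_to(pool, (n_rows, k))
            continue
        # k smallest of iid uniforms per row = uniform k-subset w/o replacement
        r = rng.random((n_rows, len(pool)))
        sel = np.argpartition(r, k - 1, axis=1)[:, :k]
        out[:, cols] = pool[sel]
    return out


def _null_distances(
    dm: DistanceMatrix,
    ibins: _IndexedBins,
    ia: np.ndarray,
    ib: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    mode: str,
) -> np.ndarray:
    """Closest distances of degree-matched resamples, one per replicate."""
    null = np.empty(n_permutations, dtype=np.float64)
    for start in range(0, n_permutations, _PERM_BLOCK):
        nb = min(_PERM_BLOCK, n_permutations - start)
        if mode == "both":
            a_rows = _sample_block(ibins, ia, nb, rng)
        else:
            a_rows = np.broadcast_to(ia, (nb, len(ia)))
        b_rows = _sample_block(ibins, ib, nb, rng)
        sub = dm.d[a_rows[:, :, None], b_rows[:, None, :]]  # (nb, |A|, |B|)
        null[start : start + nb] = (
            sub.min(axis=2).sum(axis=1) + sub.min(axis=1).sum(axis=1)
        ) / (len(ia) + len(ib))
    return null


@dataclass
class ProximityResult:
    """One module-vs-targets proximity measurement with its null summary."""

    module_name: str
    drug_name: str
    d_observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when the null is degenerate (sd == 0)
    p_empirical: float
    p_normal: float  # normal-theory lower-tail p from z; NaN if degenerate
    n_permutations: int
    seed: int
    n_A_used: int
    n_B_used: int
    mode: str = "both"
    degenerate: bool = False
    category: str | None = None
    null_distances: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "module": self.module_name,
            "category": self.category if self.category is not None else "",
            "n_A_used": self.n_A_used,
            "n_B_used": self.n_B_used,
            "d_observed": self.d_observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_empirical": self.p_empirical,
            "p_normal": self.p_normal,
        }


def _resolve_rng(
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> tuple[np.random.Generator, int]:
    if isinstance(seed, np.random.Generator):
        return seed, -1
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed), int(seed.entropy if isinstance(seed.entropy, int) else -1)
    return np.random.default_rng(int(seed)), int(seed)


def child_seed_sequence(master_seed: int, label: str) -> np.random.SeedSequence:
    """Derive a per-module seed from the master seed and the module name.

    Hash-based (not counter-based) derivation makes each module's null
    stream a function of (master seed, module name) only, so reordering the
    catalog cannot change any result.
    """
    h = int.from_bytes(
        hashlib.blake2b(label.encode(), digest_size=8).digest(), "big"
    )
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h])


def proximity_z(
    g: InteractomeGraph,
    A: GeneSet,
    B: GeneSet,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.SeedSequence = 0,
    bins: DegreeBins | None = None,
    mode: str = "both",
    dist: DistanceMatrix | None = None,
    min_bin_size: int = 100,
    drug_name: str = "drug",
    keep_null: bool = False,
) -> ProximityResult:
    """Observed closest distance plus its degree-preserving permutation null.

    Parameters mirror the screen: ``A`` is the module, ``B`` the target set,
    both already restricted to (a connected) ``g``.  ``mode="both"``
    resamples both sets each replicate; ``mode="B-only"`` keeps A fixed.
    With ``sd == 0`` across replicates the z-score is degenerate and
    reported as NaN (flagged), while the empirical p is still valid.
    """
    if mode not in ("both", "B-only"):
        raise ValueError(f"unknown null mode {mode!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if dist is None:
        dist = DistanceMatrix.from_graph(g)
    if bins is None:
        bins = build_degree_bins(g, min_bin_size=min_bin_size)
    rng, seed_int = _resolve_rng(seed)
    ia = dist.indices_of(A.genes)
    ib = dist.indices_of(B.genes)
    d_obs = _closest_from_matrix(dist, ia, ib)
    ibins = _IndexedBins(bins, dist)
    null = _null_distances(dist, ibins, ia, ib, n_permutations, rng, mode)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_permutations > 1 else 0.0
    degenerate = null_sd == 0.0
    z = float("nan") if degenerate else (d_obs - null_mean) / null_sd
    r = int((null <= d_obs).sum())
    p_emp = (r + 1) / (n_permutations + 1)
    p_norm = float("nan") if degenerate else float(norm.cdf(z))
    return ProximityResult(
        module_name=A.name,
        drug_name=drug_name,
        d_observed=d_obs,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_empirical=p_emp,
        p_normal=p_norm,
        n_permutations=n_permutations,
        seed=seed_int,
        n_A_used=len(A),
        n_B_used=len(B),
        mode=mode,
        degenerate=degenerate,
        category=A.category,
        null_distances=null if keep_null else None,
    )


SCREEN_COLUMNS = [
    "module",
    "category",
    "n_A_used",
    "n_B_used",
    "d_observed",
    "null_mean",
    "null_sd",
    "z",
    "p_empirical",
    "p_normal",
    "significant",
]


@dataclass
class ScreenTable:
    """Per-module proximity results with the significance flag applied.

    A module is flagged significant iff z < z_threshold AND
    p_empirical < p_threshold.  Rows sort by z ascending (most proximal
    first); modules with no network coverage appear last with NA metrics.
    """

    results: list[ProximityResult]
    skipped: list[tuple[str, str | None]]  # (module name, category): no coverage
    z_threshold: float = DEFAULT_Z_THRESHOLD
    p_threshold: float = DEFAULT_P_THRESHOLD

    def is_significant(self, r: ProximityResult) -> bool:
        return (
            not r.degenerate
            and r.z < self.z_threshold
            and r.p_empirical < self.p_threshold
        )

    @property
    def significant_modules(self) -> list[str]:
        return [r.module_name for r in self.results if self.is_significant(r)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            d = r.to_dict()
            d["significant"] = self.is_significant(r)
            rows.append(d)
        for name, category in self.skipped:
            rows.append(
                {
                    "module": name,
                    "category": category if category is not None else "",
                    "n_A_used": 0,
                    "n_B_used": 0,
                    "d_observed": np.nan,
                    "null_mean": np.nan,
                    "null_sd": np.nan,
                    "z": np.nan,
                    "p_empirical": np.nan,
                    "p_normal": np.nan,
                    "significant": False,
                }
            )
        df = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
        df = df.sort_values(
            ["z", "module"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(
            path, sep="\t", index=False, float_format="%.6g", na_rep="NA"
        )


def screen_modules(
    g: InteractomeGraph,
    targets: GeneSet,
    catalog: ModuleCatalog,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    min_bin_size: int = 100,
    mode: str = "both",
    drug_name: str = "drug",
    dist: DistanceMatrix | None = None,
    bins: DegreeBins | None = None,
) -> ScreenTable:
    """Proximity-screen every catalog module against the drug-target set.

    The target set and each module are restricted to the graph first; a
    module with zero coverage yields an NA row and a warning rather than a
    crash.  Each module's permutation stream derives from (seed, module
    name), so catalog order cannot change any number.
    """
    if len(catalog) == 0:
        raise ValueError("module catalog is empty")
    targets_used, _ = restrict_to_graph(targets, g)
    if dist is None:
        dist = DistanceMatrix.from_graph(g)
    if bins is None:
        bins = build_degree_bins(g, min_bin_size=min_bin_size)
    results: list[ProximityResult] = []
    skipped: list[tuple[str, str | None]] = []
    for module in catalog:
        try:
            module_used, _ = restrict_to_graph(module, g)
        except ValueError:
            logger.warning(
                "module %r has no genes in graph %r; emitting NA row",
                module.name,
                g.name,
            )
            skipped.append((module.name, module.category))
            continue
        res = proximity_z(
            g,
            module_used,
            targets_used,
            n_permutations=n_permutations,
            seed=child_seed_sequence(seed, module.name),
            bins=bins,
            mode=mode,
            dist=dist,
            drug_name=drug_name,
        )
        res.seed = int(seed)
        results.append(res)
    return ScreenTable(
        results=results,
        skipped=skipped,
        z_threshold=z_threshold,
        p_threshold=p_threshold,
    )
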