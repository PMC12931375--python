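"""Hypergeometric cluster-correspondence (MIA) and local over-representation.

Multimodal intersection analysis (MIA) scores the correspondence between a
spatial cluster and a single-cell reference cluster by the hypergeometric
tail probability of their marker-gene overlap in a shared gene universe:
with universe size N, marker-set sizes m and n and overlap k, the
enrichment score is −log10 P(X ≥ k) when k is at or above the expected
overlap m·n/N, and log10 P(X ≤ k) (a negative number) when it is below —
so positive scores mean enrichment and negative scores depletion.

The same tail statistic powers a local over-representation analysis over
user-supplied gene-set libraries (GMT format), with Benjamini–Hochberg
adjustment across sets, replacing calls to a web enrichment service.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetLibrary",
    "EnrichmentMatrix",
    "bh_adjust",
    "mia_enrichment",
    "enrich_gene_sets",
    "hypergeom_tail_score",
]

P_FLOOR = 1e-300  # floor before log10 to keep scores finite


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values.

    ``p_adj_(i) = min_{j ≥ i} ( m · p_(j) / j )`` capped at 1, returned in
    the input order; stable under permutations of the input.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class GeneSetLibrary:
    """Named gene sets over a gene universe.

    Sets are intersected with the universe on construction; genes that fall
    outside it are dropped with a warning.
    """

    sets: dict
    universe: set

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        cleaned = {}
        for name, genes in self.sets.items():
            genes = set(genes)
            outside = genes - self.universe
            if outside:
                warnings.warn(
                    f"gene set {name!r}: {len(outside)} gene(s) outside universe dropped",
                    stacklevel=2,
                )
            cleaned[name] = genes & self.universe
        self.sets = cleaned

    @classmethod
    def from_gmt(cls, path, universe) -> "GeneSetLibrary":
        """Read a GMT file (``name<TAB>description<TAB>gene...`` per line)."""
        sets = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets=sets, universe=set(universe))


@dataclass
class EnrichmentMatrix:
    """ST-cluster × reference-cluster signed MIA scores with overlap counts."""

    scores: pd.DataFrame
    overlaps: pd.DataFrame
    universe_size: int
    set_sizes_st: dict = field(default_factory=dict)
    set_sizes_ref: dict = field(default_factory=dict)

    def best_match(self, st_cluster) -> str:
        """Reference cluster with the maximal score for one ST cluster."""
        return self.scores.loc[st_cluster].idxmax()

    def to_csv(self, scores_path, overlaps_path=None) -> None:
        self.scores.to_csv(scores_path)
        if overlaps_path is not None:
            self.overlaps.to_csv(overlaps_path)


def hypergeom_tail_score(k: int, m: int, n: int, N: int) -> float:
    """Signed hypergeometric tail score for overlap ``k`` of sets of sizes
    ``m`` and ``n`` in a universe of ``N`` genes.

    Enrichment (k at or above expectation m·n/N): ``−log10 P(X ≥ k)``.
    Depletion (below expectation): ``log10 P(X ≤ k)``, a negative value.
    Probabilities are floored at 1e-300.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError("set sizes must lie within the universe")
    if k > min(m, n) or k < max(0, m + n - N):
        raise ValueError(f"impossible overlap k={k} for m={m}, n={n}, N={N}")
    expected = m * n / N if N else 0.0
    if k >= expected:
        p = stats.hypergeom.sf(k - 1, N, m, n)
        return float(-np.log10(max(p, P_FLOOR)))
    p = stats.hypergeom.cdf(k, N, m, n)
    return float(np.log10(max(p, P_FLOOR)))


def _filtered_top_markers(
    table: pd.DataFrame, p_adj_max: float, min_log2fc: float, top_n: int
) -> dict:
    """Per-cluster top-N marker lists after adjusted-p and log2fc filters,
    ranked by (log2fc desc, gene asc)."""
    out = {}
    for cl, sub in table.groupby("cluster_id", sort=True):
        sub = sub.loc[(sub["p_adj"] <= p_adj_max) & (sub["log2fc"] > min_log2fc)]
        sub = sub.sort_values(["log2fc", "gene"], ascending=[False, True])
        out[cl] = list(sub["gene"].head(top_n))
    return out


def mia_enrichment(
    st_markers: pd.DataFrame,
    sc_markers: pd.DataFrame,
    universe,
    top_n: int = 300,
    p_adj_max: float = 0.05,
    min_log2fc: float = 0.25,
) -> EnrichmentMatrix:
    """MIA correspondence matrix between spatial and reference clusters.

    Both marker tables are filtered to adjusted p ≤ ``p_adj_max`` and
    log2fc > ``min_log2fc``, then capped at the ``top_n`` strongest
    upregulated markers per cluster before overlap scoring; genes outside
    the shared ``universe`` are ignored.  Clusters with an empty marker set
    score zero against everything (with a warning).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    N = len(universe)
    st_sets = {
        cl: set(g) & universe
        for cl, g in _filtered_top_markers(st_markers, p_adj_max, min_log2fc, top_n).items()
    }
    sc_sets = {
        cl: set(g) & universe
        for cl, g in _filtered_top_markers(sc_markers, p_adj_max, min_log2fc, top_n).items()
    }
    for side, sets in (("ST", st_sets), ("reference", sc_sets)):
        empties = [cl for cl, s in sets.items() if not s]
        if empties:
            warnings.warn(
                f"{side} cluster(s) with empty marker set score 0: {empties}",
                stacklevel=2,
            )

    scores = pd.DataFrame(0.0, index=list(st_sets), columns=list(sc_sets))
    overlaps = pd.DataFrame(0, index=list(st_sets), columns=list(sc_sets))
    for st_cl, a in st_sets.items():
        for sc_cl, b in sc_sets.items():
            k = len(a & b)
            overlaps.loc[st_cl, sc_cl] = k
            if a and b:
                scores.loc[st_cl, sc_cl] = hypergeom_tail_score(k, len(a), len(b), N)
    return EnrichmentMatrix(
        scores=scores,
        overlaps=overlaps,
        universe_size=N,
        set_sizes_st={cl: len(s) for cl, s in st_sets.items()},
        set_sizes_ref={cl: len(s) for cl, s in sc_sets.items()},
    )


def enrich_gene_sets(query, library: GeneSetLibrary) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each
    library set, BH-adjusted across sets, sorted by ascending adjusted p.

    Returns columns ``set, set_size, overlap, p, p_adj``.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    outside = query - library.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside universe dropped", stacklevel=2
        )
        query &= library.universe
    if not query:
        raise ValueError("no query genes remain inside the universe")
    N = len(library.universe)
    n = len(query)
    rows = []
    for name, genes in library.sets.items():
        m = len(genes)
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, m, n)) if m else 1.0
        rows.append({"set": name, "set_size": m, "overlap": k, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["p_adj", "p", "set"]).reset_index(drop=True)
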