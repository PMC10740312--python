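"""Gene co-expression network construction and analysis.

Cleans expression tables, computes Pearson correlations across conditions,
binarizes them at a threshold selected by scale-free topology fit / mean
connectivity / cluster count, and provides the network utilities used in the
downstream experiments: summary statistics, random edge rewiring, STRING
protein-link import, topological-overlap similarity and hierarchical module
detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "CoexpressionNetwork",
    "clean_expression",
    "correlation_matrix",
    "binarize",
    "scale_free_fit",
    "scale_free_r2",
    "mean_connectivity",
    "count_components",
    "select_threshold",
    "network_stats",
    "build_network",
    "rewire_random",
    "import_string_ppi",
    "tom_similarity",
    "detect_modules",
]

DEFAULT_GRID = np.round(np.arange(0.50, 0.995, 0.01), 2)
MAD_FENCE = 5.0  # winsorization fence in MAD units around the gene median


# ---------------------------------------------------------------------------
# Expression container and cleaning
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A cleaned genes x conditions table of nonnegative expression values."""

    genes: list[str]
    conditions: list[str]
    values: np.ndarray
    cleaning_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError("values shape inconsistent with gene/condition lists")
        if len(self.conditions) < 2:
            raise ValueError("at least 2 conditions required")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def condition_values(self, condition: str) -> dict[str, float]:
        j = self.conditions.index(condition)
        return dict(zip(self.genes, self.values[:, j]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.conditions)

    @classmethod
    def from_tsv(cls, path: str, clean: bool = True) -> "ExpressionMatrix":
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return clean_expression(df) if clean else cls(
            genes=list(df.index), conditions=list(df.columns),
            values=df.to_numpy(float),
        )


def clean_expression(raw: pd.DataFrame) -> ExpressionMatrix:
    """Clean a raw genes x conditions table.

    Duplicate gene rows are averaged; genes with any missing value are
    dropped; per-gene outliers beyond median +/- 5 MAD are winsorized to the
    fence.  Every action is recorded in the cleaning log.
    """
    if raw.shape[1] < 2:
        raise ValueError("expression table needs at least 2 condition columns")
    log: list[str] = []

    dup = raw.index[raw.index.duplicated()].unique()
    if len(dup) > 0:
        raw = raw.groupby(level=0, sort=False).mean()
        log.append(f"averaged {len(dup)} duplicate gene id(s): {sorted(map(str, dup))}")

    has_na = raw.isna().any(axis=1)
    if has_na.any():
        removed = list(map(str, raw.index[has_na]))
        raw = raw.loc[~has_na]
        log.append(f"removed {len(removed)} gene(s) with missing values: {removed}")

    values = raw.to_numpy(dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1, keepdims=True)
    lo, hi = med - MAD_FENCE * mad, med + MAD_FENCE * mad
    n_clipped = int(np.sum((values < lo) | (values > hi)))
    if n_clipped:
        values = np.clip(values, lo, hi)
        log.append(f"winsorized {n_clipped} outlier value(s) at median +/- 5 MAD")

    if np.any(values < 0):
        n_neg = int(np.sum(values < 0))
        values = np.maximum(values, 0.0)
        log.append(f"clamped {n_neg} negative value(s) to 0")

    return ExpressionMatrix(
        genes=list(map(str, raw.index)),
        conditions=list(map(str, raw.columns)),
        values=values,
        cleaning_log=log,
    )


# ---------------------------------------------------------------------------
# Correlation and binarization
# ---------------------------------------------------------------------------

def correlation_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """Pearson correlation between gene rows across conditions.

    Constant rows have undefined correlation; they are reported as 0 with a
    warning so they can never create an edge.  With only 2 conditions every
    defined correlation is +/-1, which is flagged.
    """
    values = expr.values
    if expr.n_conditions == 2:
        warnings.warn(
            "only 2 conditions: all pairwise correlations are +/-1 and the "
            "network is degenerate"
        )
    sd = values.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(values)
    C = np.atleast_2d(C)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene row(s): correlation set to 0"
        )
        C[constant, :] = 0.0
        C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(np.nan_to_num(C, nan=0.0), -1.0, 1.0)


def binarize(C: np.ndarray, threshold: float, absolute: bool = False) -> np.ndarray:
    """Binary adjacency from a correlation matrix at a threshold in (0,1).

    An edge is placed where r >= threshold (signed convention by default;
    negative correlations never create edges unless ``absolute``).  The
    diagonal is zero.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    vals = np.abs(C) if absolute else C
    A = (vals >= threshold).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


# ---------------------------------------------------------------------------
# Threshold diagnostics
# ---------------------------------------------------------------------------

def scale_free_fit(degrees: Iterable[int], n_bins: int = 10) -> float:
    """R-squared of the log-log degree-distribution regression.

    Fits log10 p(k) against log10 k over the positive degrees.  When there
    are at most ``n_bins`` distinct positive degrees the empirical
    frequencies are used directly; otherwise degrees are pooled into
    ``n_bins`` logarithmic bins and p(k) is the fraction of nodes per bin at
    the bin's geometric-mean degree.  Fewer than 3 support points gives 0
    with a warning.
    """
    deg = np.asarray(list(degrees), dtype=float)
    deg = deg[deg > 0]
    if deg.size == 0:
        warnings.warn("no positive degrees: scale-free fit undefined, returning 0")
        return 0.0

    distinct = np.unique(deg)
    if distinct.size <= n_bins:
        ks = distinct
        pk = np.array([(deg == k).mean() for k in distinct])
    else:
        edges = np.logspace(
            np.log10(distinct.min()), np.log10(distinct.max()), n_bins + 1
        )
        edges[-1] *= 1 + 1e-12
        which = np.digitize(deg, edges) - 1
        ks, pk = [], []
        for b in range(n_bins):
            members = deg[which == b]
            if members.size:
                ks.append(np.exp(np.mean(np.log(members))))
                pk.append(members.size / deg.size)
        ks, pk = np.asarray(ks), np.asarray(pk)

    if ks.size < 3:
        warnings.warn(
            "fewer than 3 support points for the scale-free fit, returning 0"
        )
        return 0.0
    x, y = np.log10(ks), np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    return float(max(0.0, 1.0 - np.sum(resid**2) / ss_tot))


def scale_free_r2(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index of a binary adjacency matrix."""
    A = np.asarray(adjacency)
    if A.size == 0:
        warnings.warn("empty network: scale-free fit undefined, returning 0")
        return 0.0
    return scale_free_fit(A.sum(axis=1), n_bins=n_bins)


def mean_connectivity(adjacency: np.ndarray) -> float:
    """Average node degree 2E/V, isolated nodes included."""
    A = np.asarray(adjacency)
    if A.shape[0] == 0:
        raise ValueError("empty node set")
    return float(A.sum() / A.shape[0])


def count_components(adjacency: np.ndarray, spectral: bool = False) -> int:
    """Number of clusters in the network.

    Default: connected components containing at least 2 nodes (singletons
    are not clusters).  ``spectral=True`` instead counts near-zero Laplacian
    eigenvalues among non-isolated nodes.
    """
    A = np.asarray(adjacency)
    if A.shape[0] == 0 or A.sum() == 0:
        return 0
    if spectral:
        keep = A.sum(axis=1) > 0
        Ak = A[np.ix_(keep, keep)].astype(float)
        L = np.diag(Ak.sum(axis=1)) - Ak
        eig = np.linalg.eigvalsh(L)
        return int(np.sum(eig < 1e-8))
    G = nx.from_numpy_array(A)
    return sum(1 for comp in nx.connected_components(G) if len(comp) >= 2)


def select_threshold(
    expr_or_corr: "ExpressionMatrix | np.ndarray",
    grid: Iterable[float] = DEFAULT_GRID,
    r2_min: float = 0.5,
    absolute: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Scan a threshold grid and pick the binarization threshold.

    For every candidate the scale-free fit R^2, mean connectivity, cluster
    count and edge count are recorded.  Among candidates with R^2 >= r2_min
    the one maximizing the cluster count wins, ties broken toward the
    smallest threshold (retaining more edges).  If no candidate reaches the
    scale-free criterion the max-R^2 candidate is returned with a warning.
    """
    grid = sorted(float(t) for t in grid)
    if not grid:
        raise ValueError("empty threshold grid")
    if isinstance(expr_or_corr, ExpressionMatrix):
        if expr_or_corr.n_conditions < 3:
            raise ValueError("threshold selection needs at least 3 conditions")
        C = correlation_matrix(expr_or_corr)
    else:
        C = np.asarray(expr_or_corr, dtype=float)

    rows = []
    for t in grid:
        A = binarize(C, t, absolute=absolute)
        rows.append(
            {
                "threshold": t,
                "r2": scale_free_r2(A),
                "mean_connectivity": mean_connectivity(A),
                "n_components": count_components(A),
                "n_edges": int(A.sum() // 2),
            }
        )
    diag = pd.DataFrame(rows)

    ok = diag[diag["r2"] >= r2_min]
    if len(ok) == 0:
        warnings.warn(
            f"no threshold reaches scale-free R^2 >= {r2_min}; falling back "
            "to the maximal-R^2 candidate"
        )
        best = diag.loc[diag["r2"].idxmax()]
    else:
        top = ok[ok["n_components"] == ok["n_components"].max()]
        best = top.loc[top["threshold"].idxmin()]
    return float(best["threshold"]), diag


# ---------------------------------------------------------------------------
# Network container, stats and perturbations
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    """A binary gene-gene network with its selection diagnostics."""

    genes: list[str]
    adjacency: np.ndarray
    threshold: float | None = None
    diagnostics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.shape != (len(self.genes), len(self.genes)):
            raise ValueError("adjacency shape inconsistent with gene list")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must be hollow")
        self.adjacency = A.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edges(self) -> Iterator[tuple[str, str]]:
        iu = np.triu_indices(len(self.genes), k=1)
        for i, j in zip(*iu):
            if self.adjacency[i, j]:
                yield self.genes[i], self.genes[j]


def network_stats(adjacency: np.ndarray) -> dict:
    """Node/edge counts, average degree and the degree histogram."""
    A = np.asarray(adjacency)
    degrees = A.sum(axis=1).astype(int)
    hist: dict[int, int] = {}
    for d in degrees:
        hist[int(d)] = hist.get(int(d), 0) + 1
    n = A.shape[0]
    e = int(A.sum() // 2)
    return {
        "nodes": n,
        "edges": e,
        "average_degree": (2 * e / n) if n else 0.0,
        "degree_distribution": dict(sorted(hist.items())),
    }


def build_network(
    expr: ExpressionMatrix,
    grid: Iterable[float] = DEFAULT_GRID,
    threshold: float | None = None,
    absolute: bool = False,
) -> CoexpressionNetwork:
    """End-to-end network construction from a cleaned expression matrix."""
    C = correlation_matrix(expr)
    if threshold is None:
        threshold, diag = select_threshold(C, grid, absolute=absolute)
    else:
        diag = None
    A = binarize(C, threshold, absolute=absolute)
    return CoexpressionNetwork(
        genes=list(expr.genes), adjacency=A, threshold=threshold, diagnostics=diag
    )


def rewire_random(
    network: CoexpressionNetwork, fraction: float, seed: int = 0
) -> CoexpressionNetwork:
    """Randomly replace a fraction of edges, conserving node and edge counts.

    round(fraction * E) edges are removed uniformly at random and the same
    number of new edges is placed uniformly among the non-edges of the
    original graph (no self-loops, no duplicates, removed edges never
    reappear).  Deterministic for a given seed.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    A = network.adjacency.copy()
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    flat_edges = np.flatnonzero(A[iu])
    n_remove = int(round(fraction * flat_edges.size))
    if n_remove == 0:
        return CoexpressionNetwork(
            genes=list(network.genes), adjacency=A, threshold=network.threshold
        )

    remove = rng.choice(flat_edges, size=n_remove, replace=False)
    upper = A[iu].copy()
    non_edges = np.flatnonzero(upper == 0)  # non-edges of the original graph
    upper[remove] = 0
    if non_edges.size < n_remove:
        raise ValueError("graph too dense to place replacement edges")
    add = rng.choice(non_edges, size=n_remove, replace=False)
    upper[add] = 1
    A = np.zeros_like(A)
    A[iu] = upper
    A = A + A.T
    return CoexpressionNetwork(
        genes=list(network.genes), adjacency=A, threshold=network.threshold
    )


def import_string_ppi(
    path: str,
    id_map: Mapping[str, str] | None = None,
    score_cut: int = 900,
    genes: list[str] | None = None,
) -> CoexpressionNetwork:
    """Build a network from a STRING protein-links file.

    Keeps undirected pairs with combined_score strictly greater than
    ``score_cut`` (default 900, the high-confidence cut).  ``id_map``
    translates protein identifiers to model gene ids; unmapped proteins are
    dropped and counted.  Reciprocal duplicate lines collapse to one edge.
    """
    id_map = dict(id_map) if id_map else None
    kept: set[frozenset[str]] = set()
    n_unmapped = 0
    n_malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            parts = line.split()
            if lineno == 0 and parts and not parts[-1].lstrip("-").isdigit():
                continue  # header
            if len(parts) < 3:
                if line.strip():
                    n_malformed += 1
                continue
            p1, p2, score_s = parts[0], parts[1], parts[-1]
            try:
                score = int(score_s)
            except ValueError:
                n_malformed += 1
                continue
            if score <= score_cut:
                continue
            if id_map is not None:
                if p1 not in id_map or p2 not in id_map:
                    n_unmapped += 1
                    continue
                p1, p2 = id_map[p1], id_map[p2]
            if p1 != p2:
                kept.add(frozenset((p1, p2)))

    if n_malformed:
        warnings.warn(f"skipped {n_malformed} malformed line(s)")
    if n_unmapped:
        warnings.warn(f"dropped {n_unmapped} line(s) with unmapped protein ids")
    if not kept:
        warnings.warn("no edges survive the score cut / id mapping")

    node_list = genes if genes is not None else sorted({g for e in kept for g in e})
    index = {g: i for i, g in enumerate(node_list)}
    A = np.zeros((len(node_list), len(node_list)), dtype=np.int8)
    for e in kept:
        a, b = tuple(e)
        if a in index and b in index:
            A[index[a], index[b]] = A[index[b], index[a]] = 1
    return CoexpressionNetwork(genes=node_list, adjacency=A)


# ---------------------------------------------------------------------------
# Topological overlap and module detection
# ---------------------------------------------------------------------------

def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a binary adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with l_ij the number
    of shared neighbors; the diagonal is 1 and 0/0 cases map to 0.
    """
    A = np.asarray(adjacency, dtype=float)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    n_modules: int | None = None,
    cut_height: float | None = None,
    genes: list[str] | None = None,
) -> dict[str, str]:
    """Group genes into modules by average-linkage clustering of 1 - TOM.

    The dendrogram is cut either to a requested module count or at a static
    dissimilarity height.  Labels are ME1..MEk ordered by decreasing module
    size; ties broken by first gene index for determinism.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    names = genes if genes is not None else [f"g{i}" for i in range(n)]
    if n_modules is not None and n_modules > n:
        raise ValueError("requested more modules than genes")
    if n_modules is None and cut_height is None:
        raise ValueError("pass n_modules or cut_height")

    if n == 1:
        return {names[0]: "ME1"}
    dissim = 1.0 - tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    if n_modules is not None:
        labels = fcluster(Z, t=n_modules, criterion="maxclust")
    else:
        labels = fcluster(Z, t=cut_height, criterion="distance")

    # rank raw cluster labels by (size desc, first-member index asc)
    order = sorted(
        set(labels),
        key=lambda c: (-int(np.sum(labels == c)), int(np.argmax(labels == c))),
    )
    rename = {c: f"ME{r + 1}" for r, c in enumerate(order)}
    return {names[i]: rename[labels[i]] for i in range(n)}
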