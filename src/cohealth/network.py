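"""Weighted co-expression network construction (WGCNA-style).

The chain is: Pearson correlation of gene expression profiles -> soft
threshold (adjacency a_ij = |cor_ij|^beta with beta chosen for scale-free
topology) -> topological overlap matrix (TOM) -> average-linkage clustering
of 1 - TOM with a minimum module size -> module eigengenes, soft
connectivity and module membership (kME).

The TOM here is the unsigned formula

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{j != i} a_ij (diagonal excluded) and unit
diagonal.  Scale-free fit follows the log-log regression of the degree
density on the binned connectivities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .errors import CohealthError

log = logging.getLogger(__name__)

DEFAULT_MIN_INTERACTION_SCORE = 0.2
DEFAULT_MIN_MODULE_SIZE = 30
UNASSIGNED = 0


# ---------------------------------------------------------------------------
# correlation & adjacency
# ---------------------------------------------------------------------------

def correlation_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Gene-gene Pearson correlations; constant genes are dropped, not fatal."""
    if matrix.shape[1] < 3:
        raise CohealthError("correlation needs at least three samples")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    constant = sd == 0
    dropped = [str(g) for g in matrix.index[constant]]
    if dropped:
        log.warning("dropping %d constant-expression gene(s) before correlation", len(dropped))
        matrix = matrix.loc[~constant]
        vals = vals[~constant]
    cor = np.atleast_2d(np.corrcoef(vals))
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=matrix.index, columns=matrix.index), dropped


def adjacency(cor: pd.DataFrame, power: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor_ij|^power, unit diagonal."""
    if power < 1 or int(power) != power:
        raise CohealthError("power must be a positive integer")
    a = np.abs(cor.to_numpy(dtype=float)) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def soft_connectivity(adj: pd.DataFrame) -> pd.Series:
    """Per-gene soft connectivity k_i = sum_{j != i} a_ij."""
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=adj.index, name="k")


# ---------------------------------------------------------------------------
# scale-free topology fit and power selection
# ---------------------------------------------------------------------------

@dataclass
class ScaleFreeFit:
    """Scale-free topology fit across candidate soft-threshold powers."""

    candidates: list[int]
    r_squared: list[float]
    slopes: list[float]
    power: int
    not_scale_free: bool = False
    target_r2: float = 0.80
    n_bins: int = 10

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"power": self.candidates, "r_squared": self.r_squared,
                             "slope": self.slopes})


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10, binning: str = "equal-count",
                         ) -> tuple[float, float]:
    """R^2 and slope of the log10 p(k) vs log10 k regression.

    equal-count binning estimates the degree density per quantile bin
    (count / (n * bin width)); equal-width binning uses the per-bin
    frequency as in classic WGCNA.  Returns (nan, nan) on degenerate
    degree distributions (fewer than three usable bins).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return float("nan"), float("nan")
    if binning == "equal-count":
        edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
        if edges.size < 4:
            return float("nan"), float("nan")
        counts, edges = np.histogram(k, bins=edges)
        widths = np.diff(edges)
        with np.errstate(invalid="ignore"):
            dens = counts / (k.size * widths)
        centers = np.array([k[(k >= lo) & (k <= hi if i == len(widths) - 1 else k < hi)].mean()
                            if c else np.nan
                            for i, (lo, hi, c) in enumerate(zip(edges[:-1], edges[1:], counts))])
    elif binning == "equal-width":
        counts, edges = np.histogram(k, bins=n_bins)
        dens = counts / k.size
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        centers = np.array([k[idx == i].mean() if (idx == i).any() else np.nan
                            for i in range(n_bins)])
    else:
        raise CohealthError(f"unknown binning mode: {binning!r}")
    ok = (dens > 0) & np.isfinite(centers) & (centers > 0)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    fit = linregress(np.log10(centers[ok]), np.log10(dens[ok]))
    return float(fit.rvalue**2), float(fit.slope)


def pick_soft_power(cor: pd.DataFrame, candidates: Sequence[int] = tuple(range(1, 21)),
                    target_r2: float = 0.80, n_bins: int = 10,
                    binning: str = "equal-count") -> ScaleFreeFit:
    """Smallest power whose network is scale-free (R^2 >= target).

    Falls back to the R^2-maximizing candidate with ``not_scale_free=True``
    when no candidate reaches the target (the caller may then skip the
    experiment, mirroring the 'no modules found' rule).
    """
    if cor.shape[0] < 30:
        log.warning("scale-free fit on %d genes: degree distribution may be unstable",
                    cor.shape[0])
    abs_cor = np.abs(cor.to_numpy(dtype=float))
    np.fill_diagonal(abs_cor, 0.0)
    r2s, slopes = [], []
    for beta in candidates:
        k = (abs_cor**beta).sum(axis=1)
        r2, slope = scale_free_fit_index(k, n_bins=n_bins, binning=binning)
        r2s.append(r2)
        slopes.append(slope)
    candidates = list(candidates)
    chosen, flag = None, False
    for beta, r2, slope in zip(candidates, r2s, slopes):
        if np.isfinite(r2) and r2 >= target_r2 and slope < 0:
            chosen = beta
            break
    if chosen is None:
        flag = True
        finite = [i for i, r2 in enumerate(r2s) if np.isfinite(r2)]
        chosen = candidates[max(finite, key=lambda i: r2s[i])] if finite else candidates[0]
        log.warning("no candidate power reached scale-free R^2 >= %.2f; "
                    "falling back to power %d (not scale-free)", target_r2, chosen)
    return ScaleFreeFit(candidates=candidates, r_squared=r2s, slopes=slopes,
                        power=int(chosen), not_scale_free=flag,
                        target_r2=target_r2, n_bins=n_bins)


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned TOM with the diagonal excluded from connectivity, diagonal 1."""
    a = adj.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise CohealthError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise CohealthError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    shared = a @ a  # (A0 @ A0)_ij = sum over u != i,j since diag(A0)=0
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _split_cluster(dissim: np.ndarray, idx: np.ndarray, min_size: int,
                   cut_fraction: float, gap: float, depth: int) -> list[np.ndarray]:
    """Recursively split one cluster when the dendrogram supports it."""
    if depth <= 0 or idx.size < 2 * min_size:
        return [idx]
    sub = dissim[np.ix_(idx, idx)]
    Z = linkage(squareform(sub, checks=False), method="average")
    heights = Z[:, 2]
    root = heights[-1]
    if root <= 0:
        return [idx]
    second = heights[-2] if len(heights) > 1 else 0.0
    if (root - second) < gap * root:
        return [idx]  # no clear separation at the top of this branch
    labels = fcluster(Z, t=(root + second) / 2.0, criterion="distance")
    parts = [idx[labels == lbl] for lbl in np.unique(labels)]
    if sum(p.size >= min_size for p in parts) < 2:
        return [idx]
    out: list[np.ndarray] = []
    for p in parts:
        out.extend(_split_cluster(dissim, p, min_size, cut_fraction, gap, depth - 1))
    return out


def detect_modules(tom: pd.DataFrame, min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
                   cut_fraction: float = 0.99, deep_split: int = 2,
                   split_gap: float = 0.05) -> pd.Series:
    """Cut the 1-TOM dendrogram into modules of at least ``min_module_size``.

    Average-linkage clustering on 1 - TOM; a static cut at
    ``cut_fraction`` of the dendrogram height yields base clusters, which a
    depth-limited recursion (``deep_split`` levels) further splits when the
    top of a branch is separated from the rest by a relative merge-height
    gap of at least ``split_gap``.  Clusters below the minimum size are
    assigned label 0 (unassigned); surviving modules get labels 1..K by
    decreasing size (ties: smallest member index).
    """
    genes = tom.index
    n = len(genes)
    labels = np.zeros(n, dtype=int)
    if n < min_module_size:
        log.warning("only %d genes (< minimum module size %d): all unassigned",
                    n, min_module_size)
        return pd.Series(labels, index=genes, name="module")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    max_h = Z[:, 2].max()
    if max_h <= 0:
        labels[:] = 1  # all genes identical: one module
        return pd.Series(labels, index=genes, name="module")
    base = fcluster(Z, t=cut_fraction * max_h, criterion="distance")
    clusters: list[np.ndarray] = []
    for lbl in np.unique(base):
        idx = np.flatnonzero(base == lbl)
        if idx.size >= min_module_size:
            clusters.extend(_split_cluster(dissim, idx, min_module_size,
                                           cut_fraction, split_gap, deep_split))
    clusters = [c for c in clusters if c.size >= min_module_size]
    clusters.sort(key=lambda c: (-c.size, int(c.min())))
    for new_label, idx in enumerate(clusters, start=1):
        labels[idx] = new_label
    return pd.Series(labels, index=genes, name="module")


# ---------------------------------------------------------------------------
# eigengenes and membership
# ---------------------------------------------------------------------------

@dataclass
class EigengeneProfile:
    """First principal component of a module's standardized expression."""

    label: int
    values: pd.Series  # per-sample, unit L2 norm
    variance_explained: float
    orientation_sign: int


def _standardize_rows(vals: np.ndarray) -> np.ndarray:
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise CohealthError("module contains constant-expression genes")
    return (vals - mu) / sd


def module_eigengene(matrix: pd.DataFrame, module_genes: Sequence[str],
                     label: int = 0) -> EigengeneProfile:
    """Eigengene of one module: unit-norm PC1 across samples.

    The sign is oriented so the eigengene correlates positively with the
    module's mean standardized expression; when that correlation is zero
    (e.g. a module that is half x, half -x) the sign is fixed so the first
    gene in sorted order has positive loading.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise CohealthError("eigengene needs a module of at least two genes")
    sub = matrix.loc[module_genes]
    if sub.shape[1] < 3:
        raise CohealthError("eigengene needs at least three samples")
    X = _standardize_rows(sub.to_numpy(dtype=float))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    e = Vt[0]
    var_explained = float(S[0] ** 2 / (S**2).sum())
    mean_profile = X.mean(axis=0)
    orient = np.dot(e, mean_profile)
    if abs(orient) < 1e-12:
        first = sorted(range(len(module_genes)), key=lambda i: str(module_genes[i]))[0]
        orient = np.dot(e, X[first])
    sign = 1 if orient >= 0 else -1
    e = e * sign
    return EigengeneProfile(
        label=label,
        values=pd.Series(e, index=sub.columns, name=f"ME{label}"),
        variance_explained=var_explained,
        orientation_sign=sign,
    )


def module_membership(matrix: pd.DataFrame, eigengene: EigengeneProfile) -> pd.Series:
    """Signed kME: Pearson correlation of each gene with the eigengene.

    Constant genes get NaN (membership undefined).
    """
    e = eigengene.values.reindex(matrix.columns).to_numpy(dtype=float)
    vals = matrix.to_numpy(dtype=float)
    vc = vals - vals.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    denom = np.sqrt((vc**2).sum(axis=1) * (ec**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = (vc @ ec) / denom
    kme[denom == 0] = np.nan
    return pd.Series(np.clip(kme, -1, 1), index=matrix.index, name="kME")


# ---------------------------------------------------------------------------
# network bundle
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    """All per-experiment network artifacts in one place."""

    genes: list[str]
    correlation: pd.DataFrame
    fit: ScaleFreeFit
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series  # gene -> int label, 0 = unassigned
    connectivity: pd.Series
    eigengenes: dict[int, EigengeneProfile] = field(default_factory=dict)
    kme: dict[int, pd.Series] = field(default_factory=dict)
    min_interaction_score: float = DEFAULT_MIN_INTERACTION_SCORE
    dropped_constant_genes: list[str] = field(default_factory=list)

    @property
    def power(self) -> int:
        return self.fit.power

    def module_labels(self) -> list[int]:
        return sorted(set(self.modules) - {UNASSIGNED})

    def module_genes(self, label: int) -> list[str]:
        return [str(g) for g in self.modules.index[self.modules == label]]

    def edge_list(self, score_basis: str = "tom") -> pd.DataFrame:
        """Upper-triangle edges filtered at the minimum interaction score.

        ``score_basis`` selects whether the 0.2 floor applies to the TOM
        interaction score (default) or to the raw adjacency.
        """
        basis = self.tom if score_basis == "tom" else self.adjacency
        b = basis.to_numpy(dtype=float)
        a = self.adjacency.to_numpy(dtype=float)
        t = self.tom.to_numpy(dtype=float)
        iu = np.triu_indices(len(self.genes), k=1)
        keep = b[iu] >= self.min_interaction_score
        gi = np.asarray(self.genes)
        return pd.DataFrame({
            "gene_a": gi[iu[0][keep]],
            "gene_b": gi[iu[1][keep]],
            "adjacency": a[iu][keep],
            "tom": t[iu][keep],
        })


def build_network(matrix: pd.DataFrame, *, min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
                  candidates: Sequence[int] = tuple(range(1, 21)), target_r2: float = 0.80,
                  min_interaction_score: float = DEFAULT_MIN_INTERACTION_SCORE,
                  power: Optional[int] = None, deep_split: int = 2,
                  require_scale_free: bool = False) -> CoexpressionNetwork:
    """Run the full network chain on a preprocessed genes x samples matrix."""
    cor, dropped = correlation_matrix(matrix)
    if power is None:
        fit = pick_soft_power(cor, candidates=candidates, target_r2=target_r2)
    else:
        fit = ScaleFreeFit(candidates=[int(power)], r_squared=[float("nan")],
                           slopes=[float("nan")], power=int(power))
    if require_scale_free and fit.not_scale_free:
        raise CohealthError("no scale-free network could be derived from the correlation matrix")
    adj = adjacency(cor, fit.power)
    tom = topological_overlap(adj)
    modules = detect_modules(tom, min_module_size=min_module_size, deep_split=deep_split)
    k = soft_connectivity(adj)
    kept = matrix.loc[cor.index]
    net = CoexpressionNetwork(
        genes=[str(g) for g in cor.index], correlation=cor, fit=fit, adjacency=adj,
        tom=tom, modules=modules, connectivity=k,
        min_interaction_score=min_interaction_score, dropped_constant_genes=dropped,
    )
    for label in net.module_labels():
        prof = module_eigengene(kept, net.module_genes(label), label=label)
        net.eigengenes[label] = prof
        net.kme[label] = module_membership(kept, prof)
    return net
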