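"""Expression-matrix normalization and filtering ahead of network construction.

Covers TPM conversion for count data, log2 transformation with an
already-logged heuristic, optional quantile or Z-score normalization,
hierarchical-clustering-based sample outlier removal, and the low-expression
gene filter.  All functions take and return genes x samples DataFrames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .errors import CohealthError, ExperimentExcluded
from .simulate import MIN_SAMPLES

log = logging.getLogger(__name__)

# Log2 intensities and log-ratios live well below this; linear-scale
# microarray intensities and TPM values exceed it.
ALREADY_LOGGED_MAX = 50.0


@dataclass
class PreprocessOptions:
    """Knobs of the preprocessing stage.

    normalization: "as-deposited" leaves values untouched after the log
    step (the default, mirroring reliance on the data as normalized by the
    submitters); "quantile" and "zscore" apply the respective transforms.
    """

    log_offset: float = 1.0
    already_logged_max: float = ALREADY_LOGGED_MAX
    normalization: str = "as-deposited"
    outlier_cut_height: Optional[float] = None  # None: skip outlier removal
    low_expression_min_value: float = 1.0
    low_expression_min_fraction: float = 0.5
    gene_lengths: Optional[pd.Series] = field(default=None, repr=False)

    def __post_init__(self):
        if self.log_offset < 0:
            raise CohealthError("log offset must be >= 0")
        if self.outlier_cut_height is not None and self.outlier_cut_height <= 0:
            raise CohealthError("outlier cut height must be > 0")
        if self.normalization not in ("as-deposited", "quantile", "zscore"):
            raise CohealthError(f"unknown normalization mode: {self.normalization!r}")


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: rate = count/length, scaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    active = counts.to_numpy().sum(axis=1) > 0
    if lengths.isna().any() or (lengths.to_numpy(dtype=float)[active] <= 0).any():
        bad = counts.index[(lengths.isna() | (lengths <= 0)).to_numpy() & active]
        raise CohealthError(f"missing/non-positive gene length for expressed gene(s): {list(bad[:5])}")
    zero = counts.sum(axis=0) == 0
    if zero.any():
        raise CohealthError(f"all-zero sample(s): {', '.join(map(str, counts.columns[zero]))}")
    rate = counts.div(lengths.to_numpy(dtype=float).clip(min=1e-300), axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def looks_logged(matrix: pd.DataFrame, threshold: float = ALREADY_LOGGED_MAX) -> bool:
    """Heuristic: values capped at ~50 indicate an already log-scaled matrix."""
    return float(matrix.to_numpy().max()) <= threshold


def log_transform(matrix: pd.DataFrame, offset: float = 1.0, *, force: bool = False,
                  already_logged_max: float = ALREADY_LOGGED_MAX) -> pd.DataFrame:
    """Elementwise log2(x + offset); skipped when the matrix already looks logged."""
    if not force and looks_logged(matrix, already_logged_max):
        log.info("matrix maximum %.3g <= %.3g: treated as already log-scaled, log skipped",
                 matrix.to_numpy().max(), already_logged_max)
        return matrix
    vals = matrix.to_numpy(dtype=float)
    if offset == 0 and (vals <= 0).any():
        raise CohealthError("non-positive values with zero log offset")
    if (vals + offset <= 0).any():
        raise CohealthError("log transform undefined: values + offset <= 0")
    return pd.DataFrame(np.log2(vals + offset), index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the cross-sample mean of sorted values.

    Ties within a sample receive the mean of the reference values their
    (average) rank spans.
    """
    if matrix.shape[1] < 2:
        raise CohealthError("quantile normalization needs at least two samples")
    vals = matrix.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    n = vals.shape[0]
    out = np.empty_like(vals)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def zscore_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Z scores (Pearson-invariant; provided for parity checks)."""
    vals = matrix.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=matrix.index, columns=matrix.columns)


def remove_outlier_samples(matrix: pd.DataFrame, cut_height: float) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples outside the largest average-linkage cluster.

    Samples are clustered on Euclidean distance of their expression
    profiles; the tree is cut at ``cut_height`` and only the largest
    cluster is retained.  Raises :class:`ExperimentExcluded` when fewer
    than seven samples survive (inclusion rule).
    """
    if matrix.shape[1] < 3:
        raise CohealthError("outlier removal needs at least three samples")
    if cut_height <= 0:
        raise CohealthError("cut height must be > 0")
    Z = linkage(pdist(matrix.to_numpy(dtype=float).T, metric="euclidean"), method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    keep_label = sizes.index[0]  # largest cluster; value_counts ties -> lowest label first
    keep = labels == keep_label
    removed = [str(s) for s in matrix.columns[~keep]]
    kept = matrix.loc[:, keep]
    if kept.shape[1] < MIN_SAMPLES:
        raise ExperimentExcluded(
            "inclusion-rule",
            f"only {kept.shape[1]} samples retained after outlier removal (need more than six)",
        )
    if removed:
        log.info("outlier removal at cut height %.3g dropped samples: %s", cut_height, removed)
    return kept, removed


def filter_low_expression(matrix: pd.DataFrame, min_value: float = 1.0,
                          min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep genes with value >= min_value in >= min_fraction of samples."""
    if min_value < 0 or min_fraction < 0:
        raise CohealthError("thresholds must be >= 0")
    frac = (matrix.to_numpy(dtype=float) >= min_value).mean(axis=1)
    kept = matrix.loc[frac >= min_fraction]
    if kept.empty:
        raise CohealthError("low-expression filter removed every gene")
    return kept


def preprocess(matrix: pd.DataFrame, options: PreprocessOptions, *, platform: str = "log-intensity",
               ) -> tuple[pd.DataFrame, dict]:
    """Full preprocessing chain for one experiment.

    counts platform: TPM -> low-count filter -> log2 -> normalization ->
    outlier removal.  log-intensity platform: log2 (heuristic-guarded) ->
    normalization -> outlier removal.  Returns the processed matrix and a
    provenance dict of the steps applied.
    """
    steps: dict = {"platform": platform}
    out = matrix
    if platform == "counts":
        if options.gene_lengths is None:
            raise CohealthError("counts platform requires a gene-length table for TPM")
        out = tpm_from_counts(out, options.gene_lengths)
        steps["tpm"] = True
        out = filter_low_expression(out, options.low_expression_min_value,
                                    options.low_expression_min_fraction)
        steps["low_expression_filter"] = {
            "min_value": options.low_expression_min_value,
            "min_fraction": options.low_expression_min_fraction,
            "genes_kept": int(out.shape[0]),
        }
    logged = not looks_logged(out, options.already_logged_max)
    out = log_transform(out, options.log_offset, already_logged_max=options.already_logged_max)
    steps["log2"] = logged
    if options.normalization == "quantile":
        out = quantile_normalize(out)
    elif options.normalization == "zscore":
        out = zscore_genes(out)
    steps["normalization"] = options.normalization
    if options.outlier_cut_height is not None:
        out, removed = remove_outlier_samples(out, options.outlier_cut_height)
        steps["outliers_removed"] = removed
    return out, steps
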