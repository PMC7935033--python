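"""Functional connectivity from spike rasters.

Edges are the maximum normalized cross-correlation between the two binned
spike trains over integer-bin lags within +/- ``max_lag`` (default 20 ms,
1-ms bins), so only short-latency interactions contribute.  The
normalization is the coefficient convention — raw lagged dot product divided
by the product of the two count vectors' norms — so a perfectly lag-shifted
copy of a train scores exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .raster import SpikeRaster

__all__ = ["FunctionalNetwork", "bin_raster", "build_network"]

logger = logging.getLogger(__name__)

BIN_WIDTH = 0.001   # s
MAX_LAG = 0.020     # s


@dataclass
class FunctionalNetwork:
    """Symmetric weighted matrix of maximal normalized cross-correlations."""
    weights: np.ndarray            # (n, n), symmetric, zero diagonal, [0, 1]
    node_labels: list
    bin_width: float = BIN_WIDTH
    max_lag: float = MAX_LAG
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")
        if W.min() < -1e-12 or W.max() > 1 + 1e-9:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = np.clip(W, 0.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def save(self, path: str | Path) -> None:
        """Square delimited-text matrix with a label header row."""
        df = pd.DataFrame(self.weights, columns=self.node_labels)
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def load(cls, path: str | Path, bin_width: float = BIN_WIDTH,
             max_lag: float = MAX_LAG) -> "FunctionalNetwork":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=float), list(df.columns),
                   bin_width, max_lag)


def bin_raster(raster: SpikeRaster,
               bin_width: float = BIN_WIDTH) -> np.ndarray:
    """Per-source spike counts on a common grid covering [0, duration].

    Returns an (n_sources, n_bins) integer array; the total count equals
    the raster's spike count.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    n_bins = max(1, int(np.ceil(raster.duration / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    out = np.zeros((raster.n_sources, n_bins), dtype=np.int64)
    for i, t in enumerate(raster.spike_times):
        # duration-boundary spikes belong to the last bin
        out[i] = np.histogram(np.minimum(t, edges[-1] - 1e-12), bins=edges)[0]
    return out


def _sparse_lagged_products(X: sparse.csr_matrix, lags: int) -> np.ndarray:
    """max over lags 0..lags of sum_t x_i[t + l] * x_j[t], symmetrized.

    Computed with sparse matrix products, one per lag; the returned matrix
    holds max over both lag signs since M and M.T are both folded in.
    """
    n, T = X.shape
    best = np.zeros((n, n))
    for lag in range(lags + 1):
        if lag == 0:
            M = (X @ X.T).toarray().astype(float)
            best = np.maximum(best, M)        # symmetric already
        else:
            M = (X[:, lag:] @ X[:, :T - lag].T).toarray().astype(float)
            best = np.maximum(best, np.maximum(M, M.T))
    return best


def build_network(raster: SpikeRaster,
                  bin_width: float = BIN_WIDTH,
                  max_lag: float = MAX_LAG,
                  mean_subtract: bool = False) -> FunctionalNetwork:
    """Maximal normalized cross-correlation network of a raster.

    For each source pair the normalized cross-correlation is evaluated at
    every integer-bin lag in [-max_lag, +max_lag] and the maximum taken, so
    the matrix is symmetric by construction.  Sources with zero spikes get
    zero-weight edges (their correlation is undefined) with a logged
    warning.  ``mean_subtract=True`` centres each binned train before
    normalization (Pearson-style); the default retains the means, the usual
    spike-train convention.
    """
    if raster.n_sources < 2:
        raise ValueError("need at least 2 sources")
    counts = bin_raster(raster, bin_width)
    lags = int(round(max_lag / bin_width))
    n, T = counts.shape
    if T <= lags:
        raise ValueError("raster too short for the requested max_lag")

    X = sparse.csr_matrix(counts)
    raw = _sparse_lagged_products(X, lags)

    if not mean_subtract:
        norms = np.sqrt((counts.astype(float) ** 2).sum(axis=1))
        denom = np.outer(norms, norms)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(denom > 0, raw / denom, 0.0)
    else:
        # centred correlation from the same raw lagged products:
        # sum (x-mx)(y-my) over the overlap of length T-l; exact correction
        # terms need per-lag overlap sums, so fall back to a dense loop per
        # lag on the centred vectors (n is small; T dominates, still fast).
        C = counts.astype(float) - counts.mean(axis=1, keepdims=True)
        norms = np.sqrt((C ** 2).sum(axis=1))
        denom = np.outer(norms, norms)
        best = C @ C.T
        for lag in range(1, lags + 1):
            M = C[:, lag:] @ C[:, :T - lag].T
            best = np.maximum(best, np.maximum(M, M.T))
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(denom > 0, best / denom, 0.0)
        W = np.clip(W, 0.0, None)

    silent = np.flatnonzero(counts.sum(axis=1) == 0)
    if silent.size:
        logger.warning("%d source(s) with zero spikes: edges set to 0 "
                       "(correlation undefined): %s", silent.size,
                       [raster.source_ids[i] for i in silent])
        W[silent, :] = 0.0
        W[:, silent] = 0.0

    np.fill_diagonal(W, 0.0)
    W = np.clip((W + W.T) / 2.0, 0.0, 1.0)    # enforce exact symmetry
    return FunctionalNetwork(W, list(raster.source_ids), bin_width, max_lag,
                             meta={"mean_subtract": mean_subtract})
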