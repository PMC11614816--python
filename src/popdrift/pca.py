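"""Principal component analysis with frequency-based normalization.

Each dosage column is centered at twice the alt-allele frequency and scaled
by the binomial standard deviation sqrt(2p(1−p)) — the normalization used
for genotype PCA throughout population genetics. Missing entries contribute
0 after centering (mean imputation). Monomorphic variants carry no signal
and are dropped. An iterative outlier pass removes samples lying more than
``n_sd`` standard deviations out on any leading component, recomputing the
decomposition after each round.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panelio import MISSING, GenotypePanel

logger = logging.getLogger("popdrift")


@dataclass
class PCAResult:
    """Sample coordinates, explained-variance fractions, and flagged outliers."""

    coordinates: pd.DataFrame      # samples x k, indexed by sample id
    explained_fraction: np.ndarray  # k values, non-increasing, summing to <= 1
    eigenvalues: np.ndarray
    outliers: list = field(default_factory=list)  # (sample_id, iteration)


def normalize_panel(panel: GenotypePanel, return_index: bool = False):
    """Frequency-normalized dosage matrix; monomorphic variants dropped.

    Entry = (dosage − 2p) / sqrt(2p(1−p)); missing entries are set to 0
    after centering.
    """
    p = panel.alt_frequencies()
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.debug("normalize_panel: dropped %d monomorphic/all-missing variants",
                     n_dropped)
    p = p[keep]
    calls = panel.calls[:, keep].astype(float)
    obs = calls != MISSING
    x = (calls - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x[~obs] = 0.0
    if return_index:
        return x, np.flatnonzero(keep)
    return x


def compute_pca(panel: GenotypePanel, k: int = 10) -> PCAResult:
    """Top-k components of the sample × sample covariance of the normalized matrix.

    Explained fractions are eigenvalues over the trace of the full spectrum;
    ``k`` is truncated (with a warning) when it exceeds the rank.
    """
    if panel.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = normalize_panel(panel)
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 polymorphic variants")
    m = x.shape[1]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / m  # eigenvalues of X X^T / m
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = rank
    trace = eigvals.sum()
    coords = u[:, :k] * s[:k]
    frame = pd.DataFrame(
        coords, index=panel.samples["id"],
        columns=[f"PC{i+1}" for i in range(k)],
    )
    return PCAResult(frame, eigvals[:k] / trace, eigvals[:k])


def detect_outliers(panel: GenotypePanel, n_sd: float = 6.0, n_pcs: int = 10,
                    max_iter: int = 5, k: int = 10) -> list:
    """Iteratively flag samples beyond ``n_sd`` SD on any leading component.

    PCA is recomputed after every removal round, up to ``max_iter`` rounds.
    Returns ``[(sample_id, iteration), ...]`` in flagging order.
    """
    flagged: list = []
    current = panel
    for iteration in range(1, max_iter + 1):
        if current.n_samples < 3 or not np.isfinite(n_sd):
            break
        res = compute_pca(current, k=min(k, current.n_samples - 1))
        coords = res.coordinates.to_numpy()
        use = coords[:, :min(n_pcs, coords.shape[1])]
        mu = use.mean(axis=0)
        sd = use.std(axis=0)
        sd[sd == 0] = np.inf
        bad = (np.abs(use - mu) > n_sd * sd).any(axis=1)
        if not bad.any():
            break
        ids = res.coordinates.index[bad].tolist()
        flagged.extend((sid, iteration) for sid in ids)
        current = current.take_samples(~bad)
    return flagged


def pca_with_outlier_removal(panel: GenotypePanel, k: int = 10, n_sd: float = 6.0,
                             n_pcs: int = 10, max_iter: int = 5) -> PCAResult:
    """Outlier pass followed by a final PCA on the retained samples."""
    outliers = detect_outliers(panel, n_sd=n_sd, n_pcs=n_pcs, max_iter=max_iter, k=k)
    out_ids = {sid for sid, _ in outliers}
    keep = ~panel.samples["id"].isin(out_ids).to_numpy()
    result = compute_pca(panel.take_samples(keep), k=k)
    result.outliers = outliers
    return result
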