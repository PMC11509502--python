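"""Sample-level structure: PCA of appearance patterns and overabundance.

PCA treats samples as observations and proteins as binary features,
column-centered but unscaled (the variance of a Bernoulli feature is
informative).  The overabundance curve compares observed discovery counts
at each p-value threshold with the count expected under the uniform null,
and its reciprocal is the plug-in FDR estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from proteopair.appearance import AppearanceMatrix

__all__ = [
    "Embedding",
    "OverabundanceCurve",
    "pca_binary",
    "overabundance",
    "fdr_at_threshold",
    "default_threshold_grid",
]


@dataclass
class Embedding:
    """Low-dimensional sample coordinates from PCA."""

    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, n_components)
    explained_variance_fractions: np.ndarray  # (n_components,)


@dataclass
class OverabundanceCurve:
    """Observed vs expected discovery counts over a p-value threshold grid."""

    thresholds: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    ratio: np.ndarray
    fdr_estimate: np.ndarray
    m_tested: int


def pca_binary(a: AppearanceMatrix, n_components: int = 3) -> Embedding:
    """PCA of the binary appearance matrix, samples as observations.

    Columns (proteins) are centered, not scaled.  Component signs are fixed
    so each component's largest-magnitude protein loading is positive,
    making the embedding deterministic.
    """
    X = a.bits.T.astype(float)  # samples x proteins
    n_samples = X.shape[0]
    if n_samples <= n_components:
        raise ValueError(
            f"need more than {n_components} samples for {n_components} components, "
            f"got {n_samples}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(len(s)):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    total_var = float((s**2).sum())
    coords = u[:, :n_components] * s[:n_components]
    if total_var == 0:
        frac = np.zeros(n_components)
    else:
        frac = (s[:n_components] ** 2) / total_var
    return Embedding(
        sample_ids=list(a.sample_ids),
        coordinates=coords,
        explained_variance_fractions=frac,
    )


def default_threshold_grid(n_points: int = 50) -> np.ndarray:
    """Log-spaced p-value thresholds in [1e-4, 1]."""
    return np.logspace(-4, 0, n_points)


def overabundance(
    p_values: Sequence[float], thresholds: Sequence[float] | None = None
) -> OverabundanceCurve:
    """Observed/expected discovery counts over a threshold grid.

    `p_values` must be defined (non-NaN); NaN entries are dropped with
    m_tested counting only defined tests.  The comparison is inclusive
    (p <= threshold).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no defined p-values")
    if thresholds is None:
        thresholds = default_threshold_grid()
    t = np.asarray(thresholds, dtype=float)
    if (t <= 0).any() or (t > 1).any():
        raise ValueError("thresholds must lie in (0, 1]")
    m = p.size
    observed = np.array([(p <= a).sum() for a in t], dtype=int)
    expected = t * m
    ratio = observed / expected  # expected > 0 since thresholds > 0
    with np.errstate(divide="ignore"):
        fdr = np.where(observed > 0, np.minimum(expected / np.maximum(observed, 1), 1.0), np.nan)
    return OverabundanceCurve(
        thresholds=t,
        observed=observed,
        expected=expected,
        ratio=ratio,
        fdr_estimate=fdr,
        m_tested=m,
    )


def fdr_at_threshold(p_values: Sequence[float], alpha: float) -> float:
    """Plug-in FDR at threshold alpha: min(1, alpha * m / #{p <= alpha}).

    Returns NaN when no p-value passes the threshold.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    m = p.size
    observed = int((p <= alpha).sum())
    if observed == 0:
        return math.nan
    return min(1.0, alpha * m / observed)
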