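"""PCA on interaction fingerprints and affinity-trend regression.

The last stage of the pipeline asks whether any pose cluster's interaction
pattern tracks the experimental affinity series.  Bin populations of the
per-pose fingerprints are reduced by mean-centred PCA; for every cluster the
per-ligand mean PC1 score is regressed against the affinity (log10 CD50 by
default, raw CD50 optionally), and clusters are ranked by R².  The PC1
loading vector, reshaped back onto the 7 x 80 category/distance grid, shows
which interaction types at which distances drive the separation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .interactions import CATEGORY_ORDER, FingerprintConfig
from .io_formats import AffinityTable

logger = logging.getLogger(__name__)


@dataclass
class PcaModel:
    loadings: np.ndarray               # (n_features, n_components)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scores: np.ndarray                 # (n_items, n_components)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.loadings


@dataclass
class TrendResult:
    cluster_id: int
    site_tag: str
    mean_pc1: dict[str, float]         # ligand -> mean PC1 in this cluster
    slope: float
    intercept: float
    r_squared: float
    n_ligands: int
    affinity_scale: str                # raw_cd50 | log10_cd50


@dataclass
class LoadingSpan:
    category: str
    d_lo: float                        # left edge of first bin in the span
    d_hi: float                        # left edge of last bin in the span
    sign: int                          # sign of the loading at the span peak
    peak_loading: float


def fit_pca(features: np.ndarray, n_components: int | None = None) -> PcaModel:
    """Mean-centred PCA (no variance scaling) with a deterministic sign.

    Each component is oriented so its largest-magnitude loading is positive.
    Zero-variance input yields all-zero scores and loadings with a warning
    instead of an error.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError("need an (items >= 2) x (features >= 1) matrix")
    if n_components is None:
        n_components = min(x.shape[0] - 1, x.shape[1])
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    mean = x.mean(axis=0)
    if np.allclose(x - mean, 0.0, atol=1e-12):
        warnings.warn("zero-variance input to PCA; returning zero scores")
        return PcaModel(np.zeros((x.shape[1], n_components)),
                        np.zeros(n_components), mean,
                        np.zeros((x.shape[0], n_components)))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()        # (features, components)
    for c in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[k, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return PcaModel(loadings, pca.explained_variance_ratio_.copy(),
                    mean.copy(), scores)


def loading_profile(
    model: PcaModel,
    component: int = 0,
    config: FingerprintConfig | None = None,
    threshold_fraction: float = 0.3,
) -> list[LoadingSpan]:
    """Per-category distance spans where a component's loading is large.

    The component's loading vector is reshaped to 7 x n_bins.  For each
    category, bins whose |loading| exceeds ``threshold_fraction`` of the
    global maximum |loading| are found and the contiguous run containing the
    category's peak bin is reported as a distance span (left bin edges), with
    the sign of the loading at the peak.  Categories with no bin above the
    threshold are omitted.
    """
    if config is None:
        config = FingerprintConfig()
    vec = model.loadings[:, component]
    expected = len(CATEGORY_ORDER) * config.n_bins
    if vec.shape[0] != expected:
        raise ValueError(
            f"loading length {vec.shape[0]} is not a fingerprint of "
            f"{expected} bins")
    grid = vec.reshape(len(CATEGORY_ORDER), config.n_bins)
    gmax = np.abs(grid).max()
    if gmax == 0:
        return []
    edges = config.bin_edges()
    spans: list[LoadingSpan] = []
    for ci, cat in enumerate(CATEGORY_ORDER):
        row = grid[ci]
        above = np.abs(row) >= threshold_fraction * gmax
        if not above.any():
            continue
        peak = int(np.argmax(np.abs(row)))
        lo = peak
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = peak
        while hi < config.n_bins - 1 and above[hi + 1]:
            hi += 1
        spans.append(LoadingSpan(cat, float(edges[lo]), float(edges[hi]),
                                 int(np.sign(row[peak])), float(row[peak])))
    return spans


def cluster_mean_pc(
    scores: np.ndarray,
    cluster_labels: Sequence[int],
    ligand_ids: Sequence[str],
    min_poses: int = 3,
    component: int = 0,
) -> dict[int, dict[str, float]]:
    """Per-(cluster, ligand) mean of one PC score.

    Cells with fewer than ``min_poses`` poses are omitted (too few poses to
    define a meaningful cluster-specific binding-mode score).
    """
    s = np.asarray(scores)
    pc = s[:, component] if s.ndim == 2 else s
    df = pd.DataFrame({"pc": pc, "cluster": list(cluster_labels),
                       "ligand": list(ligand_ids)})
    out: dict[int, dict[str, float]] = {}
    grouped = df.groupby(["cluster", "ligand"])["pc"].agg(["mean", "count"])
    for (cid, lig), row in grouped.iterrows():
        if row["count"] < min_poses:
            continue
        out.setdefault(int(cid), {})[str(lig)] = float(row["mean"])
    return out


def affinity_regression(
    means: Mapping[str, float],
    affinities: AffinityTable,
    scale: str = "log10_cd50",
    include_out_of_range: bool = False,
    cluster_id: int = 0,
    site_tag: str = "",
) -> TrendResult:
    """OLS of affinity on per-ligand mean PC1 for one cluster.

    ``scale`` selects log10(CD50) (default: the series spans orders of
    magnitude) or raw CD50 in μM.  Out-of-range (">500 μM") ligands are
    excluded by default; ``include_out_of_range=True`` caps them at the
    assay bound instead (sensitivity analysis).  R² is the squared Pearson
    correlation.  A constant response is degenerate and reported as R² = 0
    with a warning; a constant predictor is an error.
    """
    if scale not in ("raw_cd50", "log10_cd50"):
        raise ValueError("scale must be raw_cd50 or log10_cd50")
    aff = affinities.capped() if include_out_of_range else affinities.numeric()
    ligs = sorted(set(means) & set(aff))
    if len(ligs) < 3:
        raise ValueError(
            f"need >= 3 ligands with both a mean PC1 and a numeric affinity "
            f"(got {len(ligs)})")
    x = np.array([means[l] for l in ligs])
    y = np.array([aff[l] for l in ligs])
    if scale == "log10_cd50":
        y = np.log10(y)
    if np.ptp(x) < 1e-12:
        raise ValueError("zero-variance predictor (all mean PC1 equal)")
    if np.ptp(y) < 1e-12:
        warnings.warn("constant affinity response; reporting R^2 = 0")
        return TrendResult(cluster_id, site_tag, {l: float(means[l]) for l in ligs},
                           0.0, float(y[0]), 0.0, len(ligs), scale)
    fit = stats.linregress(x, y)
    return TrendResult(cluster_id, site_tag,
                       {l: float(means[l]) for l in ligs},
                       float(fit.slope), float(fit.intercept),
                       float(fit.rvalue ** 2), len(ligs), scale)


def rank_clusters(results: Sequence[TrendResult]) -> list[TrendResult]:
    """Descending sort by R²; the top entry is the cluster whose binding
    mode best rationalises the affinity series."""
    if not results:
        raise ValueError("no trend results to rank")
    return sorted(results, key=lambda r: (-r.r_squared, r.site_tag, r.cluster_id))


def trend_table(results: Sequence[TrendResult]) -> pd.DataFrame:
    ranked = rank_clusters(results)
    return pd.DataFrame([
        {"site_tag": r.site_tag, "cluster_id": r.cluster_id,
         "r_squared": r.r_squared, "slope": r.slope,
         "intercept": r.intercept, "n_ligands": r.n_ligands,
         "affinity_scale": r.affinity_scale}
        for r in ranked
    ])
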