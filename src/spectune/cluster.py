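"""Functional clustering of trial-averaged traces: PCA with a
high-frequency-component filter, Gaussian-mixture modeling with BIC model
selection, and per-cluster summaries ordered by IPL depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

__all__ = ["PCAReduction", "ClusterModel", "pca_reduce", "fit_gmm_bic", "summarize_clusters"]


@dataclass
class PCAReduction:
    scores: np.ndarray            # (n_traces, n_kept)
    kept_pc_indices: np.ndarray
    explained_variance_ratio: np.ndarray   # all fitted PCs
    pca: PCA

    @property
    def variance_explained_pct(self) -> float:
        """Cumulative variance captured by all fitted components (%)."""
        return 100.0 * float(self.explained_variance_ratio.sum())


@dataclass
class ClusterModel:
    """A BIC-selected Gaussian-mixture clustering, clusters ordered by mean
    IPL depth (ascending from the INL-adjacent border when depths given)."""

    labels: np.ndarray
    n_clusters: int
    cluster_means: np.ndarray          # (n_clusters, T) trace space
    cluster_ipl_mean: np.ndarray       # (n_clusters,), NaN without depths
    bic_curve: dict[int, float]
    n_components_pca: int
    kept_pc_indices: np.ndarray
    seed: int
    gmm: GaussianMixture | None = None

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def pca_reduce(
    traces: np.ndarray,
    n_pc: int = 48,
    rate_hz: float = 42.0,
    hf_cutoff_hz: float = 2.0,
    hf_power_frac: float = 0.6,
) -> PCAReduction:
    """Project traces onto their first ``n_pc`` principal components,
    discarding components that near-exclusively carry high-frequency content
    (> ``hf_power_frac`` of spectral power above ``hf_cutoff_hz``)."""
    X = np.asarray(traces, float)
    if X.ndim != 2:
        raise ValueError("traces must be (n_traces, T)")
    n, T = X.shape
    if n_pc > T:
        raise ValueError(f"n_pc={n_pc} exceeds trace length {T}")
    n_fit = min(n_pc, n, T)
    pca = PCA(n_components=n_fit, svd_solver="full")
    scores = pca.fit_transform(X)

    freqs = np.fft.rfftfreq(T, d=1.0 / rate_hz)
    kept = []
    for i, comp in enumerate(pca.components_):
        power = np.abs(np.fft.rfft(comp)) ** 2
        total = power.sum()
        frac_hi = power[freqs > hf_cutoff_hz].sum() / total if total > 0 else 0.0
        if frac_hi <= hf_power_frac:
            kept.append(i)
        else:
            log.info("discarding PC %d: %.0f%% power above %.1f Hz",
                     i, 100 * frac_hi, hf_cutoff_hz)
    kept = np.asarray(kept, int)
    return PCAReduction(
        scores=scores[:, kept],
        kept_pc_indices=kept,
        explained_variance_ratio=pca.explained_variance_ratio_,
        pca=pca,
    )


def fit_gmm_bic(
    scores: np.ndarray,
    k_range=range(1, 41),
    n_init: int = 10,
    seed: int = 0,
    traces: np.ndarray | None = None,
    depths: np.ndarray | None = None,
    covariance_type: str = "full",
) -> ClusterModel:
    """Fit Gaussian mixtures over ``k_range`` and keep the BIC minimum.

    ``traces`` (if given) supply the space in which cluster means are
    reported; ``depths`` order the clusters by mean IPL position. Singular
    covariances fall back to a stronger regularization (logged).
    """
    X = np.asarray(scores, float)
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")

    bic_curve: dict[int, float] = {}
    best = None
    for k in ks:
        gmm = _fit_one_gmm(X, k, n_init, seed, covariance_type)
        bic_curve[k] = float(gmm.bic(X))
        if best is None or bic_curve[k] < bic_curve[best[0]]:
            best = (k, gmm)
    k_best, gmm = best
    labels = gmm.predict(X)

    # drop empty mixture components so labels are contiguous
    present = np.unique(labels)
    remap = {old: new for new, old in enumerate(present)}
    labels = np.array([remap[l] for l in labels])
    n_clusters = len(present)

    space = np.asarray(traces, float) if traces is not None else X
    means = np.vstack([space[labels == c].mean(axis=0) for c in range(n_clusters)])
    if depths is not None:
        depths = np.asarray(depths, float)
        ipl_mean = np.array([depths[labels == c].mean() for c in range(n_clusters)])
        order = np.argsort(ipl_mean)
        relabel = np.empty(n_clusters, int)
        relabel[order] = np.arange(n_clusters)
        labels = relabel[labels]
        means = means[order]
        ipl_mean = ipl_mean[order]
    else:
        ipl_mean = np.full(n_clusters, np.nan)

    return ClusterModel(
        labels=labels,
        n_clusters=n_clusters,
        cluster_means=means,
        cluster_ipl_mean=ipl_mean,
        bic_curve=bic_curve,
        n_components_pca=X.shape[1],
        kept_pc_indices=np.arange(X.shape[1]),
        seed=seed,
        gmm=gmm,
    )


def _fit_one_gmm(X, k, n_init, seed, covariance_type):
    for reg in (1e-6, 1e-3, 1e-1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gmm = GaussianMixture(
                    n_components=k,
                    covariance_type=covariance_type,
                    n_init=n_init,
                    random_state=seed,
                    reg_covar=reg,
                )
                gmm.fit(X)
            if reg > 1e-6:
                log.warning("GMM k=%d needed reg_covar=%g", k, reg)
            return gmm
        except (np.linalg.LinAlgError, ValueError):
            continue
    raise np.linalg.LinAlgError(f"GMM fit failed for k={k} at all regularizations")


def summarize_clusters(
    model: ClusterModel,
    depths: np.ndarray,
    regions: np.ndarray,
    depth_bins: int = 20,
    region_order=("AZ", "D", "N", "V"),
):
    """Per-cluster mean trace, area-normalized IPL-depth histogram, and
    region distribution normalized per region. Empty clusters are excluded
    with a warning."""
    depths = np.asarray(depths, float)
    regions = np.asarray(regions)
    edges = np.linspace(0.0, 1.0, depth_bins + 1)
    width = edges[1] - edges[0]

    ipl_hist = np.zeros((model.n_clusters, depth_bins))
    region_counts = np.zeros((model.n_clusters, len(region_order)))
    for c in range(model.n_clusters):
        sel = model.labels == c
        if not sel.any():
            warnings.warn(f"cluster {c} is empty; excluded from summaries")
            continue
        h, _ = np.histogram(depths[sel], bins=edges)
        total = h.sum()
        if total > 0:
            ipl_hist[c] = h / (total * width)  # area-normalized density
        for r, reg in enumerate(region_order):
            region_counts[c, r] = np.sum(regions[sel] == reg)
    region_totals = region_counts.sum(axis=0)
    region_hist = np.divide(
        region_counts,
        np.where(region_totals > 0, region_totals, 1.0),
        out=np.zeros_like(region_counts),
        where=region_totals > 0,
    )
    return {
        "cluster_means": model.cluster_means,
        "ipl_hist": ipl_hist,
        "ipl_bin_edges": edges,
        "region_hist": region_hist,
        "region_order": tuple(region_order),
    }
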