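"""Spectral tuning analysis: bulk tunings from cone weights, zero crossings,
opponency classification, six spectral groups, reconstruction-quality
metrics, weight statistics/correlations, IPL-depth weight histograms and
randomization controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from spectune.decompose import ConeWeightMatrix
from spectune.synthetic import CONE_ORDER, COMPONENT_ORDER, ConeTuningSet

log = logging.getLogger(__name__)

__all__ = [
    "SpectralTuning",
    "FitQuality",
    "CorrelationResult",
    "SPECTRAL_GROUPS",
    "bulk_tuning",
    "find_zero_crossings",
    "classify_opponency",
    "assign_spectral_group",
    "zero_crossing_histogram",
    "randomization_controls",
    "trimodality_score",
    "variance_explained",
    "power_explained",
    "weight_statistics",
    "weight_correlations",
    "weight_ipl_histogram",
]

SPECTRAL_GROUPS = (
    "broad",
    "uv-cone-like",
    "red-cone-like",
    "green-opponent",
    "blue-opponent",
    "uv-opponent",
)

OPPONENCY_THRESHOLD = 0.10
GREEN_CUT_NM = 510.0
BLUE_CUT_NM = 470.0


@dataclass
class SpectralTuning:
    """A weight-derived bulk spectral tuning with its classification."""

    curve: np.ndarray
    wavelength_grid_nm: np.ndarray
    zero_crossings_nm: list[float] = field(default_factory=list)
    qualifying_crossings_nm: list[float] = field(default_factory=list)
    is_opponent: bool = False
    opponency_threshold: float = OPPONENCY_THRESHOLD
    spectral_group: str | None = None
    per_component_curves: np.ndarray | None = None   # (4, n_wavelengths)


@dataclass
class FitQuality:
    """Reconstruction-quality percentages (variance and band-limited power)."""

    variance_explained_pct: float | None = None
    residual_variance_pct: float | None = None
    power_explained_pct: float | None = None
    residual_power_pct: float | None = None
    band_hz: tuple[float, float] = (0.16, 2.0)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    ci95: tuple[float, float]
    basis: str = "per-cluster mean weights"


def _weights_array(W) -> np.ndarray:
    if isinstance(W, ConeWeightMatrix):
        return W.w
    return np.asarray(W, float)


def bulk_tuning(W, cone_set: ConeTuningSet) -> np.ndarray:
    """Sum the 16 weight-scaled cone tunings, equal weight per temporal
    component: curve(lambda) = sum_c sum_k w[c,k] * S_c(lambda)."""
    arr = _weights_array(W)
    return cone_set.as_matrix() @ arr.sum(axis=1)


def per_component_tunings(W, cone_set: ConeTuningSet) -> np.ndarray:
    """(4, n_wavelengths): one spectral tuning per temporal component."""
    arr = _weights_array(W)
    return (cone_set.as_matrix() @ arr).T


def find_zero_crossings(curve: np.ndarray, wavelength_grid_nm: np.ndarray) -> list[float]:
    """Sign-change locations (linear interpolation between grid nodes), nm."""
    f = np.asarray(curve, float)
    lam = np.asarray(wavelength_grid_nm, float)
    if not np.all(np.isfinite(f)):
        raise ValueError("curve must be finite")
    out: list[float] = []
    for i in range(len(f) - 1):
        a, b = f[i], f[i + 1]
        if a == 0.0:
            if 0 < i and f[i - 1] * b < 0:
                out.append(float(lam[i]))
        elif a * b < 0:
            out.append(float(lam[i] - a * (lam[i + 1] - lam[i]) / (b - a)))
    if f[-1] == 0.0 and len(f) > 1 and f[-2] != 0.0:
        pass  # terminal touch, not a crossing
    return out


def classify_opponency(
    curve: np.ndarray,
    wavelength_grid_nm: np.ndarray,
    threshold: float = OPPONENCY_THRESHOLD,
):
    """Opponent iff the curve crosses zero and overshoots to at least
    ``threshold`` (inclusive) of the dominant-polarity peak.

    Returns ``(is_opponent, qualifying_crossings_nm)`` where qualifying
    crossings bound opposite-polarity lobes that meet the threshold.
    """
    f = np.asarray(curve, float)
    lam = np.asarray(wavelength_grid_nm, float)
    if not np.any(f):
        raise ValueError("cannot classify an all-zero curve")
    ipk = int(np.argmax(np.abs(f)))
    dom_sign = np.sign(f[ipk])
    dom_peak = abs(f[ipk])
    crossings = find_zero_crossings(f, lam)
    if not crossings:
        return False, []

    # segment the grid at crossings; lobes of opposite polarity qualify when
    # their extremum reaches threshold * dominant peak (inclusive)
    bounds = [lam[0]] + crossings + [lam[-1]]
    qualifying: set[float] = set()
    tol = 1e-9 * dom_peak
    for s in range(len(bounds) - 1):
        sel = (lam >= bounds[s]) & (lam <= bounds[s + 1])
        seg = f[sel]
        if seg.size == 0:
            continue
        if dom_sign * seg.min() < 0 or dom_sign * seg.max() < 0:
            overshoot = np.max(-dom_sign * seg)
            if overshoot >= threshold * dom_peak - tol:
                if s > 0:
                    qualifying.add(bounds[s])
                if s < len(bounds) - 2:
                    qualifying.add(bounds[s + 1])
    qual = sorted(qualifying)
    return bool(qual), qual


def dominant_crossing(curve, wavelength_grid_nm, threshold=OPPONENCY_THRESHOLD):
    """The qualifying crossing flanked by the largest pair of
    opposite-polarity lobes (None for non-opponent curves).

    Each crossing is scored by the smaller of the two extrema in its adjacent
    inter-crossing segments, so minor satellite lobes cannot claim the
    crossing that separates the two dominant lobes.
    """
    f = np.asarray(curve, float)
    lam = np.asarray(wavelength_grid_nm, float)
    is_opp, qual = classify_opponency(f, lam, threshold)
    if not is_opp:
        return None
    crossings = find_zero_crossings(f, lam)
    bounds = [lam[0]] + crossings + [lam[-1]]
    seg_amp = []
    for s in range(len(bounds) - 1):
        sel = (lam >= bounds[s]) & (lam <= bounds[s + 1])
        seg_amp.append(np.max(np.abs(f[sel])) if sel.any() else 0.0)
    best, best_score = None, -np.inf
    for x in qual:
        i = crossings.index(x)
        score = min(seg_amp[i], seg_amp[i + 1])
        if score > best_score:
            best_score, best = score, x
    return best


def assign_spectral_group(
    tuning: SpectralTuning,
    cone_set: ConeTuningSet,
    green_cut_nm: float = GREEN_CUT_NM,
    blue_cut_nm: float = BLUE_CUT_NM,
) -> str:
    """Assign one of the six spectral groups.

    Opponent tunings go by the dominant crossing position (>= 510 nm green-,
    [470, 510) blue-, < 470 nm uv-opponent); non-opponent tunings by highest
    (sign-invariant) cosine similarity to the red template, the UV template
    or a flat broadband reference. Ties break toward 'broad' (logged).
    """
    lam = tuning.wavelength_grid_nm
    if tuning.is_opponent:
        x = dominant_crossing(tuning.curve, lam, tuning.opponency_threshold)
        if x is None:  # pragma: no cover - guarded by is_opponent
            raise ValueError("opponent tuning without qualifying crossing")
        if x >= green_cut_nm:
            return "green-opponent"
        if x >= blue_cut_nm:
            return "blue-opponent"
        return "uv-opponent"

    refs = {
        "red-cone-like": cone_set.tuning["red"],
        "uv-cone-like": cone_set.tuning["uv"],
        "broad": np.ones_like(lam, dtype=float),
    }
    f = tuning.curve
    sims = {
        name: abs(float(np.dot(f, r)) / (np.linalg.norm(f) * np.linalg.norm(r)))
        for name, r in refs.items()
    }
    ranked = sorted(sims.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and np.isclose(ranked[0][1], ranked[1][1]):
        log.info("spectral-group tie (%s); assigning 'broad'", ranked[:2])
        return "broad"
    return ranked[0][0]


def analyze_tuning(W, cone_set: ConeTuningSet, threshold=OPPONENCY_THRESHOLD) -> SpectralTuning:
    """Full per-cluster tuning analysis: curve, crossings, opponency, group."""
    lam = cone_set.wavelength_grid_nm
    curve = bulk_tuning(W, cone_set)
    tuning = SpectralTuning(
        curve=curve,
        wavelength_grid_nm=lam,
        zero_crossings_nm=find_zero_crossings(curve, lam),
        per_component_curves=per_component_tunings(W, cone_set),
        opponency_threshold=threshold,
    )
    if np.any(curve):
        tuning.is_opponent, tuning.qualifying_crossings_nm = classify_opponency(
            curve, lam, threshold
        )
        tuning.spectral_group = assign_spectral_group(tuning, cone_set)
    return tuning


def zero_crossing_histogram(
    tunings: list[SpectralTuning],
    roi_counts: np.ndarray,
    mode: str = "bulk",
    bin_edges: np.ndarray | None = None,
):
    """ROI-abundance-weighted histogram of dominant zero crossings.

    ``bulk`` mode contributes one crossing per opponent cluster (total mass
    equals the summed ROI counts of opponent clusters); ``per_component``
    uses each temporal component's own tuning curve.
    """
    if bin_edges is None:
        bin_edges = np.arange(360.0, 615.0, 5.0)
    counts = np.asarray(roi_counts, float)
    hist = np.zeros(len(bin_edges) - 1)
    for tuning, n in zip(tunings, counts):
        lam = tuning.wavelength_grid_nm
        if mode == "bulk":
            curves = [tuning.curve]
        elif mode == "per_component":
            if tuning.per_component_curves is None:
                raise ValueError("per_component mode needs per-component curves")
            curves = list(tuning.per_component_curves)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for curve in curves:
            if not np.any(curve):
                continue
            x = dominant_crossing(curve, lam, tuning.opponency_threshold)
            if x is not None:
                i = np.clip(np.searchsorted(bin_edges, x, side="right") - 1,
                            0, len(hist) - 1)
                hist[i] += n
    return hist, bin_edges


def randomization_controls(
    weights: np.ndarray,
    cone_set: ConeTuningSet,
    roi_counts: np.ndarray,
    mode: str = "shuffle_across_cones",
    n_iter: int = 20,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
):
    """Null zero-crossing histograms from weight randomization.

    ``randomize`` permutes all weight values across the whole population;
    ``shuffle_across_cones`` permutes each cluster's 4-component weight rows
    among the cones. Returns ``(null_hists, bin_edges)`` with one histogram
    per iterate.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    W = np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    if bin_edges is None:
        bin_edges = np.arange(360.0, 615.0, 5.0)
    hists = []
    for _ in range(n_iter):
        if mode == "randomize":
            flat = W.reshape(-1).copy()
            rng.shuffle(flat)
            Wn = flat.reshape(W.shape)
        elif mode == "shuffle_across_cones":
            Wn = np.stack([w[rng.permutation(4), :] for w in W])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        tunings = [analyze_tuning(w, cone_set) for w in Wn]
        h, _ = zero_crossing_histogram(tunings, roi_counts, "bulk", bin_edges)
        hists.append(h)
    return np.asarray(hists), bin_edges


def trimodality_score(hist: np.ndarray, smooth_bins: float = 1.0) -> float:
    """Peak-to-trough ratio of the smoothed histogram: mean of the top three
    peaks over the mean trough between them (large = strongly multimodal)."""
    h = ndimage.gaussian_filter1d(np.asarray(hist, float), smooth_bins)
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(h)
    if peaks.size == 0:
        return 0.0
    top = peaks[np.argsort(h[peaks])[-3:]]
    top = np.sort(top)
    if len(top) == 1:
        troughs = [h[h > 0].min() if np.any(h > 0) else 0.0]
    else:
        troughs = [h[top[i]: top[i + 1] + 1].min() for i in range(len(top) - 1)]
    eps = 1e-12 + 1e-3 * h.max()
    return float(h[top].mean() / (np.mean(troughs) + eps))


def variance_explained(
    cluster_means: np.ndarray, reconstructions: np.ndarray
) -> FitQuality:
    """Across-cluster per-time-point variance captured by reconstructions and
    residuals, as a percentage of the original AUC."""
    orig = np.asarray(cluster_means, float)
    recon = np.asarray(reconstructions, float)
    if orig.shape != recon.shape:
        raise ValueError("cluster_means and reconstructions must share shape")
    v_orig = orig.var(axis=0)
    auc = v_orig.sum()
    if auc == 0.0:
        raise ValueError("original traces carry zero across-cluster variance")
    v_recon = recon.var(axis=0)
    v_resid = (orig - recon).var(axis=0)
    return FitQuality(
        variance_explained_pct=100.0 * v_recon.sum() / auc,
        residual_variance_pct=100.0 * v_resid.sum() / auc,
    )


def power_explained(
    cluster_means: np.ndarray,
    reconstructions: np.ndarray,
    rate_hz: float = 42.0,
    band_hz: tuple[float, float] = (0.16, 2.0),
) -> FitQuality:
    """Cluster-averaged magnitude-squared Fourier power in ``band_hz``
    captured by reconstructions and residuals, vs the originals (can exceed
    100%)."""
    orig = np.asarray(cluster_means, float)
    recon = np.asarray(reconstructions, float)
    if orig.shape != recon.shape:
        raise ValueError("shapes must match")
    if band_hz[1] > rate_hz / 2 or band_hz[0] >= band_hz[1]:
        raise ValueError("band must lie within the Nyquist range")

    def band_power(X):
        X = X - X.mean(axis=1, keepdims=True)
        P = np.abs(np.fft.rfft(X, axis=1)) ** 2
        freqs = np.fft.rfftfreq(X.shape[1], d=1.0 / rate_hz)
        sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
        return P[:, sel].mean(axis=0)

    p_orig = band_power(orig)
    auc = p_orig.sum()
    if auc == 0.0:
        raise ValueError("original traces carry zero band power")
    return FitQuality(
        power_explained_pct=100.0 * band_power(recon).sum() / auc,
        residual_power_pct=100.0 * band_power(orig - recon).sum() / auc,
        band_hz=band_hz,
    )


def _weights_3d(weight_table) -> np.ndarray:
    if isinstance(weight_table, pd.DataFrame):
        cols = [f"w_{c}_{k}" for c in CONE_ORDER for k in COMPONENT_ORDER]
        return weight_table[cols].to_numpy(float).reshape(-1, 4, 4)
    W = np.asarray(weight_table, float)
    if W.ndim == 2 and W.shape[1] == 16:
        return W.reshape(-1, 4, 4)
    if W.ndim == 3 and W.shape[1:] == (4, 4):
        return W
    raise ValueError("weight table must be (n, 16) or (n, 4, 4)")


def weight_statistics(weight_table, test: str = "signed_rank"):
    """Absolute-weight summaries per cone and per temporal component
    (mean +/- SD over all clusters x components) plus paired rank tests for
    every cone pair.

    ``test='signed_rank'`` (default) pairs |w| values over
    (cluster, component); ``'rank_sum'`` uses the unpaired test instead.
    """
    W = _weights_3d(weight_table)
    if W.shape[0] < 2:
        raise ValueError("need >= 2 clusters")
    absW = np.abs(W)
    per_cone = pd.DataFrame(
        {
            "cone": CONE_ORDER,
            "mean_abs_w": absW.mean(axis=(0, 2)),
            "sd_abs_w": absW.std(axis=(0, 2)),
        }
    )
    per_component = pd.DataFrame(
        {
            "component": COMPONENT_ORDER,
            "mean_abs_w": absW.mean(axis=(0, 1)),
            "sd_abs_w": absW.std(axis=(0, 1)),
        }
    )
    rows = []
    for a in range(4):
        for b in range(a + 1, 4):
            x = absW[:, a, :].reshape(-1)
            y = absW[:, b, :].reshape(-1)
            if test == "signed_rank":
                d = x - y
                if np.all(d == 0):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(x, y).pvalue)
            elif test == "rank_sum":
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append(
                {"cone_a": CONE_ORDER[a], "cone_b": CONE_ORDER[b], "p_value": p}
            )
    return {"per_cone": per_cone, "per_component": per_component,
            "pairwise_tests": pd.DataFrame(rows)}


def weight_correlations(weight_table) -> list[CorrelationResult]:
    """Pearson correlations (with Fisher-z 95% CIs) between per-cluster mean
    cone weights, for all six cone pairs."""
    W = _weights_3d(weight_table)
    n = W.shape[0]
    if n < 4:
        raise ValueError("need >= 4 clusters for correlations")
    m = W.mean(axis=2)   # (n, 4) per-cluster mean weight per cone
    out = []
    for a in range(4):
        for b in range(a + 1, 4):
            rho = float(stats.pearsonr(m[:, a], m[:, b]).statistic)
            z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
            se = 1.0 / np.sqrt(n - 3)
            lo, hi = np.tanh(z - 1.959963985 * se), np.tanh(z + 1.959963985 * se)
            out.append(
                CorrelationResult(
                    pair=(CONE_ORDER[a], CONE_ORDER[b]),
                    rho=rho,
                    ci95=(float(lo), float(hi)),
                )
            )
    return out


def weight_ipl_histogram(
    weight_table,
    depths: np.ndarray,
    combine: str = "light",
    near_zero_threshold: float = 0.5,
    depth_bins: int = 10,
    weight_bins: np.ndarray | None = None,
    on_depth_min: float = 0.5,
):
    """2-D (weight x IPL depth) histogram per cone for the combined light
    (L_tr + L_sus) or dark (D_tr + D_sus) weights, excluding near-zero
    combined weights, plus the polarity-violation fraction per depth tercile.

    Classical lamination puts Off circuits in the upper IPL (depth <
    ``on_depth_min``) and On circuits below; a positive (sign-inverting,
    "On") light weight in the Off sublamina — or vice versa — counts as a
    violation. For dark weights the expectation flips.
    """
    W = _weights_3d(weight_table)
    depths = np.asarray(depths, float)
    if np.any(depths < 0) or np.any(depths > 1):
        raise ValueError("depths must lie in [0, 1]")
    if combine == "light":
        combined = W[:, :, 0] + W[:, :, 1]
    elif combine == "dark":
        combined = W[:, :, 2] + W[:, :, 3]
    else:
        raise ValueError("combine must be 'light' or 'dark'")

    if weight_bins is None:
        lim = max(1.0, np.abs(combined).max())
        weight_bins = np.linspace(-lim, lim, 21)
    depth_edges = np.linspace(0.0, 1.0, depth_bins + 1)

    hists = {}
    violations = []
    terciles = np.array([0.0, 1 / 3, 2 / 3, 1.0])
    for c, cone in enumerate(CONE_ORDER):
        w = combined[:, c]
        keep = np.abs(w) >= near_zero_threshold
        h, _, _ = np.histogram2d(w[keep], depths[keep],
                                 bins=(weight_bins, depth_edges))
        hists[cone] = h
        expected_on = depths >= on_depth_min
        if combine == "light":
            viol = np.where(expected_on, w < 0, w > 0)
        else:
            viol = np.where(expected_on, w > 0, w < 0)
        viol = viol & keep
        for t in range(3):
            sel = keep & (depths >= terciles[t]) & (depths < terciles[t + 1] + (t == 2))
            frac = float(viol[sel].sum() / sel.sum()) if sel.sum() else 0.0
            violations.append(
                {"cone": cone, "tercile": t, "violation_frac": frac,
                 "n": int(sel.sum())}
            )
    return {
        "hists": hists,
        "weight_bin_edges": weight_bins,
        "depth_bin_edges": depth_edges,
        "violations": pd.DataFrame(violations),
    }
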