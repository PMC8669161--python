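"""Linear decomposition of flash responses into cone spectral tunings x
temporal components.

Each trial-averaged trace is projected, flash by flash, onto four
flash-locked temporal kernels (a 4 x 10 array over the central 10 LEDs); the
resulting per-component spectral curves are interpolated onto the 360-610 nm
grid and expressed as lasso-regularized linear combinations of the four cone
tuning functions, yielding 4 cones x 4 components = 16 signed weights.

Sign convention: a positive weight denotes a sign-inverting ("On"-like)
effective cone input, a negative weight a sign-conserving ("Off"-like) one;
the cone templates are stored in response polarity so that the regression
returns weights directly in this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF
from sklearn.linear_model import Lasso, LassoCV

from spectune.synthetic import (
    CONE_ORDER,
    COMPONENT_ORDER,
    ConeTuningSet,
    StimulusProtocol,
    TemporalBasis,
)

__all__ = [
    "FlashDecomposition",
    "ConeWeightMatrix",
    "Reconstruction",
    "extract_temporal_basis_nmf",
    "decompose_response",
    "interpolate_tuning",
    "fit_cone_weights",
    "fit_trace_weights",
    "normalize_weights",
    "reconstruct",
]

NEAR_ZERO_THRESHOLD = 0.5


class ConditioningError(np.linalg.LinAlgError):
    """Regressors too collinear/degenerate to fit."""


@dataclass
class FlashDecomposition:
    """Per-flash kernel coefficients: 4 temporal components x 10 central LEDs."""

    coeffs: np.ndarray                       # (4, 10)
    component_order: tuple[str, ...] = COMPONENT_ORDER
    led_subset: tuple[int, ...] = tuple(range(2, 12))

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, float)
        if self.coeffs.shape != (4, len(self.led_subset)):
            raise ValueError(
                f"coeffs must be 4 x {len(self.led_subset)}, got {self.coeffs.shape}"
            )


@dataclass
class ConeWeightMatrix:
    """4 cones x 4 temporal components of signed effective input weights."""

    w: np.ndarray                            # (4, 4) cones x components
    cone_order: tuple[str, ...] = CONE_ORDER
    component_order: tuple[str, ...] = COMPONENT_ORDER
    normalized: bool = False
    near_zero_threshold: float = NEAR_ZERO_THRESHOLD

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, float)
        if self.w.shape != (4, 4):
            raise ValueError("weight matrix must be 4 x 4")

    def near_zero_mask(self) -> np.ndarray:
        """|w| < threshold: de-emphasized in summaries/plots, never in fits."""
        return np.abs(self.w) < self.near_zero_threshold

    def flat(self) -> np.ndarray:
        return self.w.reshape(-1)


def extract_temporal_basis_nmf(
    cluster_means: np.ndarray,
    protocol: StimulusProtocol,
    n_components: int = 4,
    seed: int = 0,
    n_restarts: int = 20,
    rate_hz: float | None = None,
    max_iter: int = 2000,
) -> TemporalBasis:
    """Extract the four flash-locked temporal kernels by NMF across all
    flash-aligned snippets of the cluster means.

    Traces must cover the stimulus window (no baseline) at ``rate_hz``.
    Snippets are shifted by their minimum to non-negativity; the
    multiplicative-update solver is restarted ``n_restarts`` times keeping the
    lowest reconstruction error. Kernels come back non-negative, unit-norm and
    labeled L_tr / L_sus / D_tr / D_sus by On/Off-window support mass and
    peak-to-plateau ratio.
    """
    rate = protocol.resample_rate_hz if rate_hz is None else rate_hz
    X = np.asarray(cluster_means, float)
    if X.ndim == 1:
        X = X[None]
    nper = protocol.n_flash_samples(rate)
    n_flashes = X.shape[1] // nper
    if n_flashes < 1:
        raise ValueError("traces shorter than one flash period")

    snippets = X[:, : n_flashes * nper].reshape(-1, nper)
    keep = snippets.std(axis=1) > 1e-12
    snippets = snippets[keep]
    if snippets.size == 0:
        raise ValueError("no non-constant flash snippets to factorize")
    snippets = snippets - snippets.min(axis=1, keepdims=True)

    best_err, best_H = np.inf, None
    for r in range(n_restarts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NMF(
                n_components=n_components,
                init="random",
                solver="mu",
                max_iter=max_iter,
                random_state=seed + r,
            )
            model.fit(snippets)
        if model.reconstruction_err_ < best_err:
            best_err = model.reconstruction_err_
            best_H = model.components_.copy()
    if best_H is None or not np.isfinite(best_err):
        raise RuntimeError(
            f"NMF did not converge (best error {best_err!r}, "
            f"{len(snippets)} snippets of {nper} samples)"
        )

    kernels = _label_kernels(best_H, protocol.n_on_samples(rate))
    kernels /= np.linalg.norm(kernels, axis=1, keepdims=True)
    return TemporalBasis(kernels=kernels, rate_hz=rate)


def _label_kernels(H: np.ndarray, n_on: int) -> np.ndarray:
    """Order NMF components as (L_tr, L_sus, D_tr, D_sus).

    Light vs dark by support mass in the On window; transient vs sustained by
    the end-of-window plateau relative to the in-window peak.
    """
    light_mass = H[:, :n_on].sum(axis=1) / np.maximum(H.sum(axis=1), 1e-30)
    order = np.argsort(-light_mass)
    light_idx, dark_idx = list(order[:2]), list(order[2:])

    def sustain_ratio(k: np.ndarray, window: slice) -> float:
        seg = k[window]
        peak = seg.max()
        return float(seg[-1] / peak) if peak > 0 else 0.0

    light_idx.sort(key=lambda i: sustain_ratio(H[i], slice(0, n_on)))
    dark_idx.sort(key=lambda i: sustain_ratio(H[i], slice(n_on, H.shape[1])))
    return np.maximum(H[light_idx + dark_idx], 0.0)


def decompose_response(
    trace_mean: np.ndarray,
    basis: TemporalBasis,
    protocol: StimulusProtocol,
    cond_max: float = 1e8,
) -> FlashDecomposition:
    """Project each central-LED flash period of a (baseline-stripped)
    trial-averaged trace onto the four kernels by least squares, giving signed
    coefficients in a 4 x 10 array."""
    trace = np.asarray(trace_mean, float)
    rate = basis.rate_hz
    nper = protocol.n_flash_samples(rate)
    needed = (max(protocol.central_led_indices) + 1) * nper
    if len(trace) < needed:
        raise ValueError(
            f"trace of {len(trace)} samples does not cover the central flashes "
            f"({needed} needed)"
        )
    B = basis.kernels
    G = B @ B.T
    if np.linalg.cond(G) > cond_max:
        raise ConditioningError("temporal kernels are collinear beyond tolerance")
    coeffs = np.empty((4, len(protocol.central_led_indices)))
    for j, f in enumerate(protocol.central_led_indices):
        seg = trace[f * nper : (f + 1) * nper]
        coeffs[:, j] = np.linalg.solve(G, B @ seg)
    return FlashDecomposition(
        coeffs=coeffs, led_subset=tuple(protocol.central_led_indices)
    )


def interpolate_tuning(
    coeff_row: np.ndarray,
    led_peaks_nm: np.ndarray,
    wavelength_grid_nm: np.ndarray | None = None,
) -> np.ndarray:
    """Linearly interpolate per-LED coefficients onto the 360-610 nm grid
    (ascending wavelength; constant extrapolation beyond the outermost LEDs)."""
    if wavelength_grid_nm is None:
        wavelength_grid_nm = np.arange(360.0, 611.0)
    vals = np.asarray(coeff_row, float)
    peaks = np.asarray(led_peaks_nm, float)
    if len(vals) != len(peaks) or len(peaks) < 2:
        raise ValueError("need >= 2 matching LED points")
    order = np.argsort(peaks)
    return np.interp(wavelength_grid_nm, peaks[order], vals[order])


def _select_lambda_cv(X: np.ndarray, Y: np.ndarray, seed: int = 0) -> float:
    """5-fold CV on the four tuning curves jointly (stacked block system)."""
    Xs = np.vstack([X] * Y.shape[0])
    ys = Y.reshape(-1)
    cv = LassoCV(fit_intercept=False, cv=5, alphas=30, max_iter=50_000,
                 random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv.fit(Xs, ys)
    # convert sklearn's alpha back to the unnormalized-objective lambda
    return float(cv.alpha_ * 2 * Xs.shape[0] / Y.shape[0])


def fit_cone_weights(
    tunings: np.ndarray,
    cone_set: ConeTuningSet,
    lasso_lambda: float | str = "cv",
    seed: int = 0,
    fit_range_nm: tuple[float, float] | None = None,
) -> ConeWeightMatrix:
    """Fit the 16 cone weights: per temporal component k, solve

        argmin_w  || tau_k - sum_c w[c,k] S_c ||^2 + lambda ||w||_1

    with no intercept. ``tunings`` is (4, n_wavelengths), rows in component
    order; ``lasso_lambda='cv'`` selects lambda by 5-fold cross-validation on
    the four curves jointly. ``fit_range_nm`` optionally restricts the fitted
    wavelengths (e.g. to the span of the central LEDs, avoiding the
    constant-extrapolation edges of interpolated tunings). Returns the
    unnormalized weight matrix (apply :func:`normalize_weights` for the
    mean-|w| = 1 copy).
    """
    Y = np.asarray(tunings, float)
    if Y.ndim != 2 or Y.shape[0] != 4:
        raise ValueError("tunings must be (4, n_wavelengths)")
    X = cone_set.as_matrix()
    if X.shape[0] != Y.shape[1]:
        raise ValueError("tunings and cone_set must share the wavelength grid")
    if fit_range_nm is not None:
        sel = (cone_set.wavelength_grid_nm >= fit_range_nm[0]) & (
            cone_set.wavelength_grid_nm <= fit_range_nm[1]
        )
        if sel.sum() < 4:
            raise ValueError("fit_range_nm leaves fewer wavelengths than cones")
        X, Y = X[sel], Y[:, sel]
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > 1e10:
        raise ConditioningError("cone tuning set is rank-deficient")

    if lasso_lambda == "cv":
        lam = _select_lambda_cv(X, Y, seed=seed)
    else:
        lam = float(lasso_lambda)
    # sklearn's Lasso minimizes (1/2n)||y - Xw||^2 + alpha ||w||_1
    alpha = max(lam / (2 * X.shape[0]), 1e-15)

    W = np.empty((4, 4))
    for k in range(4):
        if not np.any(Y[k]):
            W[:, k] = 0.0
            continue
        model = Lasso(alpha=alpha, fit_intercept=False, max_iter=100_000, tol=1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, Y[k])
        W[:, k] = model.coef_
    return ConeWeightMatrix(w=W, normalized=False)


def normalize_weights(W: ConeWeightMatrix | np.ndarray) -> ConeWeightMatrix:
    """Rescale so the mean of the 16 absolute weights equals one (signs kept)."""
    arr = W.w if isinstance(W, ConeWeightMatrix) else np.asarray(W, float)
    m = np.abs(arr).mean()
    if m == 0.0:
        raise ValueError("cannot normalize an all-zero weight matrix")
    return ConeWeightMatrix(w=arr / m, normalized=True)


def fit_trace_weights(
    trace_mean: np.ndarray,
    basis: TemporalBasis,
    protocol: StimulusProtocol,
    cone_set: ConeTuningSet,
    lasso_lambda: float | str = 1e-4,
    seed: int = 0,
    restrict_to_led_span: bool = True,
) -> ConeWeightMatrix:
    """Full per-trace chain: flash decomposition -> spectral interpolation ->
    lasso cone-weight fit (restricted to the central-LED wavelength span by
    default)."""
    fd = decompose_response(trace_mean, basis, protocol)
    peaks = np.asarray(protocol.led_peaks_nm)[list(fd.led_subset)]
    tunings = np.vstack(
        [
            interpolate_tuning(fd.coeffs[k], peaks, cone_set.wavelength_grid_nm)
            for k in range(4)
        ]
    )
    fit_range = (peaks.min(), peaks.max()) if restrict_to_led_span else None
    return fit_cone_weights(
        tunings, cone_set, lasso_lambda=lasso_lambda, seed=seed,
        fit_range_nm=fit_range,
    )


@dataclass
class Reconstruction:
    """Weight-based reconstruction over the central flashes, with the 16
    cone x component sub-traces and the per-cone totals."""

    full: np.ndarray          # (T,)
    per_cone: np.ndarray      # (4, T)
    sub_traces: np.ndarray    # (4, 4, T) cones x components x time
    rate_hz: float


def reconstruct(
    W: ConeWeightMatrix | np.ndarray,
    cone_set: ConeTuningSet,
    basis: TemporalBasis,
    protocol: StimulusProtocol,
) -> Reconstruction:
    """Forward-sum the 16 weighted cone x component contributions over the
    central LEDs. Per-cone totals sum exactly to the full reconstruction."""
    arr = W.w if isinstance(W, ConeWeightMatrix) else np.asarray(W, float)
    rate = basis.rate_hz
    nper = protocol.n_flash_samples(rate)
    leds = list(protocol.central_led_indices)
    S = cone_set.sample_at([protocol.led_peaks_nm[f] for f in leds])  # (n_led, 4)
    T = len(leds) * nper
    sub = np.zeros((4, 4, T))
    for j in range(len(leds)):
        sl = slice(j * nper, (j + 1) * nper)
        for c in range(4):
            for k in range(4):
                sub[c, k, sl] = arr[c, k] * S[j, c] * basis.kernels[k]
    per_cone = sub.sum(axis=1)
    return Reconstruction(
        full=per_cone.sum(axis=0), per_cone=per_cone, sub_traces=sub, rate_hz=rate
    )
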