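"""Synthetic data generation: stimulus protocols, cone/temporal templates,
ground-truth weight populations, trial-resolved traces and triplane stacks.

Everything downstream (preprocessing, clustering, decomposition, tuning
analysis) is testable against the ground truth produced here, without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusProtocol",
    "ConeTuningSet",
    "TemporalBasis",
    "GroundTruthPopulation",
    "SyntheticScene",
    "SceneGeometry",
    "DriftParams",
    "CONE_ORDER",
    "COMPONENT_ORDER",
    "ARCHETYPE_GROUPS",
    "make_stimulus_protocol",
    "make_cone_tunings",
    "make_temporal_basis",
    "make_archetype_weights",
    "make_population",
    "simulate_roi_traces",
    "simulate_triplane_stack",
]

CONE_ORDER = ("red", "green", "blue", "uv")
COMPONENT_ORDER = ("L_tr", "L_sus", "D_tr", "D_sus")

#: default 13 LED peak wavelengths (nm), presented long to short
DEFAULT_LED_PEAKS_NM = (
    655.0, 635.0, 622.0, 592.0, 550.0, 516.0, 501.0,
    464.0, 448.0, 427.0, 407.0, 381.0, 360.0,
)
#: per-LED power at sample plane (uW): long-wavelength LEDs matched at 0.44,
#: the three UV-range LEDs reduced to 0.2
DEFAULT_LED_POWERS_UW = (0.44,) * 10 + (0.2,) * 3


class ProtocolError(ValueError):
    """Invalid stimulus protocol."""


class ParameterError(ValueError):
    """Invalid template/generator parameter."""


class PlacementError(RuntimeError):
    """Scene geometry too small for the requested terminal count."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Spectral flash protocol: 13 LEDs swept long-to-short wavelength."""

    led_peaks_nm: tuple[float, ...] = DEFAULT_LED_PEAKS_NM
    led_powers_uw: tuple[float, ...] = DEFAULT_LED_POWERS_UW
    on_s: float = 1.5
    off_s: float = 1.5
    order: str = "long_to_short"
    frame_rate_hz: float = 10.0
    resample_rate_hz: float = 42.0
    central_led_indices: tuple[int, ...] = tuple(range(2, 12))
    pre_stim_s: float = 5.0

    def __post_init__(self) -> None:
        peaks = np.asarray(self.led_peaks_nm, float)
        if peaks.ndim != 1 or len(peaks) < 2:
            raise ProtocolError("need at least two LEDs")
        if not np.all(np.diff(peaks) < 0):
            raise ProtocolError(
                "led_peaks_nm must be strictly decreasing in presentation order"
            )
        if self.on_s <= 0 or self.off_s <= 0:
            raise ProtocolError("on_s and off_s must be positive")
        if self.frame_rate_hz <= 0 or self.resample_rate_hz <= 0:
            raise ProtocolError("rates must be positive")
        bad = [i for i in self.central_led_indices if not 0 <= i < self.n_leds]
        if bad:
            raise ProtocolError(f"central_led_indices out of range: {bad}")

    @property
    def n_leds(self) -> int:
        return len(self.led_peaks_nm)

    @property
    def flash_period_s(self) -> float:
        return self.on_s + self.off_s

    @property
    def stimulus_duration_s(self) -> float:
        return self.n_leds * self.flash_period_s

    def n_flash_samples(self, rate_hz: float | None = None) -> int:
        rate = self.resample_rate_hz if rate_hz is None else rate_hz
        return int(round(self.flash_period_s * rate))

    def n_on_samples(self, rate_hz: float | None = None) -> int:
        rate = self.resample_rate_hz if rate_hz is None else rate_hz
        return int(round(self.on_s * rate))

    def n_baseline_samples(self, rate_hz: float | None = None) -> int:
        rate = self.resample_rate_hz if rate_hz is None else rate_hz
        return int(round(self.pre_stim_s * rate))


def make_stimulus_protocol(**overrides) -> StimulusProtocol:
    """Build the default 13-LED protocol (1.5 s On / 1.5 s Off, long->short
    sweep, central 10 LEDs flagged for reconstruction), with optional field
    overrides.
    """
    return StimulusProtocol(**overrides)


# ---------------------------------------------------------------------------
# cone spectral tuning templates
# ---------------------------------------------------------------------------

def _log_bell(lam: np.ndarray | float, mu_nm: float, width: float) -> np.ndarray:
    lam = np.asarray(lam, float)
    return np.exp(-0.5 * ((np.log(lam) - np.log(mu_nm)) / width) ** 2)


# (mu1, w1, mu2, w2, sign); crossing amplitude ratio solved at build time
_TEMPLATE_PARAMS: dict[str, dict] = {
    "red": dict(mu1=575.0, w1=0.10, mu2=None, w2=None, crossing=None, sign=1.0),
    "green": dict(mu1=580.0, w1=0.08, mu2=465.0, w2=0.10, crossing=523.0, sign=1.0),
    "blue": dict(mu1=540.0, w1=0.08, mu2=420.0, w2=0.10, crossing=483.0, sign=1.0),
    # UV: dominant short-wavelength lobe with a weak (~22% of peak) opposite
    # lobe longward of the 450 nm crossing
    "uv": dict(mu1=530.0, w1=0.10, mu2=372.0, w2=0.08, crossing=450.0, sign=-1.0),
}

DEFAULT_CROSSINGS_NM = {"green": 523.0, "blue": 483.0, "uv": 450.0}


@dataclass(frozen=True)
class ConeTuningSet:
    """Four cone spectral tuning functions on a shared wavelength grid."""

    wavelength_grid_nm: np.ndarray
    tuning: dict[str, np.ndarray]
    source: str = "template"

    def __post_init__(self) -> None:
        for cone in CONE_ORDER:
            if cone not in self.tuning:
                raise ParameterError(f"missing cone tuning: {cone}")
            if len(self.tuning[cone]) != len(self.wavelength_grid_nm):
                raise ParameterError("all tunings must share the wavelength grid")

    def as_matrix(self) -> np.ndarray:
        """(n_wavelengths, 4) regressor matrix, cone order red/green/blue/uv."""
        return np.column_stack([self.tuning[c] for c in CONE_ORDER])

    def sample_at(self, wavelengths_nm: Sequence[float]) -> np.ndarray:
        """(n_wavelengths, 4) tuning values at arbitrary wavelengths.

        Constant extrapolation beyond the grid edges.
        """
        w = np.asarray(wavelengths_nm, float)
        return np.column_stack(
            [np.interp(w, self.wavelength_grid_nm, self.tuning[c]) for c in CONE_ORDER]
        )


def make_cone_tunings(
    mode: str = "template",
    crossings_nm: dict[str, float] | None = None,
    wavelength_grid_nm: np.ndarray | None = None,
    tuning: dict[str, np.ndarray] | None = None,
) -> ConeTuningSet:
    """Build the four cone spectral tunings.

    ``template`` mode builds smooth opponent/non-opponent shapes from
    differences of log-wavelength bell curves, hitting the requested zero
    crossings exactly (defaults: green 523 nm, blue 483 nm, UV 450 nm; red
    non-opponent). ``measured`` mode wraps user-supplied curves.
    """
    if wavelength_grid_nm is None:
        wavelength_grid_nm = np.arange(360.0, 611.0)
    grid = np.asarray(wavelength_grid_nm, float)

    if mode in ("measured", "from_file"):
        if tuning is None:
            raise ParameterError("measured mode requires tuning curves")
        return ConeTuningSet(grid, dict(tuning), source="measured")
    if mode != "template":
        raise ParameterError(f"unknown mode {mode!r}")

    crossings = dict(DEFAULT_CROSSINGS_NM)
    if crossings_nm:
        crossings.update(crossings_nm)
    for cone, lam0 in crossings.items():
        if not grid[0] < lam0 < grid[-1]:
            raise ParameterError(
                f"requested {cone} crossing {lam0} nm outside grid "
                f"[{grid[0]}, {grid[-1]}]"
            )

    curves: dict[str, np.ndarray] = {}
    for cone in CONE_ORDER:
        p = _TEMPLATE_PARAMS[cone]
        if p["crossing"] is None:
            f = _log_bell(grid, p["mu1"], p["w1"])
        else:
            lam0 = crossings.get(cone, p["crossing"])
            ratio = _log_bell(lam0, p["mu1"], p["w1"]) / _log_bell(lam0, p["mu2"], p["w2"])
            f = _log_bell(grid, p["mu1"], p["w1"]) - ratio * _log_bell(grid, p["mu2"], p["w2"])
        curves[cone] = p["sign"] * f
    return ConeTuningSet(grid, curves, source="template")


# ---------------------------------------------------------------------------
# temporal basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemporalBasis:
    """Four non-negative, unit-L2-norm flash-locked kernels over one
    On+Off flash period: light-transient, light-sustained, dark-transient,
    dark-sustained (in that order)."""

    kernels: np.ndarray  # (4, n_flash_samples)
    labels: tuple[str, ...] = COMPONENT_ORDER
    rate_hz: float = 42.0

    def __post_init__(self) -> None:
        if self.kernels.shape[0] != 4:
            raise ParameterError("temporal basis must have exactly 4 kernels")
        if np.min(self.kernels) < 0:
            raise ParameterError("kernels must be non-negative")


def make_temporal_basis(
    protocol: StimulusProtocol,
    rate_hz: float | None = None,
    tau_transient_s: float = 0.15,
    tau_sustained_s: float = 0.20,
) -> TemporalBasis:
    """Canonical 4-kernel basis: transients decay fast from window onset,
    sustained kernels plateau through their window. Non-negative, unit norm.
    """
    rate = protocol.resample_rate_hz if rate_hz is None else rate_hz
    n = protocol.n_flash_samples(rate)
    n_on = protocol.n_on_samples(rate)
    t_on = np.arange(n_on) / rate
    t_off = np.arange(n - n_on) / rate

    kernels = np.zeros((4, n))
    kernels[0, :n_on] = np.exp(-t_on / tau_transient_s)           # L_tr
    kernels[1, :n_on] = 1.0 - np.exp(-(t_on + 1.0 / rate) / tau_sustained_s)  # L_sus
    kernels[2, n_on:] = np.exp(-t_off / tau_transient_s)          # D_tr
    kernels[3, n_on:] = 1.0 - np.exp(-(t_off + 1.0 / rate) / tau_sustained_s)  # D_sus
    kernels /= np.linalg.norm(kernels, axis=1, keepdims=True)
    return TemporalBasis(kernels=kernels, rate_hz=rate)


# ---------------------------------------------------------------------------
# ground-truth populations
# ---------------------------------------------------------------------------

REGIONS = ("AZ", "D", "N", "V")

#: canonical 4x4 weight archetypes (cones x components) for the six spectral
#: groups; rows red/green/blue/uv, columns L_tr/L_sus/D_tr/D_sus
ARCHETYPE_GROUPS = ("broad", "uv-cone-like", "red-cone-like",
                    "green-opponent", "blue-opponent", "uv-opponent")


def make_archetype_weights(group: str, scale: float = 1.0) -> np.ndarray:
    """A canonical cone-weight matrix generating one of the six spectral
    groups (bulk-tuning archetypes used for synthetic populations)."""
    w = np.zeros((4, 4))
    # component split for archetypes built from per-cone totals
    split = np.array([0.3, 0.45, 0.15, 0.10])
    if group == "broad":
        # cone totals least-squares-fitted to a flat (non-opponent) spectrum
        w = np.outer([4.3, -1.8, -0.5, 0.4], split)
    elif group == "red-cone-like":
        w[0, :] = [0.8, 1.5, 0.6, 0.3]
    elif group == "uv-cone-like":
        # cone totals fitted to the rectified UV lobe: cancels the UV
        # template's weak opposite lobe, leaving a non-opponent tuning
        w = np.outer([1.9, -1.2, 1.0, 2.1], split)
    elif group == "green-opponent":
        w[1, :] = [0.7, 1.4, 0.6, 0.3]
    elif group == "blue-opponent":
        w[2, :] = [0.7, 1.4, 0.6, 0.3]
    elif group == "uv-opponent":
        w[3, :] = [0.8, 1.5, 0.5, 0.3]
        w[0, :] = [-0.3, -0.6, -0.2, -0.1]
    else:
        raise ParameterError(f"unknown archetype group {group!r}")
    return scale * w


@dataclass
class GroundTruthPopulation:
    """Known cone-weight matrices plus per-ROI metadata for a simulated
    population."""

    weights: np.ndarray            # (n_rois, 4, 4)
    ipl_depth: np.ndarray          # (n_rois,) in [0, 1]
    region: np.ndarray             # (n_rois,) of {AZ, D, N, V}
    cluster_id: np.ndarray         # (n_rois,) generating archetype index
    noise_sd: float = 0.1
    n_repeats: int = 7
    seed: int = 0
    group_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.ipl_depth = np.asarray(self.ipl_depth, float)
        if self.weights.ndim != 3 or self.weights.shape[1:] != (4, 4):
            raise ParameterError("weights must be (n, 4, 4)")
        if not np.all(np.isfinite(self.weights)):
            raise ParameterError("weights must be finite")
        if np.any(self.ipl_depth < 0) or np.any(self.ipl_depth > 1):
            raise ParameterError("ipl_depth must lie in [0, 1]")
        if self.n_repeats < 2:
            raise ParameterError("n_repeats must be >= 2")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


def make_population(
    groups: Sequence[str] = ARCHETYPE_GROUPS,
    n_per_group: int = 20,
    weight_jitter_sd: float = 0.05,
    noise_sd: float = 0.1,
    n_repeats: int = 7,
    seed: int = 0,
    depth_span: float = 0.8,
) -> GroundTruthPopulation:
    """Sample a ground-truth population from weight archetypes.

    Archetypes are laid out at evenly spaced IPL depths (each group occupying
    a narrow depth band), emulating depth-structured functional types.
    """
    rng = np.random.default_rng(seed)
    weights, depths, regions, cids = [], [], [], []
    for g, group in enumerate(groups):
        base = make_archetype_weights(group)
        center = 0.1 + depth_span * (g + 0.5) / len(groups)
        for _ in range(n_per_group):
            weights.append(base + rng.normal(0.0, weight_jitter_sd, size=(4, 4)))
            depths.append(np.clip(center + rng.normal(0, 0.03), 0.0, 1.0))
            regions.append(REGIONS[rng.integers(len(REGIONS))])
            cids.append(g)
    return GroundTruthPopulation(
        weights=np.array(weights),
        ipl_depth=np.array(depths),
        region=np.array(regions),
        cluster_id=np.array(cids),
        noise_sd=noise_sd,
        n_repeats=n_repeats,
        seed=seed,
        group_names=tuple(groups),
    )


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftParams:
    """Slow additive confounds: linear ramp plus exponential bleach."""

    ramp_per_s: float = 0.0
    bleach_amp: float = 0.0
    bleach_tau_s: float = 60.0


def noiseless_trace(
    W: np.ndarray,
    protocol: StimulusProtocol,
    cones: ConeTuningSet,
    basis: TemporalBasis,
    include_baseline: bool = True,
) -> np.ndarray:
    """Forward model for one ROI: trace(t) = sum_c sum_k w[c,k] *
    S_c(lambda_flash) * B_k(t - t_flash), zero during the pre-stimulus
    baseline."""
    W = np.asarray(W, float)
    rate = basis.rate_hz
    S = cones.sample_at(protocol.led_peaks_nm)       # (n_leds, 4)
    flash_resp = (S @ W) @ basis.kernels             # (n_leds, n_flash)
    signal = flash_resp.reshape(-1)
    if include_baseline:
        signal = np.concatenate([np.zeros(protocol.n_baseline_samples(rate)), signal])
    return signal


def simulate_roi_traces(
    population: GroundTruthPopulation,
    protocol: StimulusProtocol,
    cones: ConeTuningSet,
    basis: TemporalBasis,
    drift: DriftParams | None = None,
    include_baseline: bool = True,
):
    """Simulate trial-resolved traces for every ROI in the population.

    Returns a list of :class:`spectune.preprocess.ROIRecord`. Each repeat is
    signal + optional drift + i.i.d. Gaussian noise; identical seeds give
    bit-identical output.
    """
    from spectune.preprocess import ROIRecord, compute_qi

    rate = basis.rate_hz
    rng = np.random.default_rng(population.seed)
    drift = drift or DriftParams()

    records = []
    t = None
    for i in range(population.n_rois):
        signal = noiseless_trace(
            population.weights[i], protocol, cones, basis, include_baseline
        )
        if t is None:
            t = np.arange(len(signal)) / rate
            drift_trace = drift.ramp_per_s * t + drift.bleach_amp * np.exp(
                -t / drift.bleach_tau_s
            )
        reps = (
            signal[:, None]
            + drift_trace[:, None]
            + rng.normal(0.0, population.noise_sd, size=(len(signal), population.n_repeats))
        )
        try:
            qi = compute_qi(_fold_stim_window(reps, protocol, rate, include_baseline))
        except ValueError:
            qi = float("nan")
        records.append(
            ROIRecord(
                id=i,
                trace_repeats=reps,
                trace_mean=reps.mean(axis=1),
                qi=qi,
                ipl_depth=float(population.ipl_depth[i]),
                region=str(population.region[i]),
                scan_id="sim",
                fish_id="sim",
            )
        )
    return records


def _fold_stim_window(reps, protocol, rate, include_baseline):
    if include_baseline:
        return reps[protocol.n_baseline_samples(rate):]
    return reps


# ---------------------------------------------------------------------------
# triplane image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneGeometry:
    """Image geometry of a (tri)plane scan."""

    nx: int = 128
    ny: int = 64
    n_planes: int = 3
    pixel_size_um: float = 0.22
    blob_sigma_px: float = 1.6   # ~5 px diameter above half-max
    ipl_band: tuple[float, float] = (0.25, 0.75)  # fraction of ny
    min_separation_px: float = 8.0
    background: float = 0.2
    blob_gain: float = 2.0
    photon_noise_sd: float = 0.02
    # extra i.i.d. noise inside the IPL band: makes the band visible in the
    # time-SD image (dense unresolved terminals) without raising its QI
    band_noise_sd: float = 0.2

    @property
    def nominal_blob_area_um2(self) -> float:
        """Expected detected footprint of one terminal (~1.9 sigma radius)."""
        return float(np.pi * (1.9 * self.blob_sigma_px * self.pixel_size_um) ** 2)


@dataclass
class SyntheticScene:
    """A simulated fluorescence stack with ground-truth terminal positions."""

    stack: np.ndarray              # (T, ny, nx, n_planes), float32
    terminal_centers: np.ndarray   # (n, 3): row, col, plane
    ipl_band: np.ndarray           # (ny, nx, n_planes) bool
    pixel_size_um: float
    frame_rate_hz: float
    n_repeats: int
    n_baseline_frames: int
    truth_traces: np.ndarray       # (n, T) noiseless per-terminal time courses
    roi_index: np.ndarray          # (n,) row into the population


def simulate_triplane_stack(
    population: GroundTruthPopulation,
    protocol: StimulusProtocol,
    cones: ConeTuningSet,
    basis: TemporalBasis | None = None,
    geometry: SceneGeometry | None = None,
) -> SyntheticScene:
    """Render the population as bright ~5 px blobs inside a horizontal IPL
    band, one full-sweep repeat after another, with photon noise.

    The terminal time courses come from the same forward model as
    :func:`simulate_roi_traces`, sampled at the acquisition frame rate.
    """
    geom = geometry or SceneGeometry()
    rate = protocol.frame_rate_hz
    if basis is None or basis.rate_hz != rate:
        basis = make_temporal_basis(protocol, rate_hz=rate)
    rng = np.random.default_rng(population.seed + 1)

    n = population.n_rois
    band_lo = int(round(geom.ipl_band[0] * geom.ny))
    band_hi = int(round(geom.ipl_band[1] * geom.ny))
    margin = int(np.ceil(2 * geom.blob_sigma_px))

    centers = _place_centers(
        n, geom, band_lo, band_hi, margin, rng
    )

    n_base = protocol.n_baseline_samples(rate)
    n_sweep = protocol.n_leds * protocol.n_flash_samples(rate)
    n_frames = n_base + population.n_repeats * n_sweep

    truth = np.zeros((n, n_frames), np.float32)
    for i in range(n):
        sweep = noiseless_trace(
            population.weights[i], protocol, cones, basis, include_baseline=False
        )
        truth[i, n_base:] = np.tile(sweep, population.n_repeats)

    stack = np.full((n_frames, geom.ny, geom.nx, geom.n_planes),
                    geom.background, np.float32)
    yy, xx = np.mgrid[0:geom.ny, 0:geom.nx]
    for i, (r, c, p) in enumerate(centers):
        blob = np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * geom.blob_sigma_px**2)
        ).astype(np.float32)
        blob[blob < 1e-3] = 0.0
        # per-terminal response normalization (independent indicator gain)
        sd = float(truth[i].std())
        sig = truth[i] / (3.0 * sd) if sd > 0 else truth[i]
        amp = geom.background + geom.blob_gain * (1.0 + sig)
        stack[:, :, :, int(p)] += blob[None] * (amp[:, None, None] - geom.background)
    stack += rng.normal(0.0, geom.photon_noise_sd, size=stack.shape).astype(np.float32)

    band = np.zeros((geom.ny, geom.nx, geom.n_planes), bool)
    band[band_lo:band_hi, :, :] = True
    if geom.band_noise_sd > 0:
        stack[:, band_lo:band_hi] += rng.normal(
            0.0, geom.band_noise_sd, size=stack[:, band_lo:band_hi].shape
        ).astype(np.float32)
    return SyntheticScene(
        stack=stack,
        terminal_centers=np.asarray(centers, float),
        ipl_band=band,
        pixel_size_um=geom.pixel_size_um,
        frame_rate_hz=rate,
        n_repeats=population.n_repeats,
        n_baseline_frames=n_base,
        truth_traces=truth,
        roi_index=np.arange(n),
    )


def _place_centers(n, geom, band_lo, band_hi, margin, rng):
    """Random centers inside the band with minimum pairwise separation
    (per plane); raises PlacementError when the geometry cannot host n."""
    lo = max(band_lo + margin, margin)
    hi = min(band_hi - margin, geom.ny - margin)
    if hi <= lo or geom.nx <= 2 * margin:
        if n > 0:
            raise PlacementError("geometry too small for any terminal")
        return np.zeros((0, 3))
    centers: list[tuple[float, float, int]] = []
    max_tries = 200 * max(n, 1)
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} terminals with separation "
                f"{geom.min_separation_px} px in {geom.nx}x{geom.ny}x{geom.n_planes}"
            )
        r = rng.uniform(lo, hi)
        c = rng.uniform(margin, geom.nx - margin)
        p = int(rng.integers(geom.n_planes))
        ok = all(
            (r - r0) ** 2 + (c - c0) ** 2 >= geom.min_separation_px**2
            for r0, c0, p0 in centers
            if p0 == p
        )
        if ok:
            centers.append((r, c, p))
    return np.asarray(centers, float)
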