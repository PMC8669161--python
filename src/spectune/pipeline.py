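"""Pipeline orchestration: validated configuration, staged execution
(simulate -> preprocess -> cluster -> decompose -> analyze) and a run
manifest with checksums for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spectune import cluster as cl
from spectune import decompose as dc
from spectune import io as sio
from spectune import preprocess as pp
from spectune import synthetic as syn
from spectune import tuning as tn

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "StageDependencyError", "run_pipeline"]

ALL_STAGES = ("simulate", "preprocess", "cluster", "decompose", "analyze")


class StageDependencyError(RuntimeError):
    """A requested stage is missing its upstream artifact."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; defaults reproduce the published
    protocol parameters (13 LEDs, 1.5 s On/Off, QI cutoff 0.4, 0.16-2 Hz
    power band)."""

    seed: int = 0
    out_dir: str = "spectune_out"
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic
    groups: tuple[str, ...] = syn.ARCHETYPE_GROUPS
    n_per_group: int = 20
    noise_sd: float = 0.1
    n_repeats: int = 7
    weight_jitter_sd: float = 0.05
    # preprocess
    qi_min: float = 0.4
    # cluster
    n_pc: int = 48
    k_range: tuple[int, int] = (1, 12)
    gmm_n_init: int = 3
    # decompose
    lasso_lambda: float | str = 1e-4
    nmf_restarts: int = 5
    # analyze
    opponency_threshold: float = 0.10
    power_band_hz: tuple[float, float] = (0.16, 2.0)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 <= self.qi_min <= 1:
            raise ValueError("qi_min must lie in [0, 1]")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")
        if self.n_per_group < 1 or self.n_repeats < 2:
            raise ValueError("need n_per_group >= 1 and n_repeats >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for k in ("stages", "groups", "k_range", "power_band_hz"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the toggled stages on synthetic data; idempotent given the
    seed. Each stage records output checksums and wall time in the manifest.
    """
    from spectune import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, package_version=__version__)

    protocol = syn.make_stimulus_protocol()
    cones = syn.make_cone_tunings()
    basis = syn.make_temporal_basis(protocol)
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        files = _STAGE_FNS[stage](config, protocol, cones, basis, state, out)
        manifest.stages[stage] = {
            "wall_s": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.name): _sha256(p) for p in files},
        }

    (out / "manifest.json").write_text(manifest.to_json())
    sio.save_protocol_yaml(out / "protocol.yaml", protocol)
    return manifest


def _stage_simulate(config, protocol, cones, basis, state, out):
    pop = syn.make_population(
        groups=config.groups,
        n_per_group=config.n_per_group,
        weight_jitter_sd=config.weight_jitter_sd,
        noise_sd=config.noise_sd,
        n_repeats=config.n_repeats,
        seed=config.seed,
    )
    records = syn.simulate_roi_traces(pop, protocol, cones, basis)
    state["population"], state["records"] = pop, records
    truth_csv = out / "truth.csv"
    sio.truth_table(pop).to_csv(truth_csv, index=False)
    traces_h5 = out / "traces.h5"
    sio.save_records_h5(traces_h5, records, rate_hz=protocol.resample_rate_hz)
    return [truth_csv, traces_h5]


def _stage_preprocess(config, protocol, cones, basis, state, out):
    if "records" not in state:
        traces_h5 = out / "traces.h5"
        if not traces_h5.exists():
            raise StageDependencyError("preprocess requires the simulate stage output")
        state["records"] = sio.load_records_h5(traces_h5)
    kept = pp.filter_rois(state["records"], qi_min=config.qi_min)
    state["kept"] = kept
    table_csv = out / "rois.csv"
    sio.roi_table(kept).to_csv(table_csv, index=False)
    return [table_csv]


def _stage_cluster(config, protocol, cones, basis, state, out):
    if "kept" not in state:
        raise StageDependencyError("cluster requires the preprocess stage")
    kept = state["kept"]
    nb = protocol.n_baseline_samples()
    traces = np.vstack([r.trace_mean[nb:] for r in kept])
    depths = np.array([r.ipl_depth for r in kept])
    red = cl.pca_reduce(traces, n_pc=min(config.n_pc, traces.shape[0] - 1))
    lo, hi = config.k_range
    model = cl.fit_gmm_bic(
        red.scores, k_range=range(lo, hi + 1), n_init=config.gmm_n_init,
        seed=config.seed, traces=traces, depths=depths,
    )
    state["cluster_model"], state["cluster_traces"] = model, traces
    means_csv = out / "cluster_means.csv"
    pd.DataFrame(model.cluster_means).to_csv(means_csv, index=False)
    labels_csv = out / "cluster_labels.csv"
    pd.DataFrame({"roi_id": [r.id for r in kept], "label": model.labels}).to_csv(
        labels_csv, index=False
    )
    bic_csv = out / "bic_curve.csv"
    pd.DataFrame(
        {"k": list(model.bic_curve), "bic": list(model.bic_curve.values())}
    ).to_csv(bic_csv, index=False)
    return [means_csv, labels_csv, bic_csv]


def _stage_decompose(config, protocol, cones, basis, state, out):
    if "cluster_model" not in state:
        raise StageDependencyError("decompose requires the cluster stage")
    model = state["cluster_model"]
    fitted_basis = dc.extract_temporal_basis_nmf(
        model.cluster_means, protocol, seed=config.seed,
        n_restarts=config.nmf_restarts,
    )
    weights = np.asarray(
        [
            dc.fit_trace_weights(
                mean, fitted_basis, protocol, cones,
                lasso_lambda=config.lasso_lambda, seed=config.seed,
            ).w
            for mean in model.cluster_means
        ]
    )
    state["weights"], state["fitted_basis"] = weights, fitted_basis
    wcsv = out / "cluster_weights.csv"
    sio.weights_to_frame(weights).to_csv(wcsv, index=False)
    bcsv = out / "temporal_basis.csv"
    pd.DataFrame(fitted_basis.kernels.T, columns=fitted_basis.labels).to_csv(
        bcsv, index=False
    )
    return [wcsv, bcsv]


def _stage_analyze(config, protocol, cones, basis, state, out):
    if "weights" not in state:
        raise StageDependencyError("analyze requires the decompose stage")
    model = state["cluster_model"]
    weights = state["weights"]
    fitted_basis = state["fitted_basis"]

    tunings = [tn.analyze_tuning(w, cones, config.opponency_threshold)
               for w in weights]
    groups_csv = out / "spectral_groups.csv"
    pd.DataFrame(
        {
            "cluster": np.arange(len(tunings)),
            "spectral_group": [t.spectral_group for t in tunings],
            "is_opponent": [t.is_opponent for t in tunings],
            "n_crossings": [len(t.qualifying_crossings_nm) for t in tunings],
        }
    ).to_csv(groups_csv, index=False)
    curves_csv = out / "bulk_tunings.csv"
    pd.DataFrame(
        np.vstack([t.curve for t in tunings]).T,
        index=cones.wavelength_grid_nm,
    ).to_csv(curves_csv, index_label="wavelength_nm")

    # reconstruction quality over the central-LED window
    nper = protocol.n_flash_samples()
    sl = slice(min(protocol.central_led_indices) * nper,
               (max(protocol.central_led_indices) + 1) * nper)
    recons = np.vstack(
        [dc.reconstruct(w, cones, fitted_basis, protocol).full for w in weights]
    )
    originals = state["cluster_traces"][:, sl]
    means = np.vstack([originals[model.labels == c].mean(axis=0)
                       for c in range(model.n_clusters)])
    fq_var = tn.variance_explained(means, recons)
    fq_pow = tn.power_explained(means, recons, rate_hz=protocol.resample_rate_hz,
                                band_hz=config.power_band_hz)
    quality_json = out / "fit_quality.json"
    quality_json.write_text(
        json.dumps(
            {
                "variance_explained_pct": fq_var.variance_explained_pct,
                "residual_variance_pct": fq_var.residual_variance_pct,
                "power_explained_pct": fq_pow.power_explained_pct,
                "residual_power_pct": fq_pow.residual_power_pct,
                "band_hz": list(fq_pow.band_hz),
            },
            indent=2,
        )
    )
    corr_csv = out / "weight_correlations.csv"
    pd.DataFrame(
        [
            {"cone_a": r.pair[0], "cone_b": r.pair[1], "rho": r.rho,
             "ci_lo": r.ci95[0], "ci_hi": r.ci95[1]}
            for r in tn.weight_correlations(weights)
        ]
    ).to_csv(corr_csv, index=False)
    return [groups_csv, curves_csv, quality_json, corr_csv]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "cluster": _stage_cluster,
    "decompose": _stage_decompose,
    "analyze": _stage_analyze,
}
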