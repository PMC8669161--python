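"""File I/O: HDF5 traces/stacks, CSV tables, YAML configs, and the adapter
for the deposited per-ROI dataset layout."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from spectune.preprocess import ROIRecord
from spectune.synthetic import (
    CONE_ORDER,
    COMPONENT_ORDER,
    GroundTruthPopulation,
    StimulusProtocol,
    SyntheticScene,
)

__all__ = [
    "weight_columns",
    "weights_to_frame",
    "frame_to_weights",
    "save_records_h5",
    "load_records_h5",
    "save_scene_h5",
    "roi_table",
    "save_protocol_yaml",
    "load_protocol_yaml",
    "truth_table",
    "FieldMappingError",
    "DEPOSIT_COLUMNS",
    "write_deposit",
    "load_dryad_deposit",
]


def weight_columns() -> list[str]:
    return [f"w_{c}_{k}" for c in CONE_ORDER for k in COMPONENT_ORDER]


def weights_to_frame(weights: np.ndarray, index=None) -> pd.DataFrame:
    W = np.asarray(weights, float).reshape(-1, 16)
    return pd.DataFrame(W, columns=weight_columns(), index=index)


def frame_to_weights(df: pd.DataFrame) -> np.ndarray:
    return df[weight_columns()].to_numpy(float).reshape(-1, 4, 4)


def save_records_h5(path, records: list[ROIRecord], rate_hz: float = 42.0) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["rate_hz"] = rate_hz
        f.attrs["n_rois"] = len(records)
        for r in records:
            g = f.create_group(f"roi/{r.id}")
            g.create_dataset("trace_repeats", data=r.trace_repeats)
            g.create_dataset("trace_mean", data=r.trace_mean)
            for key in ("qi", "ipl_depth", "region", "scan_id", "fish_id", "plane"):
                g.attrs[key] = getattr(r, key)
            if r.area_um2 is not None:
                g.attrs["area_um2"] = r.area_um2


def load_records_h5(path) -> list[ROIRecord]:
    records = []
    with h5py.File(path, "r") as f:
        for name in sorted(f["roi"], key=int):
            g = f[f"roi/{name}"]
            records.append(
                ROIRecord(
                    id=int(name),
                    trace_repeats=g["trace_repeats"][...],
                    trace_mean=g["trace_mean"][...],
                    qi=float(g.attrs["qi"]),
                    ipl_depth=float(g.attrs["ipl_depth"]),
                    region=str(g.attrs["region"]),
                    scan_id=str(g.attrs["scan_id"]),
                    fish_id=str(g.attrs["fish_id"]),
                    plane=int(g.attrs.get("plane", 0)),
                    area_um2=float(g.attrs["area_um2"]) if "area_um2" in g.attrs else None,
                )
            )
    return records


def save_scene_h5(path, scene: SyntheticScene, population: GroundTruthPopulation,
                  protocol: StimulusProtocol) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("stack", data=scene.stack, compression="gzip")
        f.create_dataset("terminal_centers", data=scene.terminal_centers)
        f.create_dataset("ipl_band", data=scene.ipl_band)
        f.create_dataset("truth/weights", data=population.weights)
        f.create_dataset("truth/traces", data=scene.truth_traces)
        f.attrs["pixel_size_um"] = scene.pixel_size_um
        f.attrs["frame_rate_hz"] = scene.frame_rate_hz
        f.attrs["n_repeats"] = scene.n_repeats
        f.attrs["n_baseline_frames"] = scene.n_baseline_frames
        for k, v in dataclasses.asdict(protocol).items():
            f.attrs[f"protocol/{k}"] = v


def roi_table(records: list[ROIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "scan_id": [r.scan_id for r in records],
            "fish_id": [r.fish_id for r in records],
            "region": [r.region for r in records],
            "ipl_depth": [r.ipl_depth for r in records],
            "qi": [r.qi for r in records],
            "area_um2": [r.area_um2 for r in records],
        }
    )


def truth_table(population: GroundTruthPopulation) -> pd.DataFrame:
    df = weights_to_frame(population.weights)
    df.insert(0, "roi_id", np.arange(population.n_rois))
    df["ipl_depth"] = population.ipl_depth
    df["region"] = population.region
    df["cluster_id"] = population.cluster_id
    return df


def save_protocol_yaml(path, protocol: StimulusProtocol) -> None:
    d = dataclasses.asdict(protocol)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(d))


def load_protocol_yaml(path) -> StimulusProtocol:
    d = yaml.safe_load(Path(path).read_text())
    for k in ("led_peaks_nm", "led_powers_uw", "central_led_indices"):
        if k in d:
            d[k] = tuple(d[k])
    return StimulusProtocol(**d)


# ---------------------------------------------------------------------------
# deposited-dataset adapter
# ---------------------------------------------------------------------------

class FieldMappingError(ValueError):
    """Deposit file does not match the expected column mapping."""


#: internal name -> default deposit column name (overridable via mapping)
DEPOSIT_COLUMNS = {
    "roi_id": "roi_id",
    "scan_id": "scan_id",
    "fish_id": "fish_id",
    "region": "region",
    "ipl_depth": "ipl_depth",
    "qi": "qi",
    "area_um2": "area_um2",
}


def write_deposit(directory, records: list[ROIRecord], weights: np.ndarray) -> None:
    """Write internal tables in the deposit layout: a per-ROI metadata table
    with the trial-averaged response spread over trace_* columns, and a
    16-weight table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = roi_table(records).rename(columns={"id": "roi_id"})
    traces = np.vstack([r.trace_mean for r in records])
    trace_df = pd.DataFrame(
        traces, columns=[f"trace_{i}" for i in range(traces.shape[1])]
    )
    pd.concat([meta.reset_index(drop=True), trace_df], axis=1).to_csv(
        directory / "rois.csv", index=False
    )
    wdf = weights_to_frame(weights)
    wdf.insert(0, "roi_id", meta["roi_id"].to_numpy())
    wdf.to_csv(directory / "weights.csv", index=False)


def load_dryad_deposit(path, mapping: dict[str, str] | None = None):
    """Load a deposited per-ROI dataset (user-downloaded, CSV layout).

    Expects ``rois.csv`` (metadata + ``trace_*`` columns holding the
    trial-averaged response) and ``weights.csv`` (16 weights per ROI). Column
    names can be remapped via ``mapping`` (internal name -> deposit name).
    Returns ``(records, weight_table, report)`` where report counts rows per
    region. Raises :class:`FieldMappingError` on schema mismatch.
    """
    path = Path(path)
    roi_file = path / "rois.csv" if path.is_dir() else path
    if not roi_file.exists():
        raise FieldMappingError(f"deposit table not found: {roi_file}")
    cols = dict(DEPOSIT_COLUMNS)
    if mapping:
        cols.update(mapping)
    try:
        df = pd.read_csv(roi_file)
    except Exception as e:
        raise FieldMappingError(f"could not parse {roi_file}: {e}") from e

    missing = [v for k, v in cols.items() if k in ("roi_id", "qi", "ipl_depth")
               and v not in df.columns]
    trace_cols = [c for c in df.columns if c.startswith("trace_")]
    if missing or not trace_cols:
        raise FieldMappingError(
            f"deposit schema mismatch: missing columns {missing}, "
            f"{len(trace_cols)} trace columns found; supply an explicit mapping"
        )
    trace_cols.sort(key=lambda c: int(c.split("_")[1]))
    traces = df[trace_cols].to_numpy(float)
    if not np.all(np.isfinite(traces)):
        raise FieldMappingError("non-finite values in trial-averaged traces")

    records = []
    for i, row in df.iterrows():
        records.append(
            ROIRecord(
                id=int(row[cols["roi_id"]]),
                trace_repeats=traces[i][:, None].repeat(2, axis=1),
                trace_mean=traces[i],
                qi=float(row[cols["qi"]]),
                ipl_depth=float(row[cols["ipl_depth"]]),
                region=str(row.get(cols["region"], "AZ")),
                scan_id=str(row.get(cols["scan_id"], "deposit")),
                fish_id=str(row.get(cols["fish_id"], "deposit")),
                area_um2=float(row[cols["area_um2"]])
                if cols["area_um2"] in df.columns else None,
            )
        )

    weight_table = None
    wfile = (path / "weights.csv") if path.is_dir() else None
    if wfile is not None and wfile.exists():
        wdf = pd.read_csv(wfile)
        missing_w = [c for c in weight_columns() if c not in wdf.columns]
        if missing_w:
            raise FieldMappingError(f"weight table missing columns: {missing_w}")
        weight_table = wdf

    regions = df[cols["region"]] if cols["region"] in df.columns else pd.Series([])
    report = {
        "n_rois": len(records),
        "rows_per_region": regions.value_counts().to_dict(),
    }
    return records, weight_table, report
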