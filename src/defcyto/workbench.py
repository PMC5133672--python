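"""Formats, configuration, plotting and reproducible pipeline runs.

Feature tables travel as CSV with the canonical header
``event_id,A,C1,D1,D2,D3,D4,T1,T2,S1,S2,M1,M2,M3,M4,AR1[,label]``
(A in um, T1 in us, T2 in 1/us, the rest dimensionless).  Cell events are
stored as one multi-page grayscale TIFF per event plus a JSON sidecar
with timing metadata and optional ground truth.  ``run_pipeline`` chains
simulate -> extract -> train -> classify into a single run directory with
a manifest of seeds and output checksums, so a run is reproducible
bit-for-bit from its config and global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import analysis, synthetic
from .features import PARAMETER_NAMES, BiophysicalProfile, batch_extract
from .synthetic import CellEvent, PopulationSpec, RenderSpec

log = logging.getLogger("defcyto")


class SchemaError(ValueError):
    """Raised when a feature-table file does not match the canonical schema."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table CSV in canonical column order."""
    t = table.copy()
    if t.index.name == "event_id":
        t = t.reset_index()
    if "event_id" not in t.columns:
        t.insert(0, "event_id", [f"event-{i}" for i in range(len(t))])
    lead = ["event_id"] + [p for p in PARAMETER_NAMES if p in t.columns]
    rest = [c for c in t.columns if c not in lead]
    t[lead + rest].to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path, require_all: bool = True) -> pd.DataFrame:
    """Read a feature-table CSV, validating the canonical schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    if "event_id" not in table.columns:
        raise SchemaError("missing mandatory column: event_id")
    if require_all:
        for p in PARAMETER_NAMES:
            if p not in table.columns:
                raise SchemaError(f"missing mandatory column: {p}")
    return table.set_index("event_id")


# ---------------------------------------------------------------------------
# event stacks


def save_event(event: CellEvent, directory: str | Path) -> Path:
    """Serialize one event: multi-page float32 TIFF + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tiff = directory / f"{event.event_id}.tif"
    tifffile.imwrite(tiff, np.stack(event.frames).astype(np.float32))
    meta = {
        "event_id": event.event_id,
        "frame_interval_us": event.frame_interval,
        "pixel_size_um": event.pixel_size,
        "junction_arrival_index": event.junction_arrival_index,
    }
    if event.label is not None:
        meta["label"] = event.label
    if event.ground_truth is not None:
        meta["ground_truth"] = event.ground_truth.as_dict()
    (directory / f"{event.event_id}.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True))
    return tiff


def load_event(tiff_path: str | Path) -> CellEvent:
    """Load an event from its TIFF stack and JSON sidecar."""
    tiff_path = Path(tiff_path)
    frames = [f.astype(float) for f in tifffile.imread(tiff_path)]
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    gt = meta.get("ground_truth")
    return CellEvent(
        event_id=meta["event_id"],
        frames=frames,
        frame_interval=meta["frame_interval_us"],
        pixel_size=meta["pixel_size_um"],
        junction_arrival_index=meta["junction_arrival_index"],
        ground_truth=BiophysicalProfile(**gt) if gt else None,
        label=meta.get("label"),
    )


def load_events(directory: str | Path) -> list[CellEvent]:
    """Load every event stack in a directory, sorted by file name."""
    return [load_event(p) for p in sorted(Path(directory).glob("*.tif"))]


# ---------------------------------------------------------------------------
# plotting


@dataclass
class DensityPlotSpec:
    """Style of a 2-D single-cell density plot (red = high density)."""

    x: str = "A"
    y: str = "D3"
    bandwidth: float | None = None
    cmap: str = "RdYlBu_r"
    grid: int = 200
    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None


def density_plot(
    table: pd.DataFrame,
    path: str | Path,
    spec: DensityPlotSpec | None = None,
    gates: Sequence[analysis.GateSpec] = (),
) -> Path:
    """Render a color density plot of two features to an image file.

    Gaussian-kernel density of the scatter, red-to-blue mapping
    high-to-low density; fitted gates can be overlaid as lines/ellipses.
    Falls back to a plain scatter (with a warning) below 10 rows.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    spec = spec or DensityPlotSpec()
    for col in (spec.x, spec.y):
        if col not in table.columns:
            raise KeyError(f"feature {col!r} not in table")
    x = table[spec.x].to_numpy(dtype=float)
    y = table[spec.y].to_numpy(dtype=float)

    fig, ax = plt.subplots(figsize=(5, 4))
    if len(table) < 10:
        warnings.warn("fewer than 10 rows; falling back to scatter", stacklevel=2)
        ax.scatter(x, y, s=8, c="k")
    else:
        kde = gaussian_kde(np.vstack([x, y]), bw_method=spec.bandwidth)
        xr = spec.x_range or (x.min(), x.max())
        yr = spec.y_range or (y.min(), y.max())
        if xr[0] >= xr[1] or yr[0] >= yr[1]:
            warnings.warn("axis ranges exclude all data; empty plot", stacklevel=2)
        else:
            gx = np.linspace(*xr, spec.grid)
            gy = np.linspace(*yr, spec.grid)
            gxx, gyy = np.meshgrid(gx, gy)
            z = kde(np.vstack([gxx.ravel(), gyy.ravel()])).reshape(gxx.shape)
            ax.pcolormesh(gxx, gyy, z, cmap=spec.cmap, shading="auto")
    for gate in gates:
        _draw_gate(ax, gate)
    ax.set_xlabel(spec.x)
    ax.set_ylabel(spec.y)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "defcyto"})
    plt.close(fig)
    return Path(path)


def _draw_gate(ax, gate: analysis.GateSpec) -> None:
    if gate.kind == "size":
        ax.axvline(gate.size_threshold, color="k", ls="--", lw=1)
    elif gate.kind == "diagonal":
        ax.axvline(gate.size_threshold, color="k", ls="--", lw=1)
        ax.axhline(gate.d3_threshold, color="k", ls="--", lw=1)
    elif gate.kind == "quantile" and gate.center is not None:
        t = np.linspace(0, 2 * np.pi, 200)
        vals, vecs = np.linalg.eigh(gate.shape_matrix)
        circ = np.vstack([np.cos(t), np.sin(t)])
        pts = (vecs @ (np.sqrt(vals)[:, None] * circ)) * gate.radius
        ax.plot(gate.center[0] + pts[0], gate.center[1] + pts[1],
                color="k", lw=1)


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_CONFIG: dict = {
    "simulate": {
        "classes": {
            "soft": {"n": 30, "diameter_mean": 14.0, "diameter_sd": 1.0,
                     "max_strain_mean": 0.55, "max_strain_sd": 0.04},
            "stiff": {"n": 30, "diameter_mean": 17.0, "diameter_sd": 1.0,
                      "max_strain_mean": 0.25, "max_strain_sd": 0.04},
        },
        "render": {},
    },
    "extract": {"window": 31},
    "analyze": {"kernel": "linear", "test_fraction": 0.3},
}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path, seed: int = 0) -> dict:
    """Run simulate -> extract -> train -> classify into one run directory.

    Every stage derives its RNG seed deterministically from the global
    seed and the stage name; the manifest records the config hash, stage
    seeds and SHA-256 checksums of every numeric artifact, so re-running
    with the same config and seed reproduces the run bit-identically.
    Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    manifest: dict = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "global_seed": seed,
        "stage_seeds": {},
        "outputs": {},
    }
    try:
        sim_cfg = config.get("simulate", DEFAULT_CONFIG["simulate"])
        render = RenderSpec(**sim_cfg.get("render", {}))
        events_dir = outdir / "events"
        for cname, ccfg in sim_cfg["classes"].items():
            s = derive_seed(seed, f"simulate:{cname}")
            manifest["stage_seeds"][f"simulate:{cname}"] = s
            rng = np.random.default_rng(s)
            kwargs = {k: v for k, v in ccfg.items() if k != "n"}
            specs = synthetic.sample_cell_specs(ccfg["n"], rng, **kwargs)
            for i, cs in enumerate(specs):
                ev = synthetic.simulate_event(
                    cs, render, event_id=f"{cname}-{i:04d}", label=cname)
                save_event(ev, events_dir)
        log.info("simulated %d events", len(list(events_dir.glob("*.tif"))))

        events = load_events(events_dir)
        window = config.get("extract", {}).get("window", 31)
        table, rejected = batch_extract(events, window=window)
        labels = {ev.event_id: ev.label for ev in events}
        table["label"] = table.index.map(labels)
        features_csv = outdir / "features.csv"
        write_feature_table(table, features_csv)
        (outdir / "rejections.json").write_text(json.dumps(rejected))
        log.info("extracted %d profiles (%d rejected)", len(table), len(rejected))

        an_cfg = config.get("analyze", DEFAULT_CONFIG["analyze"])
        s = derive_seed(seed, "analyze")
        manifest["stage_seeds"]["analyze"] = s
        rng = np.random.default_rng(s)
        n = len(table)
        test_n = int(an_cfg.get("test_fraction", 0.3) * n)
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:test_n], perm[test_n:]
        feats = list(PARAMETER_NAMES)
        bundle = analysis.train_svm(
            table.iloc[train_idx][feats], table.iloc[train_idx]["label"],
            kernel=an_cfg.get("kernel", "linear"), seed=s)
        fractions = analysis.predict_fractions(bundle, table.iloc[test_idx][feats])
        results = {
            "cv_accuracy": bundle.cv_accuracy,
            "held_out_fractions": {str(k): v for k, v in fractions.items()},
            "median_d3_over_a": analysis.deformability_size_ratio(table),
        }
        (outdir / "results.json").write_text(json.dumps(results, indent=1,
                                                        sort_keys=True))
        for p in sorted(outdir.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json", "run.log"):
                manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         sort_keys=True))
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
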