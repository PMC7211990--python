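"""Tables, configuration and provenance.

All tabular interchange is long-format delimited text with a header
(UTF-8, '.' decimal, empty cells = NA); configurations are YAML or JSON
with strict schemas (unknown keys rejected) and a provenance block
(package version, seed, config hash) sufficient to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .errors import SchemaError
from .trace_kinetics import KineticFit, RatioTrace

#: required columns of the long-format trace table
TRACE_COLUMNS = ("time_s", "cell_id", "value")

#: required columns of the per-cell fit table
FIT_COLUMNS = ("cell_id", "tau_s", "amplitude", "baseline", "rss", "converged")

#: required columns of the uncaging ROI table
ROI_COLUMNS = ("time_s", "roi_index", "ph")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}", missing=missing,
        )


def read_trace_table(path) -> list[RatioTrace]:
    """Read a long-format (time_s, cell_id, value) table into traces."""
    df = pd.read_csv(path, sep=None, engine="python")
    _require_columns(df, TRACE_COLUMNS, path)
    traces = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(RatioTrace(grp["time_s"].to_numpy(),
                                 grp["value"].to_numpy(), cell_id=str(cid)))
    return traces


def write_trace_table(traces, path) -> None:
    frames = [
        pd.DataFrame({"time_s": tr.time, "cell_id": tr.cell_id,
                      "value": tr.values})
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_fit_table(fits: dict[str, KineticFit], path) -> None:
    rows = [
        {"cell_id": cid, "tau_s": f.tau, "amplitude": f.amplitude,
         "baseline": f.baseline, "rss": f.rss, "converged": f.converged}
        for cid, f in fits.items()
    ]
    pd.DataFrame(rows, columns=list(FIT_COLUMNS)).to_csv(path, index=False)


def read_fit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    _require_columns(df, FIT_COLUMNS, path)
    return df


def write_roi_table(exp, path) -> None:
    """Write an uncaging experiment's ROI pH traces (long format)."""
    n_frames, n_roi = exp.roi_ph.shape
    df = pd.DataFrame({
        "time_s": np.repeat(exp.time, n_roi),
        "roi_index": np.tile(np.arange(n_roi), n_frames),
        "ph": exp.roi_ph.ravel(),
    })
    df.to_csv(path, index=False)


def read_roi_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ROI table; returns (frame times, pH array (frames, rois))."""
    df = pd.read_csv(path, sep=None, engine="python")
    _require_columns(df, ROI_COLUMNS, path)
    pivot = df.pivot_table(index="time_s", columns="roi_index", values="ph",
                           sort=True)
    return pivot.index.to_numpy(), pivot.to_numpy()


class RunConfig(BaseModel):
    """Strict run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "."
    scheme: dict = {}        # hb_kinetics.build_scheme kwargs
    unloading: dict = {}     # gas_diffusion simulation kwargs
    traces: dict = {}        # trace_kinetics / synthetic protocol kwargs
    uncaging: dict = {}      # h_uncaging kwargs
    assays: dict = {}        # membrane_assays kwargs
    population: dict = {}    # population_stats kwargs
    capillary: dict = {}     # capillary kwargs


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form."""
    payload = json.dumps(config.model_dump(), sort_keys=True,
                         separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance(config: RunConfig) -> dict:
    from . import __version__

    return {"package": "rbcgas", "version": __version__,
            "seed": config.seed, "config_hash": config_hash(config)}


def read_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = dict(data or {})
    data.pop("provenance", None)  # round-trip tolerant
    return RunConfig(**data)


def write_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.model_dump()
    data["provenance"] = provenance(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def write_metadata(meta: dict, path) -> None:
    """Sidecar JSON metadata emitted next to generated data files."""
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True,
                                     default=str))


def read_tiff_traces(tiff_path, mask_path) -> list[RatioTrace]:
    """Mean-ROI ratio extraction from a two-channel time-lapse TIFF.

    The stack layout is (frames, 2, y, x) with channel 0 the reference
    (green) and channel 1 the reporter (deep red); the mask image labels
    cell i with pixel value i+1.  The per-cell ratio is mean(red)/mean
    (green) over the mask, sampled on the acquisition cadence (7.8 Hz).
    """
    import tifffile

    from .trace_kinetics import DEFAULT_DT

    stack = tifffile.imread(tiff_path)
    mask = tifffile.imread(mask_path)
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise SchemaError(
            f"{tiff_path}: expected a (frames, 2, y, x) stack, "
            f"got shape {stack.shape}"
        )
    t = np.arange(stack.shape[0]) * DEFAULT_DT
    traces = []
    for label in np.unique(mask):
        if label == 0:
            continue
        sel = mask == label
        green = stack[:, 0][:, sel].mean(axis=1)
        red = stack[:, 1][:, sel].mean(axis=1)
        traces.append(RatioTrace(t, red / green, cell_id=f"cell_{label}"))
    return traces
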