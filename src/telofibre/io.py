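"""File formats: trace TSV, events CSV, result JSON, TOML configuration.

Traces travel as tab-separated text with the header
``time_s  magnet_mm  force_pN  extension_nm  bead_id`` (``magnet_mm``
optional, ``#`` comments allowed, any column order).  Values round-trip
losslessly to 9 significant digits.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fibre import FibreParams
from .rupture import RuptureEvent
from .traces import Trace
from .wlc import WLCParams

__all__ = [
    "read_trace",
    "write_trace",
    "read_events_csv",
    "write_events_csv",
    "load_config",
    "write_json",
]

_REQUIRED = ("time_s", "force_pN", "extension_nm")


def read_trace(path) -> Trace:
    """Parse a trace TSV; malformed rows are reported with line numbers."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    numeric = [c for c in ("time_s", "magnet_mm", "force_pN", "extension_nm")
               if c in df.columns]
    bad = df.index[df[numeric].isna().any(axis=1)]
    if len(bad):
        # +2: one for the header line, one for 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: malformed/NaN rows at line(s) {lines}")
    bead = str(df["bead_id"].iloc[0]) if "bead_id" in df.columns else path.stem
    return Trace(
        time=df["time_s"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        magnet_pos=df["magnet_mm"].to_numpy() if "magnet_mm" in df.columns else None,
        bead_id=bead,
    )


def write_trace(trace: Trace, path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    cols = {"time_s": trace.time}
    if trace.magnet_pos is not None:
        cols["magnet_mm"] = trace.magnet_pos
    cols["force_pN"] = trace.force
    cols["extension_nm"] = trace.extension
    cols["bead_id"] = trace.bead_id
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_events_csv(events: list[RuptureEvent], path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    pd.DataFrame(
        [
            {
                "trace_id": e.trace_id,
                "order_index": e.order_index,
                "n_remaining": e.n_remaining,
                "f_rupt_pN": e.f_rupt,
                "step_nm": e.step,
                "loading_rate_pN_s": e.loading_rate,
                "time_s": e.time,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def read_events_csv(path) -> list[RuptureEvent]:
    df = pd.read_csv(path)
    return [
        RuptureEvent(
            f_rupt=float(r.f_rupt_pN),
            step=float(r.step_nm),
            order_index=int(r.order_index),
            n_remaining=int(r.n_remaining),
            loading_rate=float(r.loading_rate_pN_s),
            trace_id=str(r.trace_id),
            time=float(getattr(r, "time_s", float("nan"))),
        )
        for r in df.itertuples()
    ]


def load_config(path) -> dict:
    """Load a TOML run configuration; unknown keys are preserved."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def fibre_params_from_config(cfg: dict) -> FibreParams:
    """Build FibreParams from the [fibre] / [wlc] tables of a config."""
    wlc = WLCParams(**cfg.get("wlc", {}))
    return replace(FibreParams(wlc=wlc), **cfg.get("fibre", {}))


def write_json(obj, path, force: bool = False, **meta) -> None:
    """Write a result JSON with embedded metadata (seed, config, version)."""
    from . import __version__

    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    payload = {"package": "telofibre", "version": __version__}
    payload.update(meta)
    payload["result"] = _jsonable(obj)
    path.write_text(json.dumps(payload, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj
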