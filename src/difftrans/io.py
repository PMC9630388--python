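"""Plain-text readers and writers for the pipeline's tables.

Formats:
  trajectories  CSV  track_id,frame,t_s,x_um,y_um,channel,state_truth
  photon trace  CSV  bin_index,count  + JSON sidecar {bin_width_s, channel}
  curve         CSV  lag_s,G,sem
  transform     JSON 6 coefficients + unit + residual
  config        YAML/JSON; every writer can log a config hash for provenance
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correlate import CorrelationCurve, PhotonTrace
from .registration import AffineTransform2D

__all__ = [
    "config_hash",
    "load_config",
    "write_trace",
    "read_trace",
    "write_curve",
    "read_curve",
    "write_transform",
    "read_transform",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_trace(trace: PhotonTrace, path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"bin_index": np.arange(len(trace.counts)), "count": trace.counts}
    ).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"bin_width_s": trace.bin_width, "channel": trace.channel_label})
    )


def read_trace(path) -> PhotonTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PhotonTrace(
        df["count"].to_numpy(), meta["bin_width_s"], meta.get("channel", "")
    )


def write_curve(curve: CorrelationCurve, path) -> None:
    sem = curve.sem if curve.sem is not None else np.full_like(curve.G, np.nan)
    pd.DataFrame({"lag_s": curve.lags, "G": curve.G, "sem": sem}).to_csv(
        path, index=False
    )


def read_curve(path, kind: str = "auto") -> CorrelationCurve:
    df = pd.read_csv(path)
    sem = df["sem"].to_numpy() if "sem" in df and df["sem"].notna().all() else None
    return CorrelationCurve(df["lag_s"].to_numpy(), df["G"].to_numpy(), sem=sem, kind=kind)


def write_transform(t: AffineTransform2D, path) -> None:
    Path(path).write_text(json.dumps(t.as_dict(), indent=1))


def read_transform(path) -> AffineTransform2D:
    d = json.loads(Path(path).read_text())
    t = AffineTransform2D(np.array(d["matrix"]), np.array(d["offset"]), unit=d.get("unit", "px"))
    t.rms_residual = d.get("rms_residual")
    return t
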