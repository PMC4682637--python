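"""Dilution-curve file I/O: 2-column CSV plus a JSON sidecar for metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fatrans.dilution import DilutionCurve, SamplingSchedule

__all__ = ["write_curve", "read_curve"]


def write_curve(curve: DilutionCurve, path: str | Path) -> None:
    """Write ``t_s,conc_per_s`` CSV and a ``.json`` sidecar with metadata."""
    path = Path(path)
    pd.DataFrame({"t_s": curve.times, "conc_per_s": curve.values}).to_csv(path, index=False)
    meta = {
        "normalized": curve.normalized,
        "schedule_edges_s": None if curve.schedule is None else curve.schedule.edges.tolist(),
        "units": {"t_s": "s", "conc_per_s": "s^-1"},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_curve(path: str | Path) -> DilutionCurve:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"t_s", "conc_per_s"} <= set(df.columns):
        raise ValueError(f"{path} lacks the t_s,conc_per_s curve columns")
    schedule = None
    normalized = False
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        normalized = bool(meta.get("normalized", False))
        edges = meta.get("schedule_edges_s")
        if edges is not None:
            schedule = SamplingSchedule(edges=np.asarray(edges, dtype=float))
    return DilutionCurve(
        times=df["t_s"].to_numpy(),
        values=df["conc_per_s"].to_numpy(),
        schedule=schedule,
        normalized=normalized,
    )
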