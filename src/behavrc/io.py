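"""Plain-text file formats.

* Stimulus: two-column delimited text (time_s, intensity_uW_mm2) with a
  YAML sidecar holding the generation parameters.
* Tracks: delimited table (track_id, time_s, state_label); the
  'in transition' label is reserved.
* Kernel: delimited table (lag_s, value) with a YAML sidecar (N, states,
  significance, 99th-percentile null norm).
* LN model: one YAML record bundling the kernel table and the nonlinearity
  (fit parameters plus the per-bin histogram table).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior_core import BehaviorTrack
from .lnmodel import LNModel, Nonlinearity
from .revcorr import Kernel
from .stimgen import StimulusSeries

__all__ = [
    "write_stimulus", "read_stimulus",
    "write_tracks", "read_tracks",
    "write_kernel", "read_kernel",
    "write_ln_model", "read_ln_model",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_stimulus(path: str | Path, stimulus: StimulusSeries, params: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": stimulus.times, "intensity_uW_mm2": stimulus.values})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = {"dt": float(stimulus.dt), "t0": float(stimulus.t0),
            "clip_min": stimulus.clip_min, "clip_max": stimulus.clip_max}
    if params:
        meta["params"] = params
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_stimulus(path: str | Path) -> StimulusSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = {}
    if _sidecar(path).exists():
        meta = yaml.safe_load(_sidecar(path).read_text()) or {}
    t = df["time_s"].to_numpy()
    dt = float(meta.get("dt", np.median(np.diff(t)) if len(t) > 1 else 1.0))
    return StimulusSeries(values=df["intensity_uW_mm2"].to_numpy(), dt=dt,
                          t0=float(meta.get("t0", t[0] if len(t) else 0.0)),
                          clip_min=meta.get("clip_min"), clip_max=meta.get("clip_max"))


def write_tracks(path: str | Path, tracks: list[BehaviorTrack]) -> None:
    frames = [
        pd.DataFrame({"track_id": tr.track_id, "time_s": tr.times,
                      "state_label": tr.labels.astype(str)})
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), sep="\t", index=False,
                                                float_format="%.6f")


def read_tracks(path: str | Path) -> list[BehaviorTrack]:
    df = pd.read_csv(Path(path), sep="\t")
    out = []
    for tid, g in df.groupby("track_id", sort=False):
        t = g["time_s"].to_numpy()
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        out.append(BehaviorTrack(track_id=str(tid), t_start=float(t[0]), dt=dt,
                                 labels=g["state_label"].to_numpy(dtype=object)))
    return out


def write_kernel(path: str | Path, kernel: Kernel, seed: int | None = None) -> None:
    path = Path(path)
    pd.DataFrame({"lag_s": kernel.lags, "value": kernel.values}).to_csv(
        path, sep="\t", index=False, float_format="%.8g")
    meta = {
        "n_events": int(kernel.n_events),
        "n_dropped": int(kernel.n_dropped),
        "to_state": kernel.to_state,
        "from_state": kernel.from_state,
        "significant": kernel.significant,
        "percentile_99": kernel.percentile_99,
        "window_half": float(kernel.window_half),
        "dt": float(kernel.dt),
        "seed": seed,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_kernel(path: str | Path) -> Kernel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = yaml.safe_load(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    values = df["value"].to_numpy()
    lag = df["lag_s"].to_numpy()
    dt = float(meta.get("dt", np.median(np.diff(lag))))
    return Kernel(values=values, dt=dt,
                  window_half=float(meta.get("window_half", lag[-1])),
                  n_events=int(meta.get("n_events", 0)),
                  to_state=meta.get("to_state"), from_state=meta.get("from_state"),
                  n_dropped=int(meta.get("n_dropped", 0)),
                  percentile_99=meta.get("percentile_99"),
                  significant=meta.get("significant"))


def write_ln_model(path: str | Path, model: LNModel) -> None:
    nl = model.nonlinearity
    record = {
        "dt": float(model.dt),
        "kernel": {
            "lag_s": [float(v) for v in model.kernel.lags],
            "value": [float(v) for v in model.kernel.values],
            "n_events": int(model.kernel.n_events),
            "to_state": model.kernel.to_state,
            "from_state": model.kernel.from_state,
            "window_half": float(model.kernel.window_half),
        },
        "nonlinearity": {
            "a": nl.a, "b": nl.b, "a_err": nl.a_err, "b_err": nl.b_err,
            "bins": {
                "center": [float(v) for v in nl.bin_centers],
                "T": [float(v) for v in nl.T],
                "F": [float(v) for v in nl.F],
                "prob": [None if not np.isfinite(v) else float(v) for v in nl.probs],
                "error": [float(v) for v in nl.errors],
            },
        },
    }
    Path(path).write_text(yaml.safe_dump(record, sort_keys=False))


def read_ln_model(path: str | Path) -> LNModel:
    rec = yaml.safe_load(Path(path).read_text())
    k = rec["kernel"]
    kernel = Kernel(values=np.asarray(k["value"], dtype=float), dt=float(rec["dt"]),
                    window_half=float(k["window_half"]), n_events=int(k["n_events"]),
                    to_state=k.get("to_state"), from_state=k.get("from_state"))
    nlr = rec["nonlinearity"]
    bins = nlr["bins"]
    probs = np.array([np.nan if v is None else v for v in bins["prob"]], dtype=float)
    nl = Nonlinearity(bin_centers=np.asarray(bins["center"], dtype=float),
                      probs=probs,
                      errors=np.asarray(bins["error"], dtype=float),
                      T=np.asarray(bins["T"], dtype=float),
                      F=np.asarray(bins["F"], dtype=float),
                      a=float(nlr["a"]), b=float(nlr["b"]),
                      a_err=float(nlr["a_err"]), b_err=float(nlr["b_err"]))
    return LNModel(kernel=kernel, nonlinearity=nl, dt=float(rec["dt"]))
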