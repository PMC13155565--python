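"""File round-tripping: spike/stimulus CSV, HDF5 simulation containers,
JSON sidecars and tidy result tables.

Formats:
* spikes: CSV with columns (unit_id, time_s); times strictly increasing per
  unit at 1e-6-s precision;
* stimuli: single-column CSV (time_s);
* simulations: HDF5 with one dataset per unit under /spikes plus the
  resolved protocol as root attributes;
* fits/selections/configs: JSON.

Unknown CSV columns are preserved on round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import InvalidSpecError
from .protocol import ProtocolSpec, SpikeTrain, StimulusTimes

__all__ = [
    "write_spikes_csv", "read_spikes_csv",
    "write_stimuli_csv", "read_stimuli_csv",
    "write_simulation_h5", "read_simulation_h5",
    "write_json", "read_json", "estimates_table",
]

TIME_DECIMALS = 6  # lossless at 1e-6 s


class ParseError(ValueError):
    pass


def write_spikes_csv(trains: list[SpikeTrain], path) -> None:
    rows = [(tr.unit_id, round(t, TIME_DECIMALS))
            for tr in trains for t in tr.discharge_times_s]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    df.to_csv(path, index=False)


def read_spikes_csv(path, duration_s: float | None = None,
                    sample_rate_hz: float = 2000.0) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    for col in ("unit_id", "time_s"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r} in {path}")
    if df["time_s"].isna().any():
        row = int(df.index[df["time_s"].isna()][0]) + 2  # 1-based + header
        raise ParseError(f"malformed time at line {row} of {path}")
    trains = []
    total = duration_s if duration_s is not None else float(df["time_s"].max())
    for uid, g in df.groupby("unit_id", sort=True):
        t = g["time_s"].to_numpy(float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = int(g.index[bad[0] + 1]) + 2
            raise InvalidSpecError(
                f"non-monotonic time at line {row} of {path}")
        trains.append(SpikeTrain(str(uid), tuple(t), total, sample_rate_hz))
    return trains


def write_stimuli_csv(stims: StimulusTimes, path) -> None:
    pd.DataFrame({"time_s": [round(t, TIME_DECIMALS)
                             for t in stims.onsets_s]}).to_csv(path,
                                                               index=False)


def read_stimuli_csv(path) -> StimulusTimes:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ParseError(f"missing column 'time_s' in {path}")
    t = df["time_s"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise InvalidSpecError(
            f"non-monotonic stimulus time at line {int(bad[0]) + 3} of {path}")
    return StimulusTimes(tuple(t))


def write_simulation_h5(trains: list[SpikeTrain], stims: StimulusTimes,
                        spec: ProtocolSpec, path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("spikes")
        for tr in trains:
            d = grp.create_dataset(tr.unit_id,
                                   data=np.asarray(tr.discharge_times_s))
            d.attrs["duration_s"] = tr.duration_s
            d.attrs["sample_rate_hz"] = tr.sample_rate_hz
        f.create_dataset("stimuli", data=np.asarray(stims.onsets_s))
        for k, v in spec.to_dict().items():
            f.attrs[k] = -1 if v is None else v


def read_simulation_h5(path) -> tuple[list[SpikeTrain], StimulusTimes, dict]:
    with h5py.File(path, "r") as f:
        trains = []
        for uid in sorted(f["spikes"]):
            d = f["spikes"][uid]
            trains.append(SpikeTrain(uid, tuple(np.asarray(d)),
                                     float(d.attrs["duration_s"]),
                                     float(d.attrs["sample_rate_hz"])))
        stims = StimulusTimes(tuple(np.asarray(f["stimuli"])))
        attrs = {k: v for k, v in f.attrs.items()}
    return trains, stims, attrs


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())


def estimates_table(record_units: dict) -> pd.DataFrame:
    """Per-unit estimates as a tidy frame (unit_id, rate_hz, detected,
    onset_ms, end_ms, duration_ms, psth_amp, psf_amp)."""
    rows = []
    for uid, (rate, est) in sorted(record_units.items()):
        rows.append({"unit_id": uid, "rate_hz": rate,
                     "detected": bool(est.detected),
                     "onset_ms": est.onset_ms, "end_ms": est.end_ms,
                     "duration_ms": est.duration_ms,
                     "psth_amp": est.psth_amplitude,
                     "psf_amp": est.psf_amplitude})
    return pd.DataFrame(rows)
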