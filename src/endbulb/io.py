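"""File dialects: TSV event tables, JSON sidecars, matrix containers, WAV.

The event-table dialect is tab-separated UTF-8 with a header row, '.'
decimal, and empty fields for missing values; columns are
(unit_id, condition, trial, time_s, rising_slope_Vps, falling_slope_Vps,
amplitude_mV, is_ap) plus optional stimulus tags.  Matrices (FRA, STRF)
are written as delimited text with a JSON sidecar holding the axes and
metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

TSV_COLUMNS = ["unit_id", "condition", "trial", "time_s", "rising_slope_Vps",
               "falling_slope_Vps", "amplitude_mV", "is_ap",
               "freq_hz", "level_db", "rep"]


def write_events_tsv(events: pd.DataFrame, path, unit_id: str = "unit0") -> None:
    df = events.copy()
    if "unit_id" not in df:
        df.insert(0, "unit_id", unit_id)
    cols = [c for c in TSV_COLUMNS if c in df.columns]
    df = df[cols]
    df["is_ap"] = df["is_ap"].astype(bool).astype(int)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_events_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise ValueError(f"malformed event table {path}: {err}") from err
    required = {"trial", "time_s", "rising_slope_Vps", "is_ap"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table {path} lacks columns {sorted(missing)}")
    df["is_ap"] = df["is_ap"].astype(bool)
    return df


def write_matrix(values: np.ndarray, path, **meta) -> None:
    """Matrix as TSV plus a JSON sidecar with axes/metadata arrays."""
    path = Path(path)
    np.savetxt(path, values, delimiter="\t")
    side = {}
    for k, v in meta.items():
        side[k] = v.tolist() if isinstance(v, np.ndarray) else v
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(side, indent=1))


def read_matrix(path) -> tuple:
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return values, meta


def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    """32-bit float WAV via scipy (audio is optional in this pipeline)."""
    from scipy.io import wavfile
    wavfile.write(path, int(round(sample_rate)),
                  np.asarray(waveform, dtype=np.float32))


def read_wav(path) -> tuple:
    from scipy.io import wavfile
    fs, data = wavfile.read(path)
    return float(fs), np.asarray(data, dtype=float)
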