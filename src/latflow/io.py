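"""Reading and writing the package's plain-text interchange formats.

Signal recordings are delimited text with columns ``time_s, left_cbfv,
right_cbfv, marker`` (marker = task label at trial-onset rows, empty
elsewhere); LI tables travel as long-format CSV (subject, task, session, li,
se); QC reports and model results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LateralityTable
from .preprocess import SignalRecording


def write_recording(recording: SignalRecording, path: str | Path) -> None:
    n = recording.n_samples
    marker = np.full(n, "", dtype=object)
    for idx, task in recording.markers:
        marker[idx] = task
    df = pd.DataFrame({
        "time_s": np.arange(n) / recording.sampling_rate,
        "left_cbfv": recording.left,
        "right_cbfv": recording.right,
        "marker": marker,
    })
    df.to_csv(path, index=False)


def read_recording(path: str | Path, subject: str = "S001",
                   session: int = 1) -> SignalRecording:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"marker": str})
    if len(df) < 2:
        raise ValueError(f"{path}: recording too short")
    dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
    markers = [(int(i), str(m)) for i, m in enumerate(df["marker"]) if m]
    return SignalRecording(
        sampling_rate=1.0 / dt,
        left=df["left_cbfv"].to_numpy(float),
        right=df["right_cbfv"].to_numpy(float),
        markers=markers, subject=subject, session=session,
    )


def write_li_table(table: LateralityTable, path: str | Path) -> None:
    table.to_long().to_csv(path, index=False)


def read_li_table(path: str | Path) -> LateralityTable:
    return LateralityTable.from_long(pd.read_csv(path))


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default,
                                     allow_nan=True))
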