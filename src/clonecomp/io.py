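"""CSV/JSON dialects shared by the generator, the inference pipeline and the CLI.

Growth-curve CSV: columns ``condition, labeled_type, replicate, time_h, signal``.
Assay CSV: columns ``round, duration_h, w_start, w_end, replicate``.
Trajectory CSV: columns ``time_h, L, W, phase``.
All files are comma-separated UTF-8 with a header row and '.' decimals; times
are in hours throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Trajectory
from .synth import CompetitionAssayRecord, GrowthCurve

__all__ = [
    "write_growth_curves",
    "read_growth_curves",
    "write_assays",
    "read_assays",
    "write_trajectory",
    "read_trajectory",
    "write_json",
    "read_json",
]

_CURVE_COLS = ["condition", "labeled_type", "replicate", "time_h", "signal"]
_ASSAY_COLS = ["round", "duration_h", "w_start", "w_end", "replicate"]


def write_growth_curves(curves: Sequence[GrowthCurve], path) -> None:
    df = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    df[_CURVE_COLS].to_csv(path, index=False)


def read_growth_curves(path) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    missing = set(_CURVE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"growth-curve CSV missing columns: {sorted(missing)}")
    out = []
    for (cond, lab, rep), g in df.groupby(
        ["condition", "labeled_type", "replicate"], sort=True
    ):
        g = g.sort_values("time_h")
        out.append(
            GrowthCurve(
                condition=cond,
                labeled_type=lab,
                replicate=str(rep),
                times=g.time_h.to_numpy(dtype=float),
                signal=g.signal.to_numpy(dtype=float),
            )
        )
    return out


def write_assays(records: Sequence[CompetitionAssayRecord], path) -> None:
    df = pd.DataFrame(
        {
            "round": [r.round_index for r in records],
            "duration_h": [r.duration_h for r in records],
            "w_start": [r.w_start for r in records],
            "w_end": [r.w_end for r in records],
            "replicate": [r.replicate for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_assays(path) -> list[CompetitionAssayRecord]:
    df = pd.read_csv(path)
    missing = set(_ASSAY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV missing columns: {sorted(missing)}")
    return [
        CompetitionAssayRecord(
            round_index=int(row["round"]),
            duration_h=float(row["duration_h"]),
            w_start=float(row["w_start"]),
            w_end=float(row["w_end"]),
            replicate=str(row["replicate"]),
        )
        for row in df.to_dict("records")
    ]


def write_trajectory(tr: Trajectory, path) -> None:
    tr.to_frame().to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        t=df.time_h.to_numpy(dtype=float),
        L=df.L.to_numpy(dtype=float),
        W=df.W.to_numpy(dtype=float),
        phase=df.phase.to_numpy(dtype=int),
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
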