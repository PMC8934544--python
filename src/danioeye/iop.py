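"""Rebound-tonometry aggregation: average repeated IOP readings per eye."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EXPECTED_READINGS = 6


@dataclass
class IopRecord:
    eye_id: str
    readings: list[float]
    mean_iop: float
    n_used: int
    qc_flags: list[str] = field(default_factory=list)


def aggregate_iop(
    readings, expected_n: int = EXPECTED_READINGS, eye_id: str = ""
) -> IopRecord:
    """Mean IOP over valid readings (the six-reading averaging protocol).

    Non-finite or non-positive readings are dropped with a qc flag; an
    unexpected retained count is flagged.  No outlier rejection beyond
    validity filtering is applied.
    """
    readings = [float(r) for r in np.atleast_1d(np.asarray(readings, dtype=float))]
    if not readings:
        raise ValueError("no readings supplied")
    arr = np.asarray(readings)
    valid = np.isfinite(arr) & (arr > 0)
    flags: list[str] = []
    if (~np.isfinite(arr)).any():
        flags.append("nonfinite_dropped")
    if (np.isfinite(arr) & (arr <= 0)).any():
        flags.append("nonpositive_dropped")
    if not valid.any():
        raise ValueError("no valid readings (all non-finite or non-positive)")
    n_used = int(valid.sum())
    if n_used != expected_n:
        flags.append(f"n_used_{n_used}_of_{expected_n}")
    return IopRecord(
        eye_id=eye_id,
        readings=readings,
        mean_iop=float(arr[valid].mean()),
        n_used=n_used,
        qc_flags=flags,
    )


def aggregate_iop_csv(path_in: str | Path, expected_n: int = EXPECTED_READINGS) -> pd.DataFrame:
    """Aggregate a (eye_id, reading_mmhg) CSV into one row per eye."""
    df = pd.read_csv(path_in)
    rows = []
    for eye_id, group in df.groupby("eye_id", sort=True):
        rec = aggregate_iop(group["reading_mmhg"].tolist(), expected_n, eye_id=str(eye_id))
        rows.append({"eye_id": rec.eye_id, "mean_iop": rec.mean_iop,
                     "n_used": rec.n_used, "qc_flags": ";".join(rec.qc_flags)})
    return pd.DataFrame(rows)
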