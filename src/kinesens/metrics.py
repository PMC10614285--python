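"""Comparison metrics for occupant displacement time histories.

Four scalar metrics summarize each simulated braking response: the peak
forward displacement of the head and of T1 (the first interior peak,
typically around 0.5 s into the maneuver) and the time-average vertical
displacement of the head and of T1 (vehicle frame, downward positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .mdrm import SensitivityResult
from .surrogate import ResponseRecord

__all__ = [
    "MetricSet",
    "peak_forward",
    "average_vertical",
    "metric_table",
    "influential",
    "DEFAULT_PEAK_WINDOW",
    "DEFAULT_AVG_WINDOW",
]

DEFAULT_PEAK_WINDOW = (0.1, 0.8)  # s
DEFAULT_AVG_WINDOW = (0.0, 1.3)  # s, full pulse duration
PEAK_PROMINENCE = 1.0  # mm


@dataclass(frozen=True)
class MetricSet:
    head_peak_fwd: float  # mm
    t1_peak_fwd: float  # mm
    head_avg_vert: float  # mm
    t1_avg_vert: float  # mm
    head_peak_time: float  # s
    t1_peak_time: float  # s
    flags: str = ""


def _series(resp: ResponseRecord, body: str) -> np.ndarray:
    if body == "head":
        return resp.head
    if body in ("t1", "T1"):
        return resp.t1
    raise ValueError(f"body must be 'head' or 'T1', got {body!r}")


def peak_forward(
    resp: ResponseRecord,
    body: str = "head",
    window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    prominence: float = PEAK_PROMINENCE,
) -> tuple[float, float, bool]:
    """First interior forward-displacement peak inside the window.

    Returns (value mm, time s, flagged).  ``flagged`` is True when no
    interior local maximum with the required prominence exists and the
    window maximum is reported instead.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty peak window")
    mask = (resp.time >= lo) & (resp.time <= hi)
    if not mask.any():
        raise ValueError("peak window outside the record")
    t = resp.time[mask]
    x = _series(resp, body)[mask, 0]
    peaks, _ = find_peaks(x, prominence=prominence)
    if len(peaks):
        i = peaks[0]
        return float(x[i]), float(t[i]), False
    i = int(np.argmax(x))
    return float(x[i]), float(t[i]), True


def average_vertical(
    resp: ResponseRecord,
    body: str = "head",
    window: tuple[float, float] = DEFAULT_AVG_WINDOW,
) -> float:
    """Time-average vertical displacement (mm, downward positive) over
    the window, by trapezoidal integration divided by window length."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty averaging window")
    mask = (resp.time >= lo) & (resp.time <= hi)
    t = resp.time[mask]
    if len(t) < 2:
        raise ValueError("averaging window outside the record")
    z = _series(resp, body)[mask, 2]
    return float(np.trapezoid(z, t) / (t[-1] - t[0]))


def metric_set(
    resp: ResponseRecord,
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    avg_window: tuple[float, float] = DEFAULT_AVG_WINDOW,
) -> MetricSet:
    hp, ht, hflag = peak_forward(resp, "head", peak_window)
    tp, tt, tflag = peak_forward(resp, "T1", peak_window)
    flags = ";".join(
        f for f, on in (("head_no_interior_peak", hflag), ("t1_no_interior_peak", tflag)) if on
    )
    return MetricSet(
        head_peak_fwd=hp,
        t1_peak_fwd=tp,
        head_avg_vert=average_vertical(resp, "head", avg_window),
        t1_avg_vert=average_vertical(resp, "T1", avg_window),
        head_peak_time=ht,
        t1_peak_time=tt,
        flags=flags,
    )


def metric_table(
    runs: list[tuple[str, ResponseRecord]],
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    avg_window: tuple[float, float] = DEFAULT_AVG_WINDOW,
) -> pd.DataFrame:
    """One row per run, deterministically ordered by run_id."""
    ids = [rid for rid, _ in runs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate run ids: {dupes}")
    rows = {}
    for rid, resp in runs:
        ms = metric_set(resp, peak_window, avg_window)
        rows[rid] = {
            "head_peak_fwd_mm": ms.head_peak_fwd,
            "head_peak_time_s": ms.head_peak_time,
            "t1_peak_fwd_mm": ms.t1_peak_fwd,
            "t1_peak_time_s": ms.t1_peak_time,
            "head_avg_vert_mm": ms.head_avg_vert,
            "t1_avg_vert_mm": ms.t1_avg_vert,
            "flags": ms.flags,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "run_id"
    return df


def influential(sens: SensitivityResult, threshold: float = 1.0 / 7.0) -> list[str]:
    """Parameters with sensitivity index strictly above the threshold,
    sorted by descending index.  The default threshold 1/7 is the
    equal-sensitivity level for seven parameters."""
    order = np.argsort(-sens.S)
    return [
        sens.parameters[i]
        for i in order
        if np.isfinite(sens.S[i]) and sens.S[i] > threshold
    ]
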