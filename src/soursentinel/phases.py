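"""Phase segmentation of bioreactor columns from sulfide and treatment data.

Each (column, time point) is assigned one of four phases:

``S``
    sulfidogenesis — before nitrate amendment (nontreated columns stay
    in S throughout);
``TM``
    transition to mitigation — nitrate applied but sulfide still above
    the threshold (1 mM by default, strict comparison);
``M``
    mitigation — entered at the first treated time point with sulfide
    at or below the threshold, and kept until nitrate withdrawal even
    if sulfide later blips above the threshold;
``R``
    rebound sulfidogenesis — from nitrate withdrawal onward.

Missing sulfide at a requested time point is filled by carrying the
last observation forward; a time point before the first observation is
an error.
"""

from __future__ import annotations

import logging
from numbers import Number
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["assign_phases"]


def _sulfide_at(times: np.ndarray, obs: pd.DataFrame, column_id: str) -> np.ndarray:
    """Sulfide at each requested time, last observation carried forward."""
    obs = obs.sort_values("time_point")
    t_obs = obs["time_point"].to_numpy(float)
    v_obs = obs["sulfide_mm"].to_numpy(float)
    idx = np.searchsorted(t_obs, times, side="right") - 1
    if (idx < 0).any():
        bad = times[idx < 0][0]
        raise ValidationError(
            f"no sulfide observation at or before day {bad} for {column_id!r}"
        )
    return v_obs[idx]


def assign_phases(
    sulfide: pd.DataFrame,
    schedule: pd.DataFrame,
    threshold_mm: float | Mapping[str, float] = 1.0,
    times: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign an S/TM/M/R phase to every (column, time point).

    Parameters
    ----------
    sulfide
        Long table ``column_id, time_point, sulfide_mm``.
    schedule
        Long table ``column_id, nitrate_start, nitrate_stop`` (day
        offsets; both null for nontreated columns).
    threshold_mm
        Sulfide threshold for the TM -> M transition. TM is kept while
        sulfide is strictly above the threshold. Either a scalar or a
        per-column mapping (falling back to 1.0).
    times
        Optional long table ``column_id, time_point`` giving the grid
        to label; defaults to the sulfide observation times.

    Returns
    -------
    DataFrame with columns ``column_id, time_point, phase``.
    """
    grid = times if times is not None else sulfide[["column_id", "time_point"]]
    sched = schedule.set_index("column_id")
    if sched.index.has_duplicates:
        raise ValidationError("duplicate column_id in schedule")

    out = []
    for column_id, grp in grid.groupby("column_id", sort=True):
        t = np.sort(np.unique(grp["time_point"].to_numpy(float)))
        if column_id not in sched.index:
            raise ValidationError(f"column {column_id!r} missing from schedule")
        row = sched.loc[column_id]
        start, stop = row["nitrate_start"], row["nitrate_stop"]
        thr = (
            float(threshold_mm)
            if isinstance(threshold_mm, Number)
            else float(threshold_mm.get(column_id, 1.0))
        )
        if pd.isna(start):
            phase = np.full(t.size, "S", dtype=object)
        else:
            obs = sulfide[sulfide["column_id"] == column_id]
            if obs.empty:
                raise ValidationError(
                    f"treated column {column_id!r} has no sulfide series"
                )
            s = _sulfide_at(t, obs, column_id)
            phase = np.full(t.size, "S", dtype=object)
            in_m = False
            for i, (ti, si) in enumerate(zip(t, s)):
                if ti < float(start):
                    continue
                if not pd.isna(stop) and ti >= float(stop):
                    phase[i] = "R"
                elif in_m or si <= thr:
                    in_m = True
                    phase[i] = "M"
                else:
                    phase[i] = "TM"
        out.append(
            pd.DataFrame(
                {
                    "column_id": column_id,
                    "time_point": t.astype(int),
                    "phase": phase,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
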