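"""Packaged reference tables.

``study_columns.tsv`` records the published per-column bookkeeping of
the 20-bioreactor souring-mitigation study this package models: how
many sequenced samples each column contributed (with and without the
three sessile sections harvested at column sacrifice), its treatment
arm, operating temperature and harvest batch. The loader can expand
that design table into a full per-sample metadata table for
bookkeeping and plumbing tests.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: day offsets of the four sessile harvest batches (day 0 = experiment start)
HARVEST_DAYS = {1: 68, 2: 73, 3: 113, 4: 148}

#: day offsets of the nitrate amendment window in the study design
NITRATE_START_DAY = 43
NITRATE_STOP_DAY = 120


def study_design() -> pd.DataFrame:
    """Return the per-column design table (one row per bioreactor)."""
    with resources.files("soursentinel.data").joinpath("study_columns.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def study_sample_metadata() -> pd.DataFrame:
    """Expand the design table into one metadata row per sequenced sample.

    Effluent samples are placed on an evenly spaced day grid from day 0
    to the column's sacrifice day (day 148 for the unharvested column);
    sessile samples (three sections) sit at the column's harvest day.
    The per-column counts reproduce the published totals: 731 samples,
    674 effluent and 57 sessile.
    """
    design = study_design()
    rows = []
    for rec in design.itertuples(index=False):
        batch = int(rec.harvest_batch)
        end_day = HARVEST_DAYS.get(batch, max(HARVEST_DAYS.values()))
        n_eff = int(rec.n_samples_effluent)
        days = np.unique(np.round(np.linspace(0, end_day, n_eff)).astype(int))
        # rounding collisions would drop samples; the grids used here are safe
        assert len(days) == n_eff
        for day in days:
            rows.append(
                {
                    "sample_id": f"{rec.column_id}_d{day:03d}",
                    "column_id": rec.column_id,
                    "time_point": int(day),
                    "sample_type": "effluent",
                    "section": "none",
                    "treatment": rec.treatment,
                    "temperature_c": float(rec.temperature_c),
                }
            )
        n_sessile = int(rec.n_samples_total) - n_eff
        sections = ("top", "middle", "bottom")[:n_sessile]
        for section in sections:
            rows.append(
                {
                    "sample_id": f"{rec.column_id}_sessile_{section}",
                    "column_id": rec.column_id,
                    "time_point": end_day,
                    "sample_type": "sessile",
                    "section": section,
                    "treatment": rec.treatment,
                    "temperature_c": float(rec.temperature_c),
                }
            )
    return pd.DataFrame(rows)
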