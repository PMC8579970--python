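"""Mitigation indicator inference from effluent community time series.

This is the analytical core of the package: starting from raw amplicon
counts it

1. divides each taxon's counts by its 16S rRNA gene copy number,
2. aggregates sequence variants to their closest-genome label,
3. converts to relative abundance (%),
4. ranks SRB genomes per column by their mean relative abundance in the
   TM phase — the top-ranked genome is the column's specific SRB
   population (SSP), the candidate biofilm-dispersal indicator,
5. computes the anomaly series (x_t - m)/m around the column mean m,
6. flags critical time points: TM-phase time points whose SSP relative
   abundance strictly exceeds the TM-phase mean,
7. scales SSP relative abundance by flow-cytometry total cell counts to
   absolute cells/ml, after removing per-phase Tukey outliers from the
   totals.

The anomaly averaging window is, by construction, all effluent time
points of the column, so every anomaly series sums to zero over its
window.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diversity import group_compare
from .errors import DomainError, ValidationError
from .io_model import ColumnIndicators, CountTable, ExperimentBundle, IndicatorReport

logger = logging.getLogger(__name__)

__all__ = [
    "correct_copy_number",
    "aggregate_to_genomes",
    "relative_abundance",
    "anomaly_series",
    "detect_critical_time_points",
    "select_ssp_candidates",
    "ssp_cell_abundance",
    "flag_tukey_outliers",
    "genome_percent_table",
    "build_indicator_report",
]


# ---------------------------------------------------------------------
# abundance transforms
# ---------------------------------------------------------------------


def correct_copy_number(counts: CountTable, annotations: pd.DataFrame) -> CountTable:
    """Divide each taxon's counts by its 16S rRNA gene copy number.

    Refuses tables already flagged as corrected (double correction
    would silently bias every downstream abundance).
    """
    if counts.corrected:
        raise ValidationError("count table is already copy-number corrected")
    missing = counts.data.columns.difference(annotations.index)
    if len(missing):
        raise ValidationError(f"taxa without copy-number annotation: {sorted(missing)[:5]}")
    copies = annotations.loc[counts.data.columns, "copy_number"].astype(float)
    if (copies <= 0).any():
        raise ValidationError("non-positive copy number in annotations")
    return CountTable(counts.data / copies.to_numpy(), corrected=True, percent=counts.percent)


def aggregate_to_genomes(counts: CountTable, annotations: pd.DataFrame) -> CountTable:
    """Sum corrected abundances of all sequence variants per genome label.

    Total abundance per sample is conserved; the result is keyed by
    ``genome_label`` instead of ``taxon_id``.
    """
    if not counts.corrected:
        raise ValidationError("aggregate_to_genomes expects a copy-number-corrected table")
    missing = counts.data.columns.difference(annotations.index)
    if len(missing):
        raise ValidationError(f"unannotated taxa: {sorted(missing)[:5]}")
    labels = annotations.loc[counts.data.columns, "genome_label"]
    out = counts.data.T.groupby(labels.to_numpy()).sum().T
    out.columns.name = "genome_label"
    return CountTable(out, corrected=True, percent=counts.percent)


def relative_abundance(counts: CountTable) -> CountTable:
    """Rescale each sample (row) to sum to 100."""
    totals = counts.data.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise DomainError(f"sample {bad!r} has zero total abundance")
    return CountTable(
        counts.data.div(totals, axis=0) * 100.0, corrected=counts.corrected, percent=True
    )


def genome_percent_table(bundle: ExperimentBundle) -> CountTable:
    """Raw counts -> copy-number-corrected genome-level relative abundance (%)."""
    corrected = correct_copy_number(bundle.counts, bundle.annotations)
    return relative_abundance(aggregate_to_genomes(corrected, bundle.annotations))


# ---------------------------------------------------------------------
# anomalies and critical time points
# ---------------------------------------------------------------------


def anomaly_series(
    values: pd.Series, window: Iterable | None = None
) -> pd.DataFrame:
    """Relative deviation (x_t - m)/m around the window mean m.

    ``values`` is a time-indexed series of relative abundances (%);
    ``window`` selects the time points the mean is taken over (all of
    them by default). Anomalies are returned for every time point.
    """
    values = values.astype(float)
    win = list(window) if window is not None else list(values.index)
    if not win:
        raise DomainError("averaging window is empty")
    m = float(values.loc[win].mean())
    if m <= 0:
        raise DomainError("window mean is not positive (signal absent from column)")
    return pd.DataFrame(
        {
            "time_point": values.index.to_numpy(),
            "anomaly": (values.to_numpy() - m) / m,
            "window_mean": m,
        }
    )


def detect_critical_time_points(
    values: pd.Series, phase_by_time: pd.Series
) -> list[int]:
    """Time points in TM whose value strictly exceeds the TM mean.

    ``values`` is the SSP relative abundance (%) per time point for one
    column; ``phase_by_time`` maps the same time points to phase
    labels. Returns a sorted list; an empty TM phase yields an empty
    list with a warning (nontreated or never-souring column).
    """
    tm_times = [t for t in values.index if phase_by_time.get(t) == "TM"]
    if not tm_times:
        warnings.warn("column has no TM phase; no critical time points", stacklevel=2)
        return []
    tm_mean = float(values.loc[tm_times].mean())
    return sorted(int(t) for t in tm_times if float(values.loc[t]) > tm_mean)


def select_ssp_candidates(
    genome_pct: pd.DataFrame,
    annotations: pd.DataFrame,
    phase_by_time: pd.Series,
    floor: float = 0.0,
) -> list[tuple[str, float]]:
    """Rank SRB genomes of one column by TM-phase mean relative abundance.

    ``genome_pct`` is a time x genome table of relative abundances (%)
    for the column's effluent samples. Ties are broken
    lexicographically by genome label. Only genomes with a TM mean
    strictly above ``floor`` are returned (the default floor of 0
    reports all SRB genomes present), so columns with several
    co-dispersing SRB populations keep all candidates.
    """
    srb_genomes = sorted(
        set(annotations.loc[annotations["is_srb"].astype(bool), "genome_label"])
    )
    if not srb_genomes:
        raise ValidationError("no SRB-flagged taxa in the annotations")
    tm_times = [t for t in genome_pct.index if phase_by_time.get(t) == "TM"]
    if not tm_times:
        raise DomainError("column has no TM phase; cannot rank SSP candidates")
    present = [g for g in srb_genomes if g in genome_pct.columns]
    means = genome_pct.loc[tm_times, present].mean(axis=0)
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(g, float(m)) for g, m in ranked if m > floor]


# ---------------------------------------------------------------------
# absolute abundance
# ---------------------------------------------------------------------


def ssp_cell_abundance(rel_pct, total_cells_per_ml):
    """SSP cells/ml = relative abundance (%) / 100 x total cells/ml."""
    rel = np.asarray(rel_pct, dtype=float)
    total = np.asarray(total_cells_per_ml, dtype=float)
    if ((rel < 0) | (rel > 100)).any():
        raise DomainError("relative abundance must be within [0, 100] percent")
    if (total <= 0).any():
        raise DomainError("total cell count must be positive")
    out = rel / 100.0 * total
    return float(out) if out.ndim == 0 else out


def flag_tukey_outliers(values: Sequence[float]) -> np.ndarray:
    """Tukey fences: flag v outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics (the
    value at position 1 + (n-1)q). Fewer than four observations cannot
    anchor the fences; all pass, with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("empty input")
    if x.size < 4:
        warnings.warn("fewer than 4 values; no outliers flagged", stacklevel=2)
        return np.zeros(x.size, dtype=bool)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)


# ---------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------


def build_indicator_report(
    bundle: ExperimentBundle,
    phase_assignment: pd.DataFrame,
    ssp_floor: float = 0.0,
) -> IndicatorReport:
    """Run the full indicator inference for every treated column.

    ``phase_assignment`` is the long table produced by
    :func:`soursentinel.phases.assign_phases`. For each treated column
    the report contains the ranked SSP candidates, the top candidate's
    anomaly series and critical time points, phase-wise SSP cell
    abundances (with critical time points split out as their own "CT"
    group and per-group Tukey outliers removed from the totals first)
    and a Kruskal-Wallis test across the phase groups.
    """
    genome_pct = genome_percent_table(bundle)
    effluent = bundle.samples[bundle.samples["sample_type"] == "effluent"]
    phase_lookup = {
        (r.column_id, r.time_point): r.phase
        for r in phase_assignment.itertuples(index=False)
    }

    columns: dict[str, ColumnIndicators] = {}
    anomaly_frames: list[pd.DataFrame] = []
    for column_id in bundle.treated_columns():
        meta = effluent[effluent["column_id"] == column_id].sort_values("time_point")
        table = genome_pct.data.loc[meta["sample_id"]]
        table.index = pd.Index(meta["time_point"].to_numpy(int), name="time_point")
        phase_by_time = pd.Series(
            [phase_lookup.get((column_id, t), "S") for t in table.index],
            index=table.index,
        )

        candidates = select_ssp_candidates(
            table, bundle.annotations, phase_by_time, floor=ssp_floor
        )
        result = ColumnIndicators(column_id=column_id, ssp_rank=candidates)
        if candidates:
            ssp = candidates[0][0]
            series = table[ssp]
            anomalies = anomaly_series(series)
            anomalies.insert(0, "signal", ssp)
            anomalies.insert(0, "column_id", column_id)
            anomaly_frames.append(anomalies)
            result.critical_time_points = detect_critical_time_points(
                series, phase_by_time
            )
            result.phase_cells, result.kruskal = _phase_cell_summary(
                bundle, column_id, series, phase_by_time, result.critical_time_points
            )
        columns[column_id] = result
        logger.info(
            "column %s: %d SSP candidates, %d critical time points",
            column_id,
            len(candidates),
            len(result.critical_time_points),
        )

    anomalies = (
        pd.concat(anomaly_frames, ignore_index=True)
        if anomaly_frames
        else IndicatorReport().anomalies
    )
    return IndicatorReport(columns=columns, anomalies=anomalies)


def _phase_cell_summary(
    bundle: ExperimentBundle,
    column_id: str,
    ssp_pct: pd.Series,
    phase_by_time: pd.Series,
    critical: list[int],
) -> tuple[dict[str, list[float]], tuple[float, float] | None]:
    """SSP cells/ml grouped by phase (critical time points as "CT")."""
    cells = bundle.cells[bundle.cells["column_id"] == column_id]
    totals = dict(zip(cells["time_point"].astype(int), cells["cells_per_ml"].astype(float)))
    groups: dict[str, list[tuple[int, float]]] = {}
    for t in ssp_pct.index:
        if int(t) not in totals:
            continue
        label = "CT" if int(t) in critical else str(phase_by_time.loc[t])
        groups.setdefault(label, []).append((int(t), totals[int(t)]))

    phase_cells: dict[str, list[float]] = {}
    for label, pairs in groups.items():
        total_vec = np.array([v for _, v in pairs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            keep = ~flag_tukey_outliers(total_vec)
        kept = [(t, v) for (t, v), k in zip(pairs, keep) if k]
        phase_cells[label] = [
            ssp_cell_abundance(float(ssp_pct.loc[t]), v) for t, v in kept
        ]

    testable = {k: v for k, v in phase_cells.items() if len(v) >= 1}
    kruskal = None
    if len(testable) >= 2:
        pooled = np.concatenate([np.asarray(v) for v in testable.values()])
        if np.unique(pooled).size > 1:
            kruskal = group_compare(testable, method="kruskal_wallis")
    return phase_cells, kruskal
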