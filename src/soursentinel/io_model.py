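"""Data model and tabular I/O for bioreactor souring time-series experiments.

An experiment is described by six flat tables that together form an
:class:`ExperimentBundle`:

``counts``
    samples x taxa table of 16S amplicon abundances (raw read counts or
    16S-copy-number-corrected values; a flag records which).
``annotations``
    one row per unique sequence variant (taxon): closest-genome label,
    SRB flag, 16S rRNA gene copy number, and presence of the
    dissimilatory sulfate reduction (DSR) pathway.
``samples``
    per-sample metadata: bioreactor column, day index, effluent/sessile,
    section, treated/nontreated, temperature.
``sulfide``
    per-column sulfide concentration time series (mM).
``schedule``
    per-column nitrate amendment window (start/stop day, dose in mM).
``cells``
    per-column flow-cytometry total cell counts (cells/ml).

Time points are stored as integer day offsets from experiment start;
calendar dates in input files are converted on load, using the earliest
date found anywhere in the bundle as day 0. The canonical on-disk
dialect is TSV with a header row; comma-separated files are accepted on
read.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

PHASES = ("S", "TM", "M", "R")
SECTIONS = ("top", "middle", "bottom", "none")
SAMPLE_TYPES = ("effluent", "sessile")
TREATMENTS = ("treated", "nontreated")

#: canonical file names inside a bundle directory
BUNDLE_FILES = {
    "counts": "counts.tsv",
    "annotations": "annotations.tsv",
    "samples": "metadata.tsv",
    "sulfide": "sulfide.tsv",
    "schedule": "schedule.tsv",
    "cells": "cells.tsv",
}

ANNOTATION_COLUMNS = ["taxon_id", "genome_label", "is_srb", "copy_number", "has_dsr"]
SAMPLE_COLUMNS = [
    "sample_id",
    "column_id",
    "time_point",
    "sample_type",
    "section",
    "treatment",
    "temperature_c",
]
SULFIDE_COLUMNS = ["column_id", "time_point", "sulfide_mm"]
SCHEDULE_COLUMNS = ["column_id", "nitrate_start", "nitrate_stop", "nitrate_mm"]
CELL_COLUMNS = ["column_id", "time_point", "cells_per_ml", "outlier"]


@dataclass
class TaxonAnnotation:
    """Annotation of one unique sequence variant."""

    taxon_id: str
    genome_label: str
    is_srb: bool
    copy_number: float
    has_dsr: bool


@dataclass
class SampleRecord:
    """Metadata for one sequenced sample."""

    sample_id: str
    column_id: str
    time_point: int
    sample_type: str
    section: str
    treatment: str
    temperature_c: float


@dataclass(eq=False)
class CountTable:
    """Samples x taxa abundance matrix with provenance flags.

    ``corrected`` records whether 16S copy-number correction has been
    applied (correction of an already-corrected table is refused
    downstream); ``percent`` records whether rows have been rescaled to
    sum to 100.
    """

    data: pd.DataFrame
    corrected: bool = False
    percent: bool = False

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in count table")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate taxon ids in count table")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            bad = self.data.index[(values < 0).any(axis=1)][0]
            raise ValidationError(f"negative count in sample {bad!r}")
        if np.isnan(values).any():
            raise ValidationError("missing values in count table")

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), self.corrected, self.percent)

    def equals(self, other: "CountTable") -> bool:
        return (
            self.corrected == other.corrected
            and self.percent == other.percent
            and self.data.shape == other.data.shape
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.data.to_numpy(float), other.data.to_numpy(float))
        )


@dataclass(eq=False)
class ExperimentBundle:
    """The joined data model for one experiment (all six tables)."""

    counts: CountTable
    annotations: pd.DataFrame  # indexed by taxon_id
    samples: pd.DataFrame
    sulfide: pd.DataFrame
    schedule: pd.DataFrame
    cells: pd.DataFrame

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check schema and referential integrity of all member tables."""
        self.counts.validate()
        self._validate_annotations()
        self._validate_samples()
        self._validate_sulfide()
        self._validate_schedule()
        self._validate_cells()

    def _validate_annotations(self) -> None:
        ann = self.annotations
        for col in ("genome_label", "is_srb", "copy_number", "has_dsr"):
            if col not in ann.columns:
                raise ValidationError(f"annotations missing column {col!r}")
        if ann.index.has_duplicates:
            raise ValidationError("duplicate taxon_id in annotations")
        if (ann["copy_number"] <= 0).any():
            bad = ann.index[ann["copy_number"] <= 0][0]
            raise ValidationError(f"non-positive copy number for taxon {bad!r}")
        missing = self.counts.data.columns.difference(ann.index)
        if len(missing):
            raise ValidationError(
                f"taxa in counts without annotation: {sorted(missing)[:5]}"
            )

    def _validate_samples(self) -> None:
        s = self.samples
        for col in SAMPLE_COLUMNS:
            if col not in s.columns:
                raise ValidationError(f"sample metadata missing column {col!r}")
        if s["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        unknown = set(s["sample_type"]) - set(SAMPLE_TYPES)
        if unknown:
            raise ValidationError(f"unknown sample_type values {sorted(unknown)}")
        unknown = set(s["treatment"]) - set(TREATMENTS)
        if unknown:
            raise ValidationError(f"unknown treatment values {sorted(unknown)}")
        # sessile <=> section != none
        sessile = s["sample_type"] == "sessile"
        bad = (sessile & (s["section"] == "none")) | (~sessile & (s["section"] != "none"))
        if bad.any():
            raise ValidationError(
                f"sample_type/section mismatch for {s.loc[bad, 'sample_id'].iloc[0]!r}"
            )
        orphans = self.counts.data.index.difference(pd.Index(s["sample_id"]))
        if len(orphans):
            raise ValidationError(
                f"samples in counts absent from metadata: {sorted(orphans)[:5]}"
            )

    def _validate_sulfide(self) -> None:
        sul = self.sulfide
        for col in SULFIDE_COLUMNS:
            if col not in sul.columns:
                raise ValidationError(f"sulfide table missing column {col!r}")
        if (sul["sulfide_mm"] < 0).any():
            raise ValidationError("negative sulfide concentration")
        for column_id, grp in sul.groupby("column_id"):
            t = grp["time_point"].to_numpy()
            if len(t) != len(np.unique(t)):
                raise ValidationError(f"duplicate sulfide time point in {column_id!r}")

    def _validate_schedule(self) -> None:
        sch = self.schedule
        for col in SCHEDULE_COLUMNS:
            if col not in sch.columns:
                raise ValidationError(f"schedule table missing column {col!r}")
        both = sch.dropna(subset=["nitrate_start", "nitrate_stop"])
        if (both["nitrate_start"] >= both["nitrate_stop"]).any():
            raise ValidationError("nitrate_start must precede nitrate_stop")
        treated_cols = set(
            self.samples.loc[self.samples["treatment"] == "treated", "column_id"]
        )
        scheduled = set(sch.loc[sch["nitrate_start"].notna(), "column_id"])
        missing = treated_cols - scheduled
        if missing:
            raise ValidationError(
                f"treated columns without nitrate schedule: {sorted(missing)}"
            )

    def _validate_cells(self) -> None:
        c = self.cells
        for col in ("column_id", "time_point", "cells_per_ml"):
            if col not in c.columns:
                raise ValidationError(f"cell count table missing column {col!r}")
        if (c["cells_per_ml"] <= 0).any():
            raise ValidationError("non-positive cell count")

    # -- helpers ------------------------------------------------------

    def treated_columns(self) -> list[str]:
        return sorted(
            set(self.samples.loc[self.samples["treatment"] == "treated", "column_id"])
        )

    def nontreated_columns(self) -> list[str]:
        return sorted(
            set(self.samples.loc[self.samples["treatment"] == "nontreated", "column_id"])
        )

    def equals(self, other: "ExperimentBundle") -> bool:
        """Field-by-field equality (used by round-trip tests)."""
        if not self.counts.equals(other.counts):
            return False
        pairs = [
            (self.annotations.sort_index(), other.annotations.sort_index()),
            (_norm(self.samples, "sample_id"), _norm(other.samples, "sample_id")),
            (_norm(self.sulfide, ["column_id", "time_point"]),
             _norm(other.sulfide, ["column_id", "time_point"])),
            (_norm(self.schedule, "column_id"), _norm(other.schedule, "column_id")),
            (_norm(self.cells, ["column_id", "time_point"]),
             _norm(other.cells, ["column_id", "time_point"])),
        ]
        for a, b in pairs:
            if a.shape != b.shape:
                return False
            for col in a.columns:
                if col not in b.columns:
                    return False
                av, bv = a[col].to_numpy(), b[col].to_numpy()
                if av.dtype.kind in "fiu" and bv.dtype.kind in "fiu":
                    if not np.allclose(
                        av.astype(float), bv.astype(float), equal_nan=True
                    ):
                        return False
                elif not (
                    pd.Series(av).fillna("<NA>") == pd.Series(bv).fillna("<NA>")
                ).all():
                    return False
        return True


def _norm(df: pd.DataFrame, by) -> pd.DataFrame:
    return df.sort_values(by, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------
# reading / writing bundles
# ---------------------------------------------------------------------


def _read_table(path: Path) -> pd.DataFrame:
    """Read a TSV (canonical) or CSV table with a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def _coerce_days(values: pd.Series, epoch) -> pd.Series:
    """Convert a time column to integer day offsets.

    Integer-valued input is passed through; anything else is parsed as
    calendar dates and measured from ``epoch``.
    """
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.notna().all() or (numeric.isna() == values.isna()).all():
        return numeric.round().astype("Int64")
    dates = pd.to_datetime(values, errors="raise")
    return ((dates - epoch).dt.days).astype("Int64")


def _find_epoch(frames: list[tuple[pd.DataFrame, list[str]]]):
    dates = []
    for df, cols in frames:
        for col in cols:
            if col not in df.columns:
                continue
            numeric = pd.to_numeric(df[col], errors="coerce")
            mask = numeric.isna() & df[col].notna()
            if mask.any():
                dates.append(pd.to_datetime(df.loc[mask, col]).min())
    return min(dates) if dates else None


def load_bundle(source: str | Path | Mapping[str, str | Path]) -> ExperimentBundle:
    """Load and validate an :class:`ExperimentBundle`.

    Parameters
    ----------
    source
        Either a directory containing the canonical file names
        (``counts.tsv``, ``annotations.tsv``, ``metadata.tsv``,
        ``sulfide.tsv``, ``schedule.tsv``, ``cells.tsv``) or a mapping
        from table name to file path.
    """
    if isinstance(source, (str, Path)):
        base = Path(source)
        paths = {k: base / v for k, v in BUNDLE_FILES.items()}
        meta_path = base / "bundle_meta.json"
    else:
        paths = {k: Path(v) for k, v in source.items()}
        missing = set(BUNDLE_FILES) - set(paths)
        if missing:
            raise ValidationError(f"missing table paths: {sorted(missing)}")
        meta_path = paths["counts"].parent / "bundle_meta.json"

    counts_raw = _read_table(paths["counts"])
    annotations = _read_table(paths["annotations"])
    samples = _read_table(paths["samples"])
    sulfide = _read_table(paths["sulfide"])
    schedule = _read_table(paths["schedule"])
    cells = _read_table(paths["cells"])

    epoch = _find_epoch(
        [
            (samples, ["time_point"]),
            (sulfide, ["time_point"]),
            (schedule, ["nitrate_start", "nitrate_stop"]),
            (cells, ["time_point"]),
        ]
    )
    samples = samples.copy()
    samples["time_point"] = _coerce_days(samples["time_point"], epoch)
    sulfide = sulfide.copy()
    sulfide["time_point"] = _coerce_days(sulfide["time_point"], epoch)
    cells = cells.copy()
    cells["time_point"] = _coerce_days(cells["time_point"], epoch)
    schedule = schedule.copy()
    for col in ("nitrate_start", "nitrate_stop"):
        schedule[col] = _coerce_days(schedule[col], epoch)
    if "outlier" not in cells.columns:
        cells["outlier"] = False
    cells["outlier"] = cells["outlier"].astype(bool)
    if "section" in samples.columns:
        samples["section"] = samples["section"].fillna("none")

    if counts_raw.empty:
        logger.warning("count table %s has no samples", paths["counts"])
        data = pd.DataFrame(
            index=pd.Index([], name="sample_id"),
            columns=counts_raw.columns[1:] if counts_raw.shape[1] else [],
            dtype=float,
        )
    else:
        data = counts_raw.set_index(counts_raw.columns[0])
        data.index.name = "sample_id"
    corrected = percent = False
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        corrected = bool(meta.get("corrected", False))
        percent = bool(meta.get("percent", False))

    bundle = ExperimentBundle(
        counts=CountTable(data.astype(float), corrected=corrected, percent=percent),
        annotations=annotations.set_index("taxon_id"),
        samples=samples,
        sulfide=sulfide,
        schedule=schedule,
        cells=cells,
    )
    bundle.validate()
    for name, df in (
        ("counts", bundle.counts.data),
        ("annotations", bundle.annotations),
        ("samples", samples),
        ("sulfide", sulfide),
        ("schedule", schedule),
        ("cells", cells),
    ):
        logger.info("loaded %s: %d records", name, len(df))
    return bundle


def write_bundle(bundle: ExperimentBundle, directory: str | Path) -> Path:
    """Write all bundle tables as TSV under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.counts.data.rename_axis("sample_id").reset_index().to_csv(
        directory / BUNDLE_FILES["counts"], sep="\t", index=False
    )
    bundle.annotations.rename_axis("taxon_id").reset_index().to_csv(
        directory / BUNDLE_FILES["annotations"], sep="\t", index=False
    )
    bundle.samples.to_csv(directory / BUNDLE_FILES["samples"], sep="\t", index=False)
    bundle.sulfide.to_csv(directory / BUNDLE_FILES["sulfide"], sep="\t", index=False)
    bundle.schedule.to_csv(directory / BUNDLE_FILES["schedule"], sep="\t", index=False)
    bundle.cells.to_csv(directory / BUNDLE_FILES["cells"], sep="\t", index=False)
    (directory / "bundle_meta.json").write_text(
        json.dumps(
            {"corrected": bundle.counts.corrected, "percent": bundle.counts.percent}
        )
    )
    return directory


# ---------------------------------------------------------------------
# indicator report
# ---------------------------------------------------------------------


@dataclass(eq=False)
class ColumnIndicators:
    """Per-column mitigation indicator results."""

    column_id: str
    #: SRB genomes ranked by TM-phase mean relative abundance (%), descending
    ssp_rank: list[tuple[str, float]] = field(default_factory=list)
    #: TM-phase time points where the top SSP exceeds its TM mean
    critical_time_points: list[int] = field(default_factory=list)
    #: phase label ("S", "CT", "M", "R") -> SSP cells/ml, Tukey outliers removed
    phase_cells: dict[str, list[float]] = field(default_factory=dict)
    #: Kruskal-Wallis (H, p) across phase groups, or None if not testable
    kruskal: tuple[float, float] | None = None


@dataclass(eq=False)
class IndicatorReport:
    """Full indicator report: per-column results plus anomaly series."""

    columns: dict[str, ColumnIndicators] = field(default_factory=dict)
    #: long-format anomalies: column_id, signal, time_point, anomaly, window_mean
    anomalies: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["column_id", "signal", "time_point", "anomaly", "window_mean"]
        )
    )

    def equals(self, other: "IndicatorReport") -> bool:
        if sorted(self.columns) != sorted(other.columns):
            return False
        for cid, a in self.columns.items():
            b = other.columns[cid]
            if (
                a.critical_time_points != b.critical_time_points
                or [g for g, _ in a.ssp_rank] != [g for g, _ in b.ssp_rank]
                or not np.allclose(
                    [m for _, m in a.ssp_rank], [m for _, m in b.ssp_rank]
                )
                or sorted(a.phase_cells) != sorted(b.phase_cells)
            ):
                return False
            for ph in a.phase_cells:
                if not np.allclose(a.phase_cells[ph], b.phase_cells[ph]):
                    return False
            ka, kb = a.kruskal, b.kruskal
            if (ka is None) != (kb is None):
                return False
            if ka is not None and not np.allclose(ka, kb, equal_nan=True):
                return False
        x, y = self.anomalies, other.anomalies
        if len(x) != len(y):
            return False
        if len(x):
            x = _norm(x, ["column_id", "signal", "time_point"])
            y = _norm(y, ["column_id", "signal", "time_point"])
            if not (
                (x["column_id"].to_numpy() == y["column_id"].to_numpy()).all()
                and (x["signal"].to_numpy() == y["signal"].to_numpy()).all()
                and np.allclose(x["time_point"], y["time_point"])
                and np.allclose(x["anomaly"], y["anomaly"])
                and np.allclose(x["window_mean"], y["window_mean"])
            ):
                return False
        return True


def write_report(report: IndicatorReport, directory: str | Path) -> Path:
    """Write ``report.json`` plus flat TSVs under ``directory``.

    The JSON file is complete (loss-free); the TSVs are convenience
    views: ``anomalies.tsv``, ``critical_points.tsv``, ``ssp_rank.tsv``
    and ``phase_cells.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    payload = {
        "columns": {
            cid: {
                "ssp_rank": [[g, m] for g, m in col.ssp_rank],
                "critical_time_points": list(col.critical_time_points),
                "phase_cells": {k: list(v) for k, v in sorted(col.phase_cells.items())},
                "kruskal": list(col.kruskal) if col.kruskal is not None else None,
            }
            for cid, col in sorted(report.columns.items())
        },
        "anomalies": _norm(
            report.anomalies, ["column_id", "signal", "time_point"]
        ).to_dict(orient="list")
        if len(report.anomalies)
        else {c: [] for c in report.anomalies.columns},
    }
    (directory / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    report.anomalies.to_csv(directory / "anomalies.tsv", sep="\t", index=False)
    rows = [
        {"column_id": cid, "time_point": t}
        for cid, col in sorted(report.columns.items())
        for t in col.critical_time_points
    ]
    pd.DataFrame(rows, columns=["column_id", "time_point"]).to_csv(
        directory / "critical_points.tsv", sep="\t", index=False
    )
    rows = [
        {"column_id": cid, "rank": i + 1, "genome_label": g, "tm_mean_pct": m}
        for cid, col in sorted(report.columns.items())
        for i, (g, m) in enumerate(col.ssp_rank)
    ]
    pd.DataFrame(rows, columns=["column_id", "rank", "genome_label", "tm_mean_pct"]).to_csv(
        directory / "ssp_rank.tsv", sep="\t", index=False
    )
    rows = [
        {"column_id": cid, "phase": ph, "cells_per_ml": v}
        for cid, col in sorted(report.columns.items())
        for ph, values in sorted(col.phase_cells.items())
        for v in values
    ]
    pd.DataFrame(rows, columns=["column_id", "phase", "cells_per_ml"]).to_csv(
        directory / "phase_cells.tsv", sep="\t", index=False
    )
    return directory


def read_report(directory: str | Path) -> IndicatorReport:
    """Reload a report written by :func:`write_report`."""
    payload = json.loads((Path(directory) / "report.json").read_text())
    columns = {
        cid: ColumnIndicators(
            column_id=cid,
            ssp_rank=[(g, float(m)) for g, m in entry["ssp_rank"]],
            critical_time_points=[int(t) for t in entry["critical_time_points"]],
            phase_cells={k: [float(x) for x in v] for k, v in entry["phase_cells"].items()},
            kruskal=tuple(entry["kruskal"]) if entry["kruskal"] is not None else None,
        )
        for cid, entry in payload["columns"].items()
    }
    anomalies = pd.DataFrame(payload["anomalies"])
    if anomalies.empty:
        anomalies = pd.DataFrame(
            columns=["column_id", "signal", "time_point", "anomaly", "window_mean"]
        )
    return IndicatorReport(columns=columns, anomalies=anomalies)
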