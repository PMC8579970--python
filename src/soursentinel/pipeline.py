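"""End-to-end orchestration of the souring-mitigation indicator analysis.

``run_pipeline`` executes, in order: bundle load/generation ->
copy-number correction -> genome aggregation -> relative abundance ->
phase segmentation -> alpha diversity and ordination -> SSP selection,
anomalies and critical time points -> phase-wise cell abundances ->
DSR pathway anomalies, cross-column average and smoothed trend. Every
stage's output is materialized as a TSV in the output directory so the
multi-stage analysis can be audited step by step; ``report.json``
carries the final indicator report and ``manifest.json`` the exact
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import alpha_diversity_table, bray_curtis_matrix, group_compare, pcoa
from .errors import ConfigError, ValidationError
from .indicators import build_indicator_report, genome_percent_table
from .io_model import (
    ExperimentBundle,
    IndicatorReport,
    load_bundle,
    write_bundle,
    write_report,
)
from .pathways import average_anomaly, dsr_anomalies, smooth_trend
from .phases import assign_phases
from .synthetic import GeneratorConfig, generate_experiment, write_truth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_PIPELINE_KEYS = {
    "mode",
    "input_dir",
    "out_dir",
    "threshold_mm",
    "shannon_base",
    "simpson_form",
    "ssp_floor",
    "smoother_df",
    "write_distances",
    "make_plots",
    "seed",
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    #: "synthetic" (generate a bundle) or "files" (load from input_dir)
    mode: str = "synthetic"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_dir: str | None = None
    out_dir: str = "soursentinel_out"
    threshold_mm: float = 1.0
    shannon_base: float | None = None  # None -> natural log
    simpson_form: str = "gini"
    ssp_floor: float = 0.0
    smoother_df: int | None = None
    write_distances: bool = False
    make_plots: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            if not self.input_dir:
                raise ConfigError("files mode requires input_dir")
            if not Path(self.input_dir).exists():
                raise ConfigError(f"input_dir {self.input_dir!r} does not exist")
        self.generator.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Flat key/value YAML; generator keys mix freely with pipeline
        keys; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_keys = {f.name for f in dataclasses.fields(GeneratorConfig)}
        unknown = set(raw) - _PIPELINE_KEYS - gen_keys
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        gen_raw = {k: v for k, v in raw.items() if k in gen_keys}
        pipe_raw = {k: v for k, v in raw.items() if k in _PIPELINE_KEYS}
        cfg = cls(**pipe_raw)
        cfg.generator = GeneratorConfig.from_dict(gen_raw) if gen_raw else GeneratorConfig()
        if cfg.seed is not None:
            cfg.generator.seed = int(cfg.seed)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig) -> IndicatorReport:
    """Run every stage and write all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1: input
    if config.mode == "synthetic":
        if config.seed is not None:
            config.generator.seed = int(config.seed)
        bundle, truth = generate_experiment(config.generator)
        write_bundle(bundle, out / "bundle")
        write_truth(truth, out / "bundle" / "truth.json")
    else:
        bundle = load_bundle(config.input_dir)
    logger.info("stage input: %d samples, %d taxa", len(bundle.samples), bundle.counts.data.shape[1])

    # stage 2: abundance transforms (variant-level % for diversity,
    # genome-level % for indicators)
    genome_pct = genome_percent_table(bundle)
    genome_pct.data.rename_axis("sample_id").reset_index().to_csv(
        out / "genome_percent.tsv", sep="\t", index=False
    )

    # stage 3: phase segmentation on the effluent metadata grid
    effluent = bundle.samples[bundle.samples["sample_type"] == "effluent"]
    phase_assignment = assign_phases(
        bundle.sulfide,
        bundle.schedule,
        threshold_mm=config.threshold_mm,
        times=effluent[["column_id", "time_point"]],
    )
    phase_assignment.to_csv(out / "phases.tsv", sep="\t", index=False)
    logger.info("stage phases: %d assignments", len(phase_assignment))

    # stage 4: alpha diversity on corrected variant-level abundances
    from .indicators import correct_copy_number, relative_abundance

    variant_pct = relative_abundance(
        correct_copy_number(bundle.counts, bundle.annotations)
    )
    diversity = alpha_diversity_table(
        variant_pct.data, shannon_base=config.shannon_base, simpson_form=config.simpson_form
    )
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
    _diversity_phase_tests(diversity, bundle, phase_assignment).to_csv(
        out / "diversity_tests.tsv", sep="\t", index=False
    )

    # stage 5: ordination of treated-column effluent samples
    treated_ids = effluent.loc[
        effluent["treatment"] == "treated", "sample_id"
    ].tolist()
    if len(treated_ids) >= 3:
        dm = bray_curtis_matrix(variant_pct.data.loc[treated_ids])
        if config.write_distances:
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                out / "distances.tsv", sep="\t"
            )
        ordination = pcoa(dm, k=2)
        frame = ordination.coordinates.copy()
        frame.reset_index().to_csv(out / "pcoa.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "axis": [f"PC{i + 1}" for i in range(len(ordination.eigenvalues))],
                "eigenvalue": ordination.eigenvalues,
                "proportion_explained": ordination.proportion_explained,
            }
        ).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index=False)
        logger.info("stage ordination: %d samples embedded", len(treated_ids))

    # stage 6: indicators
    report = build_indicator_report(bundle, phase_assignment, ssp_floor=config.ssp_floor)
    write_report(report, out)

    # stage 7: DSR pathway trend
    dsr_all = dsr_anomalies(bundle, genome_pct.data)
    dsr_all.to_csv(out / "dsr_anomaly.tsv", sep="\t", index=False)
    treated_cols = bundle.treated_columns()
    dsr_treated = dsr_all[dsr_all["column_id"].isin(treated_cols)]
    if len(dsr_treated):
        avg = average_anomaly(dsr_treated)
        avg.to_csv(out / "dsr_average_anomaly.tsv", sep="\t", index=False)
        if len(avg) >= 5:
            trend = smooth_trend(
                avg["time_point"].to_numpy(float),
                avg["mean"].to_numpy(float),
                df=config.smoother_df,
            )
            trend.frame().to_csv(out / "dsr_trend.tsv", sep="\t", index=False)
        logger.info("stage pathways: %d treated columns", len(treated_cols))

    manifest = {
        "package_version": __version__,
        "mode": config.mode,
        "seed": config.generator.seed if config.mode == "synthetic" else config.seed,
        "threshold_mm": config.threshold_mm,
        "generator": dataclasses.asdict(config.generator),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return report


def _diversity_phase_tests(
    diversity: pd.DataFrame, bundle: ExperimentBundle, phase_assignment: pd.DataFrame
) -> pd.DataFrame:
    """Kruskal-Wallis across phases for each alpha-diversity index
    (effluent samples of treated columns); descriptive only."""
    effluent = bundle.samples[
        (bundle.samples["sample_type"] == "effluent")
        & (bundle.samples["treatment"] == "treated")
    ]
    lookup = {
        (r.column_id, r.time_point): r.phase
        for r in phase_assignment.itertuples(index=False)
    }
    merged = diversity.merge(effluent, on="sample_id")
    merged["phase"] = [
        lookup.get((c, t)) for c, t in zip(merged["column_id"], merged["time_point"])
    ]
    merged = merged.dropna(subset=["phase"])
    rows = []
    for index in ("shannon", "simpson"):
        groups = {
            ph: grp[index].to_numpy(float)
            for ph, grp in merged.groupby("phase")
            if len(grp)
        }
        if len(groups) >= 2:
            try:
                stat, p = group_compare(groups, method="kruskal_wallis")
            except (ValidationError, ValueError):
                continue
            rows.append({"index": index, "test": "kruskal_wallis", "statistic": stat, "p_value": p})
    return pd.DataFrame(rows, columns=["index", "test", "statistic", "p_value"])
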