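"""Synthetic bioreactor souring-mitigation experiments with known truth.

The generator emulates the design of a long-term up-flow bioreactor
study: 20 sand-packed columns fed seawater plus volatile fatty acids,
half amended with nitrate to suppress sulfidogenesis, sampled as
effluent time series (16S amplicon counts, sulfide, total cell counts)
plus three sessile sections per column at sacrifice.

Mechanistic sketch, per column:

* A phenomenological sulfide curve: saturating rise toward a plateau;
  for treated columns an exponential decay after nitrate amendment
  that crosses the 1 mM mitigation threshold ``mitigation_lag_days``
  after the start of treatment, and a rebound after withdrawal.
* A latent planktonic community: an SRB guild whose total fraction
  tracks the (noiseless) sulfide level, a nitrate-responder (NRB)
  guild that blooms during treatment, and a Dirichlet background.
  Per-genome lognormal jitter models day-to-day community noise.
* A sessile (biofilm) community strongly enriched in a designated SRB
  genome — the column's specific SRB population (SSP).
* Biofilm dispersal: at configured day offsets after nitrate start
  (within the TM phase), the sessile composition is mixed additively
  into the effluent composition with the weight chosen so the SSP's
  latent planktonic fraction equals ``dispersal_fold`` times its
  pre-injection baseline at that day. ``dispersal_fold = 1`` disables
  the injection (negative-control mode).
* Sequencing: per-sample read depth drawn from a truncated normal;
  multinomial read sampling with per-variant probabilities
  proportional to latent fraction x 16S copy number (so copy-number
  correction recovers cell fractions).
* Flow cytometry: lognormal total cell counts with occasional extreme
  outliers.

Randomness is split into deterministic per-column substreams derived
from the single global seed, so any column is reproducible on its own.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError
from .io_model import CountTable, ExperimentBundle

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "influent_concentration",
    "sulfide_curve",
    "sample_reads",
    "generate_experiment",
]

#: SRB genomes reported as mitigation indicators in this kind of system;
#: they are the designated SSPs, cycled across treated columns.
NAMED_SRB = (
    "Desulfobacula toluolica Tol2",
    "Desulfarculus baarsii DSM 2075",
    "Desulfococcus multivorans",
)

_NRB_LABELS = (
    "Thauera sp. SYN-N01",
    "Marinobacterium sp. SYN-N02",
    "Pseudomonas stutzeri SYN-N03",
    "Sulfurimonas sp. SYN-N04",
    "Arcobacter sp. SYN-N05",
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic experiment.

    Defaults reproduce the emulated design: 20 columns (10 treated),
    a 148-day timeline sampled every 2 days, nitrate amendment from
    day 44 to day 120, biofilm dispersal pulses 2 and 4 days after
    amendment starts, and a mean sequencing depth of 40,709 reads
    (SD 10,527).
    """

    n_columns: int = 20
    n_treated: int = 10
    duration_days: int = 148
    sampling_interval_days: int = 2
    nitrate_start_day: int = 44
    nitrate_stop_day: int | None = 120
    nitrate_mm: float = 3.3

    n_background_taxa: int = 40
    n_srb_taxa: int = 6

    ssp_dispersal_day_offsets: tuple[int, ...] = (2, 4)
    dispersal_fold: float = 8.0

    mean_depth: float = 40709.0
    sd_depth: float = 10527.0
    min_depth: int = 1000

    # sulfide curve (mM / days)
    sulfide_plateau_mm: float = 2.5
    sulfide_rise_tau_days: float = 8.0
    mitigation_lag_days: float = 5.0
    sulfide_floor_mm: float = 0.05
    rebound_tau_days: float = 10.0
    sulfide_noise_sd: float = 0.05

    # latent community
    srb_fraction_s: float = 0.15
    srb_fraction_m: float = 0.02
    nrb_fraction_baseline: float = 0.02
    nrb_fraction_m: float = 0.30
    nrb_tau_days: float = 4.0
    community_noise_sd: float = 0.10
    sessile_srb_fraction: float = 0.70
    sessile_ssp_share: float = 0.70
    sessile_section_noise_sd: float = 0.15

    # effluent cell counts
    cell_count_mean_log: float = 16.1
    cell_count_sd_log: float = 0.4
    outlier_rate: float = 0.02
    outlier_fold: float = 30.0

    harvest_days: tuple[int, ...] = (68, 72, 112, 148)
    temperature_c: float = 30.0

    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_treated > self.n_columns:
            problems.append("n_treated exceeds n_columns")
        if self.n_columns < 1:
            problems.append("n_columns must be >= 1")
        if self.sampling_interval_days < 1:
            problems.append("sampling_interval_days must be >= 1")
        if self.dispersal_fold < 1:
            problems.append("dispersal_fold must be >= 1")
        if not 0 <= self.outlier_rate <= 1:
            problems.append("outlier_rate must be in [0, 1]")
        if self.n_srb_taxa < 1:
            problems.append("n_srb_taxa must be >= 1")
        if self.n_background_taxa < len(_NRB_LABELS):
            problems.append(f"n_background_taxa must be >= {len(_NRB_LABELS)}")
        if self.srb_fraction_s + self.nrb_fraction_m >= 1:
            problems.append("srb_fraction_s + nrb_fraction_m must be < 1")
        if not 0 < self.sessile_ssp_share < 1:
            problems.append("sessile_ssp_share must be in (0, 1)")
        if self.mitigation_lag_days < 2 * self.sampling_interval_days:
            problems.append("mitigation_lag_days must span >= 2 sampling intervals")
        if self.n_treated > 0:
            for off in self.ssp_dispersal_day_offsets:
                day = self.nitrate_start_day + off
                if day % self.sampling_interval_days:
                    problems.append(f"dispersal day {day} is off the sampling grid")
                if not 0 < off < self.mitigation_lag_days:
                    problems.append(
                        f"dispersal offset {off} falls outside the TM window"
                    )
            if self.nitrate_start_day % self.sampling_interval_days:
                problems.append("nitrate_start_day is off the sampling grid")
            if self.nitrate_start_day >= min(
                list(self.harvest_days) + [self.duration_days]
            ):
                problems.append("nitrate_start_day after the first column sacrifice")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        """Load a flat key/value YAML document; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
        for key in ("ssp_dispersal_day_offsets", "harvest_days"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass(eq=False)
class SyntheticTruth:
    """Generator ground truth for recovery tests."""

    #: treated column -> designated SSP genome label
    ssp: dict[str, str] = field(default_factory=dict)
    #: treated column -> injected dispersal days (absolute day offsets)
    dispersal_days: dict[str, tuple[int, ...]] = field(default_factory=dict)
    #: column -> phase -> (start_day, end_day) half-open, from the
    #: noiseless sulfide curve on the sampling grid
    phase_boundaries: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    #: column -> latent planktonic composition (time x genome, sums to 1)
    latent_planktonic: dict[str, pd.DataFrame] = field(default_factory=dict)
    #: column -> latent sessile composition (genome -> fraction)
    sessile_composition: dict[str, pd.Series] = field(default_factory=dict)


# ---------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------


def influent_concentration(
    stock_mm: float, stock_rate: float, diluent_rate: float
) -> float:
    """Concentration after in-line mixing of a stock with a diluent.

    ``stock_mm x stock_rate / (stock_rate + diluent_rate)`` — e.g.
    33 mM volatile fatty acids fed at 100 ul/h into 1 ml/h seawater
    gives a 3 mM column influent.
    """
    if stock_rate < 0 or diluent_rate < 0:
        raise DomainError("flow rates must be non-negative")
    total = stock_rate + diluent_rate
    if total == 0:
        raise DomainError("at least one flow rate must be positive")
    return float(stock_mm) * stock_rate / total


def _sulfide_noiseless(
    times: np.ndarray, treated: bool, cfg: GeneratorConfig
) -> np.ndarray:
    """Deterministic sulfide trajectory (mM) on arbitrary times."""
    t = np.asarray(times, dtype=float)
    plateau, floor = cfg.sulfide_plateau_mm, cfg.sulfide_floor_mm
    rise = plateau * (1.0 - np.exp(-t / cfg.sulfide_rise_tau_days))
    if not treated:
        return rise
    start = float(cfg.nitrate_start_day)
    stop = None if cfg.nitrate_stop_day is None else float(cfg.nitrate_stop_day)
    s_start = plateau * (1.0 - np.exp(-start / cfg.sulfide_rise_tau_days))
    # decay rate fixed so the 1 mM threshold is crossed lag days after start
    rate = np.log(max(s_start, 1.0 + 1e-9) / 1.0) / cfg.mitigation_lag_days
    out = rise.copy()
    during = t >= start
    out[during] = np.maximum(s_start * np.exp(-rate * (t[during] - start)), floor)
    if stop is not None:
        after = t >= stop
        s_stop = max(s_start * np.exp(-rate * (stop - start)), floor)
        out[after] = s_stop + (plateau - s_stop) * (
            1.0 - np.exp(-(t[after] - stop) / cfg.rebound_tau_days)
        )
    return out


def sulfide_curve(
    cfg: GeneratorConfig,
    treated: bool,
    times,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sulfide series (mM) at ``times``, with multiplicative noise.

    Nontreated columns rise monotonically to the plateau; treated
    columns decay after nitrate amendment (crossing 1 mM
    ``mitigation_lag_days`` later, so a TM phase exists) and rebound
    after withdrawal. With ``sulfide_noise_sd = 0`` the deterministic
    trajectory is returned.
    """
    t = np.asarray(times, dtype=float)
    if t.size > 1 and (np.diff(t) <= 0).any():
        raise DomainError("times must be strictly increasing")
    out = _sulfide_noiseless(t, treated, cfg)
    if cfg.sulfide_noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        out = out * np.exp(rng.normal(0.0, cfg.sulfide_noise_sd, t.size))
    return np.maximum(out, 0.0)


def sample_reads(
    composition, depth: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Multinomial read sampling from a composition vector."""
    p = np.asarray(composition, dtype=float)
    if (p < 0).any():
        raise DomainError("negative probability in composition")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DomainError("composition must sum to 1")
    if depth < 0:
        raise DomainError("depth must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(int(depth), p / p.sum()) if depth else np.zeros(p.size, int)


# ---------------------------------------------------------------------
# experiment generation
# ---------------------------------------------------------------------


def _make_taxa(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Genome and sequence-variant annotation table."""
    srb = list(NAMED_SRB[: cfg.n_srb_taxa])
    srb += [f"Desulfovibrio sp. SYN-S{i:02d}" for i in range(len(srb), cfg.n_srb_taxa)]
    nrb = list(_NRB_LABELS)
    background = nrb + [
        f"Bacterium sp. SYN-B{i:02d}" for i in range(cfg.n_background_taxa - len(nrb))
    ]
    rows = []
    idx = 0
    for genome in srb + background:
        is_srb = genome in srb
        copy_number = int(rng.integers(1, 9))
        n_variants = int(rng.integers(1, 4))
        weights = rng.dirichlet(np.ones(n_variants))
        for w in weights:
            rows.append(
                {
                    "taxon_id": f"asv{idx:05d}",
                    "genome_label": genome,
                    "is_srb": is_srb,
                    "copy_number": copy_number,
                    "has_dsr": is_srb,
                    "variant_weight": float(w),
                    "is_nrb": genome in nrb,
                }
            )
            idx += 1
    return pd.DataFrame(rows).set_index("taxon_id")


def _column_latent(
    cfg: GeneratorConfig,
    treated: bool,
    times: np.ndarray,
    srb_shares: np.ndarray,
    bg_shares: np.ndarray,
    nrb_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent genome composition (time x genome), rows summing to 1."""
    drive = np.clip(
        _sulfide_noiseless(times, treated, cfg) / cfg.sulfide_plateau_mm, 0.0, 1.0
    )
    w_srb = cfg.srb_fraction_m + (cfg.srb_fraction_s - cfg.srb_fraction_m) * drive
    w_nrb = np.full(times.size, cfg.nrb_fraction_baseline)
    if treated:
        start = float(cfg.nitrate_start_day)
        on = times >= start
        w_nrb[on] = cfg.nrb_fraction_baseline + (
            cfg.nrb_fraction_m - cfg.nrb_fraction_baseline
        ) * (1.0 - np.exp(-(times[on] - start) / cfg.nrb_tau_days))
        if cfg.nitrate_stop_day is not None:
            stop = float(cfg.nitrate_stop_day)
            off = times >= stop
            w_at_stop = cfg.nrb_fraction_baseline + (
                cfg.nrb_fraction_m - cfg.nrb_fraction_baseline
            ) * (1.0 - np.exp(-(stop - start) / cfg.nrb_tau_days))
            w_nrb[off] = cfg.nrb_fraction_baseline + (
                w_at_stop - cfg.nrb_fraction_baseline
            ) * np.exp(-(times[off] - stop) / cfg.rebound_tau_days)
    w_bg = 1.0 - w_srb - w_nrb

    nrb_shares = bg_shares * nrb_mask
    nrb_shares = nrb_shares / nrb_shares.sum()
    rest_shares = bg_shares * ~nrb_mask
    rest_shares = rest_shares / rest_shares.sum()

    n_srb = srb_shares.size
    latent = np.empty((times.size, n_srb + bg_shares.size))
    latent[:, :n_srb] = np.outer(w_srb, srb_shares)
    latent[:, n_srb:] = np.outer(w_nrb, nrb_shares) + np.outer(w_bg, rest_shares)
    if cfg.community_noise_sd > 0:
        latent *= np.exp(rng.normal(0.0, cfg.community_noise_sd, latent.shape))
    return latent / latent.sum(axis=1, keepdims=True)


def _phase_boundaries(
    cfg: GeneratorConfig, treated: bool, times: np.ndarray
) -> dict[str, tuple[int, int]]:
    """Noiseless phase intervals (half-open day ranges) on the grid."""
    end = int(times.max()) + cfg.sampling_interval_days
    if not treated:
        return {"S": (0, end)}
    start = cfg.nitrate_start_day
    s = _sulfide_noiseless(times, True, cfg)
    after = [int(t) for t, v in zip(times, s) if t >= start and v <= 1.0]
    stop = cfg.nitrate_stop_day
    m_start = min([t for t in after if stop is None or t < stop], default=None)
    out = {"S": (0, start)}
    if stop is not None and stop <= end:
        tm_end = m_start if m_start is not None else stop
        out["TM"] = (start, min(tm_end, stop, end))
        if m_start is not None and m_start < min(stop, end):
            out["M"] = (m_start, min(stop, end))
        if stop < end:
            out["R"] = (stop, end)
    else:
        tm_end = m_start if m_start is not None else end
        out["TM"] = (start, min(tm_end, end))
        if m_start is not None and m_start < end:
            out["M"] = (m_start, end)
    return {k: v for k, v in out.items() if v[0] < v[1]}


def generate_experiment(
    cfg: GeneratorConfig,
) -> tuple[ExperimentBundle, SyntheticTruth]:
    """Generate one complete synthetic experiment.

    Returns a validated :class:`ExperimentBundle` (raw counts) plus
    the :class:`SyntheticTruth` needed for recovery tests. Fully
    reproducible from ``cfg.seed``.
    """
    cfg.validate()
    taxa = _make_taxa(cfg, np.random.default_rng([cfg.seed, 999_983]))
    genomes = taxa["genome_label"].drop_duplicates().tolist()
    srb_genomes = [g for g in genomes if taxa[taxa["genome_label"] == g]["is_srb"].iloc[0]]
    bg_genomes = [g for g in genomes if g not in srb_genomes]
    nrb_mask = np.array(
        [taxa[taxa["genome_label"] == g]["is_nrb"].iloc[0] for g in bg_genomes]
    )
    genome_order = srb_genomes + bg_genomes
    variant_genome_idx = np.array(
        [genome_order.index(g) for g in taxa["genome_label"]]
    )
    variant_weight = taxa["variant_weight"].to_numpy(float)
    variant_copies = taxa["copy_number"].to_numpy(float)

    n_named = max(1, min(len(NAMED_SRB), len(srb_genomes)))
    grid = np.arange(0, cfg.duration_days + 1, cfg.sampling_interval_days)

    # harvest assignment: every column but the last nontreated one
    # (or simply the last column in an all-treated design)
    ids = [f"col{i + 1:02d}" for i in range(cfg.n_columns)]
    treated_flags = [i < cfg.n_treated for i in range(cfg.n_columns)]
    nontreated_idx = [i for i, tr in enumerate(treated_flags) if not tr]
    unharvested = nontreated_idx[-1] if nontreated_idx else cfg.n_columns - 1
    harvest_days = sorted(cfg.harvest_days)

    truth = SyntheticTruth()
    count_rows, count_ids = [], []
    sample_rows, sulfide_rows, schedule_rows, cell_rows = [], [], [], []

    for i, (column_id, treated) in enumerate(zip(ids, treated_flags)):
        rng = np.random.default_rng([cfg.seed, i])
        harvested = i != unharvested
        sac_day = harvest_days[i % len(harvest_days)] if harvested else int(grid.max())
        sac_day = int(grid[grid <= sac_day].max())
        times = grid[grid <= sac_day].astype(float)

        # within-guild shares: the named indicator SRBs get larger
        # Dirichlet weights (they are the abundant SRBs in this system)
        alpha = np.full(len(srb_genomes), 3.0)
        alpha[:n_named] = 12.0
        srb_shares = rng.dirichlet(alpha)
        bg_shares = rng.dirichlet(np.full(len(bg_genomes), 1.0))

        latent = _column_latent(
            cfg, treated, times, srb_shares, bg_shares, nrb_mask, rng
        )

        # sessile composition: SRB-dominated biofilm
        sessile = np.empty(len(genome_order))
        srb_w = np.array(srb_shares, dtype=float)
        if treated:
            ssp_genome = NAMED_SRB[i % n_named]
            ssp_idx = genome_order.index(ssp_genome)
            others = srb_w.copy()
            others[ssp_idx] = 0.0
            others = others / others.sum() * (1.0 - cfg.sessile_ssp_share)
            others[ssp_idx] = cfg.sessile_ssp_share
            srb_w = others
            truth.ssp[column_id] = ssp_genome
        sessile[: len(srb_genomes)] = cfg.sessile_srb_fraction * (
            srb_w / srb_w.sum()
        )
        sessile[len(srb_genomes):] = (1.0 - cfg.sessile_srb_fraction) * bg_shares

        # biofilm dispersal injection (TM phase only): the SSP is pushed
        # to dispersal_fold x its baseline TM-phase mean latent fraction
        if treated:
            days = tuple(
                int(cfg.nitrate_start_day + off)
                for off in sorted(cfg.ssp_dispersal_day_offsets)
            )
            truth.dispersal_days[column_id] = days
            bounds = _phase_boundaries(cfg, True, times)
            tm_lo, tm_hi = bounds["TM"]
            tm_idx = np.flatnonzero((times >= tm_lo) & (times < tm_hi))
            baseline = float(latent[tm_idx, ssp_idx].mean())
            target = cfg.dispersal_fold * baseline
            s_ssp = sessile[ssp_idx]
            if cfg.dispersal_fold > 1.0:
                for day in days:
                    (j,) = np.flatnonzero(times == day)
                    base = latent[j, ssp_idx]
                    if target >= s_ssp:
                        logger.warning(
                            "%s: dispersal target %.3f exceeds sessile SSP "
                            "fraction %.3f; clamping to pure sessile signal",
                            column_id,
                            target,
                            s_ssp,
                        )
                        weight = 1.0
                    else:
                        # solve (1-w) base + w sessile = target; a day whose
                        # noisy baseline already exceeds the target is left as is
                        weight = max((target - base) / (s_ssp - base), 0.0)
                    latent[j] = (1.0 - weight) * latent[j] + weight * sessile

        truth.phase_boundaries[column_id] = _phase_boundaries(cfg, treated, times)
        truth.latent_planktonic[column_id] = pd.DataFrame(
            latent, index=pd.Index(times.astype(int), name="time_point"), columns=genome_order
        )
        truth.sessile_composition[column_id] = pd.Series(
            sessile, index=genome_order, name=column_id
        )

        # sequencing: reads proportional to latent fraction x copy number
        depths = np.maximum(
            np.round(rng.normal(cfg.mean_depth, cfg.sd_depth, times.size)),
            cfg.min_depth,
        ).astype(int)
        for j, day in enumerate(times.astype(int)):
            p = latent[j, variant_genome_idx] * variant_weight * variant_copies
            counts = rng.multinomial(depths[j], p / p.sum())
            sid = f"{column_id}_d{day:03d}"
            count_rows.append(counts)
            count_ids.append(sid)
            sample_rows.append(
                {
                    "sample_id": sid,
                    "column_id": column_id,
                    "time_point": int(day),
                    "sample_type": "effluent",
                    "section": "none",
                    "treatment": "treated" if treated else "nontreated",
                    "temperature_c": cfg.temperature_c,
                }
            )

        if harvested:
            for section in ("top", "middle", "bottom"):
                comp = sessile * np.exp(
                    rng.normal(0.0, cfg.sessile_section_noise_sd, sessile.size)
                )
                comp = comp / comp.sum()
                depth = int(
                    max(round(rng.normal(cfg.mean_depth, cfg.sd_depth)), cfg.min_depth)
                )
                p = comp[variant_genome_idx] * variant_weight * variant_copies
                counts = rng.multinomial(depth, p / p.sum())
                sid = f"{column_id}_sessile_{section}"
                count_rows.append(counts)
                count_ids.append(sid)
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "column_id": column_id,
                        "time_point": int(sac_day),
                        "sample_type": "sessile",
                        "section": section,
                        "treatment": "treated" if treated else "nontreated",
                        "temperature_c": cfg.temperature_c,
                    }
                )

        sulfide = sulfide_curve(cfg, treated, times, rng)
        for day, value in zip(times.astype(int), sulfide):
            sulfide_rows.append(
                {"column_id": column_id, "time_point": int(day), "sulfide_mm": float(value)}
            )

        schedule_rows.append(
            {
                "column_id": column_id,
                "nitrate_start": cfg.nitrate_start_day if treated else pd.NA,
                "nitrate_stop": (
                    cfg.nitrate_stop_day
                    if treated and cfg.nitrate_stop_day is not None
                    else pd.NA
                ),
                "nitrate_mm": cfg.nitrate_mm if treated else np.nan,
            }
        )

        cells = np.exp(
            rng.normal(cfg.cell_count_mean_log, cfg.cell_count_sd_log, times.size)
        )
        is_out = rng.random(times.size) < cfg.outlier_rate
        factors = np.where(
            rng.random(times.size) < 0.5, cfg.outlier_fold, 1.0 / cfg.outlier_fold
        )
        cells = np.where(is_out, cells * factors, cells)
        for day, value in zip(times.astype(int), cells):
            cell_rows.append(
                {
                    "column_id": column_id,
                    "time_point": int(day),
                    "cells_per_ml": float(value),
                    "outlier": False,
                }
            )

    counts = pd.DataFrame(
        np.asarray(count_rows, dtype=float),
        index=pd.Index(count_ids, name="sample_id"),
        columns=taxa.index,
    )
    bundle = ExperimentBundle(
        counts=CountTable(counts, corrected=False),
        annotations=taxa[["genome_label", "is_srb", "copy_number", "has_dsr"]].copy(),
        samples=pd.DataFrame(sample_rows),
        sulfide=pd.DataFrame(sulfide_rows),
        schedule=pd.DataFrame(schedule_rows),
        cells=pd.DataFrame(cell_rows),
    )
    bundle.schedule["nitrate_start"] = bundle.schedule["nitrate_start"].astype("Int64")
    bundle.schedule["nitrate_stop"] = bundle.schedule["nitrate_stop"].astype("Int64")
    bundle.validate()
    logger.info(
        "generated experiment: %d samples (%d sessile), %d taxa",
        len(bundle.samples),
        int((bundle.samples["sample_type"] == "sessile").sum()),
        counts.shape[1],
    )
    return bundle, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    """Serialize the JSON-able part of the truth (SSP identities,
    dispersal days, phase boundaries) next to a generated bundle."""
    import json

    payload = {
        "ssp": truth.ssp,
        "dispersal_days": {k: list(v) for k, v in truth.dispersal_days.items()},
        "phase_boundaries": {
            col: {ph: list(rng_) for ph, rng_ in bounds.items()}
            for col, bounds in truth.phase_boundaries.items()
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
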