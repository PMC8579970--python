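"""Predicted dissimilatory sulfate reduction (DSR) pathway trends.

The community-level relative abundance of the DSR pathway (sulfate
reduction I, to hydrogen sulfide) is computed per sample as the sum of
genome-level relative abundances over genomes annotated as carrying
the pathway — binary pathway presence weighting, normalized to the
whole community. Per-column anomaly series use the same
(x - mean)/mean form as the SSP anomalies; the cross-column average
anomaly is summarized per time point and smoothed with a penalized
cubic spline (smoothness chosen by generalized cross-validation) with
a +/- 2 standard-error band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import DomainError, ValidationError
from .indicators import anomaly_series
from .io_model import ExperimentBundle

logger = logging.getLogger(__name__)

__all__ = [
    "dsr_relative_abundance",
    "dsr_anomalies",
    "average_anomaly",
    "TrendFit",
    "smooth_trend",
]


def dsr_relative_abundance(
    genome_pct: pd.DataFrame, annotations: pd.DataFrame
) -> pd.Series:
    """Per-sample DSR pathway relative abundance (%).

    ``genome_pct`` is a samples x genome table of relative abundances
    summing to 100 per row; genomes whose ``has_dsr`` flag is true
    contribute their full relative abundance. Every genome in the
    table must be annotated (via its member sequence variants) with a
    consistent ``has_dsr`` value.
    """
    if "has_dsr" not in annotations.columns or annotations["has_dsr"].isna().any():
        raise ValidationError("has_dsr annotation missing for some taxa")
    per_genome = annotations.groupby("genome_label")["has_dsr"].agg(["min", "max"])
    inconsistent = per_genome[per_genome["min"] != per_genome["max"]]
    if len(inconsistent):
        raise ValidationError(
            f"inconsistent has_dsr within genome(s): {list(inconsistent.index)[:3]}"
        )
    missing = genome_pct.columns.difference(per_genome.index)
    if len(missing):
        raise ValidationError(f"genomes without has_dsr annotation: {sorted(missing)[:5]}")
    dsr_genomes = [
        g for g in genome_pct.columns if bool(per_genome.loc[g, "max"])
    ]
    out = genome_pct[dsr_genomes].sum(axis=1) if dsr_genomes else pd.Series(
        0.0, index=genome_pct.index
    )
    out.name = "dsr_pct"
    return out


def dsr_anomalies(
    bundle: ExperimentBundle, genome_pct: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Per-column DSR anomaly series over each column's effluent samples.

    Returns a long table ``column_id, signal, time_point, anomaly,
    window_mean`` with ``signal`` fixed to ``"DSR"``.
    """
    dsr = dsr_relative_abundance(genome_pct, bundle.annotations)
    effluent = bundle.samples[bundle.samples["sample_type"] == "effluent"]
    frames = []
    wanted = columns if columns is not None else sorted(set(effluent["column_id"]))
    for column_id in wanted:
        meta = effluent[effluent["column_id"] == column_id].sort_values("time_point")
        if meta.empty:
            continue
        series = dsr.loc[meta["sample_id"]]
        series.index = pd.Index(meta["time_point"].to_numpy(int), name="time_point")
        frame = anomaly_series(series)
        frame.insert(0, "signal", "DSR")
        frame.insert(0, "column_id", column_id)
        frames.append(frame)
    return (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["column_id", "signal", "time_point", "anomaly", "window_mean"])
    )


def average_anomaly(
    anomalies: pd.DataFrame, times: list[int] | None = None
) -> pd.DataFrame:
    """Unweighted per-time mean and SD of anomalies across columns.

    Columns missing a time point are omitted from that point's summary
    (the contributing count is reported as ``n``); a time point
    observed in no column is dropped with a warning.
    """
    grid = sorted(set(times)) if times is not None else sorted(
        set(anomalies["time_point"])
    )
    rows = []
    for t in grid:
        vals = anomalies.loc[anomalies["time_point"] == t, "anomaly"].to_numpy(float)
        if vals.size == 0:
            warnings.warn(f"time point {t} observed in no column; omitted", stacklevel=2)
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {"time_point": t, "mean": float(vals.mean()), "sd": sd, "n": int(vals.size)}
        )
    return pd.DataFrame(rows, columns=["time_point", "mean", "sd", "n"])


# ---------------------------------------------------------------------
# trend smoothing
# ---------------------------------------------------------------------


@dataclass(eq=False)
class TrendFit:
    """Penalized-spline trend with a +/- 2 SE band."""

    times: np.ndarray
    fit: np.ndarray
    se: np.ndarray

    @property
    def lower(self) -> np.ndarray:
        return self.fit - 2.0 * self.se

    @property
    def upper(self) -> np.ndarray:
        return self.fit + 2.0 * self.se

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_point": self.times,
                "fit": self.fit,
                "se": self.se,
                "lo": self.lower,
                "hi": self.upper,
            }
        )


def _spline_design(t: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis and exact curvature penalty matrix.

    The penalty is the integrated squared second derivative, evaluated
    exactly with two-point Gauss-Legendre quadrature per knot interval
    (B'' is piecewise linear for cubic splines), so polynomials of
    degree <= 1 are unpenalized.
    """
    lo, hi = t.min(), t.max()
    n_interior = max(df - 4, 0)
    interior = (
        np.quantile(np.unique(t), np.linspace(0, 1, n_interior + 2)[1:-1])
        if n_interior
        else np.array([])
    )
    knots = np.r_[[lo] * 4, interior, [hi] * 4]
    basis = BSpline.design_matrix(t, knots, 3, extrapolate=True).toarray()
    k = basis.shape[1]
    d2 = [BSpline(knots, np.eye(k)[j], 3).derivative(2) for j in range(k)]
    penalty = np.zeros((k, k))
    gl = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    for a, b in zip(*(lambda u: (u[:-1], u[1:]))(np.unique(knots))):
        half = (b - a) / 2.0
        if half <= 0:
            continue
        xs = (a + b) / 2.0 + half * gl
        v = np.array([[f(x) for f in d2] for x in xs])
        penalty += half * v.T @ v
    return basis, penalty


def smooth_trend(times, values, df: int | None = None) -> TrendFit:
    """Penalized cubic-spline smoother with GCV-selected smoothness.

    ``df`` is the basis dimension (default ``min(10, max(n // 4, 4))``
    knots-worth of flexibility). The penalty weight is chosen by
    generalized cross-validation over a log-spaced grid; among
    statistically indistinguishable fits the smoothest is preferred.
    The SE band is the pointwise standard error of the fitted values
    under i.i.d. Gaussian noise with variance estimated from the
    residuals.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("times and values must be 1-D and aligned")
    order = np.argsort(t, kind="mergesort")
    t, y = t[order], y[order]
    if np.unique(t).size < 5:
        raise ValidationError("need at least 5 distinct time points to fit a trend")
    n = t.size
    if df is None:
        df = int(min(10, max(n // 4, 4)))
    df = max(int(df), 4)

    basis, penalty = _spline_design(t, df)
    btb = basis.T @ basis
    candidates = []
    for alpha in np.logspace(-6, 8, 29):
        inv = np.linalg.pinv(btb + alpha * penalty, rcond=1e-11, hermitian=True)
        hat = basis @ inv @ basis.T
        fit = hat @ y
        edf = float(np.trace(hat))
        rss = float((y - fit) @ (y - fit))
        gcv = n * rss / max(n - edf, 1e-8) ** 2
        candidates.append((gcv, alpha, fit, hat, edf, rss))
    gmin = min(c[0] for c in candidates)
    tol = gmin * 1e-6 + 1e-12 * (float(np.mean(y**2)) + 1.0)
    gcv, alpha, fit, hat, edf, rss = max(
        (c for c in candidates if c[0] <= gmin + tol), key=lambda c: c[1]
    )
    sigma2 = rss / max(n - edf, 1e-8)
    se = np.sqrt(np.maximum(sigma2 * np.einsum("ij,ij->i", hat, hat), 0.0))
    logger.debug("smooth_trend: alpha=%.3g edf=%.2f", alpha, edf)

    inverse = np.empty_like(order)
    inverse[order] = np.arange(n)
    return TrendFit(times=t[inverse], fit=fit[inverse], se=se[inverse])
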