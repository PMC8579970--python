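"""Alpha/beta diversity statistics and unconstrained ordination.

Defaults follow the conventions of the ecology software the analysis
is modeled on: Shannon entropy in nats and the Gini-Simpson index
(1 - sum p^2). Both are configurable. Beta diversity is Bray-Curtis
dissimilarity, embedded by classical principal coordinates analysis
(PCoA). Group comparisons use the two-sided Wilcoxon rank-sum (exact
permutation null for small samples without ties) and Kruskal-Wallis
tests; p-values here are descriptive — no pipeline decision gates on
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import scipy.stats as stats
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .errors import DomainError, ValidationError

__all__ = [
    "shannon",
    "simpson",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "OrdinationResult",
    "group_compare",
    "alpha_diversity_table",
]


def _proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise DomainError("expected a 1-D count vector")
    if (x < 0).any():
        raise DomainError("negative counts")
    total = x.sum()
    if total <= 0:
        raise DomainError("all-zero count vector")
    return x / total


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default)."""
    p = _proportions(counts)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base is not None else h


def simpson(counts, form: str = "gini") -> float:
    """Simpson's index.

    ``form="gini"`` (default) returns the Gini-Simpson diversity
    1 - sum p_i^2; ``form="dominance"`` returns the raw dominance
    sum p_i^2.
    """
    p = _proportions(counts)
    d = float((p**2).sum())
    if form == "gini":
        return 1.0 - d
    if form == "dominance":
        return d
    raise DomainError(f"unknown Simpson form {form!r}")


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum min(a,b) / (sum a + sum b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("vectors must be 1-D and of equal length")
    if (a < 0).any() or (b < 0).any():
        raise DomainError("negative abundances")
    denom = a.sum() + b.sum()
    if denom <= 0:
        raise DomainError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def bray_curtis_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between the rows of ``table``."""
    condensed = ssd.pdist(table.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(ssd.squareform(condensed), ids=[str(i) for i in table.index])


@dataclass(eq=False)
class OrdinationResult:
    """Classical-scaling embedding of a dissimilarity matrix."""

    #: sample coordinates, one retained axis per column
    coordinates: pd.DataFrame
    #: positive eigenvalues of the retained axes, descending
    eigenvalues: np.ndarray
    #: share of the positive-eigenvalue sum explained per retained axis
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix | np.ndarray, k: int = 2) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Retains at most ``k`` axes with positive eigenvalues. For inputs
    that embed exactly in Euclidean space the coordinates reproduce the
    input distances.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    if not isinstance(d, DistanceMatrix):
        arr = np.asarray(d, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have a zero diagonal")
        d = DistanceMatrix(arr, ids=[str(i) for i in range(arr.shape[0])])

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(d, method="eigh", warn_neg_eigval=False)
    eig = res.eigvals.to_numpy(dtype=float)
    tol = 1e-10 * max(np.abs(eig).max(), 1.0)
    keep = np.flatnonzero(eig > tol)[: int(k)]
    pos_sum = eig[eig > tol].sum()
    coords = res.samples.iloc[:, keep].copy()
    coords.index = pd.Index(d.ids, name="sample_id")
    coords.columns = [f"PC{i + 1}" for i in range(len(keep))]
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig[keep],
        proportion_explained=(eig[keep] / pos_sum) if pos_sum > 0 else eig[keep],
    )


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "kruskal_wallis",
) -> tuple[float, float]:
    """Nonparametric comparison of groups of observations.

    ``wilcoxon_rank_sum`` (exactly two groups) uses the two-sided
    Mann-Whitney U statistic, with the exact permutation null when the
    pooled sample has at most 10 tie-free observations and the
    tie-corrected normal approximation otherwise. ``kruskal_wallis``
    accepts two or more groups.

    Returns ``(statistic, p_value)``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if any(g.size < 1 for g in groups.values()):
        raise ValidationError("every group needs at least one observation")
    if method == "wilcoxon_rank_sum":
        if len(groups) != 2:
            raise ValidationError("wilcoxon_rank_sum requires exactly 2 groups")
        x, y = groups.values()
        pooled = np.concatenate([x, y])
        exact = pooled.size <= 10 and np.unique(pooled).size == pooled.size
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return float(res.statistic), float(res.pvalue)
    if method == "kruskal_wallis":
        if len(groups) < 2:
            raise ValidationError("kruskal_wallis requires at least 2 groups")
        res = stats.kruskal(*groups.values())
        return float(res.statistic), float(res.pvalue)
    raise ValidationError(f"unknown method {method!r}")


def alpha_diversity_table(
    table: pd.DataFrame,
    shannon_base: float | None = None,
    simpson_form: str = "gini",
) -> pd.DataFrame:
    """Per-sample Shannon and Simpson indices for a samples x taxa table."""
    records = [
        {
            "sample_id": sid,
            "shannon": shannon(row, base=shannon_base),
            "simpson": simpson(row, form=simpson_form),
        }
        for sid, row in zip(table.index, table.to_numpy(dtype=float))
    ]
    return pd.DataFrame(records, columns=["sample_id", "shannon", "simpson"])
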