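"""Summary statistics, fixed-bin frequency curves, rank correlation and
group tests for comparing 2D- and 3D-derived morphometric variables.

The comparison protocol for spine morphometry: per-variable summary tables
(mean, SEM, min, max), relative-frequency distribution curves on fixed bin
grids (so curves from samples of different size are comparable), Spearman
rank correlations between size variables, and Mann-Whitney / one-way ANOVA
tests between measurement modalities. Hypothesis tests are delegated to
scipy; this module fixes the conventions (bin edges, tie handling, exact
vs asymptotic regimes) and the report format.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, EstimationError

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryTable",
    "HistogramSpec",
    "summarize",
    "frequency_curve",
    "spearman",
    "compare_groups",
    "LENGTH_BINS",
    "AREA_BINS",
    "VOLUME_BINS",
]


@dataclass(frozen=True)
class SummaryTable:
    """Per-variable summary: n, mean, SEM (sd/sqrt(n), n-1 denominator),
    min, max, units."""

    variable: str
    n: int
    mean: float
    sem: float
    min: float
    max: float
    units: str


@dataclass(frozen=True)
class HistogramSpec:
    """A fixed bin grid: ``n_bins`` bins of width ``bin_width`` from
    ``start``. Bins are half-open [lo, hi) except the last, which is
    closed; values outside the grid are counted in the nearest end bin
    (and logged)."""

    start: float
    bin_width: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.n_bins < 1:
            raise ConfigError("bin_width must be > 0 and n_bins >= 1")

    @property
    def edges(self) -> np.ndarray:
        return self.start + self.bin_width * np.arange(self.n_bins + 1)


# The fixed grids used for the distribution-curve comparisons:
# synaptic lengths (SAL, PSD_L), contact areas (SAS, SAL_S, PSD_S and head
# areas), and head volumes.
LENGTH_BINS = HistogramSpec(start=0.0, bin_width=0.08, n_bins=10)  # um
AREA_BINS = HistogramSpec(start=0.0, bin_width=0.06, n_bins=9)  # um^2
VOLUME_BINS = HistogramSpec(start=0.0, bin_width=0.03, n_bins=10)  # um^3


def summarize(values: Sequence[float], variable: str = "", units: str = "") -> SummaryTable:
    """Mean, SEM, min and max of a sample (n >= 2 required for the SEM)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise EstimationError("need at least 2 finite values for a SEM")
    return SummaryTable(
        variable=variable,
        n=int(arr.size),
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / math.sqrt(arr.size)),
        min=float(arr.min()),
        max=float(arr.max()),
        units=units,
    )


def frequency_curve(values: Sequence[float], spec: HistogramSpec) -> np.ndarray:
    """Per-bin relative frequencies on a fixed grid; sums to 1.

    Values below the grid or at/above its upper edge are clipped into the
    first/last bin so that mass is conserved; the overflow count is logged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EstimationError("cannot bin an empty sample")
    edges = spec.edges
    n_out = int(np.sum((arr < edges[0]) | (arr > edges[-1])))
    if n_out:
        logger.info("frequency_curve: %d of %d values outside the grid, clipped", n_out, arr.size)
    idx = np.floor((arr - spec.start) / spec.bin_width).astype(int)
    idx = np.clip(idx, 0, spec.n_bins - 1)
    counts = np.bincount(idx, minlength=spec.n_bins).astype(float)
    return counts / arr.size


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank ties; symmetric in x, y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ConfigError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise EstimationError("rank correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class GroupTestReport:
    """Outcome of a between-group test, with the inputs that produced it."""

    test: str  # "mann_whitney_exact" | "mann_whitney_asymptotic" | "anova_oneway"
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]


def compare_groups(*groups: Sequence[float], exact_max_n: int = 20) -> GroupTestReport:
    """Mann-Whitney for two groups, one-way ANOVA for three or more.

    The Mann-Whitney p-value is computed by exact enumeration when both
    groups have at most ``exact_max_n`` observations (and no ties),
    otherwise by the normal approximation with continuity and tie
    correction.
    """
    if len(groups) < 2:
        raise ConfigError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ConfigError("each group needs at least 2 observations")
    sizes = tuple(int(a.size) for a in arrays)
    if len(arrays) == 2:
        a, b = arrays
        small = max(a.size, b.size) <= exact_max_n
        method = "exact" if small else "asymptotic"
        try:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:  # exact method refuses ties
            method = "asymptotic"
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return GroupTestReport(
            test=f"mann_whitney_{method}",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            group_sizes=sizes,
        )
    res = sps.f_oneway(*arrays)
    return GroupTestReport(
        test="anova_oneway",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=sizes,
    )
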