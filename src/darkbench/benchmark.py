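"""Dark-noise benchmark statistics.

A reporter vector's total dark noise is summarized against the
autofluorescence (AF) of untransformed cells by two ratios of the pooled
single-cell intensity distributions:

    D = mu_EV / mu_AF        (dynamic-range cost of the dark noise)
    S = sigma_EV / sigma_AF  (sensitivity cost)

An ideal reporter has D = S = 1: the empty-vector (EV) control is
statistically indistinguishable from autofluorescence.  Within-sample
uncertainty is quantified by a percentile bootstrap over cells (EV and AF
resampled independently — they are different strains); across independent
replicate experiments, by the standard error of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import IntensityDistribution

__all__ = [
    "BenchmarkResult",
    "ReplicateSummary",
    "compute_DS",
    "aggregate_replicates",
    "export_histogram",
]


@dataclass
class BenchmarkResult:
    D: float
    S: float
    d_ci: tuple[float, float]
    s_ci: tuple[float, float]
    d_se: float
    s_se: float
    n_ev: int
    n_af: int
    ev_condition: str = "EV"
    af_condition: str = "AF"


@dataclass
class ReplicateSummary:
    mean_D: float
    sem_D: float        # nan when k == 1
    mean_S: float
    sem_S: float
    k: int


def compute_DS(ev: IntensityDistribution, af: IntensityDistribution,
               n_boot: int = 2000, seed: int = 0) -> BenchmarkResult:
    """Point estimates and 95% percentile-bootstrap CIs for D and S."""
    if ev.n < 2 or af.n < 2:
        raise ValueError("both distributions need at least 2 cells")
    if af.mu <= 0 or af.sigma <= 0:
        raise ValueError("degenerate AF reference: mu and sigma must be > 0")
    D = ev.mu / af.mu
    S = ev.sigma / af.sigma

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ds = np.empty(n_boot)
    ss = np.empty(n_boot)
    ev_v, af_v = ev.values, af.values
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n_boot):
            e = ev_v[rng.integers(0, ev.n, ev.n)]
            a = af_v[rng.integers(0, af.n, af.n)]
            ds[i] = e.mean() / a.mean()
            ss[i] = e.std(ddof=1) / a.std(ddof=1)
    # a degenerate resample (all-equal reference values) yields inf/nan
    ds, ss = ds[np.isfinite(ds)], ss[np.isfinite(ss)]
    if ds.size < n_boot // 2 or ss.size < n_boot // 2:
        raise ValueError("too many degenerate bootstrap resamples")
    d_ci = tuple(np.percentile(ds, [2.5, 97.5]))
    s_ci = tuple(np.percentile(ss, [2.5, 97.5]))
    return BenchmarkResult(D=D, S=S, d_ci=d_ci, s_ci=s_ci,
                           d_se=float(ds.std(ddof=1)), s_se=float(ss.std(ddof=1)),
                           n_ev=ev.n, n_af=af.n,
                           ev_condition=ev.condition, af_condition=af.condition)


def aggregate_replicates(results: list[BenchmarkResult]) -> ReplicateSummary:
    """Across-replicate mean and SEM (sample SD / sqrt(k)) of D and S."""
    if not results:
        raise ValueError("need at least one replicate")
    d = np.array([r.D for r in results])
    s = np.array([r.S for r in results])
    k = len(results)
    sem_d = float(d.std(ddof=1) / math.sqrt(k)) if k >= 2 else float("nan")
    sem_s = float(s.std(ddof=1) / math.sqrt(k)) if k >= 2 else float("nan")
    return ReplicateSummary(mean_D=float(d.mean()), sem_D=sem_d,
                            mean_S=float(s.mean()), sem_S=sem_s, k=k)


def export_histogram(dist: IntensityDistribution,
                     bin_width: float | None = None,
                     bin_count: int | None = None) -> pd.DataFrame:
    """Histogram of an intensity distribution with half-open bins [left, right).

    Returns columns (bin_left, bin_right, count, frequency); counts sum to n,
    frequencies to 1.
    """
    if (bin_width is None) == (bin_count is None):
        raise ValueError("give exactly one of bin_width or bin_count")
    v = dist.values
    lo, hi = float(v.min()), float(v.max())
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n_bins = max(1, int(np.ceil((hi - lo) / bin_width)) or 1)
        edges = lo + bin_width * np.arange(n_bins + 1)
        if edges[-1] <= hi:            # keep the max inside the last bin
            edges = np.append(edges, edges[-1] + bin_width)
    else:
        if bin_count <= 0:
            raise ValueError("bin_count must be positive")
        edges = np.linspace(lo, hi + 1e-9 * max(1.0, abs(hi)), bin_count + 1)
    counts, edges = np.histogram(v, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "frequency": counts / dist.n,
    })
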