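"""Heterocovariance (HetCA) and statistical total correlation (STOCSY).

Both analyses share one kernel: for every bucket j, the sample covariance
and Pearson correlation of that bucket's intensity vector against a response
vector, across the fractions of a small consecutive window (a *package*,
typically three chromatographic neighbours).

* HetCA uses the bioactivity (% inhibition) as the response.  Buckets whose
  intensity rises with activity are *hot* (candidate features of the active
  constituent); buckets that fall as activity rises are *cold*.
* STOCSY uses one chosen bucket (the *driver*) as the response, exploiting
  the multicollinearity of resonances that belong to the same molecule: all
  signals of the driver's molecule correlate near +1 with it.

Because the two analyses differ only in the response vector, STOCSY with a
driver bucket d is literally HetCA with activity := bucket d's intensities —
a property the test suite pins down.

Covariance uses the sample (n-1) denominator.  Correlation for a
zero-variance bucket (or a zero-variance response) is *undefined* and
reported as NaN, never as 0: an empty bucket is absence of evidence, not
evidence of no correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import BucketTable
from .spectra_io import FractionSeries

__all__ = [
    "FractionPackage",
    "HetcaResult",
    "StocsyResult",
    "FeatureInterval",
    "hetca",
    "stocsy",
    "enumerate_packages",
    "hot_cold_report",
    "cov_corr_kernel",
]


class CorrelateError(ValueError):
    pass


@dataclass(frozen=True)
class FractionPackage:
    """A window of consecutive fractions (chromatographic neighbours).

    ``activity_variance`` is an optional annotation set by
    :func:`enumerate_packages` to help the user pick a window with a clear
    activity contrast; selection itself is deliberately manual.
    """

    member_indices: tuple[int, ...]
    activity_variance: float | None = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.member_indices)
        if len(idx) < 2:
            raise CorrelateError(
                "a fraction package needs >=2 members (covariance is "
                "undefined for a single observation)"
            )
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise CorrelateError(
                f"package indices must be consecutive, got {idx}"
            )
        if idx[0] < 0:
            raise CorrelateError("package indices must be non-negative")
        object.__setattr__(self, "member_indices", idx)

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class HetcaResult:
    bucket_centres: np.ndarray
    covariance: np.ndarray       # intensity · % units
    correlation: np.ndarray      # in [-1, 1]; NaN where undefined
    labels: np.ndarray           # 'hot' | 'cold' | 'neutral'
    package: FractionPackage
    threshold: float


@dataclass(frozen=True)
class StocsyResult:
    driver_ppm: float
    driver_bucket: int
    bucket_centres: np.ndarray
    covariance: np.ndarray
    correlation: np.ndarray
    package: FractionPackage


@dataclass(frozen=True)
class FeatureInterval:
    """A maximal run of same-label buckets, the unit of the hot/cold report."""

    ppm_low: float
    ppm_high: float
    label: str
    peak_abs_correlation: float
    peak_covariance: float
    n_buckets: int


def cov_corr_kernel(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise sample covariance and Pearson correlation of X against y.

    X is observations x variables, y is the response over the same
    observations.  Returns (covariance, correlation); correlation is NaN for
    any column with zero variance, and everywhere when y has zero variance.
    This single kernel backs HetCA, STOCSY and the LC-MS AUC correlation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 2 or y.shape != (n,):
        raise CorrelateError(
            f"kernel needs >=2 aligned observations, got X {X.shape}, y {y.shape}"
        )
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    cov = Xc.T @ yc / (n - 1)
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    ssy = float(yc @ yc)
    denom = np.sqrt(ssx * ssy)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), np.nan)
    return cov, corr


def _labels(corr: np.ndarray, threshold: float) -> np.ndarray:
    labels = np.full(corr.shape, "neutral", dtype=object)
    with np.errstate(invalid="ignore"):
        labels[np.nan_to_num(corr, nan=0.0) >= threshold] = "hot"
        labels[np.nan_to_num(corr, nan=0.0) <= -threshold] = "cold"
    return labels


def hetca(
    table: BucketTable,
    activity: np.ndarray,
    package: FractionPackage,
    threshold: float = 0.8,
) -> HetcaResult:
    """Per-bucket covariance/correlation of intensity against bioactivity
    over a fraction package, with hot/cold labelling.

    ``activity`` is aligned to the *full* fraction list of the table; the
    package selects the rows entering the statistics.  A package with
    constant activity yields zero covariance and undefined correlation
    everywhere (all buckets neutral) and emits a warning — there is no
    activity contrast to correlate against.
    """
    if not 0 < threshold <= 1:
        raise CorrelateError("threshold must lie in (0, 1]")
    activity = np.asarray(activity, dtype=float)
    if activity.shape != (len(table.fraction_ids),):
        raise CorrelateError(
            "activity length must equal the table's fraction count"
        )
    idx = list(package.member_indices)
    if idx[-1] >= len(table.fraction_ids):
        raise CorrelateError(
            f"package {idx} exceeds the {len(table.fraction_ids)}-fraction table"
        )
    y = activity[idx]
    if np.ptp(y) == 0:
        warnings.warn(
            "activity is constant within the package; every correlation is "
            "undefined and all buckets are neutral",
            stacklevel=2,
        )
    cov, corr = cov_corr_kernel(table.values[idx], y)
    return HetcaResult(
        bucket_centres=table.centres,
        covariance=cov,
        correlation=corr,
        labels=_labels(corr, threshold),
        package=package,
        threshold=float(threshold),
    )


def stocsy(
    table: BucketTable,
    driver_ppm: float,
    package: FractionPackage,
) -> StocsyResult:
    """Correlate every bucket against the driver bucket across the package.

    The driver bucket is the one whose centre is nearest ``driver_ppm``
    (ties resolve to the lower-ppm bucket).  The driver must fall within the
    bucketed range and must vary within the package; its own correlation is
    exactly 1 by construction.
    """
    centres = table.centres
    lo = table.left_edges[0]
    hi = table.left_edges[-1] + table.width
    if not lo <= driver_ppm <= hi:
        raise CorrelateError(
            f"driver {driver_ppm:g} ppm outside bucketed range "
            f"[{lo:g}, {hi:g}]"
        )
    idx = list(package.member_indices)
    if idx[-1] >= len(table.fraction_ids):
        raise CorrelateError(
            f"package {idx} exceeds the {len(table.fraction_ids)}-fraction table"
        )
    # argmin returns the first minimum; centres ascend, so ties go low-ppm
    driver = int(np.argmin(np.abs(centres - driver_ppm)))
    d = table.values[idx, driver]
    if np.ptp(d) == 0:
        raise CorrelateError(
            f"driver bucket at {centres[driver]:g} ppm has zero variance "
            "within the package"
        )
    cov, corr = cov_corr_kernel(table.values[idx], d)
    corr = corr.copy()
    corr[driver] = 1.0  # algebraic identity, pinned against rounding
    return StocsyResult(
        driver_ppm=float(driver_ppm),
        driver_bucket=driver,
        bucket_centres=centres,
        covariance=cov,
        correlation=corr,
        package=package,
    )


def enumerate_packages(
    series: FractionSeries, size: int = 3
) -> list[FractionPackage]:
    """All consecutive windows of ``size`` fractions, in elution order, each
    annotated with its within-window activity variance (sample variance) so
    the user can pick a window with a clear activity contrast."""
    size = int(size)
    if size < 2:
        raise CorrelateError("package size must be >=2")
    n = series.n_fractions
    if size > n:
        raise CorrelateError(
            f"package size {size} exceeds the {n}-fraction series"
        )
    out = []
    for start in range(n - size + 1):
        idx = tuple(range(start, start + size))
        var = float(np.var(series.activity[list(idx)], ddof=1))
        out.append(FractionPackage(member_indices=idx, activity_variance=var))
    return out


def hot_cold_report(
    result: HetcaResult, min_run: int = 2
) -> list[FeatureInterval]:
    """Condense a HetCA result into spectral features.

    Maximal runs of >= ``min_run`` consecutive buckets sharing a hot or cold
    label are reported as ppm intervals with their peak |correlation| and
    peak covariance, sorted by descending |peak covariance| — the tallest
    pseudo-spectrum features first, as a user would read the plot.
    """
    labels = result.labels
    width = (
        result.bucket_centres[1] - result.bucket_centres[0]
        if result.bucket_centres.size > 1
        else 0.0
    )
    intervals: list[FeatureInterval] = []
    start = None
    current = "neutral"
    for j in range(labels.size + 1):
        lab = labels[j] if j < labels.size else "neutral"
        if lab != current:
            if current in ("hot", "cold") and j - start >= min_run:
                sl = slice(start, j)
                k = start + int(np.argmax(np.abs(result.covariance[sl])))
                intervals.append(
                    FeatureInterval(
                        ppm_low=float(result.bucket_centres[start] - width / 2),
                        ppm_high=float(result.bucket_centres[j - 1] + width / 2),
                        label=str(current),
                        peak_abs_correlation=float(
                            np.nanmax(np.abs(result.correlation[sl]))
                        ),
                        peak_covariance=float(result.covariance[k]),
                        n_buckets=j - start,
                    )
                )
            current = lab
            start = j
    intervals.sort(key=lambda iv: -abs(iv.peak_covariance))
    return intervals
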