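"""Baseline correction and fixed-width bucketing of 1D NMR spectra.

Baseline model: a quartic polynomial in raw ppm,

    b(x) = A + B x + C x**2 + D x**3 + E x**4,

fit by least squares through anchor points.  Anchors are either supplied
manually or selected automatically by an iterative low-quantile scheme (fit
to everything, keep only points sitting at or below the fit plus one robust
scale unit, refit until the anchor set stabilises).  Coefficients are
reported in raw ppm units; callers worried about conditioning on wide ranges
may rescale x themselves, but the stored model is always in ppm.

Bucketing reduces a spectrum to fixed-width chemical-shift bins by **summing**
(not averaging) the data points in each bin — total in-range signal is
conserved, and with equal sample concentrations bucket sums stay proportional
to molar concentration, which is what makes the downstream covariance
analysis chemically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra_io import FractionSeries, Spectrum

__all__ = [
    "BaselineModel",
    "BucketTable",
    "fit_baseline",
    "subtract_baseline",
    "bucket",
]


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineModel:
    """Quartic baseline b(x) = A + Bx + Cx^2 + Dx^3 + Ex^4 (x in ppm).

    ``anchor_ppm`` / ``anchor_residuals`` record where the fit was anchored
    and how well it passes through those points.
    """

    coefficients: tuple[float, float, float, float, float]
    anchor_ppm: np.ndarray | None = None
    anchor_residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        if len(coeffs) != 5:
            raise PreprocessError(
                f"baseline needs exactly 5 coefficients, got {len(coeffs)}"
            )
        object.__setattr__(self, "coefficients", coeffs)

    def __call__(self, ppm) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(ppm, dtype=float), self.coefficients
        )


@dataclass(frozen=True)
class BucketTable:
    """Fixed-width bucket sums for a stack of fractions.

    ``values[i, j]`` is the summed intensity of fraction i over bucket j,
    whose interval is [left_edges[j], left_edges[j] + width) — half-open,
    except the final bucket which is closed on the right.
    """

    left_edges: np.ndarray
    width: float
    values: np.ndarray  # fractions x buckets
    fraction_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.left_edges, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.fraction_ids), edges.size):
            raise PreprocessError(
                f"values shape {vals.shape} inconsistent with "
                f"{len(self.fraction_ids)} fractions x {edges.size} buckets"
            )
        if not np.all(np.isfinite(vals)):
            raise PreprocessError("bucket values must be finite")
        object.__setattr__(self, "left_edges", edges)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "fraction_ids", tuple(self.fraction_ids))

    @property
    def n_buckets(self) -> int:
        return self.left_edges.size

    @property
    def centres(self) -> np.ndarray:
        return self.left_edges + self.width / 2.0


def _quartic_fit(ppm: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    if np.unique(ppm).size < 5:
        raise PreprocessError(
            "quartic baseline fit needs anchors at >=5 distinct ppm values"
        )
    return np.polynomial.polynomial.polyfit(ppm, intensity, 4)


def fit_baseline(
    spectrum: Spectrum,
    anchor_selector: str = "iterative-low-quantile",
    anchor_ppm: Sequence[float] | None = None,
    max_iter: int = 20,
    q: float = 1.0,
) -> BaselineModel:
    """Fit the quartic baseline.

    anchor_selector:
      * ``"manual-points"`` — fit through the data points nearest each value
        in ``anchor_ppm`` (the classical hand-picked procedure).
      * ``"iterative-low-quantile"`` — automatic: fit to all points, keep the
        points with residual <= q * robust scale (1.4826 * MAD), refit, and
        iterate until the anchor set is stable or ``max_iter`` is reached.
        Peaks stick out above the fit and are shed; the smooth floor remains.

    Fewer than 5 anchors, or anchors collapsed onto fewer than 5 distinct
    ppm values, are an error (the quartic would be underdetermined).
    """
    ppm, inten = spectrum.ppm, spectrum.intensity
    if anchor_selector == "manual-points":
        if anchor_ppm is None:
            raise PreprocessError("manual-points selection requires anchor_ppm")
        idx = np.unique(
            [int(np.argmin(np.abs(ppm - float(a)))) for a in anchor_ppm]
        )
        if idx.size < 5:
            raise PreprocessError(
                f"need >=5 distinct anchor points, got {idx.size}"
            )
        coeffs = _quartic_fit(ppm[idx], inten[idx])
        anchors = idx
    elif anchor_selector == "iterative-low-quantile":
        if ppm.size < 5:
            raise PreprocessError("spectrum too short for a quartic fit")
        keep = np.ones(ppm.size, dtype=bool)
        coeffs = _quartic_fit(ppm, inten)
        for _ in range(max_iter):
            resid = inten - np.polynomial.polynomial.polyval(ppm, coeffs)
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if scale == 0:
                break
            new_keep = resid <= q * scale
            if new_keep.sum() < 5:
                break
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
            coeffs = _quartic_fit(ppm[keep], inten[keep])
        anchors = np.flatnonzero(keep)
    else:
        raise PreprocessError(f"unknown anchor selector {anchor_selector!r}")

    resid = inten[anchors] - np.polynomial.polynomial.polyval(
        ppm[anchors], coeffs
    )
    return BaselineModel(
        coefficients=tuple(coeffs),
        anchor_ppm=ppm[anchors].copy(),
        anchor_residuals=resid,
    )


def subtract_baseline(spectrum: Spectrum, model: BaselineModel) -> Spectrum:
    """intensity' = intensity - b(ppm); the ppm axis is untouched."""
    return Spectrum(
        fraction_id=spectrum.fraction_id,
        ppm=spectrum.ppm,
        intensity=spectrum.intensity - model(spectrum.ppm),
    )


def bucket(
    series: FractionSeries,
    range_low: float = 0.5,
    range_high: float = 7.0,
    width: float = 0.0005,
    normalize: bool = False,
) -> BucketTable:
    """Sum data points into fixed-width buckets over [range_low, range_high].

    The bucket count is round((high - low) / width) so that nominal widths
    with inexact binary representation (0.0005) still give the intended
    count (6.5 / 0.0005 -> exactly 13,000).  Each in-range point lands in
    exactly one bucket: intervals are [left, left + width), the last bucket
    right-closed.  By default bucket values are raw sums; ``normalize=True``
    divides each fraction's row by its total (off by default because equal
    sample concentrations make raw sums directly comparable).
    """
    if not range_low < range_high:
        raise PreprocessError("range_low must be < range_high")
    if width <= 0:
        raise PreprocessError("width must be positive")
    ppm = series.shared_ppm
    if ppm[0] > range_low or ppm[-1] < range_high:
        raise PreprocessError(
            f"shared grid [{ppm[0]:g}, {ppm[-1]:g}] does not cover the "
            f"bucket range [{range_low:g}, {range_high:g}]"
        )
    n = int(round((range_high - range_low) / width))
    if n < 1:
        raise PreprocessError("bucket range narrower than one bucket")
    in_range = (ppm >= range_low) & (ppm <= range_high)
    pts = ppm[in_range]
    idx = np.floor((pts - range_low) / width).astype(np.intp)
    np.clip(idx, 0, n - 1, out=idx)  # right-closes the final bucket
    values = np.vstack(
        [
            np.bincount(idx, weights=row[in_range], minlength=n)
            for row in series.spectra_matrix
        ]
    )
    if normalize:
        totals = values.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise PreprocessError("cannot total-sum normalise an all-zero row")
        values = values / totals
    left_edges = range_low + width * np.arange(n)
    return BucketTable(
        left_edges=left_edges,
        width=float(width),
        values=values,
        fraction_ids=series.fraction_ids,
    )
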