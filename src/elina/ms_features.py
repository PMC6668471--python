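"""LC-MS peak handling: molecular formulas, masses, and activity correlation.

The mass side is deliberately small and self-contained: an embedded table of
IUPAC standard atomic weights (for the average molecular weight a chemist
quotes, e.g. C30H42O4 -> 466.66) and of most-abundant-isotope masses (for
the monoisotopic m/z an HRMS instrument observes).  Adduct masses include the
electron mass correction, as usual for high-resolution work.

The statistics side reuses the covariance/correlation kernel of
:mod:`elina.correlate`: a chromatographic peak whose area under the curve
(AUC) rises and falls with bioactivity across a fraction package is a
candidate carrier of the active constituent.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlate import FractionPackage, cov_corr_kernel

__all__ = [
    "MolecularFormula",
    "MsPeak",
    "MsPeakTable",
    "PeakDiagnostics",
    "parse_formula",
    "average_mass",
    "monoisotopic_mass",
    "activity_correlated_peaks",
    "match_mz",
    "read_peak_table",
    "write_peak_table",
]


class FormulaError(ValueError):
    pass


class MsFeatureError(ValueError):
    pass


# IUPAC 2021 abridged standard atomic weights (u).  Conventional single
# values are used where IUPAC gives an interval (C 12.011, H 1.008, ...).
STANDARD_ATOMIC_WEIGHTS: Mapping[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Na": 22.98976928,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.0983,
    "Br": 79.904,
    "I": 126.90447,
}

# Most-abundant-isotope masses (u), CODATA/AME values.
MONOISOTOPIC_MASSES: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Br": 78.9183371,
    "I": 126.904473,
}

ELECTRON_MASS = 0.000548579909  # u

# adduct -> (mass shift in u, description); singly charged positive ions
ADDUCT_SHIFTS: Mapping[str, float] = {
    "none": 0.0,
    "M+H": MONOISOTOPIC_MASSES["H"] - ELECTRON_MASS,    # proton, 1.007276 u
    "M+Na": MONOISOTOPIC_MASSES["Na"] - ELECTRON_MASS,  # Na+,    22.989221 u
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition, e.g. {C: 30, H: 42, O: 4}.

    Rendered canonically in Hill order: C first, H second, then the
    remaining elements alphabetically (all alphabetical when carbon-free).
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = {}
        for el, n in self.element_counts.items():
            if el not in STANDARD_ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {el}")
            if n > 0:
                counts[el] = n
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "element_counts", dict(counts))

    def __str__(self) -> str:
        counts = dict(self.element_counts)
        parts = []
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else []) + sorted(
                k for k in counts if k not in ("C", "H")
            )
        else:
            order = sorted(counts)
        for el in order:
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.element_counts)
        for el, n in other.element_counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``C30H42O4``-style formulas (omitted count = 1, symbols are
    case-sensitive).  Errors report the character position."""
    if not isinstance(text, str) or not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r} at position {pos} "
                f"({text[pos:]!r})"
            )
        el, digits = m.group(1), m.group(2)
        if el not in STANDARD_ATOMIC_WEIGHTS:
            raise FormulaError(
                f"unknown element {el!r} in {text!r} at position {pos}"
            )
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(
                f"zero count for {el} in {text!r} at position {pos}"
            )
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def average_mass(formula: MolecularFormula) -> float:
    """Average molecular weight (u) from standard atomic weights; this is
    the 'MW' a structure database prints (C30H42O4 -> 466.66 at two
    decimals).  Full precision is returned; round-half-even at two decimals
    for display."""
    return float(
        sum(
            n * STANDARD_ATOMIC_WEIGHTS[el]
            for el, n in formula.element_counts.items()
        )
    )


def monoisotopic_mass(formula: MolecularFormula, adduct: str = "none") -> float:
    """Monoisotopic mass (u), optionally as a singly charged adduct ion
    ([M+H]+ or [M+Na]+, electron mass included)."""
    if adduct not in ADDUCT_SHIFTS:
        raise MsFeatureError(
            f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_SHIFTS)}"
        )
    m = sum(
        n * MONOISOTOPIC_MASSES[el]
        for el, n in formula.element_counts.items()
    )
    return float(m + ADDUCT_SHIFTS[adduct])


@dataclass(frozen=True)
class MsPeak:
    """One LC-MS feature with its per-fraction peak areas."""

    retention_time: float  # minutes
    mz: float
    auc_by_fraction: Mapping[str, float]
    peak_id: str | None = None

    def __post_init__(self) -> None:
        if not self.retention_time > 0:
            raise MsFeatureError("retention_time must be positive")
        aucs = {str(k): float(v) for k, v in self.auc_by_fraction.items()}
        if any(v < 0 for v in aucs.values()):
            raise MsFeatureError("AUC values must be non-negative")
        object.__setattr__(self, "auc_by_fraction", aucs)

    def label(self) -> str:
        return self.peak_id or f"tR{self.retention_time:.1f}_mz{self.mz:.4f}"


@dataclass(frozen=True)
class MsPeakTable:
    peaks: tuple[MsPeak, ...]
    fraction_order: tuple[str, ...]

    def __post_init__(self) -> None:
        peaks = tuple(self.peaks)
        order = tuple(str(f) for f in self.fraction_order)
        known = set(order)
        for p in peaks:
            stray = set(p.auc_by_fraction) - known
            if stray:
                raise MsFeatureError(
                    f"peak {p.label()} has AUCs for unknown fractions "
                    f"{sorted(stray)}"
                )
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "fraction_order", order)

    def auc_matrix(self, fraction_ids: Sequence[str]) -> np.ndarray:
        """fractions x peaks matrix of AUCs (missing entries are 0)."""
        return np.array(
            [
                [p.auc_by_fraction.get(f, 0.0) for p in self.peaks]
                for f in fraction_ids
            ]
        )


@dataclass(frozen=True)
class PeakDiagnostics:
    peak: MsPeak
    correlation: float          # NaN when the AUC is constant in the window
    aucs: tuple[float, ...]
    monotone_ok: bool
    passed: bool
    reason: str


def activity_correlated_peaks(
    table: MsPeakTable,
    activity: np.ndarray,
    package: FractionPackage,
    require_monotone: bool = False,
    min_correlation: float = 0.9,
) -> list[PeakDiagnostics]:
    """Rank LC-MS peaks by their AUC–activity correlation over a package.

    A peak passes when its Pearson correlation is >= ``min_correlation``
    and, when ``require_monotone`` is set, its AUC never decreases between
    consecutive package fractions whose activity does not decrease (the
    'continuous increase of AUC' pattern along a rising activity limb).
    Constant-AUC peaks have undefined correlation and are excluded.
    The returned diagnostics cover every peak, passing ones first, ordered
    by correlation and then by AUC in the most active fraction.
    """
    activity = np.asarray(activity, dtype=float)
    idx = list(package.member_indices)
    if idx[-1] >= len(table.fraction_order):
        raise MsFeatureError(
            f"package {idx} exceeds the {len(table.fraction_order)}-fraction "
            "peak table"
        )
    frac_ids = [table.fraction_order[i] for i in idx]
    y = activity[idx]
    X = table.auc_matrix(frac_ids)
    _, corr = cov_corr_kernel(X, y)
    most_active = int(np.argmax(y))
    diags: list[PeakDiagnostics] = []
    for j, peak in enumerate(table.peaks):
        aucs = tuple(X[:, j])
        c = float(corr[j])
        monotone_ok = all(
            aucs[k + 1] >= aucs[k]
            for k in range(len(aucs) - 1)
            if y[k + 1] >= y[k]
        )
        if math.isnan(c):
            passed, reason = False, "undefined correlation (constant AUC)"
        elif c < min_correlation:
            passed, reason = False, f"correlation {c:.3f} < {min_correlation}"
        elif require_monotone and not monotone_ok:
            passed, reason = False, "AUC not monotone along rising activity"
        else:
            passed, reason = True, "passed"
        diags.append(
            PeakDiagnostics(
                peak=peak,
                correlation=c,
                aucs=aucs,
                monotone_ok=monotone_ok,
                passed=passed,
                reason=reason,
            )
        )
    diags.sort(
        key=lambda d: (
            not d.passed,
            -(d.correlation if not math.isnan(d.correlation) else -np.inf),
            -d.aucs[most_active],
        )
    )
    return diags


def match_mz(
    peak: MsPeak,
    candidates: Sequence[MolecularFormula],
    adducts: Sequence[str] = ("M+H", "M+Na"),
    tolerance_ppm: float = 5.0,
) -> list[tuple[MolecularFormula, str, float]]:
    """All (formula, adduct) pairs whose theoretical singly-charged adduct
    m/z lies within ``tolerance_ppm`` of the observed m/z, with the signed
    mass error in ppm, closest first."""
    if not tolerance_ppm > 0:
        raise MsFeatureError("tolerance_ppm must be positive")
    hits = []
    for f in candidates:
        for adduct in adducts:
            theo = monoisotopic_mass(f, adduct=adduct)
            err_ppm = (peak.mz - theo) / theo * 1e6
            if abs(err_ppm) <= tolerance_ppm:
                hits.append((f, adduct, float(err_ppm)))
    hits.sort(key=lambda h: abs(h[2]))
    return hits


def read_peak_table(path: str | Path) -> MsPeakTable:
    """Delimited peak table: columns retention_time_min, mz, then one AUC
    column per fraction ID (in elution order)."""
    path = Path(path)
    if not path.exists():
        raise MsFeatureError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"retention_time_min", "mz"}
    if not required.issubset(df.columns):
        raise MsFeatureError(
            f"{path}: need columns {sorted(required)}, got {list(df.columns)}"
        )
    meta = required | {"peak_id"}
    frac_cols = [c for c in df.columns if c not in meta]
    peaks = [
        MsPeak(
            retention_time=float(row["retention_time_min"]),
            mz=float(row["mz"]),
            auc_by_fraction={c: float(row[c]) for c in frac_cols},
            peak_id=(
                str(row["peak_id"])
                if "peak_id" in df.columns and pd.notna(row["peak_id"])
                else None
            ),
        )
        for _, row in df.iterrows()
    ]
    return MsPeakTable(peaks=tuple(peaks), fraction_order=tuple(frac_cols))


def write_peak_table(table: MsPeakTable, path: str | Path) -> None:
    rows = []
    with_ids = any(p.peak_id for p in table.peaks)
    for p in table.peaks:
        row = {"retention_time_min": p.retention_time, "mz": p.mz}
        if with_ids:
            row["peak_id"] = p.peak_id or ""
        row.update(
            {f: p.auc_by_fraction.get(f, 0.0) for f in table.fraction_order}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
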