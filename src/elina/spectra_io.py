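"""Reading, writing and alignment of 1D ¹H NMR spectra.

A :class:`Spectrum` holds one microfraction's trace (chemical shift in ppm
plus intensity in arbitrary units).  A :class:`FractionSeries` stacks many
spectra, interpolated onto one shared ppm grid, together with the per-fraction
bioactivity (% inhibition relative to a positive control).  The series is the
object the statistical stages (HetCA, STOCSY) consume.

The canonical ppm order is **ascending** everywhere inside the package; plots
reverse the axis at the rendering edge, following NMR convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "ActivityProfile",
    "FractionSeries",
    "read_spectrum",
    "read_spectra_matrix",
    "write_spectrum",
    "read_activity",
    "write_activity",
    "build_series",
    "save_series",
    "load_series",
]


class SpectraIOError(ValueError):
    """Raised for malformed spectra, activity tables, or alignment failures."""


def _delimiter_for(path: Path) -> str | None:
    # autodetect by extension: .csv → comma, anything else → whitespace/tab
    return "," if path.suffix.lower() == ".csv" else None


def _read_table(path: Path) -> pd.DataFrame:
    delim = _delimiter_for(path)
    if delim is not None:
        # round_trip parsing so write/read cycles preserve every bit
        return pd.read_csv(path, sep=delim, float_precision="round_trip")
    return pd.read_csv(path, sep=r"\s+", engine="python")


@dataclass(frozen=True)
class Spectrum:
    """One fraction's 1D NMR trace.

    ``ppm`` is strictly ascending; ``intensity`` has the same length and must
    be finite (non-finite values in the input are an error, never silently
    dropped).
    """

    fraction_id: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or inten.ndim != 1 or ppm.size != inten.size:
            raise SpectraIOError(
                f"spectrum {self.fraction_id!r}: ppm and intensity must be "
                f"1-D arrays of equal length (got {ppm.shape} vs {inten.shape})"
            )
        if ppm.size and np.any(np.diff(ppm) <= 0):
            # descending input is canonicalised by read_spectrum before we get
            # here; a violation at this level means duplicates or disorder
            raise SpectraIOError(
                f"spectrum {self.fraction_id!r}: ppm axis must be strictly "
                "ascending with no duplicate shifts"
            )
        if not np.all(np.isfinite(inten)):
            bad = int(np.flatnonzero(~np.isfinite(inten))[0])
            raise SpectraIOError(
                f"spectrum {self.fraction_id!r}: non-finite intensity at "
                f"index {bad} (ppm {ppm[bad]:g})"
            )
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return self.ppm.size


@dataclass(frozen=True)
class ActivityProfile:
    """Bioactivity of one fraction: % inhibition versus the positive control.

    The positive control defines 100 %; negative values (apparent activation)
    are legal and carried through unchanged.  ``test_concentration`` (µg/mL)
    is metadata only.
    """

    fraction_id: str
    inhibition_pct: float
    test_concentration: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.inhibition_pct):
            raise SpectraIOError(
                f"activity for {self.fraction_id!r} is not finite"
            )


@dataclass(frozen=True)
class FractionSeries:
    """Aligned spectra matrix plus per-fraction activity.

    Rows follow elution order: consecutive rows are chromatographic
    neighbours, which is what makes windowed (package-wise) covariance
    analysis meaningful.
    """

    fraction_ids: tuple[str, ...]
    shared_ppm: np.ndarray
    spectra_matrix: np.ndarray  # fractions x points
    activity: np.ndarray        # % inhibition, aligned to fraction_ids

    def __post_init__(self) -> None:
        ids = tuple(self.fraction_ids)
        ppm = np.asarray(self.shared_ppm, dtype=float)
        mat = np.asarray(self.spectra_matrix, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        if mat.shape != (len(ids), ppm.size):
            raise SpectraIOError(
                f"matrix shape {mat.shape} does not match "
                f"{len(ids)} fractions x {ppm.size} grid points"
            )
        if act.shape != (len(ids),):
            raise SpectraIOError("activity length must equal fraction count")
        if len(set(ids)) != len(ids):
            raise SpectraIOError("fraction_ids must be unique")
        if ppm.size > 1 and np.any(np.diff(ppm) <= 0):
            raise SpectraIOError("shared_ppm must be strictly ascending")
        object.__setattr__(self, "fraction_ids", ids)
        object.__setattr__(self, "shared_ppm", ppm)
        object.__setattr__(self, "spectra_matrix", mat)
        object.__setattr__(self, "activity", act)

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_ids)


def read_spectrum(
    path: str | Path,
    dialect: str = "two-column",
    fraction_id: str | None = None,
) -> Spectrum:
    """Read a single spectrum from delimited text.

    ``two-column`` files carry (ppm, intensity) rows; a header row is
    tolerated.  On-disk ppm order may be ascending or descending — the result
    is always canonical ascending.  Malformed rows and duplicate ppm values
    raise :class:`SpectraIOError` naming the offending line.
    """
    path = Path(path)
    if dialect != "two-column":
        raise SpectraIOError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise SpectraIOError(f"no such file: {path}")
    ppm: list[float] = []
    inten: list[float] = []
    delim = _delimiter_for(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delim) if delim else line.split()
            parts = [p for p in parts if p != ""]
            if len(parts) != 2:
                raise SpectraIOError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise SpectraIOError(
                    f"{path}:{lineno}: non-numeric value in row {parts!r}"
                ) from None
            ppm.append(x)
            inten.append(y)
    if not ppm:
        raise SpectraIOError(f"{path}: no data rows")
    order = np.argsort(ppm, kind="stable")
    ppm_arr = np.asarray(ppm)[order]
    if np.any(np.diff(ppm_arr) == 0):
        dup = float(ppm_arr[np.flatnonzero(np.diff(ppm_arr) == 0)[0]])
        raise SpectraIOError(f"{path}: duplicate ppm value {dup:g}")
    return Spectrum(
        fraction_id=fraction_id or path.stem,
        ppm=ppm_arr,
        intensity=np.asarray(inten)[order],
    )


def read_spectra_matrix(path: str | Path) -> list[Spectrum]:
    """Read the matrix dialect: first column ppm, one column per fraction,
    header row giving fraction IDs."""
    path = Path(path)
    if not path.exists():
        raise SpectraIOError(f"no such file: {path}")
    df = _read_table(path)
    if df.shape[1] < 2:
        raise SpectraIOError(f"{path}: matrix file needs ppm + >=1 fraction column")
    ppm = df.iloc[:, 0].to_numpy(dtype=float)
    order = np.argsort(ppm, kind="stable")
    ppm = ppm[order]
    if np.any(np.diff(ppm) == 0):
        raise SpectraIOError(f"{path}: duplicate ppm values")
    out = []
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        out.append(Spectrum(str(col), ppm, vals[order]))
    return out


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text; full float precision so that a
    write/read cycle is the identity."""
    path = Path(path)
    delim = _delimiter_for(path) or "\t"
    with open(path, "w") as fh:
        fh.write(f"ppm{delim}intensity\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{float(x)!r}{delim}{float(y)!r}\n")


def read_activity(path: str | Path) -> list[ActivityProfile]:
    """Read the activity table (columns: fraction_id, inhibition_pct,
    optional test_concentration)."""
    path = Path(path)
    if not path.exists():
        raise SpectraIOError(f"no such file: {path}")
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    if "fraction_id" not in cols or "inhibition_pct" not in cols:
        raise SpectraIOError(
            f"{path}: need columns fraction_id and inhibition_pct, "
            f"got {list(df.columns)}"
        )
    conc_col = cols.get("test_concentration")
    records = []
    for _, row in df.iterrows():
        records.append(
            ActivityProfile(
                fraction_id=str(row[cols["fraction_id"]]),
                inhibition_pct=float(row[cols["inhibition_pct"]]),
                test_concentration=(
                    float(row[conc_col]) if conc_col is not None else None
                ),
            )
        )
    ids = [r.fraction_id for r in records]
    if len(set(ids)) != len(ids):
        raise SpectraIOError(f"{path}: duplicate fraction_id values")
    return records


def write_activity(records: Sequence[ActivityProfile], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def _resolve_grid(grid) -> np.ndarray:
    """Grid spec: explicit array, or (low, high, n_points) tuple."""
    if isinstance(grid, tuple) and len(grid) == 3:
        lo, hi, n = grid
        if not (lo < hi and int(n) >= 2):
            raise SpectraIOError(f"bad grid spec {grid!r}")
        return np.linspace(float(lo), float(hi), int(n))
    arr = np.asarray(grid, dtype=float)
    if arr.ndim != 1 or arr.size < 2 or np.any(np.diff(arr) <= 0):
        raise SpectraIOError("grid must be a strictly ascending 1-D array")
    return arr


def build_series(
    spectra: Sequence[Spectrum],
    activity: Sequence[ActivityProfile],
    grid,
    fraction_order: Sequence[str] | None = None,
) -> FractionSeries:
    """Interpolate spectra onto a shared ppm grid and align activities.

    Every spectrum must match exactly one activity record and must cover the
    full grid range — linear interpolation only, extrapolation is an error
    (the source spectra are assumed to share acquisition conditions, so a
    gap means a data problem, not something to patch silently).

    ``fraction_order`` declares the elution order; it defaults to the order
    the spectra are given in.  Permuting the input list while keeping the
    declared order yields an identical series.
    """
    grid_arr = _resolve_grid(grid)
    by_id = {}
    for s in spectra:
        if s.fraction_id in by_id:
            raise SpectraIOError(f"duplicate spectrum for {s.fraction_id!r}")
        by_id[s.fraction_id] = s
    act_by_id = {a.fraction_id: a for a in activity}
    if len(act_by_id) != len(activity):
        raise SpectraIOError("duplicate activity records")
    missing = sorted(set(by_id) - set(act_by_id))
    extra = sorted(set(act_by_id) - set(by_id))
    if missing or extra:
        raise SpectraIOError(
            "spectra/activity mismatch: "
            f"fractions without activity {missing}, "
            f"activity without spectrum {extra}"
        )
    order = list(fraction_order) if fraction_order is not None else [
        s.fraction_id for s in spectra
    ]
    if sorted(order) != sorted(by_id):
        raise SpectraIOError(
            f"fraction_order {order} does not match spectra IDs {sorted(by_id)}"
        )
    rows = np.empty((len(order), grid_arr.size))
    for i, fid in enumerate(order):
        s = by_id[fid]
        if s.ppm[0] > grid_arr[0] or s.ppm[-1] < grid_arr[-1]:
            raise SpectraIOError(
                f"spectrum {fid!r} covers [{s.ppm[0]:g}, {s.ppm[-1]:g}] ppm "
                f"but the grid needs [{grid_arr[0]:g}, {grid_arr[-1]:g}]"
            )
        rows[i] = np.interp(grid_arr, s.ppm, s.intensity)
    act = np.array([act_by_id[fid].inhibition_pct for fid in order])
    return FractionSeries(
        fraction_ids=tuple(order),
        shared_ppm=grid_arr,
        spectra_matrix=rows,
        activity=act,
    )


def save_series(series: FractionSeries, path: str | Path) -> None:
    """Persist a series as a directory of two CSVs (spectra matrix +
    activity).  Round-trips exactly through :func:`load_series`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        series.spectra_matrix.T, columns=list(series.fraction_ids)
    )
    fmt = lambda v: repr(float(v))  # shortest round-trip representation
    df.insert(0, "ppm", series.shared_ppm)
    df.to_csv(path / "spectra.csv", index=False, float_format=fmt)
    pd.DataFrame(
        {
            "fraction_id": list(series.fraction_ids),
            "inhibition_pct": series.activity,
        }
    ).to_csv(path / "activity.csv", index=False, float_format=fmt)


def load_series(path: str | Path) -> FractionSeries:
    path = Path(path)
    spectra = read_spectra_matrix(path / "spectra.csv")
    activity = read_activity(path / "activity.csv")
    return build_series(
        spectra,
        activity,
        grid=spectra[0].ppm,
        fraction_order=[a.fraction_id for a in activity],
    )
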