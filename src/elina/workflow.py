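"""End-to-end workflow driver: load → baseline → bucket → HetCA → STOCSY →
MS correlation → dereplication, from one validated configuration.

The configuration is validated completely before any computation starts, and
a serialized copy is written into the output directory so every bundle is
reproducible from its own config plus the inputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlate, dereplicate, ms_features, preprocess, spectra_io
from .plotting import plot_pseudo_spectrum

__all__ = ["RunConfig", "run_workflow"]

log = logging.getLogger("elina")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one workflow run needs.  ``spectra`` is either a directory
    of per-fraction two-column files or a single matrix file; ``package``
    lists consecutive fraction IDs (elution neighbours)."""

    spectra: str
    activity: str
    outdir: str
    grid_low: float = 0.5
    grid_high: float = 7.0
    grid_points: int = 26001
    baseline_correction: bool = True
    bucket_low: float = 0.5
    bucket_high: float = 7.0
    bucket_width: float = 0.0005
    package: list[str] = field(default_factory=list)
    threshold: float = 0.8
    min_run: int = 2
    stocsy_drivers: list[float] = field(default_factory=list)
    ms_peaks: str | None = None
    ms_min_correlation: float = 0.9
    ms_require_monotone: bool = False
    candidates: str | None = None
    derep_require: list[str] = field(default_factory=list)
    derep_exclude: list[str] = field(default_factory=list)
    derep_allow: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def validate(self) -> None:
        if not Path(self.spectra).exists():
            raise ConfigError(f"spectra input not found: {self.spectra}")
        if not Path(self.activity).exists():
            raise ConfigError(f"activity file not found: {self.activity}")
        for opt in ("ms_peaks", "candidates"):
            p = getattr(self, opt)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{opt} file not found: {p}")
        if not self.grid_low < self.grid_high or self.grid_points < 2:
            raise ConfigError("invalid grid specification")
        if not self.bucket_low < self.bucket_high or self.bucket_width <= 0:
            raise ConfigError("invalid bucket specification")
        if not 0 < self.threshold <= 1:
            raise ConfigError("threshold must lie in (0, 1]")
        if self.candidates is not None and not self.derep_require:
            raise ConfigError(
                "dereplication requested but derep_require is empty"
            )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _load_spectra(path: Path) -> list[spectra_io.Spectrum]:
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".csv", ".tsv", ".txt")
        )
        if not files:
            raise ConfigError(f"no spectrum files in {path}")
        return [spectra_io.read_spectrum(p) for p in files]
    return spectra_io.read_spectra_matrix(path)


def _resolve_package(
    series: spectra_io.FractionSeries, ids: list[str]
) -> correlate.FractionPackage:
    try:
        idx = tuple(series.fraction_ids.index(f) for f in ids)
    except ValueError as exc:
        raise ConfigError(f"package fraction not in series: {exc}") from None
    return correlate.FractionPackage(idx)


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_workflow(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns a manifest of outputs.

    Any stage failure raises with a stage-named message; the CLI converts
    that into a non-zero exit.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {"outdir": str(outdir)}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"[{stage}] {exc}") from exc

    # -- load ------------------------------------------------------------
    t0 = _stage("load")
    try:
        spectra = _load_spectra(Path(config.spectra))
        activity = spectra_io.read_activity(config.activity)
        order = [a.fraction_id for a in activity]
        series = spectra_io.build_series(
            spectra,
            activity,
            grid=(config.grid_low, config.grid_high, config.grid_points),
            fraction_order=order,
        )
    except Exception as exc:
        fail("load", exc)
    log.info("loaded %d fractions (%.2fs)", series.n_fractions, time.perf_counter() - t0)

    # -- baseline --------------------------------------------------------
    if config.baseline_correction:
        t0 = _stage("baseline")
        try:
            rows = []
            for fid, row in zip(series.fraction_ids, series.spectra_matrix):
                s = spectra_io.Spectrum(fid, series.shared_ppm, row)
                model = preprocess.fit_baseline(s)
                rows.append(preprocess.subtract_baseline(s, model).intensity)
            series = spectra_io.FractionSeries(
                fraction_ids=series.fraction_ids,
                shared_ppm=series.shared_ppm,
                spectra_matrix=np.vstack(rows),
                activity=series.activity,
            )
        except Exception as exc:
            fail("baseline", exc)
        log.info("baseline corrected (%.2fs)", time.perf_counter() - t0)

    # -- bucket ----------------------------------------------------------
    t0 = _stage("bucket")
    try:
        table = preprocess.bucket(
            series, config.bucket_low, config.bucket_high, config.bucket_width
        )
    except Exception as exc:
        fail("bucket", exc)
    log.info("%d buckets (%.2fs)", table.n_buckets, time.perf_counter() - t0)

    # -- package ---------------------------------------------------------
    if config.package:
        package = _resolve_package(series, config.package)
    else:
        # no package declared: report the variance ranking and pick nothing
        packages = correlate.enumerate_packages(series)
        ranking = pd.DataFrame(
            {
                "members": [
                    ",".join(series.fraction_ids[i] for i in p.member_indices)
                    for p in packages
                ],
                "activity_variance": [p.activity_variance for p in packages],
            }
        )
        ranking.to_csv(outdir / "package_ranking.csv", index=False)
        manifest["package_ranking"] = str(outdir / "package_ranking.csv")
        raise ConfigError(
            "no fraction package declared; a variance ranking was written "
            "to package_ranking.csv — package selection is deliberately "
            "manual"
        )

    summary: list[str] = [
        f"fractions: {series.n_fractions}",
        f"buckets: {table.n_buckets} "
        f"({config.bucket_low}-{config.bucket_high} ppm, "
        f"width {config.bucket_width})",
        f"package: {','.join(config.package)}",
    ]

    # -- HetCA -----------------------------------------------------------
    t0 = _stage("hetca")
    try:
        het = correlate.hetca(
            table, series.activity, package, threshold=config.threshold
        )
        pd.DataFrame(
            {
                "bucket_centre_ppm": het.bucket_centres,
                "covariance": het.covariance,
                "correlation": het.correlation,
                "label": het.labels,
            }
        ).to_csv(outdir / "hetca.csv", index=False)
        intervals = correlate.hot_cold_report(het, min_run=config.min_run)
        pd.DataFrame([dataclasses.asdict(iv) for iv in intervals]).to_csv(
            outdir / "hetca_features.csv", index=False
        )
        plot_pseudo_spectrum(het, outdir / "hetca.svg")
    except Exception as exc:
        fail("hetca", exc)
    manifest["hetca"] = str(outdir / "hetca.csv")
    summary.append(
        f"hetca: {sum(het.labels == 'hot')} hot / "
        f"{sum(het.labels == 'cold')} cold buckets at |r| >= {config.threshold}"
    )
    for iv in intervals[:10]:
        summary.append(
            f"  {iv.label:4s} {iv.ppm_low:.3f}-{iv.ppm_high:.3f} ppm  "
            f"peak r {iv.peak_abs_correlation:+.3f}  "
            f"peak cov {iv.peak_covariance:.3g}"
        )
    log.info("hetca done (%.2fs)", time.perf_counter() - t0)

    # -- STOCSY ----------------------------------------------------------
    for driver in config.stocsy_drivers:
        t0 = _stage(f"stocsy {driver}")
        try:
            st = correlate.stocsy(table, driver, package)
            out = outdir / f"stocsy_{driver:g}.csv"
            pd.DataFrame(
                {
                    "bucket_centre_ppm": st.bucket_centres,
                    "covariance": st.covariance,
                    "correlation": st.correlation,
                }
            ).to_csv(out, index=False)
            plot_pseudo_spectrum(st, outdir / f"stocsy_{driver:g}.svg")
        except Exception as exc:
            fail("stocsy", exc)
        manifest[f"stocsy_{driver:g}"] = str(out)
        summary.append(f"stocsy: driver {driver:g} ppm -> {out.name}")
        log.info("stocsy %g done (%.2fs)", driver, time.perf_counter() - t0)

    # -- MS correlation ---------------------------------------------------
    if config.ms_peaks:
        t0 = _stage("ms-corr")
        try:
            peaks = ms_features.read_peak_table(config.ms_peaks)
            diags = ms_features.activity_correlated_peaks(
                peaks,
                series.activity,
                package,
                require_monotone=config.ms_require_monotone,
                min_correlation=config.ms_min_correlation,
            )
            pd.DataFrame(
                [
                    {
                        "peak": d.peak.label(),
                        "retention_time_min": d.peak.retention_time,
                        "mz": d.peak.mz,
                        "correlation": d.correlation,
                        "passed": d.passed,
                        "reason": d.reason,
                    }
                    for d in diags
                ]
            ).to_csv(outdir / "ms_correlation.csv", index=False)
        except Exception as exc:
            fail("ms-corr", exc)
        manifest["ms_correlation"] = str(outdir / "ms_correlation.csv")
        passing = [d for d in diags if d.passed]
        summary.append(f"ms: {len(passing)}/{len(diags)} peaks pass")
        for d in passing:
            summary.append(
                f"  {d.peak.label()}  r={d.correlation:+.3f}"
            )
        log.info("ms-corr done (%.2fs)", time.perf_counter() - t0)

    # -- dereplication ----------------------------------------------------
    if config.candidates:
        t0 = _stage("derep")
        try:
            cands = dereplicate.read_candidates(config.candidates)
            spec = dereplicate.FilterSpec(
                required_hot=frozenset(config.derep_require),
                excluded_cold=frozenset(config.derep_exclude),
                allowed_other=frozenset(config.derep_allow),
            )
            retained, audit = dereplicate.apply_filters(cands, spec)
            dereplicate.write_audit(audit, outdir / "derep_audit.csv")
        except Exception as exc:
            fail("derep", exc)
        manifest["derep_audit"] = str(outdir / "derep_audit.csv")
        summary.append(
            f"dereplication: {len(retained)}/{len(cands)} candidates retained"
        )
        if retained:
            for c in retained:
                summary.append(f"  retained: {c.name} ({c.formula})")
        else:
            summary.append(
                "  no matching structures — the active constituent may be "
                "an unreported compound"
            )
        log.info("derep done (%.2fs)", time.perf_counter() - t0)

    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    manifest["summary"] = str(outdir / "summary.txt")
    return manifest
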