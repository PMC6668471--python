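"""Candidate refinement by structure-feature filters.

After the statistical stages, candidate compounds (typically a literature
answer set per plausible molecular formula) are narrowed by three filters
that translate the pseudo-spectrum's evidence into structural requirements:

  A — *inclusion*: the candidate must carry every required hot feature
      (e.g. the scaffold backbone and a diagnostic moiety whose resonances
      correlate positively with activity);
  B — *exclusion*: the candidate must carry none of the excluded cold
      features (substructures whose resonances anti-correlate);
  C — *allow-list*: every remaining structural feature of the candidate must
      be accounted for in the pseudo-spectrum; features without spectral
      evidence (an acetyl, a methyl ester, a cyclopropyl ring ...) exclude
      the candidate.

Features are boolean tags supplied with the candidate table — this module
encodes the expert decision layer, not substructure searching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ms_features import MolecularFormula, parse_formula

__all__ = [
    "CandidateCompound",
    "FilterSpec",
    "FilterAudit",
    "apply_filters",
    "read_candidates",
    "write_audit",
]


class DereplicationError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateCompound:
    name: str
    formula: MolecularFormula
    hot_features: frozenset[str] = frozenset()
    cold_features: frozenset[str] = frozenset()
    other_features: frozenset[str] = frozenset()
    source_peak: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "hot_features", frozenset(self.hot_features))
        object.__setattr__(self, "cold_features", frozenset(self.cold_features))
        object.__setattr__(self, "other_features", frozenset(self.other_features))

    @property
    def all_tags(self) -> frozenset[str]:
        return self.hot_features | self.cold_features | self.other_features


@dataclass(frozen=True)
class FilterSpec:
    """required_hot = filter A, excluded_cold = filter B, allowed_other =
    filter C's allow-list (the user's reading of the pseudo-spectrum)."""

    required_hot: frozenset[str]
    excluded_cold: frozenset[str] = frozenset()
    allowed_other: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        req = frozenset(self.required_hot)
        exc = frozenset(self.excluded_cold)
        if req & exc:
            raise DereplicationError(
                f"tags cannot be both required and excluded: {sorted(req & exc)}"
            )
        object.__setattr__(self, "required_hot", req)
        object.__setattr__(self, "excluded_cold", exc)
        object.__setattr__(self, "allowed_other", frozenset(self.allowed_other))

    @property
    def all_tags(self) -> frozenset[str]:
        return self.required_hot | self.excluded_cold | self.allowed_other


@dataclass(frozen=True)
class FilterAudit:
    name: str
    retained: bool
    failed_filter: str | None     # 'A' | 'B' | 'C' | None
    offending_tags: tuple[str, ...]


def apply_filters(
    candidates: Sequence[CandidateCompound],
    spec: FilterSpec,
    vocabulary: Iterable[str] | None = None,
) -> tuple[list[CandidateCompound], list[FilterAudit]]:
    """Apply filters A, B, C; return (retained, audit).

    Retention is pure set logic — required_hot ⊆ hot, cold ∩ excluded = ∅,
    other ⊆ allowed — so the retained set does not depend on filter order;
    only the audit's "first failing filter" uses the fixed A→B→C order.
    Input order is preserved; names must be unique; with a ``vocabulary``
    given, any tag outside it (in candidates or spec) is an error.
    """
    names = [c.name for c in candidates]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise DereplicationError(f"duplicate candidate names: {dup}")
    if vocabulary is not None:
        vocab = set(vocabulary)
        bad = sorted(spec.all_tags - vocab)
        if bad:
            raise DereplicationError(f"unknown tag(s) in filter spec: {bad}")
        for c in candidates:
            bad = sorted(c.all_tags - vocab)
            if bad:
                raise DereplicationError(
                    f"unknown tag(s) on candidate {c.name!r}: {bad}"
                )
    retained: list[CandidateCompound] = []
    audit: list[FilterAudit] = []
    for c in candidates:
        missing_hot = spec.required_hot - c.hot_features
        hit_cold = c.cold_features & spec.excluded_cold
        stray_other = c.other_features - spec.allowed_other
        if missing_hot:
            audit.append(FilterAudit(c.name, False, "A", tuple(sorted(missing_hot))))
        elif hit_cold:
            audit.append(FilterAudit(c.name, False, "B", tuple(sorted(hit_cold))))
        elif stray_other:
            audit.append(FilterAudit(c.name, False, "C", tuple(sorted(stray_other))))
        else:
            retained.append(c)
            audit.append(FilterAudit(c.name, True, None, ()))
    return retained, audit


def _split_tags(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(t.strip() for t in str(cell).split(";") if t.strip())


def read_candidates(path: str | Path) -> list[CandidateCompound]:
    """Candidate table CSV: columns name, formula, hot, cold, other
    (semicolon-separated tags), optional source_peak."""
    path = Path(path)
    if not path.exists():
        raise DereplicationError(f"no such file: {path}")
    df = pd.read_csv(path)
    required = {"name", "formula"}
    if not required.issubset(df.columns):
        raise DereplicationError(
            f"{path}: need columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            CandidateCompound(
                name=str(row["name"]),
                formula=parse_formula(str(row["formula"])),
                hot_features=_split_tags(row.get("hot")),
                cold_features=_split_tags(row.get("cold")),
                other_features=_split_tags(row.get("other")),
                source_peak=(
                    str(row["source_peak"])
                    if "source_peak" in df.columns and pd.notna(row["source_peak"])
                    else None
                ),
            )
        )
    return out


def write_audit(audit: Sequence[FilterAudit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": a.name,
                "retained": a.retained,
                "failed_filter": a.failed_filter or "",
                "offending_tags": ";".join(a.offending_tags),
            }
            for a in audit
        ]
    ).to_csv(path, index=False)
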