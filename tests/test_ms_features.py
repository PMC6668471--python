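import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elina.correlate import FractionPackage
from elina.ms_features import (
    FormulaError,
    MolecularFormula,
    MsFeatureError,
    MsPeak,
    MsPeakTable,
    MONOISOTOPIC_MASSES,
    STANDARD_ATOMIC_WEIGHTS,
    activity_correlated_peaks,
    average_mass,
    match_mz,
    monoisotopic_mass,
    parse_formula,
    read_peak_table,
    write_peak_table,
)

from _oracles import brute_cov_corr


def _round2(x: float) -> float:
    # round-half-even display rounding at 2 decimals
    return float(np.round(x, 2))


class TestFormulaParsing:
    def test_triterpene_formula(self):
        f = parse_formula("C30H42O4")
        assert f.element_counts == {"C": 30, "H": 42, "O": 4}

    def test_implicit_count_and_hill_rendering(self):
        f = parse_formula("H2O")
        assert f.element_counts == {"H": 2, "O": 1}
        assert str(f) == "H2O"
        assert str(parse_formula("O4C30H42")) == "C30H42O4"

    def test_case_sensitive_symbols_rejected_with_position(self):
        with pytest.raises(FormulaError, match="position 2"):
            parse_formula("C2h4")

    def test_unknown_element_and_empty(self):
        with pytest.raises(FormulaError, match="unknown element"):
            parse_formula("Xx2")
        with pytest.raises(FormulaError, match="empty"):
            parse_formula("")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.dictionaries(
            st.sampled_from(sorted(STANDARD_ATOMIC_WEIGHTS)),
            st.integers(1, 99),
            min_size=1,
            max_size=5,
        )
    )
    def test_render_parse_round_trip(self, counts):
        f = MolecularFormula(counts)
        assert parse_formula(str(f)).element_counts == f.element_counts


class TestMasses:
    def test_reported_average_molecular_weights(self):
        assert _round2(average_mass(parse_formula("C30H42O4"))) == 466.66
        assert _round2(average_mass(parse_formula("C30H44O4"))) == 468.68

    def test_single_carbon_average_weight(self):
        assert average_mass(parse_formula("C")) == pytest.approx(12.011)

    def test_carbon12_monoisotopic_definition(self):
        assert monoisotopic_mass(parse_formula("C")) == 12.0

    def test_water_monoisotopic_hand_sum(self):
        # 2 * 1.00782503207 + 15.9949146196 summed by hand
        assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(
            18.0105646838, abs=1e-5
        )

    def test_monoisotopic_against_independent_library(self):
        # pyteomics computes from its own isotope table; agreement to ~1e-4 u
        # cross-checks both the embedded masses and the adduct arithmetic
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for text in ("C30H42O4", "C30H44O5", "C6H12O6"):
            f = parse_formula(text)
            assert monoisotopic_mass(f) == pytest.approx(
                pyteomics_mass.calculate_mass(formula=text), abs=2e-4
            )
        assert monoisotopic_mass(parse_formula("C30H42O4"), "M+H") == pytest.approx(
            pyteomics_mass.calculate_mass(formula="C30H42O4", ion_type="M", charge=1),
            abs=2e-4,
        )

    def test_mass_additivity(self):
        a = parse_formula("C30H42O4")
        b = parse_formula("C2H6O")
        merged = a + b
        assert average_mass(merged) == pytest.approx(
            average_mass(a) + average_mass(b), rel=1e-12
        )
        assert monoisotopic_mass(merged) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), rel=1e-12
        )

    def test_two_hydrogen_difference_is_exact_formula_arithmetic(self):
        d = average_mass(parse_formula("C30H42O4")) - average_mass(
            parse_formula("C30H44O4")
        )
        assert d == pytest.approx(-2 * STANDARD_ATOMIC_WEIGHTS["H"], abs=1e-12)

    def test_unknown_adduct_rejected(self):
        with pytest.raises(MsFeatureError, match="adduct"):
            monoisotopic_mass(parse_formula("H2O"), adduct="M+K")


def _peak(aucs, rt=25.0, mz=467.0, pid=None):
    return MsPeak(
        retention_time=rt,
        mz=mz,
        auc_by_fraction={f"F{i}": a for i, a in enumerate(aucs)},
        peak_id=pid,
    )


class TestActivityCorrelatedPeaks:
    def _table(self, peaks, n=3):
        return MsPeakTable(
            peaks=tuple(peaks), fraction_order=tuple(f"F{i}" for i in range(n))
        )

    def test_perfectly_tracking_peak_passes(self):
        table = self._table([_peak((1.0, 2.0, 3.0), pid="up")])
        act = np.array([10.0, 30.0, 50.0])
        diags = activity_correlated_peaks(
            table, act, FractionPackage((0, 1, 2)), require_monotone=True
        )
        assert diags[0].passed and diags[0].correlation == pytest.approx(1.0)
        assert diags[0].monotone_ok

    def test_constant_auc_is_undefined_and_excluded(self):
        table = self._table(
            [_peak((2.0, 2.0, 2.0), pid="flat"), _peak((1.0, 2.0, 3.0), pid="up")]
        )
        act = np.array([10.0, 30.0, 50.0])
        diags = activity_correlated_peaks(table, act, FractionPackage((0, 1, 2)))
        flat = next(d for d in diags if d.peak.peak_id == "flat")
        assert not flat.passed and math.isnan(flat.correlation)

    def test_monotone_requirement_rejects_dips(self):
        table = self._table([_peak((1.0, 3.0, 2.9), pid="dip")])
        act = np.array([10.0, 30.0, 50.0])
        loose = activity_correlated_peaks(
            table, act, FractionPackage((0, 1, 2)),
            require_monotone=False, min_correlation=0.8,
        )
        strict = activity_correlated_peaks(
            table, act, FractionPackage((0, 1, 2)),
            require_monotone=True, min_correlation=0.8,
        )
        assert loose[0].passed
        assert not strict[0].passed

    def test_ranking_matches_brute_force_recomputation(self, rng):
        n = 3
        aucs = rng.uniform(0, 100, size=(5, n))
        peaks = [_peak(tuple(aucs[j]), pid=f"p{j}") for j in range(5)]
        table = self._table(peaks, n=n)
        act = rng.uniform(0, 80, size=n)
        diags = activity_correlated_peaks(
            table, act, FractionPackage((0, 1, 2)), min_correlation=0.5
        )
        _, corr_o = brute_cov_corr(aucs.T.tolist(), act.tolist())
        by_id = {d.peak.peak_id: d for d in diags}
        for j in range(5):
            assert by_id[f"p{j}"].correlation == pytest.approx(
                corr_o[j], rel=1e-12
            )
        passing = [d.peak.peak_id for d in diags if d.passed]
        expected = {f"p{j}" for j in range(5) if corr_o[j] >= 0.5}
        assert set(passing) == expected
        # passing peaks come first, in descending correlation order
        corr_seq = [d.correlation for d in diags if d.passed]
        assert corr_seq == sorted(corr_seq, reverse=True)

    def test_peak_table_round_trip(self, tmp_path):
        table = self._table(
            [_peak((1.0, 2.0, 3.0)), _peak((5.0, 0.0, 1.0), rt=26.2, mz=469.3)]
        )
        write_peak_table(table, tmp_path / "peaks.csv")
        back = read_peak_table(tmp_path / "peaks.csv")
        assert back.fraction_order == table.fraction_order
        for a, b in zip(back.peaks, table.peaks):
            assert a.auc_by_fraction == b.auc_by_fraction
            assert a.mz == b.mz


class TestMatchMz:
    def test_exact_adduct_match_is_zero_ppm(self):
        f = parse_formula("C30H42O4")
        mz = monoisotopic_mass(f, "M+H")
        hits = match_mz(_peak((1.0,), mz=mz), [f], adducts=("M+H",))
        assert len(hits) == 1
        assert hits[0][1] == "M+H" and hits[0][2] == pytest.approx(0.0, abs=1e-9)

    def test_empty_candidate_list(self):
        assert match_mz(_peak((1.0,), mz=400.0), []) == []

    def test_tolerance_window_matches_brute_force(self, rng):
        candidates = [
            parse_formula(f"C{20 + i}H{30 + 2 * i}O{2 + (i % 4)}")
            for i in range(10)
        ]
        target = candidates[4]
        theo = monoisotopic_mass(target, "M+H")
        observed = theo * (1 + 3e-6)  # +3 ppm offset
        hits = match_mz(
            _peak((1.0,), mz=observed), candidates,
            adducts=("M+H", "M+Na"), tolerance_ppm=5.0,
        )
        # brute force over every (formula, adduct) pair
        expected = []
        for f in candidates:
            for adduct in ("M+H", "M+Na"):
                t = monoisotopic_mass(f, adduct)
                err = (observed - t) / t * 1e6
                if abs(err) <= 5.0:
                    expected.append((str(f), adduct))
        assert [(str(h[0]), h[1]) for h in hits] == expected
        assert len(hits) == 1 and hits[0][0] is target
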