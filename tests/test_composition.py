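"""Composition equations, iodine value, F/H ratio, QC behaviour."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oilnmr as o
from oilnmr.composition import ImplausibleIntegralsError

from conftest import oracle_proton_counts


def _table_from_fractions(x, y, z, w, label="model"):
    counts = oracle_proton_counts(x, y, z, w)
    return o.IntegralTable(label, counts)


class TestEquations:
    @pytest.mark.parametrize(
        "fractions, expected",
        [
            ((1.0, 0.0, 0.0, 0.0), (100.0, 0.0, 0.0)),  # tristearin
            ((0.0, 1.0, 0.0, 0.0), (0.0, 100.0, 0.0)),  # triolein
            ((0.0, 0.0, 0.0, 1.0), (0.0, 0.0, 100.0)),  # trilinolenin
            ((0.2, 0.6, 0.15, 0.05), (20.0, 60.0, 20.0)),
        ],
    )
    def test_pure_and_mixture_compositions(self, fractions, expected):
        fac = o.compute_fac(_table_from_fractions(*fractions))
        assert (fac.sfa, fac.mufa, fac.pufa) == pytest.approx(expected, abs=1e-9)

    def test_grid_inversion_to_machine_precision(self):
        """Over the 0.05-step composition simplex the equations invert the
        forward proton-count model exactly, and the three percentages sum
        to 100 identically."""
        steps = np.arange(0.0, 1.0001, 0.05)
        for x, y, z in itertools.product(steps, steps, steps):
            w = 1.0 - x - y - z
            if w < -1e-12:
                continue
            w = max(w, 0.0)
            fac = o.compute_fac(_table_from_fractions(x, y, z, w))
            assert fac.sfa == pytest.approx(100.0 * x, abs=1e-9)
            assert fac.mufa == pytest.approx(100.0 * y, abs=1e-9)
            assert fac.pufa == pytest.approx(100.0 * (z + w), abs=1e-9)
            assert fac.sfa + fac.mufa + fac.pufa == pytest.approx(100.0, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4))
    def test_closure_identity_property(self, raw):
        total = sum(raw)
        if total < 1e-6:
            return
        x, y, z, w = (v / total for v in raw)
        fac = o.compute_fac(_table_from_fractions(x, y, z, w))
        assert fac.sfa + fac.mufa + fac.pufa == pytest.approx(100.0, abs=1e-6)

    def test_printed_variant_with_h_breaks_the_mass_balance(self):
        """The published MUFA formula using H instead of the bis-allylic G
        reports a third of the truth for triolein."""
        fac = o.compute_fac(_table_from_fractions(0.0, 1.0, 0.0, 0.0),
                            eq2_uses_h=True)
        assert fac.mufa == pytest.approx(100.0 / 3.0, abs=1e-6)

    def test_zero_f_rejected(self):
        table = o.IntegralTable("s", {n: 0.0 for n in "ABCDEFGHIJ"})
        with pytest.raises(ValueError):
            o.compute_fac(table)


class TestOlefinicProtons:
    def test_triolein_op_percent(self):
        table = _table_from_fractions(0.0, 1.0, 0.0, 0.0)
        assert o.compute_op_percent(table) == pytest.approx(100.0 * 6 / 104, abs=1e-9)

    def test_saturated_oil_has_no_olefinic_protons(self):
        assert o.compute_op_percent(_table_from_fractions(1, 0, 0, 0)) == 0.0

    def test_scale_invariance(self):
        table = _table_from_fractions(0.2, 0.6, 0.15, 0.05)
        doubled = o.IntegralTable("s", {k: 2 * v for k, v in table.areas.items()})
        assert o.compute_op_percent(doubled) == pytest.approx(
            o.compute_op_percent(table), abs=1e-12
        )

    def test_op_increases_with_unsaturation(self):
        """Replacing saturated chains by linolenic ones raises %OP strictly."""
        previous = -1.0
        for w in np.linspace(0.0, 0.6, 7):
            op = o.compute_op_percent(_table_from_fractions(0.4 - w * 0.5, 0.3,
                                                            0.3 - w * 0.5, w))
            assert op > previous
            previous = op


class TestIodineValue:
    @pytest.mark.parametrize(
        "op, expected",
        [(0.0, 10.54), (1.0, 23.93), (100.0 * 6 / 104, 87.79)],
    )
    def test_linear_regression(self, op, expected):
        assert round(o.compute_iv(op), 2) == expected

    def test_strictly_increasing(self):
        ops = np.linspace(0, 12, 13)
        ivs = [o.compute_iv(v) for v in ops]
        assert np.all(np.diff(ivs) > 0)

    def test_negative_op_rejected(self):
        with pytest.raises(ValueError):
            o.compute_iv(-0.1)


class TestFHRatio:
    def test_pure_tg_gives_three_halves(self):
        for fractions in [(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 0, 1)]:
            assert o.compute_fh(_table_from_fractions(*fractions)) == 1.5

    def test_free_fatty_acids_raise_fh_and_flag(self, regions):
        spec = o.OilSpec.preset("olive", free_fatty_acid_fraction=0.10)
        spectrum, quality = o.process(o.synthesize_fid(spec))
        result = o.analyze_sample(spectrum, regions, quality)
        assert result.fh_ratio > 1.55
        assert "FH_out_of_range" in result.qc_flags

    def test_zero_h_rejected(self):
        table = o.IntegralTable("s", {"F": 6.0, "H": 0.0})
        with pytest.raises(ValueError):
            o.compute_fh(table)


class TestQC:
    def test_small_negative_fraction_clamped_and_flagged(self):
        counts = oracle_proton_counts(0.0, 1.0, 0.0, 0.0)
        counts["G"] = -0.05  # small negative bis-allylic integral (noise)
        fac = o.compute_fac(o.IntegralTable("s", counts))
        assert fac.pufa == 0.0
        assert "negative_fraction_clamped" in fac.qc_flags

    def test_large_negative_fraction_fails_the_sample(self):
        counts = oracle_proton_counts(0.0, 1.0, 0.0, 0.0)
        counts["G"] = -1.5
        with pytest.raises(ImplausibleIntegralsError, match="implausible"):
            o.compute_fac(o.IntegralTable("s", counts))

    def test_snr_failure_propagates_to_result(self, olive_spectrum, regions):
        quality = o.QualityMetrics(
            snr_b=120.0, linewidth_tms_hz=0.68,
            digital_resolution_hz=0.11, snr_ok=False, resolution_ok=True,
        )
        result = o.analyze_sample(olive_spectrum, regions, quality)
        assert "snr_fail" in result.qc_flags

    def test_tms_missing_propagates_to_result(self, regions):
        spec = o.OilSpec.preset("olive", include_tms=False)
        spectrum, quality = o.process(o.synthesize_fid(spec))
        result = o.analyze_sample(spectrum, regions, quality)
        assert "tms_missing" in result.qc_flags


class TestRoundTrip:
    @pytest.mark.parametrize("preset", ["olive", "sunflower", "linseed", "arbequina"])
    def test_noiseless_recovery_within_half_point(self, preset, regions):
        spec = o.OilSpec.preset(preset)
        spectrum, quality = o.process(o.synthesize_fid(spec))
        result = o.analyze_sample(spectrum, regions, quality)
        x, y, z, w = spec.fractions
        assert result.sfa == pytest.approx(100 * x, abs=0.5)
        assert result.mufa == pytest.approx(100 * y, abs=0.5)
        assert result.pufa == pytest.approx(100 * (z + w), abs=0.5)
        assert result.fh_ratio == pytest.approx(1.50, abs=0.02)
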