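"""Transcription-assay quantitation rules and identities."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from switchsim import (
    BandTable,
    ConfigurationError,
    MillerInput,
    apparent_rate,
    miller_units,
    pause_fraction_series,
    pause_parameters,
    termination_difference,
    termination_efficiency,
)


def make_table(times, rows):
    species = tuple((name, ln) for name, ln, _ in rows)
    intensities = np.array([vals for _, _, vals in rows], dtype=float)
    return BandTable(times=np.asarray(times, float), species=species, intensities=intensities)


class TestPauseFraction:
    def test_fraction_follows_the_stated_rule(self):
        table = make_table(
            [10.0],
            [("FL", 214, [6.0]), ("T", 164, [0.0]), ("PS1", 110, [2.0])],
        )
        frac = pause_fraction_series(table, "PS1")
        assert frac[0] == pytest.approx(2.0 / 8.0)

    def test_longest_species_fraction_is_one(self):
        table = make_table(
            [5.0, 10.0],
            [("FL", 214, [3.0, 4.0]), ("T", 164, [1.0, 2.0])],
        )
        frac = pause_fraction_series(table, "FL")
        # no species is as long or longer, so the denominator is FL itself
        assert np.allclose(frac, [1.0, 1.0])
        only_fl = make_table([5.0], [("FL", 214, [3.0]), ("T", 164, [0.0])])
        assert pause_fraction_series(only_fl, "FL")[0] == pytest.approx(1.0)

    def test_zero_denominator_lane_masked_not_zeroed(self):
        table = make_table(
            [5.0, 10.0],
            [("FL", 214, [0.0, 1.0]), ("PS1", 110, [0.0, 1.0])],
        )
        frac = pause_fraction_series(table, "PS1")
        assert frac.mask[0] and not frac.mask[1]

    def test_fractions_never_exceed_one(self, rng):
        intensities = rng.uniform(0, 5, size=(3, 6))
        table = make_table(
            np.arange(1.0, 7.0),
            [("FL", 214, intensities[0]), ("T", 164, intensities[1]), ("PS1", 110, intensities[2])],
        )
        for name in table.names:
            frac = pause_fraction_series(table, name)
            assert np.all(frac[~frac.mask] <= 1.0 + 1e-12)


class TestPauseParameters:
    def test_closed_form_decay(self):
        t = np.linspace(0, 200, 20)
        params = pause_parameters(t, 0.5 * np.exp(-0.02 * t))
        assert params.kp == pytest.approx(0.02, rel=1e-6)
        assert params.tau == pytest.approx(50.0, rel=1e-6)
        assert params.t_half == pytest.approx(np.log(2) / 0.02, rel=1e-6)

    @given(kp=st.floats(1e-4, 1.0))
    def test_unit_identities_hold_exactly(self, kp):
        t = np.linspace(0, 5 / kp, 16)
        params = pause_parameters(t, np.exp(-kp * t))
        assert params.t_half * params.kp == pytest.approx(np.log(2), rel=1e-9)
        assert params.tau * params.kp == pytest.approx(1.0, rel=1e-9)

    def test_monotone_rise_reports_blocking_not_pausing(self):
        t = np.linspace(0, 100, 12)
        assert pause_parameters(t, 1 - np.exp(-0.05 * t)) is None


class TestApparentRate:
    def test_conversion_is_length_times_kapp(self):
        t = np.linspace(0, 600, 24)
        y = 3.0 * (1 - np.exp(-0.0122 * t))
        est = apparent_rate(t, y, length=164)
        assert est.k_app == pytest.approx(0.0122, rel=1e-6)
        assert est.rate == pytest.approx(164 * 0.0122, rel=1e-6)

    def test_scale_invariance_of_rate(self):
        t = np.linspace(0, 600, 24)
        y = 1.0 * (1 - np.exp(-0.01 * t))
        a = apparent_rate(t, y, length=164)
        b = apparent_rate(t, 2.0 * y, length=164)
        assert b.rate == pytest.approx(a.rate, rel=1e-10)

    def test_non_saturating_series_warns_and_external_max_fixes_it(self):
        t = np.linspace(0, 600, 24)
        y = 5.0 * (1 - np.exp(-0.001 * t))  # far from plateau at 600 s
        with pytest.warns(UserWarning, match="did not saturate"):
            apparent_rate(t, y, length=164)
        est = apparent_rate(t, y, length=164, i_max=5.0)
        assert est.k_app == pytest.approx(0.001, rel=1e-6)


class TestTermination:
    def test_symmetry_and_boundary(self):
        equal = make_table([600.0], [("FL", 214, [2.0]), ("T", 164, [2.0])])
        assert termination_efficiency(equal) == pytest.approx(50.0)
        all_term = make_table([600.0], [("FL", 214, [0.0]), ("T", 164, [1.0])])
        assert termination_efficiency(all_term) == pytest.approx(100.0)

    def test_both_zero_is_an_error(self):
        table = make_table([600.0], [("FL", 214, [0.0]), ("T", 164, [0.0])])
        with pytest.raises(ConfigurationError, match="undefined"):
            termination_efficiency(table)

    def test_difference_reports_both_readings(self):
        minus = make_table([600.0], [("FL", 214, [6.0]), ("T", 164, [4.0])])
        plus = make_table([600.0], [("FL", 214, [3.0]), ("T", 164, [7.0])])
        diff = termination_difference(minus, plus)
        assert diff["absolute_points"] == pytest.approx(30.0)
        assert diff["relative_percent"] == pytest.approx(75.0)

    def test_per_g_label_correction(self):
        table = make_table([600.0], [("FL", 214, [4.0]), ("T", 164, [4.0])])
        # same raw intensity, but FL carries twice the G residues
        corrected = termination_efficiency(table, g_counts={"FL": 40, "T": 20})
        assert corrected == pytest.approx(100.0 * 0.2 / 0.3)


class TestMillerUnits:
    def test_zero_numerator(self):
        # A420 = 1.75 * A550 exactly (binary-exact inputs)
        assert miller_units(MillerInput(A420=0.4375, A550=0.25, A600=0.5, t=10, V=0.1)) == 0.0

    def test_printed_formula_arithmetic(self):
        mu = miller_units(MillerInput(A420=0.35, A550=0.0, A600=0.5, t=10, V=0.1))
        assert mu == pytest.approx(700.0)

    def test_doubling_a600_halves_activity(self):
        a = miller_units(MillerInput(A420=0.4, A550=0.05, A600=0.3, t=8, V=0.2))
        b = miller_units(MillerInput(A420=0.4, A550=0.05, A600=0.6, t=8, V=0.2))
        assert b == pytest.approx(a / 2)

    def test_negative_result_warns_but_returns(self):
        with pytest.warns(UserWarning, match="negative Miller"):
            mu = miller_units(MillerInput(A420=0.1, A550=0.2, A600=0.5, t=10, V=0.1))
        assert mu < 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            MillerInput(A420=0.3, A550=0.0, A600=0.5, t=0, V=0.1)


class TestBandTableIO:
    def test_tsv_round_trip(self, tmp_path):
        table = make_table(
            [5.0, 60.0],
            [("FL", 214, [1.5, 2.5]), ("T", 164, [0.5, 3.0])],
        )
        path = tmp_path / "bands.tsv"
        table.to_tsv(path)
        back = BandTable.from_tsv(path)
        assert back.species == table.species
        assert np.allclose(back.times, table.times)
        assert np.allclose(back.intensities, table.intensities)
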