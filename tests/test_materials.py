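"""Material tables: parsing, validation, interpolation, admittivity."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cellimp import materials
from cellimp.materials import (
    EPS0,
    PBS,
    MediumProperties,
    MaterialTableError,
    RangeError,
    cell_properties,
    complex_admittivity,
    load_cell_table,
    load_hela_tables,
    parse_number,
    write_cell_table,
)


@pytest.mark.parametrize(
    "token,expected",
    [
        ("2.25e-4", 2.25e-4),
        ("1.06E-02", 1.06e-2),
        ("1.06E - 02", 1.06e-2),           # spaced E-notation as typeset
        ("2.25 x 10^-4", 2.25e-4),
        ("2.25 × 10^−4", 2.25e-4),  # unicode times / minus signs
        ("8.5 × 10^3", 8.5e3),
        ("136", 136.0),
    ],
)
def test_parse_number_accepts_both_table_notations(token, expected):
    assert parse_number(token) == pytest.approx(expected, rel=1e-12)


def test_parse_number_rejects_garbage():
    with pytest.raises(MaterialTableError):
        parse_number("10^-4 x 2.25")


class TestPackagedTables:
    def test_spot_values_match_printed_cells(self, hela_tables):
        sigma, eps = hela_tables
        assert sigma.lookup(5e3, 0.1) == 2.25e-4
        assert sigma.lookup(1e5, 1.0) == 5.49e-2
        assert sigma.lookup(7e4, 0.7) == 1.06e-2  # the odd-notation cell
        assert eps.lookup(1e5, 1.0) == 8.5e3
        assert eps.lookup(5e3, 0.1) == 5.0e3

    def test_grid_shape_and_axes(self, hela_tables):
        sigma, eps = hela_tables
        for tab in (sigma, eps):
            assert tab.values.shape == (11, 10)
            assert tab.f_min == 5e3 and tab.f_max == 1e5
            assert tab.v_min == 0.1 and tab.v_max == 1.0

    def test_packaged_tables_have_no_monotonicity_violations(self, hela_tables):
        sigma, _ = hela_tables
        assert sigma.monotonicity_violations == ()

    def test_round_trip_is_bit_exact(self, hela_tables, tmp_path):
        for tab, kind in zip(hela_tables, ("conductivity", "permittivity")):
            path = tmp_path / f"{kind}.csv"
            write_cell_table(tab, path)
            back = load_cell_table(path, kind)
            assert np.array_equal(back.values, tab.values)
            assert np.array_equal(back.freqs, tab.freqs)
            assert np.array_equal(back.volts, tab.volts)


class TestValidation:
    def _rows(self):
        return [
            "freq_khz,0.1,0.2",
            "5,1e-4,2e-4",
            "10,2e-4,3e-4",
        ]

    def _load(self, rows, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("\n".join(rows) + "\n")
        return load_cell_table(p)

    def test_valid_minimal_table(self, tmp_path):
        tab = self._load(self._rows(), tmp_path)
        assert tab.values.shape == (2, 2)

    def test_missing_cell_is_rejected_naming_row(self, tmp_path):
        rows = self._rows()
        rows[2] = "10,2e-4"
        with pytest.raises(MaterialTableError, match="row 3"):
            self._load(rows, tmp_path)

    def test_non_numeric_cell_is_rejected(self, tmp_path):
        rows = self._rows()
        rows[1] = "5,oops,2e-4"
        with pytest.raises(MaterialTableError, match="row 2"):
            self._load(rows, tmp_path)

    def test_unsorted_frequency_axis_is_rejected(self, tmp_path):
        rows = self._rows()
        rows[1], rows[2] = rows[2], rows[1]
        with pytest.raises(MaterialTableError, match="frequency"):
            self._load(rows, tmp_path)

    def test_nonpositive_conductivity_is_rejected(self, tmp_path):
        rows = self._rows()
        rows[1] = "5,-1e-4,2e-4"
        with pytest.raises(MaterialTableError, match="out of physical range"):
            self._load(rows, tmp_path)

    def test_monotonicity_violation_is_reported_not_fixed(self, tmp_path):
        rows = ["freq_khz,0.1,0.2", "5,5e-4,2e-4", "10,6e-4,3e-4"]
        tab = self._load(rows, tmp_path)
        assert any("not non-decreasing in V" in v
                   for v in tab.monotonicity_violations)
        assert tab.lookup(5e3, 0.1) == 5e-4  # value untouched


class TestInterpolation:
    def test_exact_at_every_grid_node(self, hela_tables):
        sigma, _ = hela_tables
        for i, f in enumerate(sigma.freqs):
            for j, v in enumerate(sigma.volts):
                assert sigma.lookup(float(f), float(v)) == sigma.values[i, j]

    def test_hand_computed_bilinear_midpoint(self, hela_tables):
        sigma, _ = hela_tables
        # midway between the 0.1 V and 0.2 V columns at 5 kHz
        expected = (2.25e-4 + 2.60e-4) / 2
        assert sigma.lookup(5e3, 0.15) == pytest.approx(expected, rel=1e-12)

    def test_strict_policy_refuses_below_tabulated_range(self, hela_tables):
        sigma, _ = hela_tables
        with pytest.raises(RangeError):
            sigma.lookup(1e3, 0.1)
        with pytest.raises(RangeError):
            sigma.lookup(5e3, 0.05)

    def test_clamp_policy_uses_edge_value(self, hela_tables):
        sigma, _ = hela_tables
        assert sigma.lookup(1e3, 0.1, policy="clamp") == 2.25e-4
        assert sigma.lookup(2e5, 1.2, policy="clamp") == 5.49e-2

    def test_extrapolation_is_log_linear_in_frequency(self, hela_tables):
        sigma, eps = hela_tables
        # conductivity: power law through the two lowest rows
        s5, s10 = 2.25e-4, 4.25e-4
        slope = (math.log(s10) - math.log(s5)) / math.log(2)
        expected = math.exp(math.log(s5) + slope * math.log(1e3 / 5e3) / math.log(2) * math.log(2))
        got = sigma.lookup(1e3, 0.1, policy="extrapolate")
        assert got == pytest.approx(expected, rel=1e-9)
        assert got < s5  # extrapolating downward in f lowers sigma
        # permittivity is flat at 0.1 V, so extrapolation stays flat
        assert eps.lookup(1e3, 0.1, policy="extrapolate") == pytest.approx(5e3)

    def test_cell_properties_combines_both_tables(self, hela_tables):
        sigma, eps = hela_tables
        props = cell_properties(sigma, eps, 1e5, 1.0)
        assert props.sigma == 5.49e-2
        assert props.eps_r == 8.5e3


class TestAdmittivity:
    def test_dc_limit_is_pure_conduction(self):
        assert complex_admittivity(MediumProperties(2e-6, 136.0), 0.0) == 2e-6 + 0j

    def test_pbs_at_100khz(self):
        k = complex_admittivity(PBS, 1e5)
        assert k.real == 2e-6
        assert k.imag == pytest.approx(2 * math.pi * 1e5 * EPS0 * 136, rel=1e-12)
        assert k.imag == pytest.approx(7.565e-4, rel=1e-3)

    def test_unit_imaginary_construction(self):
        f = 1.0 / (2 * math.pi * EPS0)
        k = complex_admittivity(MediumProperties(0.0, 1.0), f)
        assert k == pytest.approx(1j, rel=1e-12)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            complex_admittivity(PBS, -1.0)

    @given(
        sigma=st.floats(0, 1e-3, allow_nan=False),
        eps_r=st.floats(1e2, 1e5),
        f1=st.floats(1e3, 1e7),
        f2=st.floats(1e3, 1e7),
    )
    def test_magnitude_strictly_increasing_in_frequency(self, sigma, eps_r, f1, f2):
        lo, hi = sorted((f1, f2))
        if hi / lo < 1.01:
            return
        props = MediumProperties(sigma, eps_r)
        assert abs(complex_admittivity(props, hi)) > abs(
            complex_admittivity(props, lo)
        )


def test_medium_properties_invariants():
    with pytest.raises(ValueError):
        MediumProperties(-1e-6, 136.0)
    with pytest.raises(ValueError):
        MediumProperties(1e-6, 0.5)
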