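import itertools

import numpy as np
import pandas as pd
import pytest

from threatscape import threats
from threatscape.grid import GridLayer, GridSpec


@pytest.fixture
def spec():
    return GridSpec(n_rows=3, n_cols=4, cell_size=1.0, origin_lon=0.0, origin_lat=3.0)


def layer(values, spec):
    return GridLayer(spec, np.asarray(values, dtype=float))


class TestOverexploitation:
    def test_full_footprint_range_maps_to_unit_interval(self, spec):
        vals = np.linspace(0, 100, 12).reshape(3, 4)
        out = threats.overexploitation_intensity(layer(vals, spec))
        assert out.layer.values.min() == 0.0
        assert out.layer.values.max() == 1.0
        assert out.species_specific

    def test_constant_footprint_degenerates_to_zero(self, spec):
        out = threats.overexploitation_intensity(layer(np.full((3, 4), 42.0), spec))
        np.testing.assert_array_equal(out.layer.values, 0.0)

    def test_max_footprint_cell_gets_intensity_one(self, spec):
        vals = np.zeros((3, 4)); vals[1, 2] = 80.0
        out = threats.overexploitation_intensity(layer(vals, spec))
        assert out.layer.values[1, 2] == 1.0


class TestTlu:
    def test_conversion_factors(self, spec):
        def cell(c, g, s):
            z = np.zeros((3, 4))
            out = threats.tlu(
                layer(z + c, spec), layer(z + g, spec), layer(z + s, spec)
            )
            return out.values[0, 0]

        assert cell(1, 0, 0) == pytest.approx(0.7)
        assert cell(0, 0, 0) == 0.0
        assert cell(10, 5, 5) == pytest.approx(8.0)

    def test_negative_density_rejected(self, spec):
        z = layer(np.zeros((3, 4)), spec)
        with pytest.raises(ValueError, match="cattle"):
            threats.tlu(layer(np.full((3, 4), -1.0), spec), z, z)


class TestOvergrazingIntensity:
    def test_zero_layer_stays_zero(self, spec):
        out = threats.overgrazing_intensity(layer(np.zeros((3, 4)), spec))
        np.testing.assert_array_equal(out.layer.values, 0.0)

    def test_sqrt_then_minmax(self, spec):
        vals = np.zeros((3, 4)); vals[0, :3] = [0.0, 25.0, 100.0]
        out = threats.overgrazing_intensity(layer(vals, spec))
        np.testing.assert_allclose(out.layer.values[0, :3], [0.0, 0.5, 1.0])

    def test_max_tlu_cell_is_one(self, spec):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 50, (3, 4))
        out = threats.overgrazing_intensity(layer(vals, spec))
        assert out.layer.values[np.unravel_index(vals.argmax(), vals.shape)] == 1.0


def events(rows):
    return pd.DataFrame(rows, columns=["lon", "lat", "date", "confidence"])


class TestFireFrequency:
    years = (2007, 2012)

    def test_no_events_all_zero(self, spec):
        out = threats.fire_frequency(events([]), spec, self.years)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_late_fire_counts_double(self, spec):
        early = events([(0.5, 2.5, "2008-11-15", 80.0)])
        late = events([(0.5, 2.5, "2008-02-15", 80.0)])
        f_early = threats.fire_frequency(early, spec, self.years).values[0, 0]
        f_late = threats.fire_frequency(late, spec, self.years).values[0, 0]
        assert f_late == pytest.approx(2.0 * f_early)

    def test_confidence_boundary_strictly_above_30(self, spec):
        at_30 = events([(0.5, 2.5, "2008-11-15", 30.0)])
        just_above = events([(0.5, 2.5, "2008-11-15", 30.01)])
        assert threats.fire_frequency(at_30, spec, self.years).values.sum() == 0.0
        assert threats.fire_frequency(just_above, spec, self.years).values.sum() > 0.0

    def test_single_early_event_frequency_formula(self, spec):
        ev = events([(0.5, 2.5, "2010-12-01", 90.0)])
        out = threats.fire_frequency(ev, spec, self.years)  # nominal area mode
        expected = 1.0 / (6 * (4.5 * (1.0 / (2.5 / 60))) ** 2)
        assert out.values[0, 0] == pytest.approx(expected)

    def test_additive_over_disjoint_event_sets(self, spec, rng):
        rows = [
            (rng.uniform(0, 4), rng.uniform(0.01, 3), f"20{rng.integers(7, 13):02d}-0{rng.integers(1, 4)}-10",
             rng.uniform(31, 100))
            for _ in range(30)
        ]
        all_ev = events(rows)
        a = threats.fire_frequency(events(rows[:13]), spec, self.years)
        b = threats.fire_frequency(events(rows[13:]), spec, self.years)
        both = threats.fire_frequency(all_ev, spec, self.years)
        np.testing.assert_allclose(a.values + b.values, both.values)

    def test_events_outside_year_window_dropped(self, spec):
        ev = events([(0.5, 2.5, "2001-11-15", 90.0)])
        out = threats.fire_frequency(ev, spec, self.years)
        assert out.values.sum() == 0.0

    def test_fire_intensity_chain(self, spec):
        vals = np.zeros((3, 4)); vals[0, :3] = [0.0, 1.0, 4.0]
        out = threats.fire_intensity(layer(vals, spec))
        np.testing.assert_allclose(out.layer.values[0, :3], [0.0, 0.5, 1.0])


class TestCotton:
    def test_equal_split_and_conservation(self, spec):
        pid = layer(np.array([[0] * 4, [0] * 4, [1] * 4], dtype=float), spec)
        cotton = layer(np.array([[1, 1, 0, 0], [1, 0, 0, 0], [0, 1, 1, 0]], dtype=float), spec)
        stats = pd.DataFrame({"province": [0, 1], "production": [90.0, 40.0]})
        alloc = threats.cotton_allocation(stats, cotton, pid)
        assert alloc.values[0, 0] == pytest.approx(30.0)  # 90 over 3 cells
        assert alloc.values[2, 1] == pytest.approx(20.0)  # 40 over 2 cells
        assert alloc.values.sum() == pytest.approx(130.0)

    def test_intensity_is_capped_and_normalized(self, spec):
        pid = layer(np.zeros((3, 4)), spec)
        cotton = layer(np.array([[1, 1, 0, 0]] + [[0] * 4] * 2, dtype=float), spec)
        stats = pd.DataFrame({"province": [0], "production": [50.0]})
        out = threats.cotton_intensity(stats, cotton, pid)
        assert out.capped and not out.species_specific
        assert out.layer.values.max() == 1.0

    def test_zero_production_province_zero_intensity(self, spec):
        pid = layer(np.zeros((3, 4)), spec)
        cotton = layer(np.ones((3, 4)), spec)
        stats = pd.DataFrame({"province": [0], "production": [0.0]})
        alloc = threats.cotton_allocation(stats, cotton, pid)
        assert alloc.values.sum() == 0.0

    def test_missing_province_record_errors(self, spec):
        pid = layer(np.full((3, 4), 5.0), spec)
        cotton = layer(np.ones((3, 4)), spec)
        stats = pd.DataFrame({"province": [0], "production": [10.0]})
        with pytest.raises(ValueError, match="province 5"):
            threats.cotton_allocation(stats, cotton, pid)


class TestMiningClass:
    def test_no_points_all_no_threat(self, spec):
        pts = pd.DataFrame(columns=["lon", "lat", "status"])
        out = threats.mining_class(pts, spec)
        assert (out.classes == 0).all()

    def test_multiple_sites_one_cell_capped_at_very_high(self, spec):
        pts = pd.DataFrame({
            "lon": [0.5, 0.5, 0.5], "lat": [2.5, 2.5, 2.5],
            "status": ["active"] * 3,
        })
        out = threats.mining_class(pts, spec)
        assert out.classes[0, 0] == 4
        assert (out.classes > 0).sum() == 1

    def test_inactive_sites_ignored(self, spec):
        pts = pd.DataFrame({"lon": [0.5], "lat": [2.5], "status": ["inactive"]})
        out = threats.mining_class(pts, spec)
        assert (out.classes == 0).all()


def climate_oracle(p45, p85, n45, n85):
    """Literal transcription of the ordered climate decision rules."""
    if not p45:
        return 4
    if p45 and p85 and n45 and n85:
        return 3
    if p45 and n45:
        return 2
    if p45 and not p85:
        return 1
    return 0


class TestClimateClass:
    def test_truth_table_total_and_single_valued(self):
        for combo in itertools.product([False, True], repeat=4):
            got = threats.climate_class_codes(*[np.array([v]) for v in combo])[0]
            assert got == climate_oracle(*combo)
            assert 0 <= got <= 4

    @pytest.mark.parametrize(
        "combo,expected",
        [
            ((True, True, False, False), 0),   # both retain habitat: no threat
            ((False, True, False, False), 4),  # moderate scenario already loses it
            ((True, True, True, True), 3),     # both retain it, but in novel climate
        ],
    )
    def test_published_anchor_cases(self, combo, expected):
        got = threats.climate_class_codes(*[np.array([v]) for v in combo])[0]
        assert got == expected

    def test_layer_wrapper_masks_and_classes(self, spec):
        t = layer(np.ones((3, 4)), spec)
        f = layer(np.zeros((3, 4)), spec)
        out = threats.climate_class(t, t, f, f)
        assert (out.classes == 0).all()
        out2 = threats.climate_class(f, t, f, f)
        assert (out2.classes == 4).all()
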