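"""Population dynamics, placement, rendering, and plate generation."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.ndimage as ndi
from hypothesis import given
from hypothesis import strategies as st

from ifscreen.synthetic import (
    DrugLayout,
    HillParams,
    MediaScenario,
    OpticsParams,
    PackingError,
    PlateConfig,
    PopulationParams,
    R10,
    TCM,
    TCM_MINUS_E_I,
    cancer_population,
    dilution_series,
    expected_count,
    feeder_population,
    generate_plate,
    hill_effect,
    place_cells,
    render_field,
    scenario,
    simulate_well_counts,
    well_name,
)


class TestDynamics:
    def test_two_doublings_without_drug(self):
        pop = cancer_population(n0=250.0, doubling_time_h=48.0)
        assert expected_count(pop, 0.0, 96.0) == pytest.approx(1000.0)

    def test_exponent_halved_at_ic50(self):
        pop = cancer_population(n0=250.0, doubling_time_h=48.0, ic50=50.0,
                                hill=1.0, emax=1.0)
        # E(IC50) = emax/2, so the growth exponent is half of its dose-0 value
        assert hill_effect(50.0, 50.0, 1.0, 1.0) == pytest.approx(0.5)
        assert expected_count(pop, 50.0, 96.0) == pytest.approx(250.0 * 2.0)

    def test_insensitive_population_ignores_dose(self):
        fib = PopulationParams(name="fibroblast", n0=200.0, doubling_time_h=60.0,
                               drug_sensitive=False)
        for dose in (0.0, 10.0, 1e5):
            assert expected_count(fib, dose, 96.0) == expected_count(fib, 0.0, 96.0)

    def test_feeder_count_invariant_in_dose_and_time(self):
        feeder = feeder_population(n0=500.0)
        for dose in (0.0, 1e4):
            for t in (0.0, 96.0, 500.0):
                assert expected_count(feeder, dose, t) == 500.0

    def test_negative_dose_and_time_rejected(self):
        pop = cancer_population()
        with pytest.raises(ValueError, match="dose"):
            expected_count(pop, -1.0, 96.0)
        with pytest.raises(ValueError, match="time"):
            expected_count(pop, 0.0, -5.0)

    @given(
        d1=st.floats(0.0, 1e5), d2=st.floats(0.0, 1e5),
        t=st.floats(0.0, 200.0),
    )
    def test_expected_count_monotone_nonincreasing_in_dose(self, d1, d2, t):
        pop = cancer_population(ic50=90.0)
        lo, hi = sorted((d1, d2))
        assert expected_count(pop, hi, t) <= expected_count(pop, lo, t) + 1e-9

    def test_media_shift_moves_effect_curve_right(self):
        pop = cancer_population(ic50=90.0)
        n_r10 = expected_count(pop, 90.0, 96.0, R10)
        n_tcm = expected_count(pop, 90.0, 96.0, MediaScenario("m", 1.0, 3.0))
        assert n_tcm > n_r10  # same dose inhibits less under the shifted media

    def test_tcm_minus_growth_factors_has_no_shift(self):
        assert TCM.ic50_shift > 1.0
        assert TCM_MINUS_E_I.ic50_shift == 1.0

    def test_death_term_drops_below_day0(self):
        pop = cancer_population(n0=250.0)
        pop.death_rate_per_h = 0.02
        assert expected_count(pop, 1e6, 96.0) < 250.0

    def test_sampling_reproducible_and_near_expectation(self):
        pops = [cancer_population(n0=250.0), feeder_population(500.0)]
        a = simulate_well_counts(pops, 0.0, 96.0, R10, rng=42)
        b = simulate_well_counts(pops, 0.0, 96.0, R10, rng=42)
        assert a == b
        assert a["cancer"].expected == pytest.approx(1000.0)
        assert abs(a["cancer"].sampled - 1000) < 5 * math.sqrt(1000)


class TestPlacement:
    def pops(self):
        return {"cancer": cancer_population(), "feeder": feeder_population()}

    def test_requested_counts_all_marker_positive(self):
        pl = place_cells({"cancer": 10, "feeder": 0}, self.pops(), (256, 256), 1)
        assert len(pl) == 10
        assert all(p.marker_positive for p in pl)

    def test_zero_counts_empty(self):
        assert place_cells({"cancer": 0}, self.pops(), (256, 256), 1) == []

    def test_coculture_densities_placed_with_separation(self):
        # feeder monolayer (~500) plus plated cancer cells (~250) in one field
        pl = place_cells({"cancer": 250, "feeder": 500}, self.pops(), (768, 768), 2)
        assert len(pl) == 750
        xy = np.array([[p.x, p.y] for p in pl])
        assert xy.min() >= 0 and xy.max() < 768
        # hard-core: no two centres closer than the configured fraction
        from scipy.spatial import cKDTree

        dmin = cKDTree(xy).query(xy, k=2)[0][:, 1]
        assert dmin.min() > 3.0

    def test_density_above_packing_limit_rejected(self):
        with pytest.raises(PackingError, match="packing limit"):
            place_cells({"cancer": 3000}, self.pops(), (256, 256), 1)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            place_cells({"cancer": -1}, self.pops(), (256, 256), 1)

    def test_effect_scales_nucleus_size(self):
        small = place_cells({"cancer": 50}, self.pops(), (512, 512), 3)
        big = place_cells(
            {"cancer": 50}, self.pops(), (512, 512), 3, effects={"cancer": 1.0}
        )
        mean_r = lambda pl: np.mean([p.nucleus_radius for p in pl])
        assert mean_r(big) > 1.2 * mean_r(small)


class TestRendering:
    def test_marker_negative_cell_leaves_marker_channel_at_background(self):
        optics = OpticsParams(image_size=(128, 128))
        pl = place_cells({"feeder": 1}, {"feeder": feeder_population()},
                         (128, 128), 1)
        field = render_field(pl, optics, 1, noiseless=True)
        assert np.all(field.channel_marker == optics.background_level)
        assert field.channel_nuclear.max() > optics.background_level

    def test_zero_cells_gives_background_frames(self):
        optics = OpticsParams(image_size=(64, 64))
        field = render_field([], optics, 0, noiseless=True)
        assert np.all(field.channel_nuclear == optics.background_level)
        assert np.all(field.channel_marker == optics.background_level)

    def test_noisy_empty_frame_mean_near_background(self):
        optics = OpticsParams(image_size=(128, 128))
        field = render_field([], optics, 0)
        assert field.channel_nuclear.mean() == pytest.approx(
            optics.background_level, abs=3 * optics.noise_sd
        )

    def test_connected_components_count_rendered_nuclei(self):
        """Oracle: connected components on the noiseless render equal the
        number of placed cells."""
        pops = {"cancer": cancer_population()}
        pl = place_cells({"cancer": 100}, pops, (512, 512), 5,
                         min_sep_factor=1.5)
        optics = OpticsParams(image_size=(512, 512))
        field = render_field(pl, optics, 5, noiseless=True)
        mask = field.channel_nuclear.astype(float) > optics.background_level + 300
        _, n = ndi.label(mask)
        assert n == 100

    def test_out_of_bounds_placement_rejected(self):
        from ifscreen.synthetic import CellPlacement

        bad = CellPlacement(x=500.0, y=10.0, population="cancer",
                            marker_positive=True, sigma_major=2.5,
                            sigma_minor=2.5, angle=0.0, cytoplasm_radius=8.0)
        with pytest.raises(ValueError, match="outside bounds"):
            render_field([bad], OpticsParams(image_size=(64, 64)), 0)

    def test_channels_clipped_to_bit_depth(self):
        optics = OpticsParams(image_size=(64, 64), bit_depth=8,
                              nuclear_intensity=10000.0)
        pl = place_cells({"cancer": 1}, {"cancer": cancer_population()}, (64, 64), 1)
        field = render_field(pl, optics, 1)
        assert field.channel_nuclear.dtype == np.uint8
        assert field.channel_nuclear.max() == 255


class TestPlateGeneration:
    def test_twelve_dose_quadruplicate_layout(self):
        cfg = scenario("alk_wt")
        layout = cfg.layout()
        treated = layout[(layout.plate_role == "drug") & (layout.dose_nM > 0)]
        assert len(treated) == 2 * 12 * 4  # two drugs on this plate
        assert (treated.groupby("drug").size() == 48).all()

    def test_nine_dose_layout(self):
        cfg = PlateConfig(
            populations=[cancer_population()],
            drugs=[DrugLayout("drugA", doses=dilution_series(10000.0, n=9))],
        )
        layout = cfg.layout()
        treated = layout[(layout.plate_role == "drug") & (layout.dose_nM > 0)]
        assert len(treated) == 36

    def test_empty_dose_list_rejected(self):
        with pytest.raises(ValueError, match="dose"):
            DrugLayout("drugA", doses=())

    def test_well_names_follow_384_well_convention(self):
        assert well_name(0) == "A1"
        assert well_name(383) == "P24"
        with pytest.raises(ValueError):
            well_name(384)

    def test_same_seed_reproduces_ground_truth(self, tmp_path):
        cfg = scenario("tiny", seed=9)
        r1 = generate_plate(cfg, tmp_path / "a")
        r2 = generate_plate(scenario("tiny", seed=9), tmp_path / "b")
        pd.testing.assert_frame_equal(r1.ground_truth_wells, r2.ground_truth_wells)
        pd.testing.assert_frame_equal(r1.ground_truth_cells, r2.ground_truth_cells)
        img = "images/A1_0_nuclear.tif"
        assert (tmp_path / "a" / img).read_bytes() == (tmp_path / "b" / img).read_bytes()

    def test_ground_truth_counts_match_cell_records(self, tiny_plate):
        _, result = tiny_plate
        cells = result.ground_truth_cells.groupby(["well", "population"]).size()
        wells = result.ground_truth_wells.set_index(["well", "population"])["sampled"]
        for (well, pop), n in cells.items():
            assert wells.loc[(well, pop)] == n

    def test_drug_sensitivity_override_applied(self):
        drug = DrugLayout("x", sensitivity={"cancer": HillParams(ic50=7.0)})
        pops = drug.populations_for([cancer_population(ic50=100.0),
                                     feeder_population()])
        by_name = {p.name: p for p in pops}
        assert by_name["cancer"].ic50_true == 7.0
        assert not by_name["feeder"].drug_sensitive


class TestParameterValidation:
    def test_population_invariants(self):
        with pytest.raises(ValueError):
            PopulationParams(name="x", n0=-1.0)
        with pytest.raises(ValueError):
            PopulationParams(name="x", n0=1.0, emax_true=1.5)
        with pytest.raises(ValueError):
            PopulationParams(name="x", n0=1.0, ic50_true=0.0)
        with pytest.raises(ValueError):
            PopulationParams(name="x", n0=1.0, doubling_time_h=0.0)

    def test_media_invariants(self):
        with pytest.raises(ValueError):
            MediaScenario("m", ic50_shift=0.0)
        with pytest.raises(ValueError):
            MediaScenario("m", growth_multiplier=-2.0)

    def test_optics_invariants(self):
        with pytest.raises(ValueError):
            OpticsParams(bit_depth=12)
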