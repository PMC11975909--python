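"""Generator tests: layouts, phenotype draws, rendering, cytokines, coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy.stats import binom

from phenoscreen import synthetic as syn
from conftest import make_layout_row


class TestLayout:
    def test_full_acquisition_design_enumerates_over_410k_images(self):
        donors = [f"D{i:02d}" for i in range(24)]
        layout = syn.make_layout(24, 384, 9, ["DMSO", "TLR8"], [6, 24, 48],
                                 donors)
        n = syn.count_images(layout, n_channels=5)
        assert n == 24 * 384 * 9 * 5 == 414_720
        assert n >= 410_000

    def test_single_well_identity_case(self):
        layout = syn.make_layout(1, 1, 1, ["DMSO"], [6], ["d1"])
        assert len(layout) == 1
        assert layout.iloc[0]["condition"] == "DMSO"

    def test_row_count_matches_cartesian_enumeration(self):
        layout = syn.make_layout(2, 4, 3, ["DMSO", "A"], [6, 24], ["d1"])
        # brute-force enumeration oracle
        expected = len([(p, w, f) for p in range(2) for w in range(4)
                        for f in range(3)])
        assert len(layout) == expected == 24
        key = layout[["plate_id", "well_id", "field_index"]]
        assert not key.duplicated().any()

    def test_every_plate_donor_stratum_has_dmso(self):
        layout = syn.make_layout(3, 8, 1, ["DMSO", "A", "B"], [6, 24],
                                 ["d1", "d2"])
        for _, grp in layout.groupby(["plate_id", "donor_id"]):
            assert (grp["condition"] == "DMSO").any()

    def test_missing_dmso_is_a_configuration_error(self):
        with pytest.raises(syn.ConfigurationError):
            syn.make_layout(1, 4, 1, ["A", "B"], [6], ["d1"])


class TestSimulateWell:
    def test_zero_effect_fractions_within_binomial_ci(self):
        base = syn.PhenotypeBaseline()
        truth = syn.simulate_well(make_layout_row(), syn.EffectSpec(donor_sd=0.0),
                                  1000, seed=3)
        fr = truth.realized_fractions()
        checks = {
            "large_round": (base.large_frac, 1000),
            "annexin_pos": (base.annexin, 1000),
            "fragmented_nucleus": (base.fragmented, 1000),
        }
        for key, (p, n) in checks.items():
            lo, hi = binom.ppf([0.005, 0.995], n, p) / n
            assert lo <= fr[key] <= hi, key

    def test_empty_well_flags_fractions_undefined(self):
        truth = syn.simulate_well(make_layout_row(), syn.EffectSpec(), 0, seed=0)
        assert truth.n_cells == 0
        assert all(np.isnan(v) for v in truth.realized_fractions().values())

    def test_doubled_annexin_effect_recovers_at_large_n(self):
        spec = syn.EffectSpec(
            baseline=syn.PhenotypeBaseline(annexin=0.1),
            effects={("TLR8", 24.0): syn.ConditionEffect(annexin_fold=2.0)},
            donor_sd=0.0)
        truth = syn.simulate_well(make_layout_row(condition="TLR8"), spec,
                                  10_000, seed=7)
        frac = truth.realized_fractions()["annexin_pos"]
        sd = np.sqrt(0.2 * 0.8 / 10_000)
        assert abs(frac - 0.2) < 3 * sd

    def test_determinism_identical_seed_identical_cells(self):
        row = make_layout_row()
        a = syn.simulate_well(row, syn.EffectSpec(), 200, seed=9)
        b = syn.simulate_well(row, syn.EffectSpec(), 200, seed=9)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_probability_overflow_clamps_with_warning(self):
        spec = syn.EffectSpec(
            effects={("X", 6.0): syn.ConditionEffect(annexin_fold=100.0)},
            donor_sd=0.0)
        with pytest.warns(UserWarning, match="clamped"):
            truth = syn.simulate_well(make_layout_row(condition="X", timepoint=6.0),
                                      spec, 50, seed=1)
        assert truth.n_clamped >= 1
        assert truth.realized_fractions()["annexin_pos"] <= 1.0

    def test_actin_states_mutually_exclusive_and_small_only(self):
        truth = syn.simulate_well(make_layout_row(), syn.EffectSpec(), 500, seed=2)
        c = truth.cells
        assert not (c["actin_contracted"] & c["actin_dispersed"]).any()
        large = c["size_class"] == "large_round"
        assert not (c.loc[large, ["actin_contracted", "actin_dispersed"]]
                    .any().any())
        small = ~large
        assert not c.loc[small, ["podosome_pos", "phagocytosis"]].any().any()


def _noiseless() -> syn.RenderParams:
    return syn.RenderParams(noise_sd=(0,) * 5, background_level=(0,) * 5)


class TestRenderField:
    def test_noiseless_nuclear_components_equal_cell_count(self):
        spec = syn.EffectSpec(baseline=syn.PhenotypeBaseline(fragmented=0.0),
                              donor_sd=0.0)
        truth = syn.simulate_well(make_layout_row(), spec, 12, seed=21)
        field = syn.render_field(truth, 0, _noiseless(), seed=22)
        nuc = field.channel("nucleus")
        _, n = ndi.label(nuc > 50.0)
        assert n == 12

    def test_fragmented_nuclei_lobed_but_grouped_per_cell(self):
        from skimage.measure import regionprops

        spec = syn.EffectSpec(baseline=syn.PhenotypeBaseline(fragmented=1.0),
                              donor_sd=0.0)
        truth = syn.simulate_well(make_layout_row(), spec, 6, seed=30)
        field = syn.render_field(truth, 0, _noiseless(), seed=31)
        nuc = field.channel("nucleus")
        labels, n = ndi.label(nuc > 50.0)
        # lobes stay within one cell radius, so they group into one
        # component (or cluster) per cell
        assert n == 6
        # every nuclear pixel lies within its cell's radius
        for p in regionprops(labels):
            for com in [p.centroid]:
                d = np.hypot(truth.cells["centroid_row"] - com[0],
                             truth.cells["centroid_col"] - com[1])
                nearest = d.idxmin()
                assert d[nearest] <= truth.cells.loc[nearest, "radius_px"]
        # fragmentation shows up as a markedly less convex nuclear mask
        intact = syn.simulate_well(
            make_layout_row(), syn.EffectSpec(
                baseline=syn.PhenotypeBaseline(fragmented=0.0), donor_sd=0.0),
            6, seed=30)
        f2 = syn.render_field(intact, 0, _noiseless(), seed=31)
        lab2, _ = ndi.label(f2.channel("nucleus") > 50.0)
        sol_frag = np.mean([p.solidity for p in regionprops(labels)])
        sol_intact = np.mean([p.solidity for p in regionprops(lab2)])
        assert sol_frag < sol_intact - 0.03

    def test_empty_field_is_background_plus_noise(self):
        truth = syn.simulate_well(make_layout_row(), syn.EffectSpec(), 0, seed=1)
        params = syn.RenderParams(noise_sd=(0,) * 5)
        field = syn.render_field(truth, 0, params, seed=2)
        assert np.allclose(field.data, 40.0)

    def test_rendered_diameters_match_pixel_geometry(self):
        params = syn.RenderParams(
            small_cell_diam_um=(10.0, 10.0), large_cell_diam_um=(20.0, 20.0),
            noise_sd=(0,) * 5, background_level=(0,) * 5)
        spec = syn.EffectSpec(donor_sd=0.0)
        # force one small and one large cell
        truth = syn.simulate_well(make_layout_row(), spec, 30, seed=4)
        truth.cells = truth.cells.iloc[:2].copy()
        truth.cells["size_class"] = ["small_round", "large_round"]
        truth.cells["fragmented_nucleus"] = False
        field = syn.render_field(truth, 0, params, seed=5)
        # at 0.5 um/px: cell footprints 20 px and 40 px across
        assert truth.cells["radius_px"].tolist() == [10.0, 20.0]
        mem = field.channel("membrane")
        labels, n = ndi.label(mem > 0.5 * mem.max())   # half-maximum footprint
        assert n == 2
        areas = np.sort(np.bincount(labels.ravel())[1:])
        diams = 2 * np.sqrt(areas / np.pi)
        assert abs(diams[0] - 20.0) < 2.5
        assert abs(diams[1] - 40.0) < 2.5

    def test_annexin_channel_only_marks_positive_cells(self):
        base = syn.PhenotypeBaseline(annexin=0.5)
        truth = syn.simulate_well(make_layout_row(),
                                  syn.EffectSpec(baseline=base, donor_sd=0.0),
                                  30, seed=6)
        field = syn.render_field(truth, 0, _noiseless(), seed=7)
        anx = field.channel("annexin")
        for _, cell in truth.cells.iterrows():
            r0 = int(cell["centroid_row"])
            c0 = int(cell["centroid_col"])
            r = int(cell["radius_px"]) + 3
            patch = anx[max(r0 - r, 0):r0 + r, max(c0 - r, 0):c0 + r]
            if cell["annexin_pos"]:
                assert patch.max() > 100
            else:
                assert patch.max() < 1.0

    def test_determinism_byte_identical_images(self):
        truth1 = syn.simulate_well(make_layout_row(), syn.EffectSpec(), 25, seed=8)
        truth2 = syn.simulate_well(make_layout_row(), syn.EffectSpec(), 25, seed=8)
        f1 = syn.render_field(truth1, 0, syn.RenderParams(), seed=9)
        f2 = syn.render_field(truth2, 0, syn.RenderParams(), seed=9)
        assert f1.data.tobytes() == f2.data.tobytes()

    def test_overcrowded_field_raises_placement_error(self):
        truth = syn.simulate_well(make_layout_row(), syn.EffectSpec(), 500,
                                  seed=10)
        with pytest.raises(syn.PlacementError):
            syn.render_field(truth, 0, syn.RenderParams(field_px=256), seed=11)

    def test_tiff_round_trip(self, tmp_path):
        truth = syn.simulate_well(make_layout_row(), syn.EffectSpec(), 5, seed=12)
        field = syn.render_field(truth, 0, syn.RenderParams(field_px=128), seed=13)
        path = tmp_path / "field.tiff"
        field.save(path)
        loaded = syn.FieldImage.load(path)
        assert loaded.channel_roles == field.channel_roles
        np.testing.assert_array_equal(loaded.data, field.data)


class TestCytokines:
    def _layout(self, n_donors=4):
        donors = [f"d{i}" for i in range(n_donors)]
        return syn.make_layout(n_donors, 8, 1, ["DMSO", "TLR4"], [6.0], donors)

    def test_unknown_analyte_in_fold_effects_rejected(self):
        with pytest.raises(syn.ConfigurationError, match="not in panel"):
            syn.simulate_cytokines(self._layout(),
                                   {("TLR4", 6.0, "NOPE"): 2.0}, seed=0)

    def test_noiseless_fold_recovered_exactly(self):
        table, _ = syn.simulate_cytokines(
            self._layout(), {("TLR4", 6.0, "IL-6"): 4.0},
            donor_sd=0.0, noise_sd=0.0, seed=1)
        med = table.groupby(["condition", "analyte"])["concentration"].median()
        assert med["TLR4", "IL-6"] / med["DMSO", "IL-6"] == pytest.approx(4.0)
        assert med["TLR4", "CCL2"] / med["DMSO", "CCL2"] == pytest.approx(1.0)

    def test_panel_has_51_analytes_and_all_rows_present(self):
        assert len(syn.DEFAULT_PANEL) == 51
        table, _ = syn.simulate_cytokines(self._layout(2), {}, seed=2)
        wells = self._layout(2)[["plate_id", "well_id"]].drop_duplicates()
        assert len(table) == len(wells) * 51


class TestCoupledDeltas:
    @pytest.mark.parametrize("slope", [0.03142, -0.08836])
    def test_ols_recovers_generating_slope_within_10pct(self, slope):
        d = syn.simulate_coupled_deltas(slope, 200, noise_sd=0.01, seed=0)
        fit = np.polyfit(d["delta_x"], d["delta_y"], 1)[0]
        assert abs(fit - slope) / abs(slope) < 0.10

    def test_effectspec_coupling_drives_generation(self):
        spec = syn.EffectSpec(coupling={("frac_small", "frac_fragmented"): 0.5})
        tables = syn.simulate_coupled_wells(spec, 100, noise_sd=0.0, seed=3)
        d = tables[("frac_small", "frac_fragmented")]
        np.testing.assert_allclose(d["frac_fragmented"],
                                   0.5 * d["frac_small"], atol=1e-12)
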