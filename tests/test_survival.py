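import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bnctsim as b
from bnctsim.survival import SurvivalField


class TestSurvivalProbability:
    def test_zero_dose_returns_mep(self):
        assert b.survival_probability(0.37, 0.0) == pytest.approx(0.37)

    def test_closed_form_at_one_gray(self):
        # alpha*1 + beta*1 = 0.301 with the default radiosensitivity
        assert b.survival_probability(1.0, 1.0) == pytest.approx(
            math.exp(-0.301), rel=1e-12)

    def test_zero_probability_stays_zero(self):
        assert b.survival_probability(0.0, 50.0) == 0.0

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            b.survival_probability(1.0, -1.0)

    def test_oer_divides_dose(self):
        hypoxic = b.LQParams(oer=2.0)
        assert b.survival_probability(1.0, 10.0, hypoxic) == pytest.approx(
            b.survival_probability(1.0, 5.0), rel=1e-12)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 120.0))
    @settings(max_examples=80, deadline=None)
    def test_never_exceeds_mep(self, mep, dose):
        sp = b.survival_probability(mep, dose)
        assert 0.0 <= sp <= mep + 1e-15


class TestSurvivingCells:
    def test_uniform_field_scales_with_mask_size(self):
        sp = np.full((10, 10), 0.25)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:4, :] = True
        assert b.surviving_cells(sp, mask) == pytest.approx(0.25 * 40)

    def test_matches_bruteforce_cell_sum(self, rng):
        sp = rng.random((10, 10))
        mask = rng.random((10, 10)) > 0.5
        expected = 0.0
        for i in range(10):
            for j in range(10):
                if mask[i, j]:
                    expected += sp[i, j]
        assert b.surviving_cells(sp, mask) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            b.surviving_cells(np.zeros((4, 4)), np.ones((5, 5), dtype=bool))


class TestRegionSurvivalFractions:
    def test_untreated_field_survives_fully(self, tiny_phantom):
        fld = b.mep_field(tiny_phantom, b.MEPParams(cutoff=0.3))
        masks = b.region_masks(tiny_phantom, 0.2, penumbra_width=0.1)
        sfield = SurvivalField(sp=fld.values.copy(), phantom=tiny_phantom,
                               lq=b.LQParams())
        report = b.region_survival_fractions(sfield, masks, fld)
        assert report.sf_total == pytest.approx(100.0, rel=1e-12)

    def test_sterilised_field_survives_nowhere(self, tiny_phantom):
        fld = b.mep_field(tiny_phantom, b.MEPParams(cutoff=0.3))
        masks = b.region_masks(tiny_phantom, 0.2, penumbra_width=0.1)
        sfield = SurvivalField(sp=np.zeros_like(fld.values),
                               phantom=tiny_phantom, lq=b.LQParams())
        report = b.region_survival_fractions(sfield, masks, fld)
        assert report.sf_within_beam == 0.0
        assert report.sf_total == 0.0

    def test_matches_bruteforce_on_toy_regions(self, tiny_phantom, rng):
        fld = b.mep_field(tiny_phantom, b.MEPParams(cutoff=0.3))
        masks = b.region_masks(tiny_phantom, 0.2, penumbra_width=0.1)
        sp = rng.random(fld.values.shape) * fld.values
        sfield = SurvivalField(sp=sp, phantom=tiny_phantom, lq=b.LQParams())
        report = b.region_survival_fractions(sfield, masks, fld)
        total = fld.values.sum()
        for name, mask in (("in_beam", masks.in_beam),
                           ("penumbra", masks.penumbra),
                           ("out_of_field", masks.out_of_field)):
            assert report.region_sfs()[name] == pytest.approx(
                100.0 * sp[mask].sum() / total, rel=1e-12)
        counts = report.surviving
        assert counts["total"] == pytest.approx(
            counts["in_beam"] + counts["penumbra"] + counts["out_of_field"])


class TestDifferentialSF:
    def test_rims_sum_to_total_sf(self, tiny_phantom, rng):
        fld = b.mep_field(tiny_phantom, b.MEPParams(cutoff=0.3))
        sp = rng.random(fld.values.shape) * fld.values
        sfield = SurvivalField(sp=sp, phantom=tiny_phantom, lq=b.LQParams())
        curve = b.differential_sf(sfield, fld, rim_width=0.05)
        assert curve["sf_percent"].sum() == pytest.approx(
            100.0 * sp.sum() / fld.values.sum(), rel=1e-12)

    def test_uniform_sp_rims_track_clonogen_content(self, tiny_phantom):
        fld = b.mep_field(tiny_phantom, b.MEPParams(cutoff=0.3))
        sfield = SurvivalField(sp=0.5 * fld.values, phantom=tiny_phantom,
                               lq=b.LQParams())
        curve = b.differential_sf(sfield, fld, rim_width=0.05)
        r = tiny_phantom.plane_radii
        for _, row in curve.iterrows():
            rim = (r >= row.r_outer_cm - 0.05) & (r < row.r_outer_cm)
            clonogens = fld.values[rim].sum()
            expected = 100.0 * 0.5 * clonogens / fld.values.sum()
            assert row.sf_percent == pytest.approx(expected, abs=1e-9)

    def test_no_survivors_beyond_infiltration_extent(self, reduced_run):
        curve = reduced_run.reports[0].differential
        params = reduced_run.mep_params
        beyond = curve[curve.r_outer_cm > params.cutoff
                       + reduced_run.phantom.config.gtv_radius + 0.05]
        assert np.all(beyond.sf_percent == 0.0)


class TestSFChangeAndComparison:
    def test_published_ctv_extension_rows(self):
        bnct = b.sf_change(*b.CTV_REFERENCE_SF["bnct"])
        xray = b.sf_change(*b.CTV_REFERENCE_SF["xray"])
        assert bnct == pytest.approx(53.766, abs=5e-3)
        assert xray == pytest.approx(72.912, abs=5e-3)

    def test_equal_sfs_give_zero_change(self):
        assert b.sf_change(5.0, 5.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            b.sf_change(0.0, 1.0)

    def test_comparison_against_published_totals(self):
        table = b.compare_modalities({"total": 3.92}, {"total": 12.79})
        assert table.ratio_b_over_a.iloc[0] == pytest.approx(12.79 / 3.92,
                                                             rel=1e-12)

    def test_identical_reports_have_unit_ratio(self):
        sfs = {"in_beam": 1.0, "penumbra": 2.0, "total": 3.0}
        table = b.compare_modalities(sfs, dict(sfs))
        assert np.all(table.ratio_b_over_a == 1.0)
        assert np.all(table.change_percent == 0.0)

    def test_zero_region_rejected(self):
        with pytest.raises(ValueError):
            b.compare_modalities({"total": 0.0}, {"total": 1.0})


class TestMonotonicity:
    @given(st.floats(1.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_scaling_dose_up_cannot_increase_sf(self, scale):
        rng = np.random.default_rng(7)
        mep = rng.random((12, 12))
        dose = 10.0 * rng.random((12, 12))
        base = b.survival_probability(mep, dose).sum()
        scaled = b.survival_probability(mep, scale * dose).sum()
        assert scaled <= base + 1e-12


class TestReplicateSummary:
    def test_identical_reports_have_zero_spread(self, tiny_phantom):
        fld = b.mep_field(tiny_phantom, b.MEPParams(cutoff=0.3))
        masks = b.region_masks(tiny_phantom, 0.2, penumbra_width=0.1)
        sfield = SurvivalField(sp=0.5 * fld.values, phantom=tiny_phantom,
                               lq=b.LQParams())
        report = b.region_survival_fractions(sfield, masks, fld)
        summary = b.summarize_replicates([report, report, report])
        assert summary["sd"].max() == pytest.approx(0.0, abs=1e-12)
        assert summary["mean"]["total"] == pytest.approx(50.0)
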