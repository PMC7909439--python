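"""Batch-UF mass balance: permeate concentration, yield, enrichment, purity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pepsieve as ps

R_653_1K = ps.RC_MEMBRANE_1K.retention(653.0)  # ~0.625
R_653_3K = ps.RC_MEMBRANE_3K.retention(653.0)  # ~0.305


def _flat_retention_cal(level: float) -> ps.MembraneCalibration:
    """Calibration whose clipped retention is ~constant over peptide MWs."""
    # minute slope so the clipped line is flat at `level` across 100-1e6 g/mol
    return ps.MembraneCalibration(slope=1e-12, intercept=level)


class TestRelativePermeateConcentration:
    def test_fully_transmitted_solute(self):
        for vrf in (1.0, 2.0, 10.0):
            assert ps.relative_permeate_concentration(0.0, vrf) == pytest.approx(1.0)

    def test_fully_retained_solute(self):
        for vrf in (1.0, 5.0):
            assert ps.relative_permeate_concentration(1.0, vrf) == pytest.approx(0.0)

    def test_hand_evaluated_point(self):
        assert ps.relative_permeate_concentration(0.305, 3.0) == pytest.approx(
            (3 - 3**0.305) / 2, rel=1e-12
        )
        assert ps.relative_permeate_concentration(0.305, 3.0) == pytest.approx(0.801, abs=1e-3)

    @given(r=st.floats(0, 1))
    def test_limit_at_unity_vrf(self, r):
        near = ps.relative_permeate_concentration(r, 1 + 1e-8)
        at = ps.relative_permeate_concentration(r, 1.0)
        assert at == pytest.approx(1 - r, abs=1e-12)
        assert near == pytest.approx(1 - r, abs=1e-6)

    def test_invalid_retention_rejected(self):
        with pytest.raises(ValueError):
            ps.relative_permeate_concentration(1.2, 5.0)
        with pytest.raises(ValueError):
            ps.relative_permeate_concentration(-0.1, 5.0)


class TestSpeciesYield:
    @given(r=st.floats(0, 1), vrf=st.floats(1.0 + 1e-6, 50))
    def test_closed_form_identity(self, r, vrf):
        """Mass balance x volume fraction == 1 - VRF^(R-1) to machine precision."""
        assert ps.species_yield(r, vrf) == pytest.approx(
            1 - vrf ** (r - 1), abs=1e-12
        )

    @pytest.mark.parametrize(
        "r, vrf, expected",
        [
            (R_653_1K, 5.0, 0.47),
            (R_653_1K, 10.0, 0.60),
            (R_653_3K, 5.0, 0.65),
            (R_653_3K, 10.0, 0.80),
        ],
    )
    def test_target_yields_at_published_retentions(self, r, vrf, expected):
        assert ps.species_yield(r, vrf) == pytest.approx(expected, abs=0.03)

    def test_free_solute_yield_is_volume_fraction(self):
        assert ps.species_yield(0.0, 5.0) == pytest.approx(0.8, rel=1e-12)

    @given(r=st.floats(0, 0.99), vrf=st.floats(1.01, 30))
    def test_mass_conservation(self, r, vrf):
        """Permeate + retentate mass account for all feed mass (V0 = C0 = 1)."""
        perm_mass = ps.relative_permeate_concentration(r, vrf) * (1 - 1 / vrf)
        ret_mass = vrf**r / vrf  # concentration C0*VRF^R in volume V0/VRF
        assert perm_mass + ret_mass == pytest.approx(1.0, rel=1e-9)

    @given(r=st.floats(0, 0.95), vrf=st.floats(1.1, 20))
    def test_strictly_increasing_in_vrf(self, r, vrf):
        assert ps.species_yield(r, vrf * 1.05) > ps.species_yield(r, vrf)

    @given(r=st.floats(0, 0.9), vrf=st.floats(1.1, 20))
    def test_strictly_decreasing_in_retention(self, r, vrf):
        assert ps.species_yield(r + 0.05, vrf) < ps.species_yield(r, vrf)


class TestPermeateProfile:
    def test_transparent_membrane_returns_feed(self, column, low_dh_fixture):
        chrom, _ = low_dh_fixture
        profile = ps.absorbance_to_concentration(chrom, column)
        out = ps.predict_permeate_profile(profile, _flat_retention_cal(-1e-6), 5.0)
        np.testing.assert_allclose(out.concentration, profile.concentration, rtol=1e-12)

    def test_single_species_reduces_to_scalar_balance(self, column):
        t = np.linspace(28, 30, 51)
        conc = np.exp(-0.5 * ((t - 29) / 0.2) ** 2)
        profile = ps.HydrolysateProfile(t, column.mw_at_time(t), conc)
        cal = _flat_retention_cal(0.4)
        out = ps.predict_permeate_profile(profile, cal, 5.0)
        expected = ps.relative_permeate_concentration(0.4, 5.0)
        assert out.total_concentration == pytest.approx(
            profile.total_concentration * expected, rel=1e-9
        )

    def test_matches_batch_oracle_per_species(self, mem1k):
        """Fine-step stepping oracle agrees with the closed-form profile scaling."""
        truth = ps.SyntheticTruth(
            mw=np.array([300.0, 653.0, 1000.0, 1500.0]),
            concentration=np.array([1.0, 0.5, 2.0, 3.0]),
            target_index=1,
        ).with_membrane(mem1k)
        res = ps.batch_oracle(truth, 5.0, n_steps=100_000)
        expected = ps.relative_permeate_concentration(truth.retention, 5.0)
        np.testing.assert_allclose(
            res.mean_permeate_concentration / truth.concentration, expected, rtol=1e-4
        )


class TestEnrichment:
    def test_uniform_mixture_cannot_self_enrich(self):
        profile = ps.HydrolysateProfile(
            time=np.linspace(0, 1, 10),
            mw=np.full(10, 653.0),
            concentration=np.random.default_rng(0).uniform(0.5, 1.5, 10),
        )
        tau = ps.enrichment(profile, ps.RC_MEMBRANE_1K, ps.NEOKYOTORPHIN, 5.0)
        assert tau == pytest.approx(1.0, rel=1e-12)

    def test_fully_retained_background_maximizes_enrichment(self, column):
        """With all non-target mass fully retained, tau = sum C0 / C0_target."""
        t = np.linspace(12, 34, 400)
        mw = column.mw_at_time(t)
        conc = np.zeros_like(t)
        target_zone = np.abs(mw - 653) < 20
        big_zone = mw > 10000  # retention clipped to 1 for the 1k membrane
        conc[target_zone] = 1.0
        conc[big_zone] = 5.0
        profile = ps.HydrolysateProfile(t, mw, conc)
        target_mass = np.trapezoid(np.where(target_zone, conc, 0), t)
        tau = ps.enrichment(profile, ps.RC_MEMBRANE_1K, ps.NEOKYOTORPHIN, 5.0)
        # target itself transmits at its own ratio top and bottom, cancelling
        assert tau == pytest.approx(profile.total_concentration / target_mass, rel=0.02)

    def test_low_dh_enrichment_in_the_tens_and_decreasing(self, column, low_dh_fixture):
        chrom, _ = low_dh_fixture
        profile = ps.absorbance_to_concentration(chrom, column)
        taus = [
            ps.enrichment(profile, ps.RC_MEMBRANE_1K, ps.NEOKYOTORPHIN, v)
            for v in (1.1, 5.0, 10.0)
        ]
        assert taus[0] > 10
        assert taus[0] > taus[1] > taus[2]

    def test_target_outside_profile_support_rejected(self, column):
        t = np.linspace(12, 18, 50)  # only very large molar masses
        profile = ps.HydrolysateProfile(t, column.mw_at_time(t), np.ones(50))
        with pytest.raises(ValueError, match="support"):
            ps.enrichment(profile, ps.RC_MEMBRANE_1K, ps.NEOKYOTORPHIN, 5.0)


class TestPurity:
    def test_published_product(self):
        assert ps.permeate_purity(2.6, 10.7) == pytest.approx(27.9, abs=0.2)

    def test_unit_enrichment_preserves_purity(self):
        assert ps.permeate_purity(3.1, 1.0) == pytest.approx(3.1)

    def test_rounding_sensitive_product(self):
        assert ps.permeate_purity(2.5, 17.4) == pytest.approx(43.5, abs=0.05)

    def test_capped_at_100_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            assert ps.permeate_purity(50.0, 3.0) == 100.0

    def test_area_to_concentration_coefficient(self):
        assert ps.concentration_from_area(0.01, ps.NEOKYOTORPHIN) == pytest.approx(44.196)

    def test_purity_from_areas(self):
        assert ps.purity_from_areas(0.5, 0.5) == 100.0
        assert ps.purity_from_areas(0.0, 0.5) == 0.0
        with pytest.raises(ValueError):
            ps.purity_from_areas(0.6, 0.5)


class TestVrfForYield:
    def test_inverse_of_published_yield(self, mem1k):
        r = mem1k.retention(653.0)
        goal = ps.species_yield(r, 5.0)
        assert ps.vrf_for_yield(mem1k, ps.NEOKYOTORPHIN, goal) == pytest.approx(5.0, rel=1e-9)

    def test_matched_yield_operating_points(self, mem1k, mem3k):
        """A ~50% target yield needs VRF ~5 with the tighter membrane, ~3 with the looser."""
        goal1 = ps.species_yield(mem1k.retention(653.0), 5.0)
        goal3 = ps.species_yield(mem3k.retention(653.0), 3.0)
        assert ps.vrf_for_yield(mem1k, ps.NEOKYOTORPHIN, goal1) == pytest.approx(5.0, rel=1e-9)
        assert ps.vrf_for_yield(mem3k, ps.NEOKYOTORPHIN, goal3) == pytest.approx(3.0, rel=1e-9)
        assert abs(goal1 - goal3) < 0.1  # both near 50%

    def test_small_goal_approaches_unity_vrf(self, mem1k):
        assert ps.vrf_for_yield(mem1k, ps.NEOKYOTORPHIN, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_fully_retained_target_rejected(self):
        cal = _flat_retention_cal(1.5)  # clipped retention 1 everywhere
        with pytest.raises(ValueError, match="unreachable|retained"):
            ps.vrf_for_yield(cal, ps.NEOKYOTORPHIN, 0.5)


class TestVrfSweep:
    def test_single_point_grid_matches_scalar_operations(self, column, low_dh_fixture, mem1k):
        chrom, truth = low_dh_fixture
        profile = ps.absorbance_to_concentration(chrom, column)
        pred = ps.vrf_sweep(profile, mem1k, ps.NEOKYOTORPHIN, [5.0], initial_purity=2.5)
        assert pred.target_yield[0] == pytest.approx(
            ps.species_yield(mem1k.retention(653.0), 5.0), rel=1e-12
        )
        assert pred.enrichment[0] == pytest.approx(
            ps.enrichment(profile, mem1k, ps.NEOKYOTORPHIN, 5.0), rel=1e-12
        )
        assert pred.purity[0] == pytest.approx(2.5 * pred.enrichment[0], rel=1e-12)

    def test_yield_curve_non_decreasing(self, column, low_dh_fixture, mem1k):
        chrom, _ = low_dh_fixture
        profile = ps.absorbance_to_concentration(chrom, column)
        pred = ps.vrf_sweep(profile, mem1k, ps.NEOKYOTORPHIN)
        assert np.all(np.diff(pred.target_yield) >= 0)

    def test_enrichment_flat_at_high_dh_decreasing_at_low_dh(self, column, mem1k):
        lowest_chrom, _ = ps.generate_hydrolysate(ps.preset("3dh-col", seed=4))
        low_chrom, _ = ps.generate_hydrolysate(ps.preset("3dh-dec", seed=4))
        high_chrom, _ = ps.generate_hydrolysate(ps.preset("18dh", seed=4))
        grid = np.array([1.1, 3.0, 5.0, 10.0])
        lowest = ps.vrf_sweep(
            ps.absorbance_to_concentration(lowest_chrom, column), mem1k, ps.NEOKYOTORPHIN, grid
        )
        low = ps.vrf_sweep(
            ps.absorbance_to_concentration(low_chrom, column), mem1k, ps.NEOKYOTORPHIN, grid
        )
        high = ps.vrf_sweep(
            ps.absorbance_to_concentration(high_chrom, column), mem1k, ps.NEOKYOTORPHIN, grid
        )
        # high-DH mixture: target-sized peptides dominate, tau stays ~constant near 1
        assert high.enrichment[-1] / high.enrichment[0] > 0.9
        # low-DH decolored-like mixture: tau falls visibly along the run
        assert low.enrichment[0] > 3 * high.enrichment[0]
        assert low.enrichment[-1] < low.enrichment[0]
        # the colored-like mixture gives the largest enrichments, ~flat here
        # because nearly all its background mass is above the retention clip
        assert lowest.enrichment[0] > 10
        assert abs(lowest.enrichment[-1] / lowest.enrichment[0] - 1) < 0.1

    def test_invalid_grid_rejected(self, column, low_dh_fixture, mem1k):
        chrom, _ = low_dh_fixture
        profile = ps.absorbance_to_concentration(chrom, column)
        with pytest.raises(ValueError):
            ps.vrf_sweep(profile, mem1k, ps.NEOKYOTORPHIN, [5.0, 3.0])
        with pytest.raises(ValueError):
            ps.vrf_sweep(profile, mem1k, ps.NEOKYOTORPHIN, [0.5, 3.0])


class TestProductivity:
    def test_unit_case(self):
        assert ps.productivity(1.0, 1.0, 1.0) == 1.0

    def test_bench_scale_unit_conversion(self):
        # 8.6 mg over an 88 cm^2 membrane in one hour
        assert ps.productivity(0.0086, 88e-4, 1.0) == pytest.approx(0.977, abs=0.005)

    def test_doubling_duration_halves_productivity(self):
        assert ps.productivity(1.0, 1.0, 2.0) == pytest.approx(
            ps.productivity(1.0, 1.0, 1.0) / 2
        )

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ps.productivity(1.0, 0.0, 1.0)


class TestOperatingPoint:
    def test_permeate_volume(self):
        op = ps.UFOperatingPoint(vrf=5.0, initial_volume=0.2)
        assert op.permeate_volume == pytest.approx(0.16)

    def test_invalid_vrf_rejected(self):
        with pytest.raises(ValueError):
            ps.UFOperatingPoint(vrf=0.5)
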