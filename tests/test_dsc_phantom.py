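"""Forward tracer-kinetics model and phantom generator contracts."""

import math

import numpy as np
import pytest

from adsev.aif_select import signal_to_concentration
from adsev.dsc_phantom import (AcquisitionParams, ConcCurve,
                               GammaVariateParams, PhantomSpec, RegionSpec,
                               TimeGrid, TissueParams,
                               concentration_to_signal, default_acquisition,
                               default_grid, default_phantom_spec,
                               gamma_amplitude_for_peak, gamma_variate,
                               generate_phantom, residue_function,
                               tissue_concentration)


class TestGammaVariate:
    def test_zero_before_and_at_bolus_arrival(self):
        grid = TimeGrid(dt=0.5, n=100)
        curve = gamma_variate(GammaVariateParams(t0=10, a=1, r=3, b=1.5), grid)
        assert np.all(curve.values[grid.t <= 10.0] == 0.0)
        assert curve.values.min() >= 0.0

    def test_mode_at_t0_plus_r_times_b(self):
        grid = TimeGrid(dt=0.01, n=3000)
        curve = gamma_variate(GammaVariateParams(t0=10, a=1, r=3, b=1.5), grid)
        assert np.argmax(curve.values) * grid.dt == pytest.approx(14.5, abs=0.011)
        # single interior maximum: strictly unimodal after onset
        vals = curve.values[grid.t > 10.0]
        peak = np.argmax(vals)
        assert np.all(np.diff(vals[:peak]) > 0)
        assert np.all(np.diff(vals[peak:]) < 0)

    def test_value_matches_direct_scalar_evaluation(self):
        # hand evaluation at t=14.5: tau=4.5 -> 4.5^3 * exp(-3)
        grid = TimeGrid(dt=0.5, n=60)
        curve = gamma_variate(GammaVariateParams(t0=10, a=1, r=3, b=1.5), grid)
        expected = 4.5 ** 3 * math.exp(-4.5 / 1.5)
        assert curve.values[int(14.5 / 0.5)] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.5368466, rel=1e-7)

    def test_rejects_invalid_parameters(self):
        for bad in [dict(t0=-1, a=1, r=3, b=1), dict(t0=0, a=0, r=3, b=1),
                    dict(t0=0, a=1, r=3, b=np.nan)]:
            with pytest.raises(ValueError):
                GammaVariateParams(**bad)

    def test_amplitude_scaling_hits_requested_peak(self):
        a = gamma_amplitude_for_peak(6.0, 3.0, 1.5)
        params = GammaVariateParams(t0=10, a=a, r=3, b=1.5)
        assert params.peak_value == pytest.approx(6.0, rel=1e-12)


class TestResidueFunction:
    def test_starts_at_one_and_non_increasing(self):
        grid = TimeGrid(dt=0.5, n=64)
        for model in ("exponential", "boxcar"):
            r = residue_function(4.0, grid, model)
            assert r.values[0] == 1.0
            assert np.all(np.diff(r.values) <= 0)

    def test_boxcar_is_plug_flow(self):
        grid = TimeGrid(dt=0.5, n=32)
        r = residue_function(4.0, grid, "boxcar").values
        assert np.all(r[grid.t < 4.0] == 1.0)
        assert np.all(r[grid.t >= 4.0] == 0.0)

    def test_exponential_integrates_to_mtt(self):
        grid = TimeGrid(dt=0.01, n=4000)
        r = residue_function(4.0, grid, "exponential")
        assert r.auc() == pytest.approx(4.0, abs=0.01)

    def test_rejects_non_positive_mtt(self):
        with pytest.raises(ValueError):
            residue_function(0.0, TimeGrid(dt=1, n=8))


class TestTissueConcentration:
    def test_zero_flow_gives_zero_curve(self):
        grid = default_grid()
        aif = gamma_variate(default_phantom_spec().aif_params, grid)
        ct = tissue_concentration(aif, TissueParams(0, 0, 1.0), grid)
        assert np.all(ct.values == 0.0)

    def test_unit_area_spike_reproduces_scaled_residue(self):
        grid = TimeGrid(dt=0.5, n=64)
        spike = np.zeros(grid.n)
        spike[0] = 1.0 / grid.dt
        aif = ConcCurve(spike, grid)
        tissue = TissueParams.from_cbf_cbv(60.0, 4.0)
        ct = tissue_concentration(aif, tissue, grid)
        expected = (60.0 / 6000.0) * residue_function(4.0, grid).values
        np.testing.assert_allclose(ct.values, expected, atol=1e-12)

    def test_matches_fine_grid_quadrature(self):
        """Rectangle-rule convolution converges first order to the
        near-continuum quadrature of the same integral: ~2% of peak at
        dt=0.1 shrinking to ~0.2% at dt=0.01."""
        fine = TimeGrid(dt=0.001, n=40000)
        params = GammaVariateParams(t0=10, a=1.0, r=3, b=1.5)
        tissue = TissueParams.from_cbf_cbv(60.0, 4.0)
        ct_f = tissue_concentration(gamma_variate(params, fine), tissue, fine)
        peak = ct_f.values.max()
        errs = {}
        for dt, n, stride in ((0.1, 400, 100), (0.01, 4000, 10)):
            grid = TimeGrid(dt=dt, n=n)
            ct = tissue_concentration(gamma_variate(params, grid), tissue,
                                      grid)
            errs[dt] = np.abs(ct.values - ct_f.values[::stride]).max()
        assert errs[0.1] < 0.02 * peak
        assert errs[0.01] < 0.002 * peak
        assert errs[0.01] < 0.15 * errs[0.1]  # first-order shrinkage

    def test_grid_mismatch_rejected(self):
        aif = gamma_variate(GammaVariateParams(t0=1, a=1, r=3, b=1),
                            TimeGrid(dt=1, n=16))
        with pytest.raises(ValueError):
            tissue_concentration(aif, TissueParams.from_cbf_cbv(60, 4),
                                 TimeGrid(dt=1, n=32))


class TestSignalModel:
    def test_baseline_and_closed_form(self):
        acq = AcquisitionParams(te=1.0, s0=50.0, kappa=1.0)
        grid = TimeGrid(dt=1, n=8)
        assert np.all(concentration_to_signal(ConcCurve(np.zeros(8), grid), acq)
                      == 50.0)
        s = concentration_to_signal(ConcCurve(np.ones(8), grid), acq)
        np.testing.assert_allclose(s, 50.0 * math.exp(-1.0))

    def test_round_trip_with_inversion(self):
        rng = np.random.default_rng(3)
        acq = default_acquisition()
        c = rng.uniform(0, 5, size=(2, 2, 1, 40))
        c[..., : acq.n_baseline] = 0.0  # baseline must be tracer-free
        signal = acq.s0 * np.exp(-acq.kappa * acq.te * c)
        recovered, valid = signal_to_concentration(signal, acq)
        assert valid.all()
        np.testing.assert_allclose(recovered, c, atol=1e-10)


class TestTissueParams:
    def test_central_volume_enforced(self):
        with pytest.raises(ValueError, match="central-volume"):
            TissueParams(cbf=60, cbv=4, mtt=5.0)
        ok = TissueParams.from_cbf_cbv(60, 4)
        assert ok.mtt == pytest.approx(4.0)

    def test_mtt_required_positive_with_flow(self):
        with pytest.raises(ValueError):
            TissueParams(cbf=10, cbv=0, mtt=0.0)


class TestGeneratePhantom:
    def test_background_is_flat_baseline_without_noise(self, noiseless_phantom):
        ph = noiseless_phantom
        bg = ph.region_indices("background")
        assert np.all(ph.signal[bg] == ph.acq.s0)
        for m in (ph.cbf, ph.cbv, ph.mtt):
            assert np.all(m[bg] == 0.0)

    def test_same_seed_is_bit_identical(self):
        spec = default_phantom_spec(shape=(8, 8, 2))
        grid = TimeGrid(dt=0.5, n=60)
        acq = default_acquisition(2.0)
        a = generate_phantom(spec, acq, grid, seed=5)
        b = generate_phantom(spec, acq, grid, seed=5)
        assert a.signal.tobytes() == b.signal.tobytes()
        c = generate_phantom(spec, acq, grid, seed=6)
        assert a.signal.tobytes() != c.signal.tobytes()

    def test_noiseless_arterial_voxel_inverts_to_true_aif(self, noiseless_phantom):
        ph = noiseless_phantom
        conc, valid = signal_to_concentration(ph.signal, ph.acq)
        art = ph.region_indices("artery")
        assert valid[art].all()
        assert np.abs(conc[art] - ph.true_aif.values).max() < 1e-8

    def test_truth_maps_satisfy_central_volume(self, noiseless_phantom):
        ph = noiseless_phantom
        flow = ph.cbf > 0
        np.testing.assert_allclose(ph.mtt[flow],
                                   60.0 * ph.cbv[flow] / ph.cbf[flow],
                                   atol=1e-9)

    def test_partial_volume_peak_monotone(self):
        """Voxel peak concentration is non-decreasing in the arterial fraction."""
        grid = default_grid()
        spec = default_phantom_spec()
        aif = gamma_variate(spec.aif_params, grid)
        tissue = TissueParams.from_cbf_cbv(60.0, 4.0)
        ct = tissue_concentration(aif, tissue, grid).values
        peaks = [np.max(pv * aif.values + (1 - pv) * ct)
                 for pv in np.linspace(0, 1, 11)]
        assert np.all(np.diff(peaks) >= 0)

    def test_spec_without_artery_rejected(self):
        gray = TissueParams.from_cbf_cbv(60, 4)
        with pytest.raises(ValueError, match="arterial"):
            PhantomSpec(
                shape=(4, 4, 1),
                aif_params=GammaVariateParams(t0=10, a=1, r=3, b=1.5),
                regions=(RegionSpec("bg", (0, 4, 0, 4, 0, 1), None),
                         RegionSpec("gray", (1, 3, 1, 3, 0, 1), gray)),
            )
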