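"""Prior-map estimation: decay rates, field map, dipole inversion, CBVv, CBF."""

import numpy as np
import pytest
from scipy import ndimage

from oxibold import (
    estimate_fieldmap,
    fit_decay_rates,
    invert_dipole,
    quantify_cbf,
    quantify_cbvv,
    simulate_ausfide,
    simulate_pcasl,
    simulate_vsvsl,
)
from oxibold.config import AcquisitionConfig
from oxibold.constants import DEFAULT_CONSTANTS
from oxibold.dipole import dipole_kernel, forward_field
from oxibold.phantom import AusfideSeries, LabeledPair, PcaslSeries
from oxibold.physics import VoxelState, delta_omega, qbold_signal, r2prime_model
from oxibold.priors import fit_all_priors


def make_series(mag_f, mag_e, acq, phase_f=None):
    mag_f = np.asarray(mag_f, dtype=complex)
    mag_e = np.asarray(mag_e, dtype=complex)
    if phase_f is not None:
        mag_f = mag_f * np.exp(1j * phase_f)
    return AusfideSeries(fid=mag_f, echo=mag_e, te_fid=acq.te_fid,
                         te_echo=acq.te_echo, tr=acq.ausfide_tr)


class TestDecayRates:
    def test_arithmetic_identity_on_pure_exponentials(self, acq):
        te_f, te_e = acq.te_fid, acq.te_echo
        fid = 100 * np.exp(-25.0 * te_f)[None, None, None, :]
        echo = 60 * np.exp(-15.0 * te_e)[None, None, None, :]
        series = make_series(fid, echo, acq)
        r2, r2p, r2star, info = fit_decay_rates(series, np.ones((1, 1, 1), bool))
        assert r2[0, 0, 0] == pytest.approx(20.0, abs=1e-9)
        assert r2p[0, 0, 0] == pytest.approx(5.0, abs=1e-9)
        assert r2star[0, 0, 0] == pytest.approx(25.0, abs=1e-9)

    def test_monoexponential_prior_bias_within_ten_percent(self, acq):
        # the fc curvature at early echoes makes the monoexponential R2'
        # prior biased low; the bias must stay within 10 % for this voxel
        st = VoxelState(yv=0.6, dbv=0.03, r2=20.0, r2p_nh=1.0, chi_nb=0.0,
                        cbvv=0.03, hct=0.44)
        truth = float(r2prime_model(st))
        assert truth == pytest.approx(5.794, abs=2e-3)
        fid = qbold_signal(st, acq, "FID", acq.te_fid)[None, None, None, :]
        echo = qbold_signal(st, acq, "ECHO", acq.te_echo)[None, None, None, :]
        series = make_series(fid, echo, acq)
        _, r2p, _, _ = fit_decay_rates(series, np.ones((1, 1, 1), bool))
        assert r2p[0, 0, 0] == pytest.approx(truth, rel=0.10)

    def test_linear_regime_rates_within_one_percent(self, acq):
        # restricted to echoes with dw*t >= 3 (linear fc regime) the fitted
        # monoexponential rates match R2 +/- R2' to better than 1 %
        st = VoxelState(yv=0.6, dbv=0.03, r2=20.0, r2p_nh=1.0, chi_nb=0.0,
                        cbvv=0.03, hct=0.44)
        dw = delta_omega(0.44, 0.6)
        fid = qbold_signal(st, acq, "FID", acq.te_fid)
        echo = qbold_signal(st, acq, "ECHO", acq.te_echo)
        sel_f = dw * acq.te_fid >= 3
        sel_e = dw * (acq.ausfide_tr - acq.te_echo) >= 3
        sub = AusfideSeries(
            fid=fid[None, None, None, sel_f], echo=echo[None, None, None, sel_e],
            te_fid=acq.te_fid[sel_f], te_echo=acq.te_echo[sel_e],
            tr=acq.ausfide_tr)
        r2, r2p, r2star, _ = fit_decay_rates(sub, np.ones((1, 1, 1), bool))
        r2p_true = float(r2prime_model(st))
        assert r2star[0, 0, 0] == pytest.approx(20.0 + r2p_true, rel=0.01)
        assert (r2 - r2p)[0, 0, 0] == pytest.approx(20.0 - r2p_true, rel=0.01)

    def test_monte_carlo_r2_error_at_snr_100(self, acq):
        # 500 noisy replicates of one voxel: median |R2 error| < 2 %
        st = VoxelState(yv=0.6, dbv=0.03, r2=20.0, r2p_nh=1.0, chi_nb=0.0,
                        cbvv=0.03, hct=0.44, a_f=100.0, a_e=60.0)
        fid = qbold_signal(st, acq, "FID", acq.te_fid)
        echo = qbold_signal(st, acq, "ECHO", acq.te_echo)
        rng = np.random.default_rng(42)
        n = 500
        noisy_f = fid + rng.normal(0, 1, (n, 1, 1, 17)) + 1j * rng.normal(
            0, 1, (n, 1, 1, 17))
        noisy_e = echo + rng.normal(0, 1, (n, 1, 1, 17)) + 1j * rng.normal(
            0, 1, (n, 1, 1, 17))
        series = make_series(noisy_f, noisy_e, acq)
        r2, _, _, _ = fit_decay_rates(series, np.ones((n, 1, 1), bool))
        assert np.median(np.abs(r2 - 20.0)) / 20.0 < 0.02

    def test_negative_r2p_clipped_and_flagged(self, acq):
        te_f, te_e = acq.te_fid, acq.te_echo
        fid = 100 * np.exp(-15.0 * te_f)[None, None, None, :]
        echo = 60 * np.exp(-25.0 * te_e)[None, None, None, :]  # rate_E > rate_F
        series = make_series(fid, echo, acq)
        r2, r2p, _, info = fit_decay_rates(series, np.ones((1, 1, 1), bool))
        assert r2p[0, 0, 0] == 0.0
        assert info["r2p_clipped"][0, 0, 0]

    def test_all_zero_voxel_marked_invalid(self, acq):
        fid = np.zeros((1, 1, 1, 17), complex)
        echo = np.zeros((1, 1, 1, 17), complex)
        series = make_series(fid, echo, acq)
        r2, _, _, info = fit_decay_rates(series, np.ones((1, 1, 1), bool))
        assert not info["valid"][0, 0, 0]
        assert np.isnan(r2[0, 0, 0])

    def test_too_few_echoes_rejected(self, acq):
        series = AusfideSeries(fid=np.ones((1, 1, 1, 2), complex),
                               echo=np.ones((1, 1, 1, 2), complex),
                               te_fid=acq.te_fid[:2], te_echo=acq.te_echo[:2],
                               tr=acq.ausfide_tr)
        with pytest.raises(ValueError):
            fit_decay_rates(series, np.ones((1, 1, 1), bool))


class TestFieldmap:
    def _uniform_offset_series(self, acq, db0_ppm, shape=(2, 2, 2)):
        c = DEFAULT_CONSTANTS
        te = acq.te_fid
        mag = 100 * np.exp(-20.0 * te)
        phase = c.gamma * c.b0 * db0_ppm * 1e-6 * te
        fid = np.broadcast_to(mag * np.exp(1j * phase), (*shape, te.size))
        return make_series(fid, np.broadcast_to(mag, (*shape, te.size)), acq)

    def test_zero_phase_gives_zero_field(self, acq):
        series = self._uniform_offset_series(acq, 0.0)
        db0, info = estimate_fieldmap(series, np.ones((2, 2, 2), bool))
        np.testing.assert_allclose(db0, 0.0, atol=1e-12)

    def test_uniform_offset_recovered_exactly(self, acq):
        series = self._uniform_offset_series(acq, 0.1)
        db0, _ = estimate_fieldmap(series, np.ones((2, 2, 2), bool))
        np.testing.assert_allclose(db0, 0.1, atol=1e-9)

    def test_wrapped_offset_recovered_by_temporal_unwrapping(self, acq):
        # 1.5 ppm at 3 T wraps several times over the echo train but the
        # inter-echo increment stays below pi, so unwrapping recovers it
        c = DEFAULT_CONSTANTS
        increment = c.gamma * c.b0 * 1.5e-6 * acq.ausfide_echo_spacing
        assert np.pi / 2 < increment < np.pi
        series = self._uniform_offset_series(acq, 1.5)
        series = make_series(np.abs(series.fid) * np.exp(
            1j * np.angle(series.fid)), np.abs(series.echo), acq)
        db0, info = estimate_fieldmap(series, np.ones((2, 2, 2), bool))
        np.testing.assert_allclose(db0, 1.5, atol=1e-9)
        assert not info["aliased"].any()


class TestDipole:
    def test_kernel_analytic_values(self):
        d = dipole_kernel((8, 8, 8))
        # k purely along z -> 1/3 - 1 = -2/3; kz = 0 plane -> 1/3
        assert d[0, 0, 1] == pytest.approx(-2.0 / 3.0)
        assert d[1, 0, 0] == pytest.approx(1.0 / 3.0)
        assert d[0, 2, 0] == pytest.approx(1.0 / 3.0)
        assert d[0, 0, 0] == 0.0

    def test_zero_field_gives_zero_chi(self):
        mask = np.ones((8, 8, 8), bool)
        chi = invert_dipole(np.zeros((8, 8, 8)), mask, reg=1e-2)
        np.testing.assert_allclose(chi, 0.0, atol=1e-15)

    def test_forward_field_vanishes_inside_uniform_sphere(self):
        # analytic property of the dipole kernel convention: the field
        # perturbation inside a uniform sphere is zero
        ax = np.linspace(-1, 1, 32)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        sph = x ** 2 + y ** 2 + z ** 2 <= 0.4 ** 2
        field = forward_field(sph * 0.1)
        interior = ndimage.binary_erosion(sph, iterations=3)
        assert np.abs(field[interior]).max() < 0.01 * 0.1

    def test_sphere_round_trip(self):
        """Forward-convolve a synthetic uniform sphere (chi = 0.1 ppm) and
        invert. Accuracy metric: RMSE over the volume excluding a 2-voxel
        shell around the object boundary, normalized by the object
        susceptibility (0.1 ppm); must be below 10 %."""
        ax = np.linspace(-1, 1, 32)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        sph = x ** 2 + y ** 2 + z ** 2 <= 0.4 ** 2
        chi = sph * 0.1
        field = forward_field(chi)
        rec = invert_dipole(field, np.ones_like(sph, bool), reg=1e-2,
                            detrend_order=None)
        shell = ndimage.binary_dilation(sph, iterations=2) & ~(
            ndimage.binary_erosion(sph, iterations=2))
        keep = ~shell
        nrmse = np.sqrt(np.mean((rec[keep] - chi[keep]) ** 2)) / 0.1
        assert nrmse < 0.10

    def test_linearity_in_field(self, rng):
        mask = np.ones((12, 12, 12), bool)
        f1 = rng.normal(size=(12, 12, 12))
        f2 = rng.normal(size=(12, 12, 12))
        a = invert_dipole(f1 + 2 * f2, mask, reg=1e-2, detrend_order=None)
        b = (invert_dipole(f1, mask, reg=1e-2, detrend_order=None)
             + 2 * invert_dipole(f2, mask, reg=1e-2, detrend_order=None))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonpositive_regularization_rejected(self):
        with pytest.raises(ValueError):
            invert_dipole(np.zeros((8, 8, 8)), np.ones((8, 8, 8), bool), reg=0.0)


class TestCbvv:
    def test_equal_volumes_give_zero(self, acq):
        pair = LabeledPair(control=np.full((4, 4, 4), 7.0),
                           tag=np.full((4, 4, 4), 7.0),
                           m0b=100.0, ti=acq.vsvl_ti, blood_t1=acq.blood_t1)
        cbvv, _ = quantify_cbvv(pair, acq, 100.0)
        np.testing.assert_array_equal(cbvv, 0.0)

    def test_worked_value(self, acq):
        pair = LabeledPair(control=np.full((2, 2, 2), 103.007),
                           tag=np.full((2, 2, 2), 100.0),
                           m0b=100.0, ti=1.14, blood_t1=1.65)
        cbvv, _ = quantify_cbvv(pair, acq, 100.0)
        np.testing.assert_allclose(cbvv, 0.03, rtol=2e-4)

    def test_round_trip_exact(self, acq, phantom):
        pair = simulate_vsvsl(phantom, acq, m0b=100.0)
        cbvv, info = quantify_cbvv(pair, acq, 100.0)
        np.testing.assert_allclose(cbvv[phantom.brain_mask],
                                   phantom.cbvv[phantom.brain_mask], atol=1e-12)

    def test_negative_clipped_with_flag(self, acq):
        pair = LabeledPair(control=np.full((2, 2, 2), 99.0),
                           tag=np.full((2, 2, 2), 100.0),
                           m0b=100.0, ti=1.14, blood_t1=1.65)
        cbvv, info = quantify_cbvv(pair, acq, 100.0)
        assert np.all(cbvv == 0.0)
        assert info["clipped"].all()

    def test_invalid_m0b_rejected(self, acq):
        pair = LabeledPair(control=np.ones((2, 2, 2)), tag=np.ones((2, 2, 2)),
                           m0b=100.0, ti=1.14, blood_t1=1.65)
        with pytest.raises(ValueError):
            quantify_cbvv(pair, acq, 0.0)


class TestCbf:
    def test_zero_difference_gives_zero(self, acq):
        series = PcaslSeries(control=np.ones((2, 3, 3, 3)),
                             label=np.ones((2, 3, 3, 3)),
                             m0=np.full((3, 3, 3), 100.0))
        cbf, _ = quantify_cbf(series, acq)
        np.testing.assert_array_equal(cbf, 0.0)

    def test_consensus_worked_value(self, acq):
        # dM/M0 = 0.01 at the consensus defaults gives ~97.4 mL/100 g/min
        m0 = np.full((2, 2, 2), 100.0)
        series = PcaslSeries(control=np.full((1, 2, 2, 2), 100.5),
                             label=np.full((1, 2, 2, 2), 99.5), m0=m0)
        cbf, _ = quantify_cbf(series, acq)
        np.testing.assert_allclose(cbf, 97.4, rtol=1e-3)

    def test_round_trip_exact(self, acq, phantom):
        series = simulate_pcasl(phantom, acq)
        cbf, _ = quantify_cbf(series, acq)
        m = phantom.brain_mask
        np.testing.assert_allclose(cbf[m], phantom.cbf[m], atol=1e-9)

    def test_linearity_in_difference(self, acq):
        m0 = np.full((2, 2, 2), 100.0)
        s1 = PcaslSeries(control=np.full((1, 2, 2, 2), 101.0),
                         label=np.full((1, 2, 2, 2), 100.0), m0=m0)
        s2 = PcaslSeries(control=np.full((1, 2, 2, 2), 102.0),
                         label=np.full((1, 2, 2, 2), 100.0), m0=m0)
        np.testing.assert_allclose(2 * quantify_cbf(s1, acq)[0],
                                   quantify_cbf(s2, acq)[0], rtol=1e-12)

    def test_nonpositive_m0_flagged(self, acq):
        m0 = np.zeros((2, 2, 2))
        series = PcaslSeries(control=np.ones((1, 2, 2, 2)),
                             label=np.zeros((1, 2, 2, 2)), m0=m0)
        cbf, info = quantify_cbf(series, acq)
        assert np.isnan(cbf).all()
        assert not info["valid"].any()


class TestPriorsIntegration:
    def test_r2star_identity(self, noiseless_priors):
        p = noiseless_priors
        finite = np.isfinite(p.r2star)
        np.testing.assert_allclose(p.r2star[finite], (p.r2 + p.r2p)[finite],
                                   atol=1e-9)

    def test_noiseless_round_trip_tolerances(self, phantom, noiseless_priors):
        p = noiseless_priors
        m = phantom.brain_mask
        np.testing.assert_allclose(p.cbvv[m], phantom.cbvv[m], atol=1e-9)
        np.testing.assert_allclose(p.cbf[m], phantom.cbf[m], atol=1e-6)
        np.testing.assert_allclose(p.db0[m], phantom.db0_total()[m], atol=1e-9)

    def test_errors_grow_with_noise(self, phantom, acq):
        # median absolute R2 error increases monotonically across noise levels
        errs = []
        for sd in (0.5, 2.0, 8.0):
            aus = simulate_ausfide(phantom, acq, noise_sd=sd, seed=21)
            from oxibold.priors import fit_decay_rates as fdr

            r2, _, _, _ = fdr(aus, phantom.tissue_mask)
            m = phantom.tissue_mask & np.isfinite(r2)
            errs.append(np.median(np.abs(r2[m] - phantom.r2[m])))
        assert errs[0] < errs[1] < errs[2]
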