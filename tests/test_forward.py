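import numpy as np
import pytest

from _oracles import uniform_disc_derivative_trace, uniform_disc_trace
from conftest import FS, V_SOUND
from eatomo import phantoms
from eatomo.forward import (ArrayGeometry, TransducerResponse, add_noise,
                            apply_response, propagate)
from eatomo.sigproc import estimate_tof, lowpass


def single_detector(distance, extra=256):
    n_samp = int(np.ceil(distance / V_SOUND * FS)) + extra
    return ArrayGeometry(n_elements=1, ring_radius=distance,
                         sampling_rate=FS, n_samples=n_samp,
                         element_angles=np.array([0.0]))


class TestPropagate:
    def test_zero_source_zero_traces(self, water_medium_small, ring128):
        data = propagate(np.zeros((129, 129)), water_medium_small, ring128)
        assert np.all(data.traces == 0)

    def test_center_point_source_symmetry_and_arrival(self,
                                                      water_medium_small):
        """A centre source reaches all 128 elements identically at d/v_s."""
        p0 = phantoms.point_map((129, 129), 0.05e-3, (0.0, 0.0))
        geom = ArrayGeometry(n_elements=128, ring_radius=0.050,
                             sampling_rate=FS, n_samples=1600, t0=30e-6)
        data = propagate(p0, water_medium_small, geom)
        assert np.allclose(data.traces, data.traces[0])
        tof = estimate_tof(data.traces[0], FS, t0=30e-6)
        assert tof == pytest.approx(0.050 / V_SOUND, abs=1.5 / FS)

    def test_as_printed_matches_chord_arc_solution(self, water_medium_small):
        """Retarded-potential trace of a uniform disc vs the closed form."""
        a, dist = 1.5e-3, 0.050
        p0 = phantoms.disc_map((129, 129), 0.05e-3, (0, 0), a, supersample=8)
        geom = single_detector(dist)
        geom = ArrayGeometry(n_elements=1, ring_radius=dist,
                             sampling_rate=FS,
                             n_samples=int(8e-3 / V_SOUND * FS) + 64,
                             element_angles=np.array([0.0]),
                             t0=(dist - 4e-3) / V_SOUND)
        num = propagate(p0, water_medium_small, geom,
                        form="as_printed").traces[0]
        ana = uniform_disc_trace(geom.times, dist, a, V_SOUND)
        num_f, ana_f = lowpass(num, 6e6, FS), lowpass(ana, 6e6, FS)
        err = np.linalg.norm(num_f - ana_f) / np.linalg.norm(ana_f)
        assert err < 0.01

    def test_derivative_form_is_analytic_nwave(self, water_medium_small):
        """Derivative form reproduces the bipolar N-wave within 2% L2.

        Compared inside the 6 MHz detection band: the exact derivative has
        integrable sqrt singularities at the disc shoulders, so only the
        band-limited waveforms are square-integrable.
        """
        a, dist = 1.5e-3, 0.050
        p0 = phantoms.disc_map((129, 129), 0.05e-3, (0, 0), a, supersample=8)
        n_samp = int(8e-3 / V_SOUND * FS) + 64
        t0 = (dist - 4e-3) / V_SOUND
        geom = ArrayGeometry(n_elements=1, ring_radius=dist,
                             sampling_rate=FS, n_samples=n_samp,
                             element_angles=np.array([0.0]), t0=t0)
        num = propagate(p0, water_medium_small, geom, form="derivative",
                        oversample=4).traces[0]
        ana = uniform_disc_derivative_trace(t0, n_samp, FS, dist, a, V_SOUND)
        num_f, ana_f = lowpass(num, 6e6, FS), lowpass(ana, 6e6, FS)
        err = np.linalg.norm(num_f - ana_f) / np.linalg.norm(ana_f)
        assert err < 0.02
        # bipolar with its zero crossing at the disc-centre flight time
        i0 = np.argmax(num_f)
        i1 = np.argmin(num_f)
        assert num_f.max() > 0 > num_f.min()
        t_cross = geom.times[min(i0, i1) + np.argmin(
            np.abs(num_f[min(i0, i1):max(i0, i1)]))]
        assert t_cross == pytest.approx(dist / V_SOUND, rel=0.02)

    def test_amplitude_decays_as_inverse_distance(self, water_medium_small):
        # compare pulse integrals: bin-conserving, so the 1/d law is clean
        p0 = phantoms.disc_map((129, 129), 0.05e-3, (0, 0), 0.5e-3)
        sums = []
        for dist in (0.030, 0.060):
            data = propagate(p0, water_medium_small, single_detector(dist),
                             form="as_printed")
            sums.append(data.traces.sum())
        assert sums[0] / sums[1] == pytest.approx(2.0, rel=0.02)

    def test_linearity(self, water_medium_small, rng):
        geom = single_detector(0.040)
        q1 = phantoms.disc_map((129, 129), 0.05e-3, (0.5e-3, 0), 0.8e-3)
        q2 = phantoms.gaussian_map((129, 129), 0.05e-3, (-1e-3, 1e-3), 1e-3)
        a, b = 2.3, -0.7
        lhs = propagate(a * q1 + b * q2, water_medium_small, geom).traces
        rhs = (a * propagate(q1, water_medium_small, geom).traces
               + b * propagate(q2, water_medium_small, geom).traces)
        assert np.allclose(lhs, rhs, atol=1e-12 * np.abs(lhs).max())

    def test_arrival_reciprocity(self, water_medium_small):
        """Exchanging the source/detector sides of the ring preserves TOF."""
        c = 2e-3
        p_right = phantoms.point_map((129, 129), 0.05e-3, (c, 0.0))
        p_left = phantoms.point_map((129, 129), 0.05e-3, (-c, 0.0))
        det_right = ArrayGeometry(n_elements=1, ring_radius=0.040,
                                  sampling_rate=FS, n_samples=1300,
                                  element_angles=np.array([0.0]))
        det_left = ArrayGeometry(n_elements=1, ring_radius=0.040,
                                 sampling_rate=FS, n_samples=1300,
                                 element_angles=np.array([np.pi]))
        t1 = estimate_tof(
            propagate(p_left, water_medium_small, det_right).traces[0], FS)
        t2 = estimate_tof(
            propagate(p_right, water_medium_small, det_left).traces[0], FS)
        assert t1 == pytest.approx(t2, abs=0.5 / FS)

    def test_source_outside_ring_rejected(self, water_medium_small):
        p0 = phantoms.point_map((129, 129), 0.05e-3, (2e-3, 0))
        geom = ArrayGeometry(n_elements=4, ring_radius=0.030,
                             sampling_rate=FS, n_samples=64)
        with pytest.raises(ValueError, match="outside"):
            propagate(p0, water_medium_small, geom, source_offset=(0.029, 0))


class TestApplyResponse:
    def make_tone(self, freq, geom_samples=2048):
        t = np.arange(geom_samples) / FS
        geom = ArrayGeometry(n_elements=1, ring_radius=0.05,
                             sampling_rate=FS, n_samples=geom_samples,
                             element_angles=np.array([0.0]))
        from eatomo.forward import ChannelData
        return ChannelData(traces=np.sin(2 * np.pi * freq * t)[None, :],
                           sampling_rate=FS, geometry=geom)

    def test_in_band_tone_preserved(self):
        out = apply_response(self.make_tone(5e6))
        gain = np.abs(out.traces[0, 200:-200]).max()
        assert 20 * np.log10(gain) > -1.0

    def test_out_of_band_tone_suppressed(self):
        out = apply_response(self.make_tone(12e6))
        atten = np.abs(out.traces[0, 200:-200]).max()
        assert 20 * np.log10(atten) < -40.0

    def test_dc_removed(self):
        data = self.make_tone(5e6)
        data = data.copy_with(np.full_like(data.traces, 3.0))
        out = apply_response(data)
        assert np.abs(out.traces[0, 200:-200]).max() < 1e-6

    def test_filtered_nwave_spectrum_peaks_in_band(self, water_medium_small):
        p0 = phantoms.disc_map((129, 129), 0.05e-3, (0, 0), 0.3e-3)
        data = apply_response(propagate(p0, water_medium_small,
                                        single_detector(0.040)))
        spec = np.abs(np.fft.rfft(data.traces[0]))
        freqs = np.fft.rfftfreq(data.n_samples, 1 / FS)
        f_peak = freqs[np.argmax(spec)]
        assert 2e6 <= f_peak <= 6e6

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            apply_response(self.make_tone(5e6),
                           TransducerResponse(center_frequency=15e6,
                                              band=(10e6, 25e6)))


class TestAddNoise:
    def make_data(self, water_medium_small):
        p0 = phantoms.disc_map((129, 129), 0.05e-3, (0, 0), 0.3e-3)
        return propagate(p0, water_medium_small, single_detector(0.040))

    def test_same_seed_bit_identical(self, water_medium_small):
        data = self.make_data(water_medium_small)
        n1 = add_noise(data, 20.0, seed=42)
        n2 = add_noise(data, 20.0, seed=42)
        assert np.array_equal(n1.traces, n2.traces)

    def test_infinite_snr_is_identity(self, water_medium_small):
        data = self.make_data(water_medium_small)
        out = add_noise(data, np.inf, seed=0)
        assert np.array_equal(out.traces, data.traces)

    def test_target_snr_achieved(self, water_medium_small):
        data = self.make_data(water_medium_small)
        noisy = add_noise(data, 20.0, seed=1)
        resid = noisy.traces - data.traces
        measured = 20 * np.log10(np.abs(data.traces).max() / resid.std())
        assert 19.0 <= measured <= 21.0

    def test_zero_data_rejected(self, water_medium_small, ring128):
        data = propagate(np.zeros((129, 129)), water_medium_small, ring128)
        with pytest.raises(ValueError, match="zero"):
            add_noise(data, 20.0, seed=0)
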