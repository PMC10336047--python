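"""Preprocessing stages: band-pass, ERP subtraction, Laplacian, Morlet."""

import numpy as np
import pandas as pd
import pytest

from dyadsync.eeg_pipeline import (
    BANDS,
    EpochSet,
    band_freqs,
    bandpass_filter,
    default_cycles,
    morlet_phase,
    subtract_erp,
    surface_laplacian,
)
from dyadsync.montage import SCALP_LABELS, standard_montage


def make_epochs(data, sfreq=256.0, tmin=-2.0, ch_names=None):
    n_ep, n_ch, _ = data.shape
    if ch_names is None:
        ch_names = list(SCALP_LABELS[:n_ch])
    events = pd.DataFrame(
        dict(epoch=np.arange(n_ep), trial=np.arange(n_ep) // 3,
             rep=np.arange(n_ep) % 3 + 1)
    )
    return EpochSet(data, ch_names, sfreq, tmin, events, "p0")


@pytest.fixture()
def sine_epochs():
    sfreq = 256.0
    t = np.arange(int(4 * sfreq)) / sfreq - 2.0
    data = np.zeros((3, 2, len(t)))
    data[:, 0] = np.sin(2 * np.pi * 10 * t)
    data[:, 1] = np.sin(2 * np.pi * 100 * t)
    return make_epochs(data), t


class TestBandDefinitions:
    def test_band_edges_assigned_once(self):
        grid = band_freqs()
        assert len(grid) == len(set(grid))
        assert 8.0 in BANDS["alpha"] and 8.0 not in BANDS["theta"]
        assert 13.0 in BANDS["beta"] and 13.0 not in BANDS["alpha"]

    def test_cycles_linear(self):
        c = default_cycles(np.array([4.0, 25.0]))
        assert c[0] == 4.0 and c[1] == 8.0


class TestBandpass:
    def test_in_band_preserved_out_band_attenuated(self, sine_epochs):
        eps, t = sine_epochs
        out = bandpass_filter(eps, 1.0, 42.0)
        mid = slice(256, -256)  # avoid filter edge transients
        in_ratio = out.data[0, 0, mid].std() / eps.data[0, 0, mid].std()
        out_ratio = out.data[0, 1, mid].std() / eps.data[0, 1, mid].std()
        assert in_ratio == pytest.approx(1.0, abs=0.05)
        assert out_ratio < 10 ** (-20 / 20)  # >= 20 dB down one octave out

    def test_dc_removed(self):
        eps = make_epochs(np.full((3, 2, 1024), 7.5))
        out = bandpass_filter(eps, 1.0, 42.0)
        assert np.abs(out.data).max() < 0.5

    def test_incompatible_band_rejected(self):
        eps = make_epochs(np.zeros((3, 2, 256)), sfreq=64.0)
        with pytest.raises(ValueError):
            bandpass_filter(eps, 1.0, 42.0)


class TestERPSubtraction:
    def test_identical_epochs_zeroed(self, rng):
        wave = rng.normal(size=(1, 2, 512))
        eps = make_epochs(np.repeat(wave, 6, axis=0))
        out = subtract_erp(eps)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_group_mean_zero(self, rng):
        eps = make_epochs(rng.normal(size=(12, 3, 256)))
        out = subtract_erp(eps)
        for rep in (1, 2, 3):
            idx = out.events.index[out.events["rep"] == rep]
            assert np.allclose(out.data[idx].mean(axis=0), 0.0, atol=1e-12)

    def test_random_phase_oscillation_survives(self, rng):
        """Non-phase-locked (induced) activity keeps most of its power."""
        sfreq, n_s, n_ep = 256.0, 1024, 30
        t = np.arange(n_s) / sfreq
        data = np.stack(
            [np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))
             for _ in range(n_ep)]
        )[:, None, :]
        eps = make_epochs(data)
        out = subtract_erp(eps)
        power_in = (data**2).mean()
        power_out = (out.data**2).mean()
        assert power_out > 0.9 * power_in

    def test_single_epoch_group_rejected(self, rng):
        data = rng.normal(size=(1, 2, 128))
        eps = make_epochs(data)
        with pytest.raises(ValueError, match="single epoch"):
            subtract_erp(eps)


class TestSurfaceLaplacian:
    def test_uniform_potential_maps_to_zero(self):
        eps = make_epochs(np.full((2, 25, 64), 3.0), ch_names=list(SCALP_LABELS))
        out = surface_laplacian(eps)
        assert np.abs(out.data).max() < 1e-6 * 3.0 or np.allclose(
            out.data, 0.0, atol=1e-4
        )

    def test_linearity(self, rng):
        x = rng.normal(size=(2, 25, 32))
        y = rng.normal(size=(2, 25, 32))
        a, b = 1.7, -0.4
        ex = make_epochs(x, ch_names=list(SCALP_LABELS))
        ey = make_epochs(y, ch_names=list(SCALP_LABELS))
        exy = make_epochs(a * x + b * y, ch_names=list(SCALP_LABELS))
        lx = surface_laplacian(ex).data
        ly = surface_laplacian(ey).data
        lxy = surface_laplacian(exy).data
        assert np.allclose(lxy, a * lx + b * ly, rtol=1e-6, atol=1e-8)

    def test_mastoids_dropped(self, rng):
        labels = list(SCALP_LABELS) + ["M1", "M2"]
        eps = make_epochs(rng.normal(size=(2, 27, 32)), ch_names=labels)
        out = surface_laplacian(eps)
        assert out.ch_names == list(SCALP_LABELS)

    def test_matches_reference_implementation(self, rng):
        """Agrees with the CSD of an established EEG package on a
        focal-source fixture, given the same electrode geometry."""
        import warnings

        import mne

        from dyadsync.eeg_pipeline import _fit_sphere

        data = rng.normal(size=(3, 25, 64))
        # add a focal bump at Cz
        cz = list(SCALP_LABELS).index("Cz")
        data[:, cz, :] += 5.0
        eps = make_epochs(data, ch_names=list(SCALP_LABELS))
        ours = surface_laplacian(eps).data

        montage = standard_montage().set_index("label")
        pos = montage.loc[list(SCALP_LABELS), ["x", "y", "z"]].to_numpy()
        center = _fit_sphere(pos)
        info = mne.create_info(list(SCALP_LABELS), eps.sfreq, "eeg")
        mne_eps = mne.EpochsArray(data * 1e-6, info, tmin=eps.tmin,
                                  verbose="error")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mne_eps.set_montage(
                mne.channels.make_dig_montage(
                    ch_pos={c: pos[i] for i, c in enumerate(SCALP_LABELS)},
                    coord_frame="head",
                )
            )
            ref = mne.preprocessing.compute_current_source_density(
                mne_eps, sphere=(*center, 1.0), verbose="error"
            ).get_data()
        # same spline, same geometry, unit sphere radius: proportional maps
        r = np.corrcoef(ours.ravel(), ref.ravel())[0, 1]
        assert r > 0.999

    def test_degenerate_montage_rejected(self, rng):
        montage = standard_montage()
        montage[["x", "z"]] = 0.0  # collapse to a line
        eps = make_epochs(rng.normal(size=(1, 25, 8)),
                          ch_names=list(SCALP_LABELS))
        with pytest.raises(ValueError):
            surface_laplacian(eps, montage=montage)


class TestMorletPhase:
    def test_phase_slope_matches_frequency(self):
        sfreq, f0 = 256.0, 10.0
        t = np.arange(int(4 * sfreq)) / sfreq - 2.0
        data = np.cos(2 * np.pi * f0 * t)[None, None, :] * np.ones((3, 1, 1))
        eps = make_epochs(data)
        pt = morlet_phase(eps, freqs=np.array([f0]))
        sl = slice(len(t) // 2 - 128, len(t) // 2 + 128)
        phase = np.unwrap(pt.angle[0, 0, 0, sl].astype(float))
        slope = np.polyfit(t[sl], phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * f0, rel=0.01)

    def test_identical_signals_zero_phase_difference(self, rng):
        data = rng.normal(size=(2, 1, 1024))
        data = np.concatenate([data, data], axis=1)
        eps = make_epochs(data, ch_names=["Cz", "Pz"])
        pt = morlet_phase(eps, freqs=np.array([10.0]))
        assert np.allclose(pt.angle[:, 0], pt.angle[:, 1], atol=1e-6)

    def test_matches_analytic_signal_phase(self):
        """Morlet phase of a narrowband signal tracks the Hilbert
        analytic-signal phase away from the edges."""
        from scipy.signal import hilbert

        sfreq = 256.0
        t = np.arange(int(4 * sfreq)) / sfreq - 2.0
        x = np.cos(2 * np.pi * 10 * t) + 0.3 * np.cos(2 * np.pi * 10.5 * t)
        eps = make_epochs(x[None, None, :])
        pt = morlet_phase(eps, freqs=np.array([10.0]))
        ref = np.angle(hilbert(x))
        mid = slice(256, -256)
        d = np.angle(np.exp(1j * (pt.angle[0, 0, 0, mid] - ref[mid])))
        assert np.abs(d).max() < 0.1

    def test_angles_in_range_and_finite(self, rng):
        eps = make_epochs(rng.normal(size=(2, 2, 1024)),
                          ch_names=["Cz", "Pz"])
        pt = morlet_phase(eps, freqs=np.array([8.0, 10.0]))
        assert np.all(np.isfinite(pt.angle))
        assert pt.angle.min() >= -np.pi - 1e-6
        assert pt.angle.max() <= np.pi + 1e-6

    def test_above_nyquist_rejected(self, rng):
        eps = make_epochs(rng.normal(size=(1, 1, 256)), sfreq=40.0,
                          ch_names=["Cz"])
        with pytest.raises(ValueError):
            morlet_phase(eps, freqs=np.array([25.0]))

    def test_low_cycles_warns(self, rng):
        eps = make_epochs(rng.normal(size=(1, 1, 1024)), ch_names=["Cz"])
        with pytest.warns(UserWarning, match="cycles"):
            morlet_phase(eps, freqs=np.array([10.0]),
                         n_cycles=np.array([2.0]))


class TestDeterminismAndOrder:
    def test_stages_deterministic(self, rng):
        data = rng.normal(size=(6, 25, 256))
        eps = make_epochs(data, ch_names=list(SCALP_LABELS))
        a = subtract_erp(surface_laplacian(bandpass_filter(eps)))
        b = subtract_erp(surface_laplacian(bandpass_filter(eps)))
        assert np.array_equal(a.data, b.data)

    def test_laplacian_and_erp_commute(self, rng):
        """Both stages are linear, so their order does not matter."""
        data = rng.normal(size=(6, 25, 128))
        eps = make_epochs(data, ch_names=list(SCALP_LABELS))
        ab = subtract_erp(surface_laplacian(eps)).data
        ba = surface_laplacian(subtract_erp(eps)).data
        assert np.allclose(ab, ba, atol=1e-10)


class TestEpochSetIO:
    def test_h5_roundtrip(self, rng, tmp_path):
        eps = make_epochs(rng.normal(size=(4, 3, 128)).astype(np.float32))
        path = tmp_path / "epochs.h5"
        eps.save(path)
        back = EpochSet.load(path)
        assert np.array_equal(back.data, eps.data)
        assert back.ch_names == eps.ch_names
        assert back.sfreq == eps.sfreq
        pd.testing.assert_frame_equal(
            back.events[["epoch", "trial", "rep"]],
            eps.events[["epoch", "trial", "rep"]],
            check_dtype=False,
        )
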