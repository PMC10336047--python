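"""Preprocessing from epoched EEG to single-trial phase angles.

The stage order is fixed: band-pass filter -> surface Laplacian ->
ERP subtraction -> complex Morlet wavelet phase extraction.  The Laplacian
and ERP subtraction are both linear, so their relative order does not
change the result; the Laplacian is applied first, before any
angle-related step, to attenuate volume conduction at the channel level.

Phase angles are produced per epoch x channel x frequency x sample on a
1 Hz grid within three bands (theta 4-7 Hz, alpha 8-12 Hz, beta 13-25 Hz;
band edges are assigned to the band whose nominal range starts there, so
8 Hz belongs to alpha and 13 Hz to beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from scipy import signal

from .montage import MASTOID_LABELS, SCALP_LABELS, standard_montage

#: 1 Hz frequency grids per band; edges deduplicated (8 -> alpha, 13 -> beta)
BANDS: dict[str, np.ndarray] = {
    "theta": np.arange(4, 8, dtype=float),
    "alpha": np.arange(8, 13, dtype=float),
    "beta": np.arange(13, 26, dtype=float),
}


def band_freqs(bands: list[str] | None = None) -> np.ndarray:
    """Concatenated frequency grid for the requested bands (default all)."""
    bands = list(BANDS) if bands is None else bands
    return np.concatenate([BANDS[b] for b in bands])


def default_cycles(freqs: np.ndarray) -> np.ndarray:
    """Morlet cycles rising linearly 4 -> 8 over 4 -> 25 Hz."""
    freqs = np.asarray(freqs, dtype=float)
    return np.clip(4.0 + 4.0 * (freqs - 4.0) / 21.0, 3.0, 8.0)


@dataclass
class EpochSet:
    """Epoched multichannel EEG: data is (epochs, channels, samples) in µV.

    ``events`` maps epoch index to (trial, rep); ``tmin`` is the time of
    the first sample relative to feedback onset.
    """

    data: np.ndarray
    ch_names: list[str]
    sfreq: float
    tmin: float
    events: pd.DataFrame
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if len(self.events) != self.data.shape[0]:
            raise ValueError("events must have one row per epoch")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), events=self.events.copy())

    def pick(self, labels: list[str]) -> "EpochSet":
        idx = [self.ch_names.index(l) for l in labels]
        return replace(self, data=self.data[:, idx, :], ch_names=list(labels))

    def time_index(self, t: float) -> int:
        return int(round((t - self.tmin) * self.sfreq))

    # -- persistence (HDF5) -------------------------------------------------

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.attrs["sfreq"] = self.sfreq
            f.attrs["tmin"] = self.tmin
            f.attrs["participant_id"] = self.participant_id
            f.create_dataset(
                "ch_names", data=np.array(self.ch_names, dtype="S16")
            )
            ev = f.create_group("events")
            for col in self.events.columns:
                ev.create_dataset(col, data=self.events[col].to_numpy())

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as f:
            events = pd.DataFrame(
                {col: f["events"][col][()] for col in f["events"]}
            )
            return cls(
                data=f["data"][()],
                ch_names=[c.decode() for c in f["ch_names"][()]],
                sfreq=float(f.attrs["sfreq"]),
                tmin=float(f.attrs["tmin"]),
                events=events,
                participant_id=str(f.attrs["participant_id"]),
            )


def epochs_from_edf(path, event_samples, sfreq_out=None, tmin=-2.0, tmax=2.0,
                    events: pd.DataFrame | None = None,
                    participant_id: str = "") -> EpochSet:
    """Ingest a continuous EDF recording and cut feedback-locked epochs.

    ``event_samples`` are feedback-onset sample indices in the raw
    recording; ``events`` optionally supplies the (trial, rep) table.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sf = raw.info["sfreq"]
    data = raw.get_data(units="uV")
    n0, n1 = int(round(tmin * sf)), int(round(tmax * sf))
    epochs = np.stack([data[:, s + n0:s + n1] for s in event_samples])
    if events is None:
        events = pd.DataFrame(
            dict(epoch=np.arange(len(event_samples)),
                 trial=np.arange(len(event_samples)) // 3,
                 rep=np.arange(len(event_samples)) % 3 + 1)
        )
    return EpochSet(epochs, list(raw.ch_names), sf, tmin, events,
                    participant_id)


# ---------------------------------------------------------------------------
# Stages


def bandpass_filter(epochs: EpochSet, low: float = 1.0, high: float = 42.0,
                    order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass applied along samples."""
    nyq = epochs.sfreq / 2.0
    if high >= nyq:
        raise ValueError(
            f"high edge {high} Hz incompatible with sfreq {epochs.sfreq}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=epochs.sfreq,
                        output="sos")
    out = epochs.copy()
    out.data = signal.sosfiltfilt(sos, epochs.data.astype(float), axis=-1)
    return out


def subtract_erp(epochs: EpochSet, groupby: str = "rep") -> EpochSet:
    """Remove the across-epoch mean waveform per channel within each
    condition group (default: feedback repetition), leaving induced
    (non-phase-locked) activity."""
    out = epochs.copy()
    out.data = out.data.astype(float)
    groups = epochs.events.groupby(groupby).indices
    for key, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(
                f"group {groupby}={key!r} has a single epoch; "
                "ERP subtraction would zero it"
            )
        out.data[idx] -= out.data[idx].mean(axis=0, keepdims=True)
    return out


def _fit_sphere(pos: np.ndarray) -> np.ndarray:
    """Least-squares sphere center of the electrode cloud."""
    A = np.column_stack([2 * pos, np.ones(len(pos))])
    b = (pos**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def _spline_matrices(positions: np.ndarray, m: int, n_legendre: int):
    """Perrin spherical-spline G and H matrices on the unit sphere.

    Electrodes are projected onto the best-fitting sphere before the
    angular distances are computed.
    """
    pos = np.asarray(positions, dtype=float)
    pos = pos - _fit_sphere(pos)
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise ValueError("electrode at sphere center")
    unit = pos / norms[:, None]
    cosang = np.clip(unit @ unit.T, -1.0, 1.0)
    if np.linalg.matrix_rank(unit) < 3:
        raise ValueError("degenerate (coplanar) montage")
    n = np.arange(1, n_legendre + 1, dtype=float)
    g_coef = (2 * n + 1) / (n * (n + 1)) ** m
    h_coef = -(2 * n + 1) / (n * (n + 1)) ** (m - 1)
    # evaluate sum_n c_n P_n(x) via a Legendre series with zero 0th term
    G = npleg.legval(cosang, np.concatenate([[0.0], g_coef])) / (4 * np.pi)
    H = -npleg.legval(cosang, np.concatenate([[0.0], h_coef])) / (4 * np.pi)
    return G, H


def surface_laplacian(
    epochs: EpochSet,
    montage: pd.DataFrame | None = None,
    m: int = 4,
    lam: float = 1e-5,
    n_legendre: int = 50,
) -> EpochSet:
    """Spherical-spline (Perrin-style) surface Laplacian, per time sample.

    Mastoid channels are dropped; the operator is linear in the input and
    maps a spatially uniform potential to (approximately) zero.
    """
    scalp = [c for c in epochs.ch_names if c not in MASTOID_LABELS]
    eps = epochs.pick(scalp)
    montage = standard_montage() if montage is None else montage
    pos = montage.set_index("label").loc[scalp, ["x", "y", "z"]].to_numpy(float)
    G, H = _spline_matrices(pos, m=m, n_legendre=n_legendre)
    n_ch = len(scalp)
    Gs = G + lam * np.eye(n_ch)
    Gs_inv = np.linalg.inv(Gs)
    col_sums = Gs_inv.sum(axis=0)  # 1 x ch
    total = col_sums.sum()

    n_ep, _, n_s = eps.data.shape
    flat = eps.data.astype(float).transpose(0, 2, 1).reshape(-1, n_ch)
    d = flat @ Gs_inv
    C = d - np.outer(d.sum(axis=1) / total, col_sums)
    lap = C @ H.T
    out = eps.copy()
    out.data = lap.reshape(n_ep, n_s, n_ch).transpose(0, 2, 1)
    return out


@dataclass
class PhaseTensor:
    """Instantaneous phase per (epoch, channel, frequency, sample), radians.

    ``edge_margin`` gives, per frequency, the number of samples at each
    epoch edge lying outside the valid convolution support (half the
    wavelet length); those samples must not enter ISPC windows.
    """

    angle: np.ndarray
    freqs: np.ndarray
    ch_names: list[str]
    sfreq: float
    tmin: float
    events: pd.DataFrame
    edge_margin: np.ndarray = field(default=None)  # type: ignore[assignment]
    participant_id: str = ""

    def band_index(self, band: str) -> np.ndarray:
        """Indices into ``freqs`` belonging to a named band."""
        want = BANDS[band]
        idx = np.array([np.flatnonzero(self.freqs == f) for f in want])
        if any(len(i) == 0 for i in idx):
            raise ValueError(f"frequency grid does not cover band {band!r}")
        return idx.ravel()

    def valid_window(self, t_start: float, t_stop: float) -> None:
        """Raise if [t_start, t_stop) touches edge-flagged samples at any
        frequency."""
        n_s = self.angle.shape[-1]
        i0 = int(round((t_start - self.tmin) * self.sfreq))
        i1 = int(round((t_stop - self.tmin) * self.sfreq))
        worst = int(self.edge_margin.max())
        if i0 < worst or i1 > n_s - worst:
            raise ValueError(
                f"window [{t_start}, {t_stop}) s overlaps the wavelet edge "
                f"margin ({worst} samples)"
            )


def morlet_phase(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    n_cycles: np.ndarray | None = None,
) -> PhaseTensor:
    """Complex Morlet wavelet phase per frequency of the grid.

    Frequencies default to the full theta/alpha/beta 1 Hz grid; cycle
    counts default to :func:`default_cycles`.
    """
    import warnings

    from mne.time_frequency import tfr_array_morlet

    freqs = band_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    if n_cycles is None:
        n_cycles = default_cycles(freqs)
    n_cycles = np.asarray(n_cycles, dtype=float)
    if np.any(n_cycles < 3):
        warnings.warn("fewer than 3 Morlet cycles gives unstable phase",
                      stacklevel=2)
    if np.any(freqs >= epochs.sfreq / 2):
        raise ValueError("frequency grid exceeds the Nyquist frequency")
    angle = tfr_array_morlet(
        epochs.data.astype(float), epochs.sfreq, freqs=freqs,
        n_cycles=n_cycles, output="phase", verbose="error",
    )
    margin = np.ceil(n_cycles / (2.0 * freqs) * epochs.sfreq).astype(int)
    return PhaseTensor(
        angle=angle.astype(np.float32),
        freqs=freqs,
        ch_names=list(epochs.ch_names),
        sfreq=epochs.sfreq,
        tmin=epochs.tmin,
        events=epochs.events.copy(),
        edge_margin=margin,
        participant_id=epochs.participant_id,
    )


def preprocess(
    epochs: EpochSet,
    montage: pd.DataFrame | None = None,
    bands: list[str] | None = None,
    freqs: np.ndarray | None = None,
    low: float = 1.0,
    high: float = 42.0,
) -> PhaseTensor:
    """Full preprocessing chain: band-pass -> Laplacian -> ERP subtraction
    -> Morlet phase."""
    if freqs is None:
        freqs = band_freqs(bands)
    out = bandpass_filter(epochs, low=low, high=high)
    out = surface_laplacian(out, montage=montage)
    out = subtract_erp(out)
    return morlet_phase(out, freqs=freqs)
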