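"""Synthetic band-limited oscillatory EEG with planted phase coupling.

Each channel is a sum of narrowband Gaussian "oscillators" (one per
frequency band) plus 1/f background noise.  Narrowband noise has a
randomly drifting phase, so two independent channels decorrelate within
a trial and single-trial phase clustering sits at chance.

Coupling is planted per (channel pair, band, time window, feedback
repetition): within the window, the destination channel's band component
is replaced (cross-faded at the edges) by a copy of the source channel's
analytic band signal whose instantaneous phase is offset by i.i.d.
von Mises(0, kappa) draws.  The raw phase difference between the pair is
then exactly von Mises distributed, so the expected phase-clustering value
of the planted pair is the von Mises mean resultant length I1(k)/I0(k) -
an analytic oracle recorded in the manifest.  Plans may instead tie kappa
to the trial's ground-truth prediction error (monotone scaling), to plant
PE-dependent synchrony.

Inter-brain plans use the same mechanism across the two participants'
recordings for the same trial, so the downstream pipeline treats intra
and inter pairs identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from ..eeg_pipeline import EpochSet
from ..montage import MASTOID_LABELS, SCALP_LABELS
from ..task_behavior import Session
from .behavior import GroundTruthManifest

#: continuous band ranges (Hz) used by the oscillator generator
BAND_RANGES = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 25.0)}

WINDOWS = {"early": (0.0, 0.5), "late": (0.5, 1.0)}


def vonmises_resultant(kappa: float) -> float:
    """Mean resultant length of a von Mises distribution, I1(k)/I0(k)."""
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


@dataclass(frozen=True)
class CouplingSpec:
    """One planted coupling: pair of channels, band, window, condition.

    ``participants`` are indices (0, 1) within the dyad; equal indices give
    intra-brain coupling, unequal inter-brain.  ``rep`` selects the
    feedback repetition (1-3) whose epochs are coupled.  If ``pe_linked``,
    kappa is scaled per epoch by the destination participant's normalized
    ground-truth prediction error (kappa is then the maximum).
    """

    pair: tuple[str, str]
    band: str
    window: str = "early"
    rep: int = 2
    kappa: float = 10.0
    participants: tuple[int, int] = (0, 0)
    pe_linked: bool = False

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.band not in BAND_RANGES:
            raise ValueError(f"unknown band {self.band!r}")
        if self.window not in WINDOWS:
            raise ValueError(f"unknown window {self.window!r}")
        if self.rep not in (1, 2, 3):
            raise ValueError("rep must be 1, 2 or 3")


@dataclass
class EEGSimConfig:
    """Study conditions for the EEG generator.

    Defaults follow the recording setup being emulated: 1024 Hz sampling,
    epochs from -2 to 2 s around each feedback onset, 25 scalp channels
    plus two mastoids.
    """

    sfreq: float = 1024.0
    tmin: float = -2.0
    tmax: float = 2.0
    channels: tuple[str, ...] = SCALP_LABELS + MASTOID_LABELS
    bands: tuple[str, ...] = ("theta", "alpha", "beta")
    amplitudes: dict = field(
        default_factory=lambda: {"theta": 1.0, "alpha": 1.5, "beta": 0.8}
    )
    noise_amp: float = 1.0
    noise_exponent: float = 1.0
    coupling: list[CouplingSpec] = field(default_factory=list)
    crossfade: float = 0.05  # s, raised-cosine ramp at window edges
    #: plant oscillators and couplings at the current-source-density level
    #: and emit their regularized inverse image as scalp potentials, so a
    #: surface-Laplacian stage recovers the planted structure instead of
    #: smearing it across neighboring channels
    csd_space: bool = True
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round((self.tmax - self.tmin) * self.sfreq))

    def validate(self) -> None:
        labels = set(self.channels)
        seen = set()
        for plan in self.coupling:
            if not set(plan.pair) <= labels:
                raise ValueError(f"coupling pair {plan.pair} not in montage")
            key = (plan.participants, plan.pair, plan.band, plan.window,
                   plan.rep)
            if key in seen:
                raise ValueError(f"overlapping coupling plans for {key}")
            seen.add(key)


def _analytic_band_noise(rng, n_ep, n_s, sfreq, f_lo, f_hi, amp):
    """Analytic (one-sided spectrum) narrowband Gaussian noise."""
    freqs = np.fft.fftfreq(n_s, d=1.0 / sfreq)
    band = (freqs >= f_lo) & (freqs < f_hi)
    spec = np.zeros((n_ep, n_s), dtype=np.complex128)
    nb = int(band.sum())
    spec[:, band] = rng.standard_normal((n_ep, nb)) + 1j * rng.standard_normal(
        (n_ep, nb)
    )
    z = np.fft.ifft(spec, axis=-1)
    z *= amp / max(z.real.std(), 1e-30)
    return z.astype(np.complex64)


def _inverse_csd_matrix(channels) -> tuple[np.ndarray, list[int]]:
    """Pseudo-inverse of the spherical-spline Laplacian over the scalp
    channels (the spatially uniform mode, invisible to the Laplacian, is
    dropped).  Returns the matrix and the scalp channel indices."""
    from ..eeg_pipeline import _spline_matrices
    from ..montage import standard_montage

    scalp_idx = [i for i, c in enumerate(channels)
                 if c not in MASTOID_LABELS]
    scalp = [channels[i] for i in scalp_idx]
    montage = standard_montage().set_index("label")
    pos = montage.loc[scalp, ["x", "y", "z"]].to_numpy(float)
    G, H = _spline_matrices(pos, m=4, n_legendre=50)
    n = len(scalp)
    Gs_inv = np.linalg.inv(G + 1e-5 * np.eye(n))
    col = Gs_inv.sum(axis=0)
    T = H @ (Gs_inv - np.outer(col, col) / col.sum())
    return np.linalg.pinv(T, rcond=1e-8), scalp_idx


def _pink_noise(rng, n_ep, n_s, sfreq, exponent, amp):
    freqs = np.fft.rfftfreq(n_s, d=1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_ep, len(freqs)))
        + 1j * rng.standard_normal((n_ep, len(freqs)))
    ) * shape
    x = np.fft.irfft(spec, n=n_s, axis=-1)
    x *= amp / max(x.std(), 1e-30)
    return x.astype(np.float32)


def simulate_eeg(
    dyads: list[tuple[Session, Session]],
    config: EEGSimConfig,
    manifest: GroundTruthManifest | None = None,
) -> tuple[dict[str, EpochSet], GroundTruthManifest]:
    """Generate epoched recordings for every participant of every dyad.

    Returns a dict participant_id -> EpochSet and the manifest extended
    with one entry per (dyad, coupling plan) recording the planted kappa,
    its analytic expected phase-clustering value, and the realized mean
    resultant of the drawn phase offsets.
    """
    config.validate()
    if manifest is None:
        manifest = GroundTruthManifest(seed=config.seed, model="")
    rng = np.random.default_rng(config.seed)
    n_s = config.n_samples
    ch_index = {c: i for i, c in enumerate(config.channels)}
    out: dict[str, EpochSet] = {}

    for d, (sess_a, sess_b) in enumerate(dyads):
        sessions = (sess_a, sess_b)
        n_trials = len(sess_a.trials)
        n_ep = 3 * n_trials
        events = pd.DataFrame(
            dict(
                epoch=np.arange(n_ep),
                trial=np.arange(n_ep) // 3,
                rep=np.arange(n_ep) % 3 + 1,
            )
        )
        data = [
            np.zeros((n_ep, len(config.channels), n_s), dtype=np.float32)
            for _ in range(2)
        ]
        # channels whose analytic band signal must be kept for coupling
        needed: dict[str, set[tuple[int, int]]] = {b: set() for b in config.bands}
        for plan in config.coupling:
            for role in range(2):
                needed[plan.band].add(
                    (plan.participants[role], ch_index[plan.pair[role]])
                )

        cache: dict[tuple[str, int, int], np.ndarray] = {}
        for band in config.bands:
            f_lo, f_hi = BAND_RANGES[band]
            amp = config.amplitudes.get(band, 1.0)
            for ip in range(2):
                for ci in range(len(config.channels)):
                    z = _analytic_band_noise(
                        rng, n_ep, n_s, config.sfreq, f_lo, f_hi, amp
                    )
                    data[ip][:, ci, :] += z.real
                    if (ip, ci) in needed[band]:
                        cache[(band, ip, ci)] = z

        for plan in config.coupling:
            _apply_plan(plan, cache, data, events, config, sessions, manifest,
                        ch_index, rng, dyad_index=d)

        inv_csd = None
        if config.csd_space:
            inv_csd, scalp_idx = _inverse_csd_matrix(config.channels)
        for ip, sess in enumerate(sessions):
            for ci in range(len(config.channels)):
                data[ip][:, ci, :] += _pink_noise(
                    rng, n_ep, n_s, config.sfreq, config.noise_exponent,
                    config.noise_amp,
                )
            if inv_csd is not None:
                data[ip][:, scalp_idx, :] = np.einsum(
                    "ij,ejs->eis", inv_csd.astype(np.float32),
                    data[ip][:, scalp_idx, :],
                )
            out[sess.participant_id] = EpochSet(
                data=data[ip],
                ch_names=list(config.channels),
                sfreq=config.sfreq,
                tmin=config.tmin,
                events=events.copy(),
                participant_id=sess.participant_id,
            )
    return out, manifest


def _pe_per_epoch(manifest, pid, events) -> np.ndarray:
    """Per-epoch PE (NaN for FB1 epochs) from the behavior ground truth."""
    pe = manifest.pe(pid)  # ordered (trial asc, FB1->FB2 then FB2->FB3)
    out = np.full(len(events), np.nan)
    k = 0
    for t in range(events["trial"].max() + 1):
        for rep in (2, 3):
            sel = (events["trial"] == t) & (events["rep"] == rep)
            out[sel.to_numpy()] = pe[k]
            k += 1
    return out


def _apply_plan(plan, cache, data, events, config, sessions, manifest,
                ch_index, rng, dyad_index):
    ip_s, ip_d = plan.participants
    ci_s, ci_d = ch_index[plan.pair[0]], ch_index[plan.pair[1]]
    z_src = cache[(plan.band, ip_s, ci_s)]
    z_dst = cache[(plan.band, ip_d, ci_d)]
    t0, t1 = WINDOWS[plan.window]
    w0 = int(round((t0 - config.tmin) * config.sfreq))
    w1 = int(round((t1 - config.tmin) * config.sfreq))
    sel = np.flatnonzero((events["rep"] == plan.rep).to_numpy())
    n_w = w1 - w0

    if plan.pe_linked:
        pe = _pe_per_epoch(manifest, sessions[ip_d].participant_id, events)
        pe_sel = pe[sel]
        lo, hi = np.nanmin(pe_sel), np.nanmax(pe_sel)
        scale = (pe_sel - lo) / (hi - lo) if hi > lo else np.ones_like(pe_sel)
        kappas = plan.kappa * np.nan_to_num(scale)
    else:
        kappas = np.full(len(sel), plan.kappa)

    ramp_n = min(int(round(config.crossfade * config.sfreq)), n_w // 4)
    weight = np.ones(n_w)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        weight[:ramp_n] = ramp
        weight[-ramp_n:] = ramp[::-1]

    resultants = np.empty(len(sel))
    for j, (e, kap) in enumerate(zip(sel, kappas)):
        delta = rng.vonmises(0.0, kap, size=n_w)
        resultants[j] = np.abs(np.exp(1j * delta).mean())
        coupled = (z_src[e, w0:w1] * np.exp(1j * delta)).real
        own = z_dst[e, w0:w1].real
        data[ip_d][e, ci_d, w0:w1] += weight * (coupled - own)

    manifest.coupling.append(
        dict(
            dyad=dyad_index,
            participants=plan.participants,
            pair=plan.pair,
            band=plan.band,
            window=plan.window,
            rep=plan.rep,
            kappa=plan.kappa,
            pe_linked=plan.pe_linked,
            expected_ispc=vonmises_resultant(plan.kappa),
            realized_resultant_mean=float(resultants.mean()),
        )
    )
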