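"""Single-trial inter-site phase clustering (ISPC).

ISPC of a channel pair is the magnitude of the time-averaged unit phasor
of their phase difference within a window:

    ISPC = | mean_t exp(i * (phi_i(t) - phi_j(t))) |

Clustering is over time samples within the single trial's window, so each
feedback event contributes one value per pair x frequency; values are then
averaged over the frequencies of a band and tabulated per (pair, band,
window, feedback event).  Intra-brain mode enumerates the 300 unordered
scalp pairs of one head; inter-brain mode the 625 ordered cross-head
pairs of a dyad.  Mastoids are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

from .eeg_pipeline import BANDS, PhaseTensor
from .montage import MASTOID_LABELS, SCALP_LABELS

#: analysis windows in seconds after feedback onset, half-open
WINDOWS: dict[str, tuple[float, float]] = {"early": (0.0, 0.5), "late": (0.5, 1.0)}


@dataclass(frozen=True)
class PairSet:
    """Electrode pairs for one connectivity mode."""

    mode: str  # "intra" | "inter"
    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)


def enumerate_pairs(mode: str, labels: list[str] | None = None) -> PairSet:
    """All unordered within-head pairs (intra) or the full cross product of
    head-A x head-B channels (inter); mastoids excluded."""
    labels = list(SCALP_LABELS) if labels is None else [
        l for l in labels if l not in MASTOID_LABELS
    ]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate channel labels")
    if mode == "intra":
        pairs = tuple(combinations(labels, 2))
    elif mode == "inter":
        pairs = tuple(product(labels, labels))
    else:
        raise ValueError(f"mode must be 'intra' or 'inter', got {mode!r}")
    return PairSet(mode=mode, pairs=pairs)


def ispc_trial(phase_i: np.ndarray, phase_j: np.ndarray,
               axis: int = -1) -> np.ndarray:
    """ISPC of two phase series over the given axis; result in [0, 1]."""
    phase_i, phase_j = np.asarray(phase_i), np.asarray(phase_j)
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase series must share a shape")
    return np.abs(np.exp(1j * (phase_i - phase_j)).mean(axis=axis))


def band_window_aggregate(per_freq_ispc: np.ndarray, axis: int = 0) -> np.ndarray:
    """Equal-weight mean of per-frequency ISPC values within a band."""
    per_freq_ispc = np.asarray(per_freq_ispc)
    if np.any(~np.isfinite(per_freq_ispc)):
        raise ValueError("missing per-frequency ISPC values")
    return per_freq_ispc.mean(axis=axis)


def _window_samples(phases: PhaseTensor, window: str) -> tuple[int, int]:
    t0, t1 = WINDOWS[window]
    phases.valid_window(t0, t1)
    i0 = int(round((t0 - phases.tmin) * phases.sfreq))
    i1 = int(round((t1 - phases.tmin) * phases.sfreq))
    return i0, i1


def _check_alignment(pa: PhaseTensor, pb: PhaseTensor) -> None:
    ea = pa.events[["trial", "rep"]].to_numpy()
    eb = pb.events[["trial", "rep"]].to_numpy()
    if ea.shape != eb.shape:
        raise ValueError(
            f"dyad epoch counts differ: {ea.shape[0]} vs {eb.shape[0]}"
        )
    bad = np.flatnonzero((ea != eb).any(axis=1))
    if bad.size:
        raise ValueError(
            "dyad epochs not aligned by (trial, rep); offending epochs: "
            f"{bad[:10].tolist()}"
        )


def _pair_matrix(z_a: np.ndarray, z_b: np.ndarray) -> np.ndarray:
    """Mean cross-phasor magnitude for all channel pairs.

    ``z_*`` are unit phasors (channels, samples); returns (ch_a, ch_b).
    """
    n = z_a.shape[-1]
    return np.abs(z_a @ z_b.conj().T) / n


def build_connectivity(
    phases_a: PhaseTensor,
    phases_b: PhaseTensor | None = None,
    bands: list[str] | None = None,
    windows: list[str] | None = None,
    dyad_id: str = "",
    unit_id: str = "",
) -> pd.DataFrame:
    """Full single-trial ISPC table.

    Intra mode (``phases_b`` omitted): all scalp pairs within
    ``phases_a``.  Inter mode: pairs channel i of participant A with
    channel j of participant B for the same (trial, rep) epoch.

    Returns a long DataFrame with columns dyad, unit, trial, rep, chan_i,
    chan_j, pair, band, window, ispc.
    """
    inter = phases_b is not None
    mode = "inter" if inter else "intra"
    if inter:
        _check_alignment(phases_a, phases_b)
    else:
        phases_b = phases_a
    bands = [b for b in BANDS if set(BANDS[b]) <= set(phases_a.freqs)] \
        if bands is None else bands
    windows = list(WINDOWS) if windows is None else windows

    scalp = [c for c in phases_a.ch_names if c not in MASTOID_LABELS]
    idx_a = [phases_a.ch_names.index(c) for c in scalp]
    idx_b = [phases_b.ch_names.index(c) for c in scalp]
    pair_set = enumerate_pairs(mode, scalp)
    lab_pos = {c: k for k, c in enumerate(scalp)}
    rows_i = np.array([lab_pos[i] for i, _ in pair_set.pairs])
    rows_j = np.array([lab_pos[j] for _, j in pair_set.pairs])
    chan_i = np.array([i for i, _ in pair_set.pairs])
    chan_j = np.array([j for _, j in pair_set.pairs])

    n_ep = phases_a.angle.shape[0]
    n_pairs = len(pair_set)
    frames = []
    for band in bands:
        f_idx = phases_a.band_index(band)
        for window in windows:
            i0, i1 = _window_samples(phases_a, window)
            # unit phasors restricted to scalp channels, band, window
            za = np.exp(1j * phases_a.angle[:, idx_a][:, :, f_idx, i0:i1])
            zb = np.exp(1j * phases_b.angle[:, idx_b][:, :, f_idx, i0:i1]) \
                if inter else za
            n_w = i1 - i0
            vals = np.empty((n_ep, n_pairs))
            for e in range(n_ep):
                # per-frequency cross-phasor magnitudes, then band mean
                mats = np.abs(
                    np.einsum("cfs,dfs->fcd", za[e], zb[e].conj())
                ) / n_w
                band_mat = band_window_aggregate(mats, axis=0)
                vals[e] = band_mat[rows_i, rows_j]
            frames.append(
                pd.DataFrame(
                    dict(
                        epoch=np.repeat(np.arange(n_ep), n_pairs),
                        chan_i=np.tile(chan_i, n_ep),
                        chan_j=np.tile(chan_j, n_ep),
                        ispc=vals.ravel(),
                        band=band,
                        window=window,
                    )
                )
            )
    table = pd.concat(frames, ignore_index=True)
    ev = phases_a.events.set_index("epoch")[["trial", "rep"]]
    table = table.join(ev, on="epoch")
    table["pair"] = table["chan_i"] + "-" + table["chan_j"]
    table["dyad"] = dyad_id
    table["unit"] = unit_id or phases_a.participant_id
    return table[
        ["dyad", "unit", "trial", "rep", "chan_i", "chan_j", "pair",
         "band", "window", "ispc"]
    ]


def node_degree(credible_pairs: list[tuple[str, str]],
                labels: list[str] | None = None) -> pd.Series:
    """Per-electrode count of credible connections (for connection maps)."""
    labels = list(SCALP_LABELS) if labels is None else labels
    deg = pd.Series(0, index=labels, dtype=int, name="degree")
    for i, j in credible_pairs:
        deg[i] += 1
        if j != i:
            deg[j] += 1
    return deg
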