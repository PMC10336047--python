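"""Electrode montage: the study's 25 scalp channels plus two mastoids.

Positions come from the standard 10-20/10-10 template shipped with MNE,
restricted to the labels used here.  Connectivity analyses exclude the
mastoids; they are carried only so ingest of full recordings round-trips.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

SCALP_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "FC1", "FC2", "FC5", "FC6",
    "Cz", "C3", "C4",
    "CP1", "CP2", "CP5", "CP6",
    "Pz", "P3", "P4", "P7", "P8",
    "POz", "Oz",
)
MASTOID_LABELS: tuple[str, ...] = ("M1", "M2")
ALL_LABELS: tuple[str, ...] = SCALP_LABELS + MASTOID_LABELS

_MONTAGE_CACHE: pd.DataFrame | None = None


def standard_montage() -> pd.DataFrame:
    """3-D positions (meters, head frame) for all 27 channels.

    Returns a DataFrame with columns label, x, y, z in montage order.
    """
    global _MONTAGE_CACHE
    if _MONTAGE_CACHE is None:
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            tmpl = mne.channels.make_standard_montage("standard_1005")
        pos = tmpl.get_positions()["ch_pos"]
        rows = [
            dict(label=lab, **dict(zip("xyz", np.asarray(pos[lab], dtype=float))))
            for lab in ALL_LABELS
        ]
        _MONTAGE_CACHE = pd.DataFrame(rows, columns=["label", "x", "y", "z"])
    return _MONTAGE_CACHE.copy()


def scalp_positions(montage: pd.DataFrame | None = None) -> np.ndarray:
    """(25, 3) position array for the scalp channels, in SCALP_LABELS order."""
    montage = standard_montage() if montage is None else montage
    idx = montage.set_index("label")
    return idx.loc[list(SCALP_LABELS), ["x", "y", "z"]].to_numpy(dtype=float)


def write_montage_tsv(path, montage: pd.DataFrame | None = None) -> None:
    (standard_montage() if montage is None else montage).to_csv(
        path, sep="\t", index=False
    )


def read_montage_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"montage TSV missing columns: {sorted(missing)}")
    return df
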