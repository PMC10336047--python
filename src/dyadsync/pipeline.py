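"""End-to-end pipeline runner with reproducibility plumbing.

Stages: simulate behavior -> RL fits -> simulate EEG -> preprocessing ->
connectivity -> first level -> second level.  Each stage's tabular output
is persisted under the run directory; a rerun with ``resume=True`` picks
up from persisted intermediates.  All randomness flows from the master
seed through per-stage seeds derived by hashing the stage name, so
stochastic stages are isolated: changing one stage's inputs never shifts
another's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import WINDOWS, build_connectivity
from .eeg_pipeline import BANDS, EpochSet, preprocess
from .first_level import DesignSpec, run_first_level
from .montage import SCALP_LABELS, standard_montage
from .rl_models import fit_all_models, loglik_table, pairwise_ll_contrasts, pe_frame
from .second_level import BMAConfig, ROPEConfig, build_credibility_map, fit_bma
from .synthetic import BehaviorSimConfig, EEGSimConfig, simulate_dyad_behavior, \
    simulate_eeg
from .task_behavior import (
    label_adjustment_trials,
    read_behavior_tsv,
    write_behavior_tsv,
)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """One self-contained pipeline run."""

    out_dir: str = "run"
    master_seed: int = 0
    mode: str = "intra"  # "intra" | "inter"
    bands: tuple[str, ...] = ("theta", "alpha", "beta")
    windows: tuple[str, ...] = ("early", "late")
    design_kind: str = "fb"
    contrast: str = "fb2_minus_fb1"
    behavior: BehaviorSimConfig = field(default_factory=BehaviorSimConfig)
    eeg: EEGSimConfig = field(default_factory=EEGSimConfig)
    bma: BMAConfig = field(default_factory=BMAConfig)
    rope: ROPEConfig = field(default_factory=ROPEConfig)
    #: "none" feeds unit-level first-level estimates to the BMA (residual
    #: scale identified); "fixed" pools per connection first
    pooling: str = "none"
    rl_restarts: int = 10
    fit_rl_models: bool = True
    save_epochs: bool = False
    resume: bool = False

    def validate(self) -> None:
        if self.mode not in ("intra", "inter"):
            raise ValueError("mode must be 'intra' or 'inter'")
        unknown = set(self.bands) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")
        unknown = set(self.windows) - set(WINDOWS)
        if unknown:
            raise ValueError(f"unknown windows: {sorted(unknown)}")
        DesignSpec(self.design_kind, self.contrast)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    checksums: dict
    versions: dict
    started: float
    finished: float = 0.0

    def save(self, path: Path) -> None:
        with open(path, "w") as f:
            json.dump(_to_jsonable(dataclasses.asdict(self)), f, indent=2)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full pipeline; returns the run manifest.

    Outputs under ``config.out_dir``: behavior.tsv, rl_fits.csv / pe.csv /
    ll_contrasts.csv (when RL fitting is on), connectivity.csv.gz,
    estimates_<band>_<window>.tsv, credibility_<band>_<window>.tsv,
    node_degree_<band>_<window>.tsv, posterior_<band>_<window>.json and
    manifest.json.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.master_seed, s)
             for s in ("behavior", "rl", "eeg", "bma")}
    manifest = RunManifest(
        config=_to_jsonable(config),
        seeds=seeds,
        checksums={},
        versions=dict(
            dyadsync=__version__,
            python=platform.python_version(),
            numpy=np.__version__,
            pandas=pd.__version__,
        ),
        started=time.time(),
    )

    # -- behavior ----------------------------------------------------------
    behavior_path = out / "behavior.tsv"
    bconf = dataclasses.replace(config.behavior, seed=seeds["behavior"])
    dyads, truth = simulate_dyad_behavior(bconf)
    if config.resume and behavior_path.exists():
        logger.info("resume: loading persisted behavior log")
        sessions = read_behavior_tsv(behavior_path)
        by_id = {s.participant_id: s for s in sessions}
        dyads = [(by_id[a.participant_id], by_id[b.participant_id])
                 for a, b in dyads]
    else:
        write_behavior_tsv([s for pair in dyads for s in pair], behavior_path)
    all_sessions = [s for pair in dyads for s in pair]

    # -- RL fits -----------------------------------------------------------
    pe_tables = []
    if config.fit_rl_models:
        fits = {}
        rows = []
        for i, s in enumerate(all_sessions):
            fits[s.participant_id] = fit_all_models(
                s, n_restarts=config.rl_restarts, seed=seeds["rl"] + 10 * i
            )
            for m, fr in fits[s.participant_id].items():
                rows.append(
                    dict(participant_id=s.participant_id, model=m,
                         alpha=fr.params.alpha, tau=fr.params.tau,
                         loglik=fr.loglik, bic=fr.bic)
                )
                pf = pe_frame(fr, s.participant_id)
                pe_tables.append(pf)
        pd.DataFrame(rows).to_csv(out / "rl_fits.csv", index=False)
        pd.concat(pe_tables).to_csv(out / "pe.csv", index=False)
        if len(all_sessions) >= 2:
            pairwise_ll_contrasts(
                loglik_table(fits)
            ).to_csv(out / "ll_contrasts.csv", index=False)

    # -- EEG + preprocessing + connectivity ---------------------------------
    conn_path = out / "connectivity.csv.gz"
    if config.resume and conn_path.exists():
        logger.info("resume: loading persisted connectivity table")
        table = pd.read_csv(conn_path)
    else:
        econf = dataclasses.replace(config.eeg, seed=seeds["eeg"])
        recordings, truth = simulate_eeg(dyads, econf, manifest=truth)
        montage = standard_montage()
        freqs = np.concatenate([BANDS[b] for b in config.bands])
        tables = []
        for (sa, sb) in dyads:
            phases = {}
            for s in (sa, sb):
                eps = recordings[s.participant_id]
                if config.save_epochs:
                    eps.save(out / f"epochs_{s.participant_id}.h5")
                phases[s.participant_id] = preprocess(
                    eps, montage=montage, freqs=freqs
                )
                recordings[s.participant_id] = None  # free memory
            pa, pb = phases[sa.participant_id], phases[sb.participant_id]
            if config.mode == "intra":
                for s in (sa, sb):
                    tables.append(
                        build_connectivity(
                            phases[s.participant_id],
                            bands=list(config.bands),
                            windows=list(config.windows),
                            dyad_id=sa.dyad_id,
                        )
                    )
            else:
                tables.append(
                    build_connectivity(
                        pa, pb, bands=list(config.bands),
                        windows=list(config.windows),
                        dyad_id=sa.dyad_id, unit_id=sa.dyad_id,
                    )
                )
        table = pd.concat(tables, ignore_index=True)
        table.to_csv(conn_path, index=False)
        with open(out / "connectivity_meta.json", "w") as f:
            json.dump(
                dict(bands=list(config.bands), windows=list(config.windows),
                     mode=config.mode, n_rows=len(table)), f
            )
        with open(out / "ground_truth.json", "w") as f:
            json.dump(_to_jsonable(dataclasses.asdict(truth)), f, indent=2)

    # -- first + second level -----------------------------------------------
    spec = DesignSpec(config.design_kind, config.contrast)
    labels_df = None
    if config.design_kind == "fb_adj":
        rows = []
        for s in all_sessions:
            for lab in label_adjustment_trials(s):
                rows.append(dict(unit=s.participant_id, trial=lab.trial_index,
                                 label=lab.label))
        labels_df = pd.DataFrame(rows)
    pe_df = None
    if config.design_kind == "fb_pe":
        pe_df = pd.concat(pe_tables)
        pe_df = pe_df[pe_df["model"] == "M1"].rename(
            columns={"participant_id": "unit"}
        )

    bma_conf = dataclasses.replace(config.bma, seed=seeds["bma"])
    for band in config.bands:
        for window in config.windows:
            sl = table[(table["band"] == band) & (table["window"] == window)]
            estimates = run_first_level(sl, spec, labels=labels_df, pe=pe_df,
                                        pooling=config.pooling)
            est_path = out / f"estimates_{band}_{window}.tsv"
            estimates.to_csv(est_path, sep="\t", index=False)
            posterior = fit_bma(estimates, bma_conf)
            cmap = build_credibility_map(posterior, estimates, config.rope)
            cmap.table.to_csv(out / f"credibility_{band}_{window}.tsv",
                              sep="\t", index=False)
            cred_pairs = list(
                cmap.credible[["chan_i", "chan_j"]].itertuples(index=False)
            )
            from .connectivity import node_degree

            node_degree(cred_pairs, list(SCALP_LABELS)).to_csv(
                out / f"node_degree_{band}_{window}.tsv", sep="\t"
            )
            with open(out / f"posterior_{band}_{window}.json", "w") as f:
                json.dump(
                    _to_jsonable(
                        dict(population=cmap.population,
                             rope_halfwidth=cmap.rope_halfwidth,
                             diagnostics=posterior.diagnostics)
                    ), f, indent=2,
                )

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.checksums[p.name] = _checksum(p)
    manifest.finished = time.time()
    manifest.save(out / "manifest.json")
    return manifest


def validate_inputs(
    behavior_tsv: str | None = None,
    epochs_h5: str | None = None,
    montage_tsv: str | None = None,
) -> list[str]:
    """Schema checks for external inputs; returns a list of issues
    (empty when everything is well formed)."""
    from .task_behavior import LOG_COLUMNS

    issues: list[str] = []
    if behavior_tsv is not None:
        try:
            df = pd.read_csv(behavior_tsv, sep="\t")
        except Exception as exc:  # noqa: BLE001
            issues.append(f"behavior log unreadable: {exc}")
        else:
            missing = set(LOG_COLUMNS) - set(df.columns)
            if missing:
                issues.append(
                    f"behavior log missing columns: {sorted(missing)}"
                )
            elif not set(df["rep"].unique()) <= {1, 2, 3}:
                issues.append("behavior log rep column must be 1, 2 or 3")
    if epochs_h5 is not None:
        try:
            eps = EpochSet.load(epochs_h5)
        except Exception as exc:  # noqa: BLE001
            issues.append(f"epoch container unreadable: {exc}")
        else:
            n_scalp = len([c for c in eps.ch_names
                           if c not in ("M1", "M2")])
            if n_scalp != len(SCALP_LABELS):
                issues.append(
                    f"epoch container has {n_scalp} scalp channels; "
                    f"expected {len(SCALP_LABELS)}"
                )
            if not {"trial", "rep"} <= set(eps.events.columns):
                issues.append("epoch events must provide trial and rep")
    if montage_tsv is not None:
        try:
            from .montage import read_montage_tsv

            read_montage_tsv(montage_tsv)
        except Exception as exc:  # noqa: BLE001
            issues.append(f"montage unreadable: {exc}")
    return issues
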