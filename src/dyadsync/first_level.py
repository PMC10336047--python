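"""Mass-univariate first level: beta regression of single-trial ISPC.

Per connection and per unit of analysis (participant for intra-brain,
dyad for inter-brain), single-trial ISPC values are modeled with a beta
likelihood (logit link for the mean, log link for the precision) against
the feedback-repetition factor, optionally interacting with the
adjustment dichotomy or the RL prediction error.  Least-squares-means
contrasts are linear combinations of the mean-model coefficients on the
link scale, with standard errors from the coefficient covariance.  Unit
contrasts are combined into one (estimate, SE) per connection by
fixed-effect inverse-variance weighting before the second level.

Sign convention: a positive FB2-FB1 contrast means synchrony increased
at FB2 relative to FB1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel

logger = logging.getLogger(__name__)

DESIGN_KINDS = ("fb", "fb_adj", "fb_pe")
CONTRASTS = {
    "fb": ("fb2_minus_fb1", "fb3_minus_fb2"),
    "fb_adj": ("adj_low_minus_high_fb3_minus_fb2",),
    "fb_pe": ("pe_fb2", "pe_fb3", "pe_fb3_minus_fb2"),
}


@dataclass(frozen=True)
class DesignSpec:
    """First-level model and contrast selection.

    ``kind``: "fb" (ISPC ~ FB_rep), "fb_adj" (ISPC ~ FB_rep x Adj, mixed
    trials excluded), "fb_pe" (ISPC ~ FB_rep x PE over FB2/FB3, PE
    standardized within unit).  ``contrast`` must belong to the kind.
    """

    kind: str
    contrast: str

    def __post_init__(self) -> None:
        if self.kind not in DESIGN_KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.contrast not in CONTRASTS[self.kind]:
            raise ValueError(
                f"contrast {self.contrast!r} not available for {self.kind!r}"
            )


@dataclass(frozen=True)
class ContrastEstimate:
    """One connection's contrast on the link (logit) scale."""

    connection: str
    estimate: float
    se: float
    n_obs: int


def compress_boundary(y: np.ndarray) -> np.ndarray:
    """Shrink [0,1] responses strictly inside the open interval:
    y' = (y*(n-1) + 0.5)/n.  The beta likelihood is undefined at 0/1."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def beta_regression_fit(y: np.ndarray, X: np.ndarray):
    """ML beta regression; returns (coef, cov) for the mean submodel.

    ``y`` must already lie strictly in (0,1); ``X`` must be full rank.
    Raises on non-convergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses must lie strictly in (0, 1)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = BetaModel(y, X, exog_precision=np.ones((len(y), 1)))
    with np.errstate(all="ignore"):
        res = model.fit(disp=0)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("beta regression produced non-finite estimates")
    k = X.shape[1]
    cov = np.asarray(res.cov_params())[:k, :k]
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        raise RuntimeError("beta regression covariance is degenerate")
    return np.asarray(res.params[:k]), cov


def lsmeans_contrast(coef: np.ndarray, cov: np.ndarray,
                     c: np.ndarray) -> tuple[float, float]:
    """Linear contrast c'beta with delta-method SE on the link scale."""
    c = np.asarray(c, dtype=float)
    est = float(c @ coef)
    var = float(c @ cov @ c)
    if var < 0:
        raise ValueError("negative contrast variance")
    return est, np.sqrt(var)


# ---------------------------------------------------------------------------
# Design construction


def _design_fb(sub: pd.DataFrame):
    rep = sub["rep"].to_numpy()
    X = np.column_stack([np.ones(len(sub)), rep == 2, rep == 3]).astype(float)
    contrasts = {
        "fb2_minus_fb1": np.array([0.0, 1.0, 0.0]),
        "fb3_minus_fb2": np.array([0.0, -1.0, 1.0]),
    }
    return X, contrasts


def _design_fb_adj(sub: pd.DataFrame):
    sub = sub[sub["adj"].isin(["high_high", "low_low"])]
    rep = sub["rep"].to_numpy()
    low = (sub["adj"] == "low_low").to_numpy()
    X = np.column_stack(
        [np.ones(len(sub)), rep == 2, rep == 3, low,
         (rep == 2) & low, (rep == 3) & low]
    ).astype(float)
    # (FB3-FB2 | low_low) - (FB3-FB2 | high_high)
    contrasts = {
        "adj_low_minus_high_fb3_minus_fb2":
            np.array([0.0, 0.0, 0.0, 0.0, -1.0, 1.0]),
    }
    return sub, X, contrasts


def _design_fb_pe(sub: pd.DataFrame):
    sub = sub[sub["rep"].isin([2, 3])].dropna(subset=["pe"])
    rep = sub["rep"].to_numpy()
    pe = sub["pe"].to_numpy()
    X = np.column_stack(
        [np.ones(len(sub)), rep == 3, pe, (rep == 3) * pe]
    ).astype(float)
    contrasts = {
        "pe_fb2": np.array([0.0, 0.0, 1.0, 0.0]),
        "pe_fb3": np.array([0.0, 0.0, 1.0, 1.0]),
        "pe_fb3_minus_fb2": np.array([0.0, 0.0, 0.0, 1.0]),
    }
    return sub, X, contrasts


def _unit_contrast(sub: pd.DataFrame, spec: DesignSpec):
    if spec.kind == "fb":
        X, contrasts = _design_fb(sub)
    elif spec.kind == "fb_adj":
        sub, X, contrasts = _design_fb_adj(sub)
    else:
        sub, X, contrasts = _design_fb_pe(sub)
    y = compress_boundary(sub["ispc"].to_numpy())
    coef, cov = beta_regression_fit(y, X)
    est, se = lsmeans_contrast(coef, cov, contrasts[spec.contrast])
    return est, se, len(y)


def pool_units(estimates: list[tuple[float, float]]) -> tuple[float, float]:
    """Fixed-effect inverse-variance combination of unit-level contrasts."""
    w = np.array([1.0 / se**2 for _, se in estimates])
    e = np.array([est for est, _ in estimates])
    return float((w * e).sum() / w.sum()), float(1.0 / np.sqrt(w.sum()))


def run_first_level(
    table: pd.DataFrame,
    spec: DesignSpec,
    labels: pd.DataFrame | None = None,
    pe: pd.DataFrame | None = None,
    pooling: str = "fixed",
    max_failure_rate: float = 0.10,
) -> pd.DataFrame:
    """Per-connection contrast estimates from a single-band/window table.

    ``table`` is a ConnectivityTable slice (one band, one window) with
    columns unit, trial, rep, chan_i, chan_j, pair, ispc.  ``labels``
    (unit, trial, label) is required for kind "fb_adj"; ``pe`` (unit,
    trial, rep, pe) for kind "fb_pe" and is standardized within unit.
    ``pooling`` is "fixed" (inverse-variance, default) or "none"
    (one row per unit per connection).

    Returns a DataFrame with columns connection, chan_i, chan_j,
    estimate, se, n_units, n_obs.
    """
    for col in ("band", "window"):
        if col in table.columns and table[col].nunique() > 1:
            raise ValueError(f"table must be filtered to a single {col}")
    table = table.copy()
    if spec.kind == "fb_adj":
        if labels is None:
            raise ValueError("fb_adj design requires adjustment labels")
        table = table.merge(
            labels.rename(columns={"label": "adj"}), on=["unit", "trial"],
            how="left",
        )
    if spec.kind == "fb_pe":
        if pe is None:
            raise ValueError("fb_pe design requires a PE table")
        pe = pe.copy()
        pe["pe"] = pe.groupby("unit")["pe"].transform(
            lambda x: (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        )
        table = table.merge(pe[["unit", "trial", "rep", "pe"]],
                            on=["unit", "trial", "rep"], how="left")

    n_total = n_failed = 0
    rows = []
    for (ci, cj), conn_df in table.groupby(["chan_i", "chan_j"], sort=True):
        unit_results = []
        for unit, sub in conn_df.groupby("unit"):
            n_total += 1
            try:
                unit_results.append((unit, *_unit_contrast(sub, spec)))
            except Exception as exc:  # noqa: BLE001 - logged and counted
                n_failed += 1
                logger.warning("fit failed for %s-%s unit %s: %s",
                               ci, cj, unit, exc)
        if not unit_results:
            continue
        if pooling == "none":
            for unit, est, se, n in unit_results:
                rows.append(
                    dict(connection=f"{ci}-{cj}", chan_i=ci, chan_j=cj,
                         unit=unit, estimate=est, se=se, n_units=1, n_obs=n)
                )
        else:
            est, se = pool_units([(e, s) for _, e, s, _ in unit_results])
            rows.append(
                dict(connection=f"{ci}-{cj}", chan_i=ci, chan_j=cj,
                     estimate=est, se=se, n_units=len(unit_results),
                     n_obs=sum(n for *_, n in unit_results))
            )
    if n_total and n_failed / n_total > max_failure_rate:
        raise RuntimeError(
            f"{n_failed}/{n_total} first-level fits failed "
            f"(> {max_failure_rate:.0%})"
        )
    return pd.DataFrame(rows)
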