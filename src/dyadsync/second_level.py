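"""Hierarchical Bayesian meta-analysis across connections, with the
HDI + ROPE credibility rule.

Model (observations indexed by connection c and analysis unit,
from the first level):

    y_cu ~ Normal(beta0 + u_c, sqrt(sigma^2 + se_cu^2))
    u_c  ~ Normal(0, sigma_u)

    beta0   ~ Normal(0, 10)                (population intercept)
    sigma   ~ half-Student-t(nu=3, 0, 2.5) (residual scale)
    sigma_u ~ Gamma(shape=1, rate=10)      (varying-effect scale)

The first-level standard errors enter as known measurement-error SDs
(they can be switched off).  Because everything is Gaussian given the
hyperparameters, the u_c are marginalized analytically (matrix
determinant lemma) and MCMC runs over the hyperparameters only;
per-connection effects beta0 + u_c are then drawn exactly from their
Gaussian conditional for each retained posterior sample.  This partial
pooling is itself the multiple-comparison mitigation: no further
correction is applied.

With several units per connection, the residual scale sigma is
identified by within-connection scatter and sigma_u by between-
connection scatter.  With a single pooled estimate per connection, the
likelihood constrains only T^2 = sigma^2 + sigma_u^2; the sampler then
runs over (beta0, log T) and draws the variance split from its
conditional prior, which is the exact posterior of that model - but
per-connection effects mix over shrinkage levels, so unit-level input
is the better-identified default upstream.

A connection is credibly different from zero when the ROPE
[-h, +h], h = 0.01 * SD(y), lies wholly outside the 95% highest-density
interval of its effect posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BMAConfig", "ROPEConfig", "CredibilityMap", "PosteriorSamples",
    "fit_bma", "hdi", "rope_decision", "build_credibility_map",
]


@dataclass
class BMAConfig:
    """Priors and sampler settings for the meta-analysis."""

    prior_intercept_sd: float = 10.0
    prior_sigma_scale: float = 2.5
    prior_sigma_df: float = 3.0
    prior_u_shape: float = 1.0
    prior_u_rate: float = 10.0
    use_measurement_error: bool = True
    n_walkers: int = 32
    n_steps: int = 6000
    n_burn: int = 2000
    thin: int = 8
    seed: int = 0
    rhat_max: float = 1.01

    def __post_init__(self) -> None:
        for name in ("prior_intercept_sd", "prior_sigma_scale",
                     "prior_u_rate", "prior_u_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ROPEConfig:
    """95% HDI + ROPE decision rule; halfwidth = rope_factor * SD(y)."""

    hdi_mass: float = 0.95
    rope_factor: float = 0.01
    sd_y: float | None = None  # computed from the data when None

    def halfwidth(self, y: np.ndarray) -> float:
        sd = float(np.std(y, ddof=1)) if self.sd_y is None else self.sd_y
        h = self.rope_factor * sd
        if h <= 0:
            raise ValueError("ROPE halfwidth must be > 0")
        return h


@dataclass
class PosteriorSamples:
    """Posterior draws from :func:`fit_bma`."""

    beta0: np.ndarray            # (S,)
    sigma_u: np.ndarray          # (S,)
    sigma: np.ndarray            # (S,)
    effects: np.ndarray          # (S, C): beta0 + u_c per connection
    connections: list[str]
    diagnostics: dict = field(default_factory=dict)


@dataclass
class CredibilityMap:
    """Per-connection posterior summaries and credibility decisions."""

    table: pd.DataFrame          # connection, chan_i, chan_j, mean, hdi_low,
    #                              hdi_high, credible, sign
    population: dict             # posterior summary of beta0
    rope_halfwidth: float

    @property
    def credible(self) -> pd.DataFrame:
        return self.table[self.table["credible"]]


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples (sorted-window).

    Warns when the shortest window is ambiguous (several candidate windows
    within 0.1% of the minimal width), as under multimodality.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        return float(x[0]), float(x[0])
    k = max(int(np.ceil(mass * n)), 2)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    wmin = widths[i]
    if wmin > 0 and len(widths) > 10:
        # near-minimal windows starting far from the chosen one signal an
        # ambiguous (e.g. multimodal) shortest-interval problem
        near = np.flatnonzero(widths <= wmin * 1.05)
        if np.abs(near - i).max() > 0.5 * len(widths):
            import warnings

            warnings.warn("HDI window ambiguous; distribution may be "
                          "multimodal", stacklevel=2)
    return float(x[i]), float(x[i + k - 1])


#: grid over the (sigma_u, sigma) split angle phi in (0, pi/2)
_PHI_GRID = np.linspace(1e-4, np.pi / 2 - 1e-4, 256)


def _split_log_weights(T: float, cfg: BMAConfig) -> np.ndarray:
    """Unnormalized conditional log density of the split angle phi given
    the total scale T, where sigma_u = T sin(phi), sigma = T cos(phi).

    The likelihood depends on (sigma_u, sigma) only through
    T^2 = sigma_u^2 + sigma^2, so given T the split follows the prior:
    Gamma(shape, rate) on sigma_u times half-Student-t on sigma.
    """
    sigma_u = T * np.sin(_PHI_GRID)
    sigma = T * np.cos(_PHI_GRID)
    nu, s = cfg.prior_sigma_df, cfg.prior_sigma_scale
    return (
        (cfg.prior_u_shape - 1.0) * np.log(sigma_u)
        - cfg.prior_u_rate * sigma_u
        - 0.5 * (nu + 1.0) * np.log1p((sigma / s) ** 2 / nu)
    )


def _log_prior_T(log_T: float, cfg: BMAConfig) -> float:
    """Marginal log prior of log T induced by the (sigma_u, sigma) priors
    in polar coordinates (numerical integral over the split angle)."""
    from scipy.special import logsumexp

    T = np.exp(log_T)
    log_w = _split_log_weights(T, cfg)
    log_integral = logsumexp(log_w) + np.log(_PHI_GRID[1] - _PHI_GRID[0])
    # polar Jacobian T, plus log-scale sampling Jacobian T
    return float(log_integral + 2.0 * log_T)


def _log_post(theta, y, se2, cfg: BMAConfig) -> float:
    """Log posterior of (beta0, log T) with the split angle integrated out."""
    beta0, log_T = theta
    if abs(log_T) > 30:
        return -np.inf
    lp = -0.5 * (beta0 / cfg.prior_intercept_sd) ** 2
    lp += _log_prior_T(log_T, cfg)
    if not np.isfinite(lp):
        return -np.inf
    T2 = np.exp(2.0 * log_T)
    var = T2 + se2
    resid2 = (y - beta0) ** 2
    return lp - 0.5 * float(np.sum(np.log(2 * np.pi * var) + resid2 / var))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over (n_chains, n_draws) for one scalar parameter."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w)) if w > 0 else 1.0


def sample_prior(cfg: BMAConfig, n: int = 4000) -> PosteriorSamples:
    """Direct draws from the priors (likelihood disabled) - the
    prior-predictive reference for the hyperparameters."""
    rng = np.random.default_rng(cfg.seed)
    beta0 = rng.normal(0.0, cfg.prior_intercept_sd, n)
    sigma_u = rng.gamma(cfg.prior_u_shape, 1.0 / cfg.prior_u_rate, n)
    sigma = np.abs(
        rng.standard_t(cfg.prior_sigma_df, n) * cfg.prior_sigma_scale
    )
    return PosteriorSamples(beta0, sigma_u, sigma,
                            effects=beta0[:, None].copy(),
                            connections=["prior"], diagnostics={})


def _run_sampler(log_post, args, p0, param_names, config):
    """emcee run + convergence gate; returns (thinned flat chain,
    diagnostics dict)."""
    import emcee

    sampler = emcee.EnsembleSampler(
        config.n_walkers, p0.shape[1], log_post, args=args,
        moves=[(emcee.moves.DEMove(), 0.8),
               (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(config.seed + 1).get_state()
    sampler.run_mcmc(p0, config.n_steps, progress=False)
    chain = sampler.get_chain(discard=config.n_burn)  # (steps, walkers, dim)
    rhats = {
        name: _split_rhat(chain[:, :, i].T)
        for i, name in enumerate(param_names)
    }
    ess = {
        name: _effective_sample_size(chain[:, :, i])
        for i, name in enumerate(param_names)
    }
    if max(rhats.values()) >= config.rhat_max:
        raise RuntimeError(f"MCMC not converged: split-R-hat {rhats}")
    flat = chain[::config.thin].reshape(-1, p0.shape[1])
    diag = dict(rhat=rhats, ess=ess,
                acceptance=float(sampler.acceptance_fraction.mean()))
    return flat, diag


def _log_post_units(theta, y, se2, idx, n_conn, cfg: BMAConfig) -> float:
    """Log posterior of (beta0, log s_u, log s) for unit-level input.

    The u_c are marginalized per connection with the matrix determinant
    lemma: y_c ~ N(beta0 1, diag(D) + s_u^2 11') with D_i = s^2 + se_i^2.
    """
    beta0, log_su, log_s = theta
    if abs(log_su) > 30 or abs(log_s) > 30:
        return -np.inf
    sigma_u, sigma = np.exp(log_su), np.exp(log_s)
    # priors (with log-scale Jacobians)
    lp = -0.5 * (beta0 / cfg.prior_intercept_sd) ** 2
    lp += cfg.prior_u_shape * log_su - cfg.prior_u_rate * sigma_u
    nu, s = cfg.prior_sigma_df, cfg.prior_sigma_scale
    lp += -0.5 * (nu + 1.0) * np.log1p((sigma / s) ** 2 / nu) + log_s
    # likelihood
    D = sigma**2 + se2
    r = y - beta0
    inv_D = 1.0 / D
    A = np.bincount(idx, weights=inv_D, minlength=n_conn)
    B = np.bincount(idx, weights=r * inv_D, minlength=n_conn)
    quad = np.sum(r * r * inv_D) - np.sum(
        sigma_u**2 * B * B / (1.0 + sigma_u**2 * A)
    )
    logdet = np.sum(np.log(2 * np.pi * D)) + np.sum(
        np.log1p(sigma_u**2 * A)
    )
    return float(lp - 0.5 * (logdet + quad))


def fit_bma(estimates: pd.DataFrame, config: BMAConfig | None = None
            ) -> PosteriorSamples:
    """Fit the meta-analysis to a first-level estimates table.

    ``estimates`` needs columns connection, estimate, se; several rows
    may share a connection (unit-level input), in which case the residual
    and varying-effect scales are separately identified.  Returns
    posterior samples including the per-connection effects beta0 + u_c.
    Raises when split-R-hat of any hyperparameter exceeds the configured
    threshold.
    """
    config = config or BMAConfig()
    conns_all = estimates["connection"].astype(str).to_numpy()
    conns = list(dict.fromkeys(conns_all))  # first-appearance order
    if len(conns) < 10:
        raise ValueError("need at least 10 connections for the meta-analysis")
    y = estimates["estimate"].to_numpy(dtype=float)
    se = estimates["se"].to_numpy(dtype=float)
    se2 = se**2 if config.use_measurement_error else np.zeros_like(se)
    conn_pos = {c: i for i, c in enumerate(conns)}
    idx = np.array([conn_pos[c] for c in conns_all])
    rng = np.random.default_rng(config.seed)

    if len(conns_all) == len(conns):
        beta0, sigma_u, sigma, diag = _sample_pooled(y, se2, config, rng)
    else:
        beta0, sigma_u, sigma, diag = _sample_units(
            y, se2, idx, len(conns), config, rng
        )

    # exact Gaussian conditional for u_c given the hyperparameters
    S = len(beta0)
    D = sigma[:, None] ** 2 + se2[None, :]          # (S, rows)
    inv_D = 1.0 / D
    A = np.zeros((S, len(conns)))
    B = np.zeros((S, len(conns)))
    r = y[None, :] - beta0[:, None]
    for c in range(len(conns)):
        cols = idx == c
        A[:, c] = inv_D[:, cols].sum(axis=1)
        B[:, c] = (r[:, cols] * inv_D[:, cols]).sum(axis=1)
    v = 1.0 / (1.0 / sigma_u[:, None] ** 2 + A)
    m = v * B
    u = m + np.sqrt(v) * rng.standard_normal(m.shape)
    return PosteriorSamples(
        beta0=beta0, sigma_u=sigma_u, sigma=sigma,
        effects=beta0[:, None] + u, connections=conns,
        diagnostics=diag,
    )


def _sample_pooled(y, se2, config, rng):
    """One estimate per connection: sample (beta0, log T) and draw the
    sigma_u / sigma split from its conditional prior (exact: the
    likelihood is flat in the split)."""
    sd_y = max(y.std(ddof=1), 1e-3)
    p0 = np.column_stack([
        y.mean() + rng.normal(0, sd_y / 8, config.n_walkers),
        np.log(sd_y) + rng.normal(0, 0.05, config.n_walkers),
    ])
    flat, diag = _run_sampler(
        _log_post, (y, se2, config), p0, ("beta0", "log_T"), config
    )
    beta0 = flat[:, 0]
    T = np.exp(flat[:, 1])
    dphi = _PHI_GRID[1] - _PHI_GRID[0]
    phi = np.empty(len(T))
    for i, t in enumerate(T):
        log_w = _split_log_weights(t, config)
        w = np.exp(log_w - log_w.max())
        w /= w.sum()
        phi[i] = rng.choice(_PHI_GRID, p=w) + rng.uniform(-dphi / 2, dphi / 2)
    phi = np.clip(phi, 1e-6, np.pi / 2 - 1e-6)
    return beta0, T * np.sin(phi), T * np.cos(phi), diag


def _sample_units(y, se2, idx, n_conn, config, rng):
    """Unit-level input: sample (beta0, log sigma_u, log sigma); both
    scales are identified (within- vs between-connection scatter)."""
    conn_means = np.array([y[idx == c].mean() for c in range(n_conn)])
    sd_between = max(conn_means.std(ddof=1), 1e-3)
    resid = y - conn_means[idx]
    sd_within = max(resid.std(ddof=1), 1e-3)
    p0 = np.column_stack([
        y.mean() + rng.normal(0, sd_between / 8, config.n_walkers),
        np.log(sd_between) + rng.normal(0, 0.05, config.n_walkers),
        np.log(sd_within) + rng.normal(0, 0.05, config.n_walkers),
    ])
    flat, diag = _run_sampler(
        _log_post_units, (y, se2, idx, n_conn, config), p0,
        ("beta0", "log_sigma_u", "log_sigma"), config,
    )
    return flat[:, 0], np.exp(flat[:, 1]), np.exp(flat[:, 2]), diag


def _effective_sample_size(chain: np.ndarray) -> float:
    """Crude ESS from lag-autocorrelation of the chain mean across walkers."""
    x = chain.mean(axis=1)
    x = x - x.mean()
    n = len(x)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf = acf / acf[0] if acf[0] > 0 else acf
    tau = 1.0
    for k in range(1, min(n // 2, 200)):
        if acf[k] < 0.05:
            break
        tau += 2.0 * acf[k]
    return float(n * chain.shape[1] / tau)


def rope_decision(effect_samples: np.ndarray, halfwidth: float,
                  mass: float = 0.95) -> tuple[bool, str, float, float]:
    """HDI+ROPE rule for one connection.

    Credible iff [-h, +h] and the HDI are disjoint; the sign is the sign
    of the posterior mean when credible, else "none".  Returns
    (credible, sign, hdi_low, hdi_high).
    """
    lo, hi = hdi(effect_samples, mass)
    credible = (lo > halfwidth) or (hi < -halfwidth)
    sign = "none"
    if credible:
        sign = "+" if float(np.mean(effect_samples)) > 0 else "-"
    return credible, sign, lo, hi


def build_credibility_map(
    posterior: PosteriorSamples,
    estimates: pd.DataFrame,
    rope: ROPEConfig | None = None,
) -> CredibilityMap:
    """Apply the decision rule to every connection.

    ``estimates`` is the same table passed to :func:`fit_bma`; its
    dependent variable defines SD(y) for the ROPE halfwidth, and its
    chan_i/chan_j columns (if present) flow into the map for node-degree
    summaries.
    """
    rope = rope or ROPEConfig()
    y = estimates["estimate"].to_numpy(dtype=float)
    h = rope.halfwidth(y)
    rows = []
    has_ch = {"chan_i", "chan_j"} <= set(estimates.columns)
    uniq = estimates.drop_duplicates(subset=["connection"])
    est_idx = uniq.set_index(uniq["connection"].astype(str))
    for c, name in enumerate(posterior.connections):
        samp = posterior.effects[:, c]
        credible, sign, lo, hi = rope_decision(samp, h, rope.hdi_mass)
        row = dict(
            connection=name,
            mean=float(samp.mean()),
            hdi_low=lo,
            hdi_high=hi,
            credible=credible,
            sign=sign,
        )
        if has_ch:
            row["chan_i"] = est_idx.loc[name, "chan_i"]
            row["chan_j"] = est_idx.loc[name, "chan_j"]
        rows.append(row)
    b0 = posterior.beta0
    lo0, hi0 = hdi(b0, rope.hdi_mass)
    return CredibilityMap(
        table=pd.DataFrame(rows),
        population=dict(mean=float(b0.mean()), sd=float(b0.std(ddof=1)),
                        hdi_low=lo0, hdi_high=hi0),
        rope_halfwidth=h,
    )
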