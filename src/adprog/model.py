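"""Hierarchical Bayesian progression model: priors, joint density, fitting.

The joint model ties the pieces together: each subject's latent 5-vector
evolves under the affine velocity field from a subject-specific initial
state x0^s; x0^s has a Gaussian population prior with unknown mean mu0 and
scale tau0; channel observations enter through sigmoid links with Gaussian
(or right-censored Gaussian) noise; diagnosis labels enter through the
ordered logit.  ``ProgressionModel.fit`` draws from the posterior with a
blocked adaptive Metropolis-within-Gibbs sampler (see ``_mcmc``) and returns
a ``ProgressionResults`` object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr

from .clinical import LABEL_INDEX, OrderedLogitParams, label_loglik
from .dynamics import CHANNELS, CHANNEL_INDEX, N_STATE, VelocityParams, sparsity_mask
from .io import Cohort
from .observation import (
    CensorSpec,
    LinkParams,
    default_censoring,
    default_links,
    inverse_sigmoid_link,
)

logger = logging.getLogger("adprog")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelConfig:
    """Priors, link/censoring configuration and MCMC settings.

    Prior scales follow a weakly informative philosophy on the standardised
    latent scale: velocity entries should produce order-one changes per
    decade, population means are loose, and scale parameters get half-normal
    priors.  Observation-noise prior scales are expressed as a fraction of
    each channel's link range so that channels measured in pg/mL and
    dimensionless traits are treated alike.
    """

    age_center: float = 75.0
    age_scale: float = 10.0
    links: dict[str, LinkParams] = field(default_factory=default_links)
    censoring: dict[str, CensorSpec] = field(default_factory=default_censoring)
    estimate_links: bool = False
    # prior scales
    prior_velocity_scale: float = 0.5
    prior_mu0_scale: float = 5.0
    prior_tau0_scale: float = 2.5
    prior_sigma_rel_scale: float = 0.2   # half-normal scale = rel * (upper - lower)
    prior_ologit_scale: float = 5.0
    prior_cutgap_scale: float = 5.0
    prior_slope_logscale: float = 0.3
    prior_midpoint_scale: float = 1.0
    # sampler settings
    chains: int = 2
    warmup: int = 1000
    draws: int = 1000
    thin: int = 1
    velocity_updates_per_sweep: int = 2
    seed: int = 0
    likelihood_weight: float = 1.0
    progress: bool = False

    def __post_init__(self) -> None:
        if self.chains < 1 or self.draws < 1 or self.warmup < 0:
            raise ValueError("chains and draws must be >= 1, warmup >= 0")
        for name, val in (
            ("prior_velocity_scale", self.prior_velocity_scale),
            ("prior_mu0_scale", self.prior_mu0_scale),
            ("prior_tau0_scale", self.prior_tau0_scale),
            ("prior_sigma_rel_scale", self.prior_sigma_rel_scale),
            ("prior_ologit_scale", self.prior_ologit_scale),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    def standardize_age(self, age: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(age, dtype=float) - self.age_center) / self.age_scale

    def sigma_prior_scales(self) -> np.ndarray:
        return np.array([
            self.prior_sigma_rel_scale * (self.links[c].upper - self.links[c].lower)
            for c in CHANNELS
        ])


# ---------------------------------------------------------------------------
# Parameter vector layout
# ---------------------------------------------------------------------------

_MASK = sparsity_mask()
FREE_ENTRIES = np.flatnonzero(~_MASK.ravel())          # 19 free entries per matrix
N_FREE_PER_MATRIX = FREE_ENTRIES.size
N_VEL = 3 * N_FREE_PER_MATRIX + N_STATE                 # V, W_age, W_apoe free + v0


def pack_velocity(params: VelocityParams) -> np.ndarray:
    return np.concatenate([
        params.V.ravel()[FREE_ENTRIES],
        params.W_age.ravel()[FREE_ENTRIES],
        params.W_apoe.ravel()[FREE_ENTRIES],
        params.v0,
    ])


def unpack_velocity(vec: np.ndarray) -> VelocityParams:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_VEL,):
        raise ValueError(f"velocity vector must have length {N_VEL}")
    mats = []
    for i in range(3):
        flat = np.zeros(N_STATE * N_STATE)
        flat[FREE_ENTRIES] = vec[i * N_FREE_PER_MATRIX:(i + 1) * N_FREE_PER_MATRIX]
        mats.append(flat.reshape(N_STATE, N_STATE))
    v0 = vec[3 * N_FREE_PER_MATRIX:]
    return VelocityParams(V=mats[0], W_age=mats[1], W_apoe=mats[2], v0=v0)


def pack_ologit(p: OrderedLogitParams) -> np.ndarray:
    return np.concatenate([[p.c1, np.log(p.c2 - p.c1)], p.beta_x, p.beta_y])


def unpack_ologit(vec: np.ndarray) -> OrderedLogitParams:
    c1 = float(vec[0])
    c2 = c1 + float(np.exp(vec[1]))
    return OrderedLogitParams(c1=c1, c2=c2, beta_x=vec[2:7].copy(), beta_y=vec[7:9].copy())


@dataclass
class ParamPoint:
    """One complete parameter configuration of the joint model."""

    velocity: VelocityParams
    sigma: np.ndarray                 # (5,) observation noise per channel
    ologit: OrderedLogitParams
    mu0: np.ndarray                   # (5,) population mean of x0
    tau0: np.ndarray                  # (5,) population sd of x0
    x0: np.ndarray                    # (n_subjects, 5)
    links: dict[str, LinkParams] | None = None


# ---------------------------------------------------------------------------
# Flattened cohort arrays (the sampler's working representation)
# ---------------------------------------------------------------------------


class FlatData:
    """Cohort unrolled into flat numpy arrays indexed by (subject, time) rows.

    ``times`` holds every distinct (subject, time) at which a latent state is
    needed (observation or diagnosis); observation and diagnosis rows point
    into it.  This lets one batched matrix-exponential call produce all
    latent states for a parameter draw.
    """

    def __init__(self, cohort: Cohort, config: ModelConfig):
        self.config = config
        self.subject_ids = cohort.subject_ids
        self.n_subjects = cohort.n_subjects
        cov = cohort.covariates
        self.age_std = config.standardize_age(cov["age"].to_numpy(float))
        self.apoe = cov["apoe4"].to_numpy(int)
        self.ycov = np.column_stack([self.age_std, self.apoe.astype(float)])
        self.site_id = cov["site_id"].astype(str).to_numpy()

        sid_index = {sid: i for i, sid in enumerate(self.subject_ids)}
        obs = cohort.observations
        dia = cohort.diagnoses
        o_subj = obs["subject_id"].map(sid_index).to_numpy(int)
        d_subj = dia["subject_id"].map(sid_index).to_numpy(int) if len(dia) else np.zeros(0, int)
        o_t = obs["time_years"].to_numpy(float)
        d_t = dia["time_years"].to_numpy(float) if len(dia) else np.zeros(0)

        # unique (subject, time) pairs
        key = np.concatenate([
            np.column_stack([o_subj, o_t]),
            np.column_stack([d_subj, d_t]),
        ])
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        self.times_subj = uniq[:, 0].astype(int)
        self.times = uniq[:, 1]
        self.n_times = uniq.shape[0]
        self.o_time = inverse[: len(obs)]
        self.d_time = inverse[len(obs):]

        self.o_subj = o_subj
        self.o_chan = obs["channel"].map(CHANNEL_INDEX).to_numpy(int)
        self.o_value = obs["value"].to_numpy(float)
        self.o_censored = obs["censored"].to_numpy(bool)
        self.o_se = obs["se"].to_numpy(float) if "se" in obs.columns else np.zeros(len(obs))
        self.d_subj = d_subj
        self.d_label = dia["label"].map(LABEL_INDEX).to_numpy(int) if len(dia) else np.zeros(0, int)

        for c, censored in zip(self.o_chan, self.o_censored):
            if censored and config.censoring.get(CHANNELS[c]) is None:
                raise ValueError(
                    f"censored observation on channel {CHANNELS[c]!r} which has no censoring spec"
                )
        self.set_links(config.links)

    def set_links(self, links: dict[str, LinkParams]) -> None:
        """(Re)build per-observation-row link parameter arrays."""
        lower = np.array([links[c].lower for c in CHANNELS])
        span = np.array([links[c].upper - links[c].lower for c in CHANNELS])
        slope = np.array([links[c].slope for c in CHANNELS])
        mid = np.array([links[c].midpoint for c in CHANNELS])
        self.row_lower = lower[self.o_chan]
        self.row_span = span[self.o_chan]
        self.row_slope = slope[self.o_chan]
        self.row_mid = mid[self.o_chan]
        limits = np.full(N_STATE, np.nan)
        for name, spec in self.config.censoring.items():
            if spec.upper_limit is not None:
                limits[CHANNEL_INDEX[name]] = spec.upper_limit
        self.row_limit = limits[self.o_chan]

    # -- likelihood pieces --------------------------------------------------
    def latent(self, M: np.ndarray, m: np.ndarray, x0: np.ndarray) -> np.ndarray:
        """Latent states at every flat (subject, time) row."""
        return np.einsum("tij,tj->ti", M, x0[self.times_subj]) + m

    def obs_loglik_rows(self, L: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        lat = L[self.o_time, self.o_chan]
        mean = self.row_lower + self.row_span * expit(self.row_slope * (lat - self.row_mid))
        sd = np.sqrt(sigma[self.o_chan] ** 2 + self.o_se ** 2)
        z = (self.o_value - mean) / sd
        ll = -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI
        if self.o_censored.any():
            cens = self.o_censored
            ll[cens] = log_ndtr((mean[cens] - self.row_limit[cens]) / sd[cens])
        return ll

    def diag_loglik_rows(self, L: np.ndarray, ologit: OrderedLogitParams) -> np.ndarray:
        if self.d_label.size == 0:
            return np.zeros(0)
        eta = L[self.d_time] @ ologit.beta_x + self.ycov[self.d_subj] @ ologit.beta_y
        return label_loglik(self.d_label, eta, ologit.c1, ologit.c2)

    def x0_logprior_rows(self, x0: np.ndarray, mu0: np.ndarray, tau0: np.ndarray) -> np.ndarray:
        z = (x0 - mu0) / tau0
        return (-0.5 * z * z - np.log(tau0) - 0.5 * _LOG_2PI).sum(axis=1)


def _half_normal_logpdf(x: np.ndarray, scale: np.ndarray | float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, -0.5 * (x / scale) ** 2 - np.log(scale), -np.inf)


def population_logprior(point: ParamPoint, config: ModelConfig) -> float:
    """Log prior of the population-level parameters (x0 prior lives in the
    hierarchical term, not here)."""
    lp = 0.0
    vel = pack_velocity(point.velocity)
    lp += float(np.sum(-0.5 * (vel / config.prior_velocity_scale) ** 2))
    lp += float(np.sum(-0.5 * (point.mu0 / config.prior_mu0_scale) ** 2))
    lp += float(np.sum(_half_normal_logpdf(point.tau0, config.prior_tau0_scale)))
    lp += float(np.sum(_half_normal_logpdf(point.sigma, config.sigma_prior_scales())))
    ol = point.ologit
    lp += -0.5 * (ol.c1 / config.prior_ologit_scale) ** 2
    lp += float(_half_normal_logpdf(np.array([ol.c2 - ol.c1]), config.prior_cutgap_scale)[0])
    lp += float(np.sum(-0.5 * (ol.beta_x / config.prior_ologit_scale) ** 2))
    lp += float(np.sum(-0.5 * (ol.beta_y / config.prior_ologit_scale) ** 2))
    if config.estimate_links and point.links is not None:
        for c in CHANNELS:
            ln = point.links[c]
            ref = config.links[c]
            lp += -0.5 * (np.log(ln.slope) / config.prior_slope_logscale) ** 2
            lp += -0.5 * ((ln.midpoint - ref.midpoint) / config.prior_midpoint_scale) ** 2
    return lp


def build_joint_loglik(cohort: Cohort, point: ParamPoint, config: ModelConfig | None = None) -> float:
    """Joint log density (up to normalising constants of the priors).

    Sum over subjects of the hierarchical x0 prior, all observation
    log-likelihood terms along the exact latent trajectories, and all
    diagnosis log-likelihood terms; plus the population-parameter priors.
    """
    config = config or ModelConfig()
    flat = FlatData(cohort, config)
    if point.links is not None:
        flat.set_links(point.links)
    from .dynamics import affine_propagators  # local import to avoid cycle at module load

    w = config.likelihood_weight
    lp = population_logprior(point, config)
    lp += float(flat.x0_logprior_rows(point.x0, point.mu0, point.tau0).sum())
    if flat.n_times:
        A = (point.velocity.V
             + flat.age_std[:, None, None] * point.velocity.W_age
             + flat.apoe[:, None, None] * point.velocity.W_apoe)
        M, m = affine_propagators(A[flat.times_subj], np.broadcast_to(point.velocity.v0, (flat.n_times, N_STATE)), flat.times)
        L = flat.latent(M, m, point.x0)
        lp += w * float(flat.obs_loglik_rows(L, point.sigma).sum())
        lp += w * float(flat.diag_loglik_rows(L, point.ologit).sum())
    return lp


# ---------------------------------------------------------------------------
# Posterior draws container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Joint posterior draws with a chain dimension.

    Arrays have shape (chains, draws, ...).  The velocity vector layout is
    the packed free-entry order of ``pack_velocity``; helper methods return
    the structured parameter objects for any draw.
    """

    vel: np.ndarray          # (C, D, N_VEL)
    sigma: np.ndarray        # (C, D, 5)
    ologit: np.ndarray       # (C, D, 9) packed
    mu0: np.ndarray          # (C, D, 5)
    tau0: np.ndarray         # (C, D, 5)
    x0: np.ndarray           # (C, D, n, 5)
    subject_ids: list[str]
    config: ModelConfig
    diagnostics: pd.DataFrame | None = None

    @property
    def n_chains(self) -> int:
        return self.vel.shape[0]

    @property
    def n_draws(self) -> int:
        return self.vel.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def velocity_params(self, k: int) -> VelocityParams:
        return unpack_velocity(self.stacked("vel")[k])

    def ologit_params(self, k: int) -> OrderedLogitParams:
        return unpack_ologit(self.stacked("ologit")[k])

    def point(self, k: int) -> ParamPoint:
        return ParamPoint(
            velocity=self.velocity_params(k),
            sigma=self.stacked("sigma")[k],
            ologit=self.ologit_params(k),
            mu0=self.stacked("mu0")[k],
            tau0=self.stacked("tau0")[k],
            x0=self.stacked("x0")[k],
        )

    @classmethod
    def from_point(
        cls,
        point: ParamPoint,
        config: ModelConfig,
        subject_ids: list[str] | None = None,
        n_draws: int = 1,
    ) -> "PosteriorDraws":
        """Degenerate draws concentrated at one parameter point.

        Useful for forecasting under known (e.g. simulation-truth)
        parameters, where only the subject initial state remains uncertain.
        """
        n = point.x0.shape[0]
        subject_ids = subject_ids or [f"SUB{i:04d}" for i in range(n)]

        def tile(vec):
            return np.broadcast_to(vec, (1, n_draws) + np.shape(vec)).copy()

        return cls(
            vel=tile(pack_velocity(point.velocity)),
            sigma=tile(np.asarray(point.sigma, float)),
            ologit=tile(pack_ologit(point.ologit)),
            mu0=tile(point.mu0), tau0=tile(point.tau0), x0=tile(point.x0),
            subject_ids=list(subject_ids), config=config,
        )

    def thin_to(self, k: int, rng: np.random.Generator | None = None) -> "PosteriorDraws":
        """Evenly subsample draws (per chain) down to about k total."""
        per_chain = max(1, k // self.n_chains)
        idx = np.linspace(0, self.n_draws - 1, per_chain).round().astype(int)
        return PosteriorDraws(
            vel=self.vel[:, idx], sigma=self.sigma[:, idx], ologit=self.ologit[:, idx],
            mu0=self.mu0[:, idx], tau0=self.tau0[:, idx], x0=self.x0[:, idx],
            subject_ids=self.subject_ids, config=self.config, diagnostics=self.diagnostics,
        )

    # -- serialization (columnar CSV) ---------------------------------------
    def population_dataframe(self) -> pd.DataFrame:
        """Flat table of population-parameter draws (one row per draw)."""
        cols: dict[str, np.ndarray] = {}
        names = velocity_param_names()
        flat_vel = self.stacked("vel")
        for j, name in enumerate(names):
            cols[name] = flat_vel[:, j]
        for j, c in enumerate(CHANNELS):
            cols[f"sigma[{c}]"] = self.stacked("sigma")[:, j]
        ol = self.stacked("ologit")
        cols["c1"] = ol[:, 0]
        cols["c2"] = ol[:, 0] + np.exp(ol[:, 1])
        for j, c in enumerate(CHANNELS):
            cols[f"beta_x[{c}]"] = ol[:, 2 + j]
        cols["beta_y[age]"] = ol[:, 7]
        cols["beta_y[apoe4]"] = ol[:, 8]
        for j, c in enumerate(CHANNELS):
            cols[f"mu0[{c}]"] = self.stacked("mu0")[:, j]
            cols[f"tau0[{c}]"] = self.stacked("tau0")[:, j]
        df = pd.DataFrame(cols)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws))
        df.insert(1, "draw", np.tile(np.arange(self.n_draws), self.n_chains))
        return df

    def write_csv(self, path) -> None:
        self.population_dataframe().to_csv(path, index=False)


def velocity_param_names() -> list[str]:
    names = []
    for mat in ("V", "W_age", "W_apoe"):
        for flat_idx in FREE_ENTRIES:
            i, j = divmod(int(flat_idx), N_STATE)
            names.append(f"{mat}[{CHANNELS[i]},{CHANNELS[j]}]")
    names.extend(f"v0[{c}]" for c in CHANNELS)
    return names


def default_initial_point(
    flat: FlatData,
    config: ModelConfig,
    rng: np.random.Generator,
    jitter: float = 0.0,
) -> ParamPoint:
    """Data-informed starting point: each subject's x0 seeded from the
    inverse-linked earliest uncensored observation per channel."""
    x0 = np.zeros((flat.n_subjects, N_STATE))
    counts = np.zeros((flat.n_subjects, N_STATE))
    for i in np.argsort(flat.times[flat.o_time]):  # earliest first
        s, c = flat.o_subj[i], flat.o_chan[i]
        if counts[s, c] == 0 and not flat.o_censored[i]:
            link = config.links[CHANNELS[c]]
            v = np.clip(flat.o_value[i], link.lower + 1e-6 * (link.upper - link.lower),
                        link.upper - 1e-6 * (link.upper - link.lower))
            x0[s, c] = inverse_sigmoid_link(v, link)
            counts[s, c] = 1
    mu0 = x0.mean(axis=0)
    tau0 = np.clip(x0.std(axis=0), 0.3, None)
    sigma = 0.1 * np.array([config.links[c].upper - config.links[c].lower for c in CHANNELS])
    point = ParamPoint(
        velocity=VelocityParams.zeros(),
        sigma=sigma,
        ologit=OrderedLogitParams(c1=-1.0, c2=1.0, beta_x=np.zeros(N_STATE), beta_y=np.zeros(2)),
        mu0=mu0, tau0=tau0, x0=x0,
        links=dict(config.links) if config.estimate_links else None,
    )
    if jitter > 0:
        point.x0 = point.x0 + jitter * rng.standard_normal(point.x0.shape)
        point.mu0 = point.mu0 + jitter * rng.standard_normal(N_STATE)
    return point


# ---------------------------------------------------------------------------
# Model façade
# ---------------------------------------------------------------------------


class ProgressionModel:
    """Multivariate ODE progression model bound to a cohort.

    Parameters
    ----------
    cohort : Cohort
        Longitudinal observations, diagnoses and covariates.
    config : ModelConfig, optional
        Priors, links, censoring and sampler settings.
    """

    def __init__(self, cohort: Cohort, config: ModelConfig | None = None):
        if cohort.n_subjects < 1:
            raise ValueError("cohort is empty")
        self.cohort = cohort
        self.config = config or ModelConfig()
        self.flat = FlatData(cohort, self.config)

    @classmethod
    def from_dataframes(
        cls,
        observations: pd.DataFrame,
        diagnoses: pd.DataFrame,
        covariates: pd.DataFrame,
        config: ModelConfig | None = None,
    ) -> "ProgressionModel":
        cohort = Cohort(covariates=covariates, observations=observations, diagnoses=diagnoses)
        return cls(cohort.anchor_times(), config)

    def loglik(self, point: ParamPoint) -> float:
        """Joint posterior log density at a parameter point."""
        return build_joint_loglik(self.cohort, point, self.config)

    def initial_point(self, rng: np.random.Generator | None = None, jitter: float = 0.0) -> ParamPoint:
        """Data-informed starting point: x0 from inverse-linked first visits."""
        return default_initial_point(self.flat, self.config, rng or np.random.default_rng(0), jitter)

    def fit(self, **overrides) -> "ProgressionResults":
        """Run MCMC and return results; keyword overrides update the config."""
        from ._mcmc import run_chains
        from .results import ProgressionResults

        config = replace(self.config, **overrides) if overrides else self.config
        draws = run_chains(self.flat, config)
        return ProgressionResults(self, draws)
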