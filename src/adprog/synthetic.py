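"""ADNI-like synthetic cohorts simulated from known parameters.

The generator forward-simulates the full model: subject covariates, initial
latent states from the population distribution, exact latent trajectories,
sigmoid-linked noisy channel observations with right-censored amyloid, and
ordinal diagnosis labels.  Visit schedules emulate the sparse, irregular and
unsynchronised sampling of observational AD studies: roughly biennial CSF
lumbar punctures (about two per subject, short follow-up) and annual-ish
cognitive testing (about five to six visits, longer follow-up), with at most
one diagnosis assessment per year.

Ground truth (parameters, initial states, noiseless trajectories and
conversion times) is stored next to the cohort so recovery experiments never
need re-simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clinical
from .clinical import LABELS, OrderedLogitParams
from .dynamics import CHANNELS, CovariateVector, VelocityParams, assemble_system, solve_trajectory
from .io import Cohort
from .observation import (
    CensorSpec,
    LinkParams,
    NoiseParams,
    default_censoring,
    default_links,
    default_noise,
    sigmoid_link,
)


def default_true_velocity() -> VelocityParams:
    """Illustrative truth on the standardised latent scale (units: per year).

    Chosen to mimic the qualitative findings on the real cohort: tau
    accumulation accelerates with the tau level itself and with amyloid
    burden (low latent abeta), cognition declines when either CSF marker is
    abnormal, APOE4 carriers accumulate amyloid faster, and CSF dynamics are
    slower than cognition.  The latent abeta component is oriented so that
    larger values mean higher observed CSF abeta (healthier).
    """
    V = np.array([
        #  tau   abeta   lang   mem  praxis
        [0.12, -0.10, 0.00, 0.00, 0.00],   # d tau/dt
        [-0.05, -0.08, 0.00, 0.00, 0.00],  # d abeta/dt
        [0.10, -0.08, -0.05, 0.00, 0.00],  # d lang/dt
        [0.14, -0.10, 0.00, -0.05, 0.00],  # d mem/dt
        [0.08, -0.06, 0.00, 0.00, -0.05],  # d praxis/dt
    ])
    W_age = np.array([
        [0.03, 0.00, 0.00, 0.00, 0.00],
        [0.00, -0.02, 0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00, 0.00, 0.00],
        [0.03, 0.00, 0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00, 0.00, 0.00],
    ])
    W_apoe = np.array([
        [0.04, 0.00, 0.00, 0.00, 0.00],
        [-0.02, -0.04, 0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00, 0.00, 0.00],
        [0.05, -0.03, 0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00, 0.00, 0.00],
    ])
    v0 = np.array([0.02, -0.02, 0.01, 0.02, 0.01])
    return VelocityParams(V=V, W_age=W_age, W_apoe=W_apoe, v0=v0)


def default_ordered_logit() -> OrderedLogitParams:
    return OrderedLogitParams(
        c1=-0.6,
        c2=1.6,
        beta_x=np.array([0.8, -0.8, 0.5, 0.9, 0.4]),
        beta_y=np.array([0.2, 0.3]),
    )


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Visit-schedule defaults are calibrated so that per-subject observation
    counts and follow-up durations land near the real cohort's summary
    statistics (about 1.9 CSF and 5.6 cognitive observations per subject,
    mean follow-ups of roughly 1.5 and 4 years, maxima near 10 and 15
    years).
    """

    n_subjects: int = 150
    n_sites: int = 6
    seed: int = 0
    # covariates
    age_mean: float = 73.0
    age_sd: float = 7.0
    apoe4_prevalence: float = 0.45
    age_center: float = 75.0
    age_scale: float = 10.0
    # population initial-state distribution
    mu0: np.ndarray = field(default_factory=lambda: np.zeros(5))
    tau0: np.ndarray = field(default_factory=lambda: np.ones(5))
    # structural parameters
    velocity: VelocityParams = field(default_factory=default_true_velocity)
    links: dict[str, LinkParams] = field(default_factory=default_links)
    noise: dict[str, NoiseParams] = field(default_factory=default_noise)
    censoring: dict[str, CensorSpec] = field(default_factory=default_censoring)
    ordered_logit: OrderedLogitParams = field(default_factory=default_ordered_logit)
    # visit schedules (years)
    csf_followup_mean: float = 2.6
    csf_followup_max: float = 10.0
    csf_interval: float = 1.7
    csf_keep_prob: float = 0.95
    csf_max_visits: int = 8
    cog_followup_mean: float = 4.8
    cog_followup_max: float = 15.0
    cog_interval: float = 0.7
    cog_keep_prob: float = 0.80
    cog_max_visits: int = 16
    visit_jitter: float = 0.15
    # optional regular-visit override (e.g. recovery studies: 4 visits over 3 y)
    regular_visits: int | None = None
    regular_followup: float | None = None
    missingness: float = 0.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_sites <= 0:
            raise ValueError("n_subjects and n_sites must be positive")
        if not 0.0 <= self.apoe4_prevalence <= 1.0:
            raise ValueError("apoe4_prevalence must lie in [0, 1]")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.tau0 = np.asarray(self.tau0, dtype=float)
        if np.any(self.tau0 <= 0):
            raise ValueError("tau0 must be positive componentwise")


@dataclass
class GroundTruth:
    """Everything the generator knew: parameters, states, conversion times."""

    config: GeneratorConfig
    x0: np.ndarray                      # (n, 5)
    covariates: np.ndarray              # (n, 2) standardized age, apoe4
    conversion_time: np.ndarray         # (n,) years; NaN = never within horizon
    horizon: float

    def to_json(self) -> str:
        cfg = self.config
        payload = {
            "seed": cfg.seed,
            "n_subjects": cfg.n_subjects,
            "velocity": {
                "V": cfg.velocity.V.tolist(),
                "W_age": cfg.velocity.W_age.tolist(),
                "W_apoe": cfg.velocity.W_apoe.tolist(),
                "v0": cfg.velocity.v0.tolist(),
            },
            "mu0": cfg.mu0.tolist(),
            "tau0": cfg.tau0.tolist(),
            "x0": self.x0.tolist(),
            "covariates": self.covariates.tolist(),
            "conversion_time": [None if np.isnan(t) else t for t in self.conversion_time],
            "horizon": self.horizon,
        }
        return json.dumps(payload, indent=2)


def _schedule(rng: np.random.Generator, followup_mean: float, followup_max: float,
              interval: float, keep_prob: float, max_visits: int, jitter: float) -> np.ndarray:
    """Baseline visit plus a thinned, jittered periodic grid up to follow-up."""
    fup = min(rng.exponential(followup_mean), followup_max)
    grid = np.arange(interval, fup + 1e-9, interval)
    keep = rng.random(grid.size) < keep_prob
    times = grid[keep] + rng.uniform(-jitter, jitter, size=keep.sum())
    times = times[(times > 0.05)]
    times = np.concatenate(([0.0], np.sort(times)))[:max_visits]
    return times


def true_conversion_time(
    x0: np.ndarray,
    y: CovariateVector,
    velocity: VelocityParams,
    ologit: OrderedLogitParams,
    horizon: float = 30.0,
    step: float = 1.0 / 24.0,
) -> float:
    """First time the noiseless P(AD) curve crosses 0.5 (NaN if never)."""
    sys = assemble_system(velocity, y)
    grid = np.arange(0.0, horizon + step, step)
    traj = solve_trajectory(x0, sys, grid)
    p_ad = clinical.probs_along_trajectory(traj, y.vector, ologit)[:, 2]
    above = np.nonzero(p_ad >= 0.5)[0]
    if above.size == 0:
        return float("nan")
    i = above[0]
    if i == 0:
        return 0.0
    t0, t1 = grid[i - 1], grid[i]
    p0, p1 = p_ad[i - 1], p_ad[i]
    return float(t0 + (0.5 - p0) / (p1 - p0) * (t1 - t0))


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Forward-simulate a cohort; returns the cohort and its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    site_ids = np.array([f"S{i % config.n_sites:02d}" for i in range(n)])
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 55.0, 92.0)
    apoe = (rng.random(n) < config.apoe4_prevalence).astype(int)
    age_std = (ages - config.age_center) / config.age_scale
    x0 = config.mu0 + config.tau0 * rng.standard_normal((n, 5))

    obs_rows: list[dict] = []
    diag_rows: list[dict] = []
    conv = np.full(n, np.nan)
    horizon = 30.0
    for s in range(n):
        sid = f"SUB{s:04d}"
        y = CovariateVector(age_std=float(age_std[s]), apoe4=int(apoe[s]))
        sys = assemble_system(config.velocity, y)
        if config.regular_visits is not None:
            fup = config.regular_followup if config.regular_followup is not None else 3.0
            t_csf = np.linspace(0.0, fup, config.regular_visits)
            t_cog = t_csf.copy()
            cog_fup = fup
        else:
            t_csf = _schedule(rng, config.csf_followup_mean, config.csf_followup_max,
                              config.csf_interval, config.csf_keep_prob,
                              config.csf_max_visits, config.visit_jitter)
            t_cog = _schedule(rng, config.cog_followup_mean, config.cog_followup_max,
                              config.cog_interval, config.cog_keep_prob,
                              config.cog_max_visits, config.visit_jitter)
            cog_fup = t_cog.max()
        # diagnosis assessments: annual, at most one per year
        t_diag = np.arange(0.0, max(cog_fup, 0.0) + 1e-9, 1.0)

        all_times = np.unique(np.concatenate([t_csf, t_cog, t_diag]))
        traj = solve_trajectory(x0[s], sys, all_times)
        tidx = {t: i for i, t in enumerate(all_times)}

        for channels, times in (((0, 1), t_csf), ((2, 3, 4), t_cog)):
            for t in times:
                for c in channels:
                    if config.missingness > 0 and rng.random() < config.missingness:
                        continue
                    name = CHANNELS[c]
                    link = config.links[name]
                    mean = sigmoid_link(traj[tidx[t], c], link)
                    value = mean + config.noise_scale * config.noise[name].sigma * rng.standard_normal()
                    censored = False
                    spec = config.censoring.get(name)
                    if spec is not None and spec.upper_limit is not None and value > spec.upper_limit:
                        value, censored = spec.upper_limit, True
                    if spec is not None and spec.lower_limit is not None and value < spec.lower_limit:
                        value, censored = spec.lower_limit, True
                    obs_rows.append({
                        "subject_id": sid, "site_id": site_ids[s],
                        "time_years": float(t), "channel": name,
                        "value": float(value), "censored": censored, "se": 0.0,
                    })
        probs = clinical.probs_along_trajectory(
            traj[[tidx[t] for t in t_diag]], y.vector, config.ordered_logit
        )
        for t, p in zip(t_diag, probs):
            lab = LABELS[rng.choice(3, p=p / p.sum())]
            diag_rows.append({"subject_id": sid, "time_years": float(t), "label": lab})
        conv[s] = true_conversion_time(x0[s], y, config.velocity, config.ordered_logit, horizon=horizon)

    cohort = Cohort(
        covariates=pd.DataFrame({
            "subject_id": [f"SUB{s:04d}" for s in range(n)],
            "site_id": site_ids, "age": ages, "apoe4": apoe,
        }),
        observations=pd.DataFrame(obs_rows),
        diagnoses=pd.DataFrame(diag_rows),
        metadata={"generator_seed": config.seed, "n_subjects": n, "synthetic": True},
    )
    truth = GroundTruth(
        config=config,
        x0=x0,
        covariates=np.column_stack([age_std, apoe.astype(float)]),
        conversion_time=conv,
        horizon=horizon,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Frozen fixtures
# ---------------------------------------------------------------------------

FIXTURE_SPECS = {
    "tiny": dict(n_subjects=12, n_sites=2, seed=20301),
    "small": dict(n_subjects=150, n_sites=6, seed=20302),
    "medium": dict(n_subjects=600, n_sites=12, seed=20303),
}

# frozen checksums of the fixture cohorts (regenerated deterministically)
FIXTURE_CHECKSUMS = {
    "tiny": "ace4960b09f8592fe6b6bf6dae12328d75fc626b4d23afa7b01946615a16c351",
    "small": "f68d4760d88ca98fac40356bac848ea3e612464c41137c1cfd39509e51b8af14",
}


def cohort_checksum(cohort: Cohort) -> str:
    """SHA-256 of the canonical CSV serialisation (order- and format-stable)."""
    h = hashlib.sha256()
    for df in (cohort.covariates, cohort.observations.drop(columns=["se"], errors="ignore"), cohort.diagnoses):
        h.update(df.to_csv(index=False, float_format="%.8g").encode())
    return h.hexdigest()


def make_fixture(scale: str = "tiny") -> tuple[Cohort, GroundTruth]:
    """Frozen-seed cohorts for tests: tiny (12/2), small (150/6), medium (600/12)."""
    if scale not in FIXTURE_SPECS:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SPECS)}, got {scale!r}")
    cfg = GeneratorConfig(**FIXTURE_SPECS[scale])
    return generate_cohort(cfg)
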