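"""Results object wrapping posterior draws with diagnostics and summaries."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import N_STATE
from .model import ParamPoint, PosteriorDraws, ProgressionModel, unpack_velocity

logger = logging.getLogger("adprog")

RHAT_THRESHOLD = 1.05


def _arviz():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        import arviz
    return arviz


class ProgressionResults:
    """Posterior of the progression model fitted to one cohort.

    Carries the joint draws, convergence diagnostics (split R-hat, effective
    sample size), posterior summaries, and posterior-predictive replication.
    Forecasting for new subjects lives in the ``prediction`` module and is
    reachable through :meth:`forecast_subject`.
    """

    def __init__(self, model: ProgressionModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._diagnostics: pd.DataFrame | None = None
        self.warnings: list[str] = []
        draws.diagnostics = self.diagnostics()  # attaches convergence report

    # -- diagnostics --------------------------------------------------------
    def diagnostics(self) -> pd.DataFrame:
        """Split R-hat and bulk/tail ESS for every population parameter."""
        if self._diagnostics is not None:
            return self._diagnostics
        az = _arviz()
        df = self.draws.population_dataframe()
        names = [c for c in df.columns if c not in ("chain", "draw")]
        C, D = self.draws.n_chains, self.draws.n_draws
        data = {name: df[name].to_numpy().reshape(C, D) for name in names}
        idata = az.from_dict(posterior=data)
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata) if C > 1 else None
            ess = az.ess(idata)
        for name in names:
            r = float(rhat[name].values) if rhat is not None else np.nan
            rows.append({"param": name, "rhat": r, "ess_bulk": float(ess[name].values)})
        out = pd.DataFrame(rows).set_index("param")
        bad = out[out["rhat"] > RHAT_THRESHOLD]
        if len(bad):
            msg = f"{len(bad)} population parameters have split R-hat > {RHAT_THRESHOLD} (worst: " \
                  f"{bad['rhat'].idxmax()} = {bad['rhat'].max():.3f}); treat estimates with caution"
            self.warnings.append(msg)
            logger.warning(msg)
        self._diagnostics = out
        return out

    @property
    def converged(self) -> bool:
        d = self.diagnostics()
        return bool((d["rhat"].dropna() <= RHAT_THRESHOLD).all())

    # -- summaries ----------------------------------------------------------
    def summary(self, hdi_prob: float = 0.9) -> pd.DataFrame:
        """Posterior mean, sd and HDI per population parameter."""
        az = _arviz()
        df = self.draws.population_dataframe()
        names = [c for c in df.columns if c not in ("chain", "draw")]
        diag = self.diagnostics()
        rows = []
        for name in names:
            x = df[name].to_numpy()
            lo, hi = az.hdi(x, hdi_prob=hdi_prob)
            rows.append({
                "param": name, "mean": x.mean(), "sd": x.std(),
                f"hdi_{hdi_prob:.0%}_low": lo, f"hdi_{hdi_prob:.0%}_high": hi,
                "rhat": diag.loc[name, "rhat"], "ess_bulk": diag.loc[name, "ess_bulk"],
            })
        return pd.DataFrame(rows).set_index("param")

    def posterior_mean_point(self) -> ParamPoint:
        d = self.draws
        return ParamPoint(
            velocity=unpack_velocity(d.stacked("vel").mean(axis=0)),
            sigma=d.stacked("sigma").mean(axis=0),
            ologit=_mean_ologit(d),
            mu0=d.stacked("mu0").mean(axis=0),
            tau0=d.stacked("tau0").mean(axis=0),
            x0=d.stacked("x0").mean(axis=0),
        )

    # -- posterior predictive ----------------------------------------------
    def posterior_predictive(self, n_draws: int = 100, seed: int = 0) -> pd.DataFrame:
        """Replicate the cohort's observations under thinned posterior draws.

        Returns the observation table augmented with per-row posterior
        predictive mean, central 95% interval, replicated-censoring
        frequency, and an ``inside_95`` coverage flag for uncensored rows.
        """
        from .dynamics import affine_propagators

        flat = self.model.flat
        sub = self.draws.thin_to(n_draws)
        K = sub.n_chains * sub.n_draws
        rng = np.random.default_rng(seed)
        reps = np.empty((K, flat.o_value.size))
        cens = np.zeros((K, flat.o_value.size), dtype=bool)
        for k in range(K):
            pt = sub.point(k)
            A = (pt.velocity.V
                 + flat.age_std[:, None, None] * pt.velocity.W_age
                 + flat.apoe[:, None, None] * pt.velocity.W_apoe)
            M, m = affine_propagators(
                A[flat.times_subj],
                np.broadcast_to(pt.velocity.v0, (flat.n_times, N_STATE)),
                flat.times,
            )
            L = flat.latent(M, m, pt.x0)
            lat = L[flat.o_time, flat.o_chan]
            from scipy.special import expit
            mean = flat.row_lower + flat.row_span * expit(flat.row_slope * (lat - flat.row_mid))
            sd = np.sqrt(pt.sigma[flat.o_chan] ** 2 + flat.o_se ** 2)
            val = mean + sd * rng.standard_normal(mean.shape)
            over = np.isfinite(flat.row_limit) & (val > flat.row_limit)
            val = np.where(over, flat.row_limit, val)
            reps[k] = val
            cens[k] = over
        lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
        out = self.model.cohort.observations.copy()
        out["pp_mean"] = reps.mean(axis=0)
        out["pp_low"] = lo
        out["pp_high"] = hi
        out["pp_censored_frac"] = cens.mean(axis=0)
        out["inside_95"] = (~flat.o_censored) & (flat.o_value >= lo) & (flat.o_value <= hi)
        return out

    # -- forecasting convenience --------------------------------------------
    def forecast_subject(self, subject_id: str, **kwargs):
        from .prediction import forecast_subject

        return forecast_subject(self.model.cohort.subject(subject_id), self.draws, **kwargs)

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.draws.write_csv(directory / "draws.csv")
        self.diagnostics().to_csv(directory / "diagnostics.csv")
        self.summary().to_csv(directory / "summary.csv")


def _mean_ologit(draws: PosteriorDraws):
    from .model import unpack_ologit

    return unpack_ologit(draws.stacked("ologit").mean(axis=0))
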