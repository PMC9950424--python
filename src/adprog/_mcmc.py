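"""Blocked adaptive Metropolis-within-Gibbs sampler for the joint posterior.

The model structure makes a blocked scheme efficient:

* all per-subject initial states are updated in one vectorised sweep (their
  full conditionals are independent given the population parameters, and the
  affine-flow propagators depend only on population parameters, so a sweep
  costs a handful of matrix-vector products);
* velocity parameters are updated in adaptive-Metropolis blocks (V with v0,
  and the two covariate-interaction matrices), each requiring one batched
  matrix-exponential recomputation;
* observation noise and ordered-logit blocks reuse the cached latent states;
* the population mean of the initial states is a conjugate Gibbs draw, and
  the population scales are a cheap random-walk block on the log scale.

Proposal covariances follow Haario-style adaptation with Robbins-Monro
step-size tuning toward standard acceptance targets; adaptation runs during
warmup only, so the kept draws come from a fixed transition kernel.
"""

from __future__ import annotations

import logging

import numpy as np

from .dynamics import N_STATE, expm_batch
from .model import (
    FlatData,
    ModelConfig,
    N_FREE_PER_MATRIX,
    N_VEL,
    ParamPoint,
    PosteriorDraws,
    pack_ologit,
    pack_velocity,
    unpack_ologit,
    unpack_velocity,
)

logger = logging.getLogger("adprog")

_LOG_2PI = float(np.log(2.0 * np.pi))

# velocity blocks: (V, v0) and (W_age, W_apoe)
_VEL_BLOCKS = (
    np.concatenate([np.arange(N_FREE_PER_MATRIX), np.arange(3 * N_FREE_PER_MATRIX, N_VEL)]),
    np.arange(N_FREE_PER_MATRIX, 3 * N_FREE_PER_MATRIX),
)


class _AMBlock:
    """Adaptive-Metropolis proposal for one parameter block."""

    def __init__(self, dim: int, width: np.ndarray | float = 1.0, target: float = 0.234):
        # width: rough marginal scale guess (e.g. the prior sd) per component
        self.dim = dim
        self.log_scale = np.log(2.38 / np.sqrt(dim))
        self.target = target
        w = np.broadcast_to(np.asarray(width, float), (dim,)).astype(float)
        self.floor = np.diag((0.1 * w) ** 2)    # keeps proposals from collapsing
        self.chol = np.diag(w)
        # equal-weight (Welford) moments of the visited states
        self.count = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))
        self._since_chol = 0

    def propose(self, rng: np.random.Generator, cur: np.ndarray) -> np.ndarray:
        return cur + np.exp(self.log_scale) * (self.chol @ rng.standard_normal(self.dim))

    def set_cov(self, cov: np.ndarray) -> None:
        """Install an externally computed proposal covariance (e.g. a
        Gauss-Newton approximation) and stop empirical covariance learning."""
        self.chol = np.linalg.cholesky(cov + self.floor)
        self.log_scale = np.log(2.38 / np.sqrt(self.dim))
        self.frozen = True

    def adapt(self, cur: np.ndarray, acc_prob: float, it: int) -> None:
        self.log_scale += (it + 10.0) ** -0.6 * (acc_prob - self.target)
        if getattr(self, "frozen", False):
            return
        self.count += 1
        delta = cur - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, cur - self.mean)
        self._since_chol += 1
        if self._since_chol >= 50 and self.count > 2 * self.dim:
            self._since_chol = 0
            cov = self.m2 / self.count + self.floor
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass


class _Sampler:
    def __init__(self, flat: FlatData, config: ModelConfig, rng: np.random.Generator, init: ParamPoint):
        self.flat = flat
        self.cfg = config
        self.rng = rng
        self.w = config.likelihood_weight
        n = flat.n_subjects

        # Internally the velocity field is parametrised against centred
        # covariates, A = V~ + (age - age_bar) W_age + (apoe - apoe_bar) W_apoe
        # with V~ = V + age_bar W_age + apoe_bar W_apoe: an exact linear
        # reparametrisation that removes the strong V/W posterior
        # correlations.  Draws are stored in the original parametrisation.
        self.age_bar = float(flat.age_std.mean())
        self.apoe_bar = float(flat.apoe.mean())
        self.age_c = flat.age_std - self.age_bar
        self.apoe_c = flat.apoe - self.apoe_bar
        self.vel = self._to_tilde(pack_velocity(init.velocity))
        self.log_sigma = np.log(init.sigma)
        self.olg = pack_ologit(init.ologit)
        self.mu0 = init.mu0.copy()
        self.log_tau0 = np.log(init.tau0)
        self.x0 = init.x0.copy()
        self.links = dict(init.links) if init.links is not None else None

        # adaptation state; widths start at the prior scales (shrunk when the
        # likelihood is informative, which the warmup adaptation handles)
        if self.w > 0:
            vel_width: float = 0.05
            sig_width = olg_width = tau_width = 0.1
        else:
            vel_width = config.prior_velocity_scale
            sig_width, olg_width, tau_width = 0.5, config.prior_ologit_scale, 0.5
        self.b_vel = [_AMBlock(len(idx), width=vel_width) for idx in _VEL_BLOCKS]
        self.b_sigma = _AMBlock(N_STATE, width=sig_width)
        self.b_olg = _AMBlock(9, width=olg_width)
        self.b_tau0 = _AMBlock(N_STATE, width=tau_width)
        hier_width = np.concatenate([np.full(N_STATE, 0.3 if self.w > 0 else config.prior_mu0_scale),
                                     np.full(N_STATE, 0.2 if self.w > 0 else 0.7)])
        self.b_hier = _AMBlock(2 * N_STATE, width=hier_width)
        wu = config.warmup
        self._precond_iters = {wu // 4, wu // 2, (3 * wu) // 4} if wu >= 40 else set()
        self.x0_step = np.full(n, 0.3)
        self.x0_var = np.ones((n, N_STATE))
        self.x0_mean = self.x0.copy()

        # latent-scale pseudo-observation pieces (data- and link-dependent only)
        rows = ~flat.o_censored
        self._uncens = rows
        p = np.clip((flat.o_value[rows] - flat.row_lower[rows]) / flat.row_span[rows], 1e-3, 1.0 - 1e-3)
        self._pseudo_u = flat.row_mid[rows] + np.log(p / (1.0 - p)) / flat.row_slope[rows]
        self._pseudo_dlink = flat.row_span[rows] * flat.row_slope[rows] * p * (1.0 - p)
        self._pseudo_subj = flat.o_subj[rows]
        self._pseudo_time = flat.o_time[rows]
        self._pseudo_chan = flat.o_chan[rows]
        # map from centred (tilde) to original velocity coordinates, for the
        # exact prior precision in tilde space
        nf = N_FREE_PER_MATRIX
        T = np.eye(N_VEL)
        T[:nf, nf:2 * nf] = -self.age_bar * np.eye(nf)
        T[:nf, 2 * nf:3 * nf] = -self.apoe_bar * np.eye(nf)
        self._tilde_prior_prec = T.T @ T / config.prior_velocity_scale**2

        self._cond_cache = None
        self._recompute_velocity_caches(self.vel)
        self._refresh_row_caches()

    # -- cache plumbing -----------------------------------------------------
    def _to_orig(self, vec: np.ndarray) -> np.ndarray:
        out = vec.copy()
        nf = N_FREE_PER_MATRIX
        out[:nf] = vec[:nf] - self.age_bar * vec[nf:2 * nf] - self.apoe_bar * vec[2 * nf:3 * nf]
        return out

    def _to_tilde(self, vec: np.ndarray) -> np.ndarray:
        out = vec.copy()
        nf = N_FREE_PER_MATRIX
        out[:nf] = vec[:nf] + self.age_bar * vec[nf:2 * nf] + self.apoe_bar * vec[2 * nf:3 * nf]
        return out

    def _propagators(self, vel_vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flat = self.flat
        vp = unpack_velocity(vel_vec)
        A = (vp.V
             + self.age_c[:, None, None] * vp.W_age
             + self.apoe_c[:, None, None] * vp.W_apoe)
        aug = np.zeros((flat.n_times, N_STATE + 1, N_STATE + 1))
        aug[:, :N_STATE, :N_STATE] = A[flat.times_subj]
        aug[:, :N_STATE, N_STATE] = vp.v0
        aug *= flat.times[:, None, None]
        E = expm_batch(aug)
        return E[:, :N_STATE, :N_STATE], E[:, :N_STATE, N_STATE]

    def _recompute_velocity_caches(self, vel_vec: np.ndarray) -> None:
        self.M, self.m = self._propagators(vel_vec)
        self.L = self.flat.latent(self.M, self.m, self.x0)

    def _refresh_row_caches(self) -> None:
        flat = self.flat
        n = flat.n_subjects
        self.obs_rows = flat.obs_loglik_rows(self.L, np.exp(self.log_sigma))
        self.diag_rows = flat.diag_loglik_rows(self.L, unpack_ologit(self.olg))
        self.subj_obs = np.bincount(flat.o_subj, weights=self.obs_rows, minlength=n)
        self.subj_diag = np.bincount(flat.d_subj, weights=self.diag_rows, minlength=n) if self.diag_rows.size else np.zeros(n)
        self.x0_prior = flat.x0_logprior_rows(self.x0, self.mu0, np.exp(self.log_tau0))

    # -- priors on blocks ---------------------------------------------------
    def _vel_logprior(self, vel_vec: np.ndarray) -> float:
        # prior lives on the original (uncentred) parametrisation; the linear
        # map between the two has unit Jacobian
        return float(np.sum(-0.5 * (self._to_orig(vel_vec) / self.cfg.prior_velocity_scale) ** 2))

    def _sigma_logprior(self, log_sigma: np.ndarray) -> float:
        sigma = np.exp(log_sigma)
        scales = self.cfg.sigma_prior_scales()
        # half-normal on sigma plus the log-scale Jacobian
        return float(np.sum(-0.5 * (sigma / scales) ** 2 + log_sigma))

    def _olg_logprior(self, olg: np.ndarray) -> float:
        s = self.cfg.prior_ologit_scale
        gap = np.exp(olg[1])
        lp = -0.5 * (olg[0] / s) ** 2
        lp += -0.5 * (gap / self.cfg.prior_cutgap_scale) ** 2 + olg[1]  # half-normal + Jacobian
        lp += float(np.sum(-0.5 * (olg[2:] / s) ** 2))
        return lp

    def _tau0_logprior(self, log_tau0: np.ndarray) -> float:
        tau0 = np.exp(log_tau0)
        return float(np.sum(-0.5 * (tau0 / self.cfg.prior_tau0_scale) ** 2 + log_tau0))

    # -- block updates ------------------------------------------------------
    def update_x0(self, it: int, adapting: bool) -> None:
        flat, rng = self.flat, self.rng
        n = flat.n_subjects
        sd = np.sqrt(self.x0_var)
        prop = self.x0 + self.x0_step[:, None] * sd * rng.standard_normal((n, N_STATE))
        Lp = flat.latent(self.M, self.m, prop)
        obs_p = flat.obs_loglik_rows(Lp, np.exp(self.log_sigma))
        diag_p = flat.diag_loglik_rows(Lp, unpack_ologit(self.olg))
        so_p = np.bincount(flat.o_subj, weights=obs_p, minlength=n)
        sd_p = np.bincount(flat.d_subj, weights=diag_p, minlength=n) if diag_p.size else np.zeros(n)
        pr_p = flat.x0_logprior_rows(prop, self.mu0, np.exp(self.log_tau0))
        logr = self.w * (so_p - self.subj_obs + sd_p - self.subj_diag) + pr_p - self.x0_prior
        acc = np.log(rng.random(n)) < logr
        if acc.any():
            self.x0[acc] = prop[acc]
            tmask = acc[flat.times_subj]
            self.L[tmask] = Lp[tmask]
            omask = acc[flat.o_subj]
            self.obs_rows[omask] = obs_p[omask]
            if diag_p.size:
                dmask = acc[flat.d_subj]
                self.diag_rows[dmask] = diag_p[dmask]
                self.subj_diag[acc] = sd_p[acc]
            self.subj_obs[acc] = so_p[acc]
            self.x0_prior[acc] = pr_p[acc]
        if adapting:
            gamma = (it + 10.0) ** -0.6
            self.x0_step *= np.exp(gamma * (np.minimum(np.exp(logr), 1.0) - 0.28))
            delta = self.x0 - self.x0_mean
            self.x0_mean += gamma * delta
            self.x0_var += gamma * (delta * delta - self.x0_var)
            np.clip(self.x0_var, 1e-4, None, out=self.x0_var)

    def _pseudo_precisions(self) -> np.ndarray:
        """Latent-scale precision of each uncensored pseudo-observation."""
        flat = self.flat
        rows = self._uncens
        sd_obs = np.sqrt(np.exp(self.log_sigma)[self._pseudo_chan] ** 2 + flat.o_se[rows] ** 2)
        return (self._pseudo_dlink / sd_obs) ** 2

    def _x0_conditional(self, M: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gaussian surrogate for the per-subject x0 conditional.

        Observations are pulled back through the inverse sigmoid link
        (pseudo-observations on the latent scale with delta-method noise), in
        which the trajectory is linear in x0; diagnosis and censored rows are
        omitted.  Returns (mean (n,5), precision (n,5,5)).  Used only inside
        Metropolis-Hastings proposals, so the approximation is corrected
        exactly at acceptance time.
        """
        n = self.flat.n_subjects
        tau0 = np.exp(self.log_tau0)
        prec = np.zeros((n, N_STATE, N_STATE))
        prec[:] = np.diag(1.0 / tau0**2)
        rhs = np.zeros((n, N_STATE))
        rhs[:] = self.mu0 / tau0**2
        if self.w > 0 and self._pseudo_u.size:
            wgt = self.w * self._pseudo_precisions()
            a = M[self._pseudo_time, self._pseudo_chan, :]            # (R,5)
            resid = self._pseudo_u - m[self._pseudo_time, self._pseudo_chan]
            R = a.shape[0]
            outer = (wgt[:, None, None] * np.einsum("ri,rj->rij", a, a)).reshape(R, N_STATE * N_STATE)
            idx = self._pseudo_subj[:, None] * (N_STATE * N_STATE) + np.arange(N_STATE * N_STATE)
            prec += np.bincount(idx.ravel(), weights=outer.ravel(),
                                minlength=n * N_STATE * N_STATE).reshape(n, N_STATE, N_STATE)
            idx5 = self._pseudo_subj[:, None] * N_STATE + np.arange(N_STATE)
            rhs += np.bincount(idx5.ravel(), weights=((wgt * resid)[:, None] * a).ravel(),
                               minlength=n * N_STATE).reshape(n, N_STATE)
        mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
        return mean, prec

    def _current_conditional(self):
        if self._cond_cache is None:
            mean, prec = self._x0_conditional(self.M, self.m)
            self._cond_cache = (mean, prec, np.linalg.cholesky(prec))
        return self._cond_cache

    def refresh_velocity_preconditioner(self) -> None:
        """Install Gauss-Newton proposal covariances for the velocity blocks.

        In the linearised pseudo-observation model the subject initial states
        marginalise out analytically, leaving a Gaussian marginal likelihood
        whose Jacobian in the velocity parameters is cheap to difference.
        The resulting Fisher information (plus the exact prior precision in
        the centred coordinates) gives proposal covariances that are shaped
        like the x0-marginal posterior, which random-walk covariance
        adaptation cannot learn within a realistic warmup.
        """
        if self.w <= 0 or self._pseudo_u.size == 0:
            return
        tau0 = np.exp(self.log_tau0)
        wgt = self.w * self._pseudo_precisions()
        a0 = self.M[self._pseudo_time, self._pseudo_chan, :]           # d lat / d x0
        lat0 = np.einsum("ri,ri->r", a0, self.x0[self._pseudo_subj]) + self.m[self._pseudo_time, self._pseudo_chan]
        R = lat0.size
        h = 1e-4
        J = np.empty((R, N_VEL))                                       # d lat / d vel, x0 fixed
        for j in range(N_VEL):
            v = self.vel.copy()
            v[j] += h
            Mj, mj = self._propagators(v)
            latj = (np.einsum("ri,ri->r",
                              Mj[self._pseudo_time, self._pseudo_chan, :],
                              self.x0[self._pseudo_subj])
                    + mj[self._pseudo_time, self._pseudo_chan])
            J[:, j] = (latj - lat0) / h
        # marginal Fisher via the Schur complement over the subject states:
        # F = F_vv - sum_s F_vx,s F_xx,s^-1 F_xv,s
        fisher = self._tilde_prior_prec + (J.T * wgt) @ J
        order = np.argsort(self._pseudo_subj, kind="stable")
        bounds = np.searchsorted(self._pseudo_subj[order], np.arange(self.flat.n_subjects + 1))
        prior_xx = np.diag(1.0 / tau0**2)
        for s in range(self.flat.n_subjects):
            idx = order[bounds[s]:bounds[s + 1]]
            if idx.size == 0:
                continue
            A_s = a0[idx] * wgt[idx, None]                             # weighted design
            F_xx = prior_xx + a0[idx].T @ A_s
            F_vx = J[idx].T @ A_s                                      # (62,5)
            fisher -= F_vx @ np.linalg.solve(F_xx, F_vx.T)
        cov = np.linalg.inv(fisher)
        for idx, am in zip(_VEL_BLOCKS, self.b_vel):
            block_cov = cov[np.ix_(idx, idx)]
            try:
                am.set_cov(block_cov)
            except np.linalg.LinAlgError:
                pass

    @staticmethod
    def _gauss_sample_and_logpdf(mean, prec, rng, x=None):
        """Sample from N(mean, prec^-1) per subject (or evaluate at x); returns
        (value, log density summed over subjects)."""
        chol = np.linalg.cholesky(prec)                                # (n,5,5)
        logdet = float(np.log(np.einsum("nii->ni", chol)).sum())       # = 0.5 log|P| summed
        if x is None:
            z = rng.standard_normal(mean.shape)
            # solve L^T d = z  =>  x = mean + d  has covariance P^-1
            d = np.linalg.solve(np.swapaxes(chol, 1, 2), z[..., None])[..., 0]
            x = mean + d
            quad = 0.5 * float((z * z).sum())
        else:
            d = x - mean
            Ld = np.einsum("nji,nj->ni", chol, d)                      # L^T d
            quad = 0.5 * float((Ld * Ld).sum())
        logpdf = logdet - quad - 0.5 * mean.size * _LOG_2PI
        return x, logpdf

    def update_velocity(self, it: int, adapting: bool) -> None:
        """Ridge-following joint move: propose a velocity block and translate
        every subject's x0 by the induced shift of its linearised conditional
        mean.  The translation is deterministic with unit Jacobian and exact
        reverse symmetry, so the acceptance ratio is just the joint density
        ratio — but the move walks along the velocity/initial-state ridge
        instead of across it."""
        flat = self.flat
        n = flat.n_subjects
        for idx, am in zip(_VEL_BLOCKS, self.b_vel):
            prop_vel = self.vel.copy()
            prop_vel[idx] = am.propose(self.rng, self.vel[idx])
            Mp, mp = self._propagators(prop_vel)
            mean_p, prec_p = self._x0_conditional(Mp, mp)
            mean_c, prec_c, Lc = self._current_conditional()
            # transport each subject's residual through the conditional:
            # whiten under the current precision, unwhiten under the proposed
            Lp_ = np.linalg.cholesky(prec_p)
            z = np.einsum("nji,nj->ni", Lc, self.x0 - mean_c)          # L_c^T r
            x0_p = mean_p + np.linalg.solve(np.swapaxes(Lp_, 1, 2), z[..., None])[..., 0]
            log_jac = float(np.log(np.einsum("nii->ni", Lc)).sum()
                            - np.log(np.einsum("nii->ni", Lp_)).sum())
            Lp = flat.latent(Mp, mp, x0_p)
            obs_p = flat.obs_loglik_rows(Lp, np.exp(self.log_sigma))
            diag_p = flat.diag_loglik_rows(Lp, unpack_ologit(self.olg))
            prior_p = flat.x0_logprior_rows(x0_p, self.mu0, np.exp(self.log_tau0))
            logr = (self.w * (obs_p.sum() - self.obs_rows.sum() + diag_p.sum() - self.diag_rows.sum())
                    + prior_p.sum() - self.x0_prior.sum()
                    + self._vel_logprior(prop_vel) - self._vel_logprior(self.vel)
                    + log_jac)
            acc_prob = float(np.exp(min(logr, 0.0)))
            if np.log(self.rng.random()) < logr:
                self.vel = prop_vel
                self.x0 = x0_p
                self.M, self.m, self.L = Mp, mp, Lp
                self.obs_rows, self.diag_rows = obs_p, diag_p
                self.subj_obs = np.bincount(flat.o_subj, weights=obs_p, minlength=n)
                if diag_p.size:
                    self.subj_diag = np.bincount(flat.d_subj, weights=diag_p, minlength=n)
                self.x0_prior = prior_p
                self._cond_cache = (mean_p, prec_p, Lp_)
            if adapting:
                am.adapt(self.vel[idx], acc_prob, it)

    def update_sigma(self, it: int, adapting: bool) -> None:
        prop = self.b_sigma.propose(self.rng, self.log_sigma)
        obs_p = self.flat.obs_loglik_rows(self.L, np.exp(prop))
        logr = (self.w * (obs_p.sum() - self.obs_rows.sum())
                + self._sigma_logprior(prop) - self._sigma_logprior(self.log_sigma))
        acc_prob = float(np.exp(min(logr, 0.0)))
        if np.log(self.rng.random()) < logr:
            self.log_sigma = prop
            self.obs_rows = obs_p
            self.subj_obs = np.bincount(self.flat.o_subj, weights=obs_p, minlength=self.flat.n_subjects)
            self._cond_cache = None
        if adapting:
            self.b_sigma.adapt(self.log_sigma, acc_prob, it)

    def update_ologit(self, it: int, adapting: bool) -> None:
        if self.flat.d_label.size == 0:
            return
        prop = self.b_olg.propose(self.rng, self.olg)
        diag_p = self.flat.diag_loglik_rows(self.L, unpack_ologit(prop))
        logr = (self.w * (diag_p.sum() - self.diag_rows.sum())
                + self._olg_logprior(prop) - self._olg_logprior(self.olg))
        acc_prob = float(np.exp(min(logr, 0.0)))
        if np.log(self.rng.random()) < logr:
            self.olg = prop
            self.diag_rows = diag_p
            self.subj_diag = np.bincount(self.flat.d_subj, weights=diag_p, minlength=self.flat.n_subjects)
        if adapting:
            self.b_olg.adapt(self.olg, acc_prob, it)

    def update_mu0(self) -> None:
        # conjugate normal-normal given x0 and tau0
        n = self.flat.n_subjects
        tau2 = np.exp(2.0 * self.log_tau0)
        prec = n / tau2 + 1.0 / self.cfg.prior_mu0_scale ** 2
        mean = (self.x0.sum(axis=0) / tau2) / prec
        self.mu0 = mean + self.rng.standard_normal(N_STATE) / np.sqrt(prec)
        self.x0_prior = self.flat.x0_logprior_rows(self.x0, self.mu0, np.exp(self.log_tau0))
        self._cond_cache = None

    def update_tau0(self, it: int, adapting: bool) -> None:
        prop = self.b_tau0.propose(self.rng, self.log_tau0)
        pr_p = self.flat.x0_logprior_rows(self.x0, self.mu0, np.exp(prop))
        logr = (pr_p.sum() - self.x0_prior.sum()
                + self._tau0_logprior(prop) - self._tau0_logprior(self.log_tau0))
        acc_prob = float(np.exp(min(logr, 0.0)))
        if np.log(self.rng.random()) < logr:
            self.log_tau0 = prop
            self.x0_prior = pr_p
            self._cond_cache = None
        if adapting:
            self.b_tau0.adapt(self.log_tau0, acc_prob, it)

    def update_hierarchy_noncentered(self, it: int, adapting: bool) -> None:
        """Interweaving move: update (mu0, tau0) with the standardised initial
        states z = (x0 - mu0) / tau0 held fixed, translating/rescaling every
        subject's x0 jointly.  Breaks the centered-parameterisation funnel."""
        flat = self.flat
        tau0 = np.exp(self.log_tau0)
        z = (self.x0 - self.mu0) / tau0
        cur = np.concatenate([self.mu0, self.log_tau0])
        prop = self.b_hier.propose(self.rng, cur)
        mu0_p, log_tau0_p = prop[:N_STATE], prop[N_STATE:]
        x0_p = mu0_p + np.exp(log_tau0_p) * z
        Lp = flat.latent(self.M, self.m, x0_p)
        obs_p = flat.obs_loglik_rows(Lp, np.exp(self.log_sigma))
        diag_p = flat.diag_loglik_rows(Lp, unpack_ologit(self.olg))
        # in non-centered coordinates the z-density drops out of the ratio
        logr = self.w * (obs_p.sum() - self.obs_rows.sum() + diag_p.sum() - self.diag_rows.sum())
        logr += float(np.sum(-0.5 * (mu0_p / self.cfg.prior_mu0_scale) ** 2
                             - (-0.5 * (self.mu0 / self.cfg.prior_mu0_scale) ** 2)))
        logr += self._tau0_logprior(log_tau0_p) - self._tau0_logprior(self.log_tau0)
        acc_prob = float(np.exp(min(logr, 0.0)))
        if np.log(self.rng.random()) < logr:
            self.mu0, self.log_tau0, self.x0 = mu0_p, log_tau0_p, x0_p
            self.L = Lp
            self.obs_rows, self.diag_rows = obs_p, diag_p
            n = flat.n_subjects
            self.subj_obs = np.bincount(flat.o_subj, weights=obs_p, minlength=n)
            if diag_p.size:
                self.subj_diag = np.bincount(flat.d_subj, weights=diag_p, minlength=n)
            self.x0_prior = flat.x0_logprior_rows(self.x0, self.mu0, np.exp(self.log_tau0))
            self._cond_cache = None
        if adapting:
            self.b_hier.adapt(np.concatenate([self.mu0, self.log_tau0]), acc_prob, it)

    def sweep(self, it: int, adapting: bool) -> None:
        if adapting and it > 0 and it in self._precond_iters:
            self.refresh_velocity_preconditioner()
        self.update_x0(it, adapting)
        for _ in range(max(1, self.cfg.velocity_updates_per_sweep)):
            self.update_velocity(it, adapting)
        self.update_sigma(it, adapting)
        self.update_ologit(it, adapting)
        self.update_mu0()
        self.update_tau0(it, adapting)
        self.update_hierarchy_noncentered(it, adapting)


def run_chains(flat: FlatData, config: ModelConfig) -> PosteriorDraws:
    """Run the configured number of chains and collect draws."""
    from .model import default_initial_point

    n = flat.n_subjects
    C, D = config.chains, config.draws
    out = {
        "vel": np.empty((C, D, N_VEL)),
        "sigma": np.empty((C, D, N_STATE)),
        "ologit": np.empty((C, D, 9)),
        "mu0": np.empty((C, D, N_STATE)),
        "tau0": np.empty((C, D, N_STATE)),
        "x0": np.empty((C, D, n, N_STATE)),
    }
    seeds = np.random.SeedSequence(config.seed).spawn(C)
    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        init = default_initial_point(flat, config, rng, jitter=0.05 if c else 0.0)
        s = _Sampler(flat, config, rng, init)
        total = config.warmup + D * config.thin
        kept = 0
        for it in range(total):
            s.sweep(it, adapting=it < config.warmup)
            if it >= config.warmup and (it - config.warmup) % config.thin == 0:
                out["vel"][c, kept] = s._to_orig(s.vel)
                out["sigma"][c, kept] = np.exp(s.log_sigma)
                out["ologit"][c, kept] = s.olg
                out["mu0"][c, kept] = s.mu0
                out["tau0"][c, kept] = np.exp(s.log_tau0)
                out["x0"][c, kept] = s.x0
                kept += 1
            if config.progress and (it + 1) % 200 == 0:
                logger.info("chain %d: %d/%d sweeps", c, it + 1, total)
    return PosteriorDraws(
        vel=out["vel"], sigma=out["sigma"], ologit=out["ologit"],
        mu0=out["mu0"], tau0=out["tau0"], x0=out["x0"],
        subject_ids=list(flat.subject_ids), config=config,
    )
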