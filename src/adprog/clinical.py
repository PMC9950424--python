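"""Ordered-logit model of the clinical diagnosis (CN < MCI < AD).

The diagnostic label at an assessment time is modelled as an ordinal outcome
with linear predictor eta = beta_x . x(t) + beta_y . y built from the latent
disease state at that time and the subject covariates, and two ordered
cutpoints:

    P(CN)        = logistic(c1 - eta)
    P(CN or MCI) = logistic(c2 - eta)

so the three label probabilities are differences of the cumulative curve.
Decision boundaries in biomarker space (where the most likely label flips)
shift with the covariates through beta_y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .dynamics import N_STATE

LABELS = ("CN", "MCI", "AD")
LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class OrderedLogitParams:
    """Cutpoints (c1 < c2) and regression coefficients of the diagnosis model."""

    c1: float
    c2: float
    beta_x: np.ndarray
    beta_y: np.ndarray

    def __post_init__(self) -> None:
        if not self.c1 < self.c2:
            raise ValueError(f"cutpoints must satisfy c1 < c2, got {self.c1} >= {self.c2}")
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        if self.beta_x.shape != (N_STATE,):
            raise ValueError(f"beta_x must have length {N_STATE}")
        if self.beta_y.shape != (2,):
            raise ValueError("beta_y must have length 2 (age_std, apoe4)")


def label_probs_from_eta(eta: np.ndarray | float, c1: float, c2: float) -> np.ndarray:
    """(CN, MCI, AD) probabilities from the linear predictor; rows sum to 1."""
    eta = np.asarray(eta, dtype=float)
    p_cn = expit(c1 - eta)
    p_cn_mci = expit(c2 - eta)
    return np.stack([p_cn, p_cn_mci - p_cn, 1.0 - p_cn_mci], axis=-1)


def linear_predictor(x: np.ndarray, y: np.ndarray, params: OrderedLogitParams) -> np.ndarray:
    """eta = beta_x . x + beta_y . y, broadcasting over leading dims of x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x @ params.beta_x + y @ params.beta_y


def label_probs(x: np.ndarray, y: np.ndarray, params: OrderedLogitParams) -> np.ndarray:
    """Probability vector (CN, MCI, AD) for a latent state and covariates."""
    return label_probs_from_eta(linear_predictor(x, y, params), params.c1, params.c2)


def probs_along_trajectory(traj: np.ndarray, y: np.ndarray, params: OrderedLogitParams) -> np.ndarray:
    """Row-wise label probabilities along a latent trajectory (T x 5 -> T x 3)."""
    traj = np.asarray(traj, dtype=float)
    if traj.ndim == 1:
        traj = traj[None, :]
    return label_probs(traj, y, params)


def label_loglik(labels: np.ndarray, eta: np.ndarray, c1: float, c2: float) -> np.ndarray:
    """Log probability of observed label indices (0=CN, 1=MCI, 2=AD)."""
    probs = label_probs_from_eta(eta, c1, c2)
    idx = np.asarray(labels, dtype=int)
    picked = np.take_along_axis(probs, idx[..., None], axis=-1)[..., 0]
    return np.log(np.clip(picked, 1e-300, None))
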