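"""Measurement layer: sigmoid links, (censored) Gaussian likelihoods, IRT.

Latent disease components live on a dimensionless scale; each observed
channel is connected to its component through a bounded, strictly increasing
sigmoid (plateau at both ends) plus Gaussian noise on the observation scale.
CSF amyloid-beta is right-censored at the assay detection limit
(1700 pg/mL): censored rows contribute the Gaussian tail mass instead of a
density.  Cognitive item responses are handled with a graded response model
and scored into three domain traits (language, memory, praxis) with
curvature-based standard errors; larger trait values mean worse cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, log_ndtr
from scipy.stats import norm

ABETA_UPPER_LIMIT_PG_ML = 1700.0

COG_DOMAINS = ("lang", "mem", "praxis")


@dataclass(frozen=True)
class LinkParams:
    """Sigmoid link for one channel: lower/upper asymptotes (observation
    units), slope (>0, per latent unit) and midpoint (latent units)."""

    lower: float
    upper: float
    slope: float
    midpoint: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError(f"upper ({self.upper}) must exceed lower ({self.lower})")
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")


@dataclass(frozen=True)
class NoiseParams:
    """Gaussian observation noise for one channel (observation units)."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class CensorSpec:
    """Detection limits for one channel; either side may be absent."""

    upper_limit: float | None = None
    lower_limit: float | None = None

    def __post_init__(self) -> None:
        if self.upper_limit is not None and self.lower_limit is not None:
            if not self.lower_limit < self.upper_limit:
                raise ValueError("lower_limit must be below upper_limit")


def sigmoid_link(x: np.ndarray | float, link: LinkParams) -> np.ndarray | float:
    """Map latent values to the observation scale through the bounded sigmoid."""
    return link.lower + (link.upper - link.lower) * expit(link.slope * (np.asarray(x, float) - link.midpoint))


def inverse_sigmoid_link(value: np.ndarray | float, link: LinkParams) -> np.ndarray | float:
    """Latent value producing a given observation-scale value (must lie strictly
    inside the asymptotes)."""
    v = np.asarray(value, dtype=float)
    p = (v - link.lower) / (link.upper - link.lower)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("value outside the open interval (lower, upper) has no preimage")
    return link.midpoint + np.log(p / (1.0 - p)) / link.slope


def gaussian_loglik(value: np.ndarray | float, mean: np.ndarray | float, noise: NoiseParams) -> np.ndarray | float:
    """Log density of an uncensored observation."""
    return norm.logpdf(np.asarray(value, float), loc=mean, scale=noise.sigma)


def censored_gaussian_loglik(
    mean: np.ndarray | float,
    noise: NoiseParams,
    censor: CensorSpec,
    side: str = "upper",
) -> np.ndarray | float:
    """Log tail mass for a censored observation.

    Right-censoring (side="upper") contributes log P(X > upper_limit); left
    censoring is symmetric.  Raises if the requested limit is not configured.
    """
    mean = np.asarray(mean, dtype=float)
    if side == "upper":
        if censor.upper_limit is None:
            raise ValueError("censored observation on a channel without an upper limit")
        # P(X > L) = Phi((mean - L) / sigma)
        return log_ndtr((mean - censor.upper_limit) / noise.sigma)
    if side == "lower":
        if censor.lower_limit is None:
            raise ValueError("censored observation on a channel without a lower limit")
        return log_ndtr((censor.lower_limit - mean) / noise.sigma)
    raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")


def default_links() -> dict[str, LinkParams]:
    """Default sigmoid links: CSF channels in pg/mL, traits near-linear in
    their plausible range.  Asymptotes are fixed per channel (roughly the
    observed data range widened), anchoring the latent scale."""
    return {
        "tau": LinkParams(lower=50.0, upper=1200.0, slope=0.9, midpoint=1.5),
        "abeta": LinkParams(lower=200.0, upper=2400.0, slope=0.8, midpoint=0.0),
        "lang": LinkParams(lower=-4.0, upper=4.0, slope=1.0, midpoint=0.0),
        "mem": LinkParams(lower=-4.0, upper=4.0, slope=1.0, midpoint=0.0),
        "praxis": LinkParams(lower=-4.0, upper=4.0, slope=1.0, midpoint=0.0),
    }


def default_noise() -> dict[str, NoiseParams]:
    """Assay and test-retest noise levels typical of the modelled channels."""
    return {
        "tau": NoiseParams(40.0),
        "abeta": NoiseParams(120.0),
        "lang": NoiseParams(0.30),
        "mem": NoiseParams(0.30),
        "praxis": NoiseParams(0.30),
    }


def default_censoring() -> dict[str, CensorSpec]:
    """Amyloid-beta is right-censored at the assay's upper detection limit."""
    return {"abeta": CensorSpec(upper_limit=ABETA_UPPER_LIMIT_PG_ML)}


# ---------------------------------------------------------------------------
# Item response theory (graded response model)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Item:
    """One polytomous item: discrimination a > 0, strictly ascending category
    thresholds (latent units), and the cognitive domain it loads on."""

    discrimination: float
    thresholds: tuple[float, ...]
    domain: str

    def __post_init__(self) -> None:
        if self.discrimination < 0:
            raise ValueError("discrimination must be non-negative")
        th = np.asarray(self.thresholds, dtype=float)
        if th.size == 0:
            raise ValueError("item needs at least one threshold")
        if np.any(np.diff(th) <= 0):
            raise ValueError(f"thresholds must be strictly ascending, got {self.thresholds}")
        if self.domain not in COG_DOMAINS:
            raise ValueError(f"domain must be one of {COG_DOMAINS}, got {self.domain!r}")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass
class ItemBank:
    items: list[Item] = field(default_factory=list)

    def by_domain(self, domain: str) -> list[tuple[int, Item]]:
        return [(i, it) for i, it in enumerate(self.items) if it.domain == domain]


def irt_category_probs(trait: float, item: Item) -> np.ndarray:
    """Graded-response category probabilities at a trait value.

    P(cat >= c) = logistic(a * (trait - b_c)); category probabilities are
    successive differences of the cumulative curve.  Higher trait means
    higher (worse) categories.
    """
    th = np.asarray(item.thresholds, dtype=float)
    cum = expit(item.discrimination * (trait - th))
    full = np.concatenate(([1.0], cum, [0.0]))
    return full[:-1] - full[1:]


def _irt_neg_logpost(trait: float, responses: list[tuple[Item, int]]) -> float:
    lp = -0.5 * trait * trait  # standard-normal prior
    for item, cat in responses:
        p = irt_category_probs(trait, item)[cat]
        lp += np.log(max(p, 1e-300))
    return -lp


def score_traits(
    responses: list[tuple[Item, int]],
    bank: ItemBank | None = None,
) -> dict[str, tuple[float, float] | None]:
    """MAP trait estimate and curvature standard error per cognitive domain.

    responses: (item, observed category index) pairs for one visit.  Each
    domain is scored from its own items under a standard-normal prior; a
    domain with no responses maps to None (missing).
    """
    out: dict[str, tuple[float, float] | None] = {}
    for domain in COG_DOMAINS:
        dom = [(it, c) for it, c in responses if it.domain == domain]
        if not dom:
            out[domain] = None
            continue
        res = minimize_scalar(_irt_neg_logpost, args=(dom,), bounds=(-8.0, 8.0), method="bounded")
        est = float(res.x)
        h = 1e-4
        curv = (
            _irt_neg_logpost(est + h, dom) - 2.0 * _irt_neg_logpost(est, dom) + _irt_neg_logpost(est - h, dom)
        ) / (h * h)
        se = float(1.0 / np.sqrt(max(curv, 1e-8)))
        out[domain] = (est, se)
    return out
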