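"""Validation machinery: leave-one-site-out CV, discrimination, calibration,
decision curves, and time-to-conversion error analysis.

The cross-validation design holds out all subjects of one recruiting site
per fold (internal-external validation).  Each held-out subject is forecast
from its first two years of follow-up; predictions are scored at every
diagnosis assessment after the window.  Discrimination is AUROC of P(AD)
against the binarised label; calibration uses confidence- and
classwise-reliability diagrams with Beta-Binomial credible intervals at
0.2-width bins; clinical utility uses decision-curve net benefit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist, rankdata

from .io import Cohort
from .model import ModelConfig, ProgressionModel
from .prediction import (
    DEFAULT_HORIZON_YEARS,
    DEFAULT_WINDOW_YEARS,
    forecast_subject,
    time_to_conversion,
)

logger = logging.getLogger("adprog")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def loso_split(cohort: Cohort) -> list[tuple[list[str], str]]:
    """One fold per site: (training sites, held-out site).

    Folds partition subjects by recruiting site, so no subject appears on
    both sides of any fold.
    """
    sites = cohort.sites
    if len(sites) < 2:
        raise ValueError(
            "leave-one-site-out needs at least 2 sites; "
            "use grouped k-fold on another grouping variable instead"
        )
    return [([s for s in sites if s != test], test) for test in sites]


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outranks a random negative (ties 1/2).

    Computed from the rank-sum (Mann-Whitney U) with average ranks, which is
    exactly the concordant-pair count with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC is undefined with a single class present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def _beta_binomial_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Central posterior interval of a Beta(1,1)-Binomial accuracy."""
    a = (1.0 - level) / 2.0
    return (
        float(beta_dist.ppf(a, 1 + k, 1 + n - k)),
        float(beta_dist.ppf(1 - a, 1 + k, 1 + n - k)),
    )


def _bin_table(probs: np.ndarray, correct: np.ndarray, bin_width: float) -> pd.DataFrame:
    edges = np.arange(0.0, 1.0 + 1e-12, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (probs >= lo) & (probs < hi) if hi < 1.0 else (probs >= lo) & (probs <= 1.0)
        n = int(in_bin.sum())
        k = int(correct[in_bin].sum())
        ci = _beta_binomial_interval(k, n)
        rows.append({
            "bin_low": lo, "bin_high": hi, "count": n,
            "accuracy": k / n if n else np.nan,
            "ci_low": ci[0], "ci_high": ci[1],
        })
    return pd.DataFrame(rows)


def reliability_diagrams(
    preds: pd.DataFrame,
    bin_width: float = 0.2,
    confidence_min: float = 0.4,
) -> dict[str, pd.DataFrame]:
    """Confidence- and classwise-reliability tables with Beta-Binomial CIs.

    ``preds`` needs columns p_cn, p_mci, p_ad and label.  The confidence
    diagram bins the maximum class probability and reports overall accuracy
    (argmax equals the true class), restricted to probabilities above
    ``confidence_min`` since 1/3 is the smallest attainable maximum over
    three classes.  Classwise diagrams bin the probability assigned to each
    class and report that class's accuracy.  Empty bins carry the prior-only
    Beta(1,1) interval.
    """
    if len(preds) == 0:
        raise ValueError("no predictions to calibrate")
    P = preds[["p_cn", "p_mci", "p_ad"]].to_numpy(float)
    labels = preds["label"].map({"CN": 0, "MCI": 1, "AD": 2}).to_numpy(int)
    maxp = P.max(axis=1)
    argmax = P.argmax(axis=1)
    conf = _bin_table(maxp, argmax == labels, bin_width)
    conf = conf[conf["bin_high"] > confidence_min].reset_index(drop=True)
    out = {"confidence": conf}
    for j, cls in enumerate(("cn", "mci", "ad")):
        out[f"class_{cls}"] = _bin_table(P[:, j], labels == j, bin_width)
    return out


# ---------------------------------------------------------------------------
# Decision curves
# ---------------------------------------------------------------------------


def net_benefit(
    p_ad: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decision-curve net benefit for the model, treat-all and treat-none.

    NB(p_th) = TP/N - FP/N * p_th / (1 - p_th), treating P(AD) > p_th as
    test-positive.  Treat-all classifies everyone positive (its curve
    crosses zero exactly at the prevalence); treat-none is identically 0.
    """
    p_ad = np.asarray(p_ad, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if thresholds is None:
        thresholds = np.arange(0.05, 0.96, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    N = labels.size
    prevalence = labels.mean()
    rows = []
    for th in thresholds:
        pos = p_ad > th
        tp = float((pos & labels).sum()) / N
        fp = float((pos & ~labels).sum()) / N
        odds = th / (1.0 - th)
        rows.append({
            "threshold": th,
            "nb_model": tp - fp * odds,
            "nb_treat_all": prevalence - (1.0 - prevalence) * odds,
            "nb_treat_none": 0.0,
        })
    df = pd.DataFrame(rows)
    df.attrs["prevalence"] = float(prevalence)
    return df


# ---------------------------------------------------------------------------
# Time-to-conversion errors
# ---------------------------------------------------------------------------


def conversion_error_analysis(
    predictions: pd.DataFrame,
    observed: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Compare predicted t50 with observed conversion (or censoring) times.

    ``predictions``: subject_id, t50, horizon (t50 may be NaN =
    beyond-horizon, in which case the horizon is used as a right-censored
    prediction).  ``observed``: subject_id, converted (bool), event_time
    (first AD diagnosis for converters, max follow-up otherwise).  Errors
    are predicted minus observed; negative values for non-converters flag
    premature predicted conversion.  The cumulative |error| curve covers
    converters only.
    """
    df = predictions.merge(observed, on="subject_id", how="inner")
    t50 = df["t50"].to_numpy(float)
    pred = np.where(np.isfinite(t50), t50, df["horizon"].to_numpy(float))
    df["predicted_time"] = pred
    df["censored_prediction"] = ~np.isfinite(t50)
    df["error"] = pred - df["event_time"].to_numpy(float)
    conv = df[df["converted"]].copy()
    abs_err = np.sort(np.abs(conv["error"].to_numpy(float)))
    cum = pd.DataFrame({
        "abs_error": abs_err,
        "cum_fraction": (np.arange(1, abs_err.size + 1) / abs_err.size) if abs_err.size else [],
    })
    return {"errors": df, "cumulative": cum}


# ---------------------------------------------------------------------------
# End-to-end leave-one-site-out experiment
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Aggregated leave-one-site-out evaluation artefacts."""

    predictions: pd.DataFrame
    reliability: dict[str, pd.DataFrame]
    netbenefit: pd.DataFrame
    auroc_table: pd.DataFrame
    conversion: dict[str, pd.DataFrame]
    summary: dict = field(default_factory=dict)

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.predictions.to_csv(directory / "predictions.csv", index=False)
        pd.concat(
            [df.assign(diagram=name) for name, df in self.reliability.items()]
        ).to_csv(directory / "reliability.csv", index=False)
        self.netbenefit.to_csv(directory / "netbenefit.csv", index=False)
        self.auroc_table.to_csv(directory / "auroc.csv", index=False)
        self.conversion["errors"].to_csv(directory / "conversion_errors.csv", index=False)
        with open(directory / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, default=float)


def _observed_outcomes(cohort: Cohort, subject_ids: list[str]) -> pd.DataFrame:
    rows = []
    for sid in subject_ids:
        dia = cohort.diagnoses[cohort.diagnoses["subject_id"] == sid]
        ad = dia[dia["label"] == "AD"]
        converted = len(ad) > 0
        rows.append({
            "subject_id": sid,
            "converted": converted,
            "event_time": float(ad["time_years"].min()) if converted else float(dia["time_years"].max()),
        })
    return pd.DataFrame(rows)


def run_loso_experiment(
    cohort: Cohort,
    config: ModelConfig | None = None,
    window: float = DEFAULT_WINDOW_YEARS,
    horizon: float = DEFAULT_HORIZON_YEARS,
    auroc_horizons: tuple[float, ...] = (3.0, 5.0, 7.0),
    forecast_draws: int = 100,
    seed: int = 0,
) -> EvalReport:
    """Fit on all-but-one site, forecast the held-out site, aggregate scores.

    For every fold the model is refitted on the training sites only; each
    test subject with baseline-window data is forecast from its first
    ``window`` years, and a prediction is recorded at each diagnosis
    assessment after the window.  A master seed fans out deterministic
    per-fold seeds.  Folds whose test site has no post-window assessments
    are skipped with a warning.
    """
    config = config or ModelConfig()
    folds = loso_split(cohort)
    fold_seeds = np.random.SeedSequence(seed).generate_state(len(folds)) % (2**31)
    records = []
    conv_preds = []
    for fold_i, (train_sites, test_site) in enumerate(folds):
        cov = cohort.covariates
        train_ids = list(cov.loc[cov["site_id"].isin(train_sites), "subject_id"])
        test_ids = list(cov.loc[cov["site_id"] == test_site, "subject_id"])
        assert not set(train_ids) & set(test_ids), "train/test subject leakage"
        test_cohort = cohort.subset(test_ids)
        post = test_cohort.diagnoses[test_cohort.diagnoses["time_years"] > window]
        if len(post) == 0:
            logger.warning("fold %d (site %s): no post-window assessments; skipped", fold_i, test_site)
            continue
        train = cohort.subset(train_ids)
        fold_cfg = replace(config, seed=int(fold_seeds[fold_i]))
        model = ProgressionModel(train, fold_cfg)
        results = model.fit()
        draws = results.draws
        for sid in test_ids:
            subj = cohort.subject(sid)
            if len(subj.observations[subj.observations["time_years"] <= window]) == 0:
                continue
            assessments = subj.diagnoses[subj.diagnoses["time_years"] > window]
            t_max = max(horizon, float(subj.diagnoses["time_years"].max()) + 1e-6)
            try:
                fc = forecast_subject(
                    subj, draws, fold_cfg, t_max=t_max, window=window,
                    n_draws=forecast_draws, seed=int(fold_seeds[fold_i]),
                )
            except (ValueError, FloatingPointError) as exc:
                logger.warning("subject %s skipped: %s", sid, exc)
                continue
            for _, row in assessments.iterrows():
                p = np.array([np.interp(row["time_years"], fc.grid, fc.mean_probs[:, j]) for j in range(3)])
                records.append({
                    "subject_id": sid, "site_id": test_site, "fold": fold_i,
                    "time_years": float(row["time_years"]),
                    "p_cn": p[0], "p_mci": p[1], "p_ad": p[2],
                    "label": row["label"],
                })
            conv_preds.append(time_to_conversion(fc, horizon=horizon))

    preds = pd.DataFrame(records)
    if len(preds) == 0:
        raise ValueError("no scored predictions: every fold lacked post-window assessments")
    # AUROC at fixed horizons (assessments within +-0.5 years of the horizon)
    auroc_rows = []
    for h in auroc_horizons:
        sel = preds[np.abs(preds["time_years"] - h) <= 0.5]
        sel = sel.sort_values("time_years").groupby("subject_id").first().reset_index()
        y = (sel["label"] == "AD").to_numpy()
        if y.any() and not y.all():
            auroc_rows.append({"horizon_years": h, "auroc": auroc(sel["p_ad"].to_numpy(), y), "n": len(sel)})
        else:
            auroc_rows.append({"horizon_years": h, "auroc": np.nan, "n": len(sel)})
    y_all = (preds["label"] == "AD").to_numpy()
    if y_all.any() and not y_all.all():
        auroc_rows.append({"horizon_years": np.nan, "auroc": auroc(preds["p_ad"].to_numpy(), y_all),
                           "n": len(preds)})
    last = preds.sort_values("time_years").groupby("subject_id").last().reset_index()
    y_last = (last["label"] == "AD").to_numpy()
    if y_last.any() and not y_last.all():
        auroc_rows.append({"horizon_years": -1.0, "auroc": auroc(last["p_ad"].to_numpy(), y_last),
                           "n": len(last)})
    auroc_table = pd.DataFrame(auroc_rows)

    reliability = reliability_diagrams(preds)
    nb = net_benefit(preds["p_ad"].to_numpy(), y_all)
    conv_df = pd.DataFrame([
        {"subject_id": p.subject_id, "t50": p.t50, "horizon": p.horizon} for p in conv_preds
    ])
    observed = _observed_outcomes(cohort, list(conv_df["subject_id"])) if len(conv_df) else pd.DataFrame(
        columns=["subject_id", "converted", "event_time"])
    conversion = conversion_error_analysis(conv_df, observed) if len(conv_df) else {
        "errors": pd.DataFrame(), "cumulative": pd.DataFrame()}

    pooled = auroc_table.loc[auroc_table["horizon_years"].isna(), "auroc"]
    summary = {
        "n_folds": len(folds),
        "n_predictions": len(preds),
        "auroc_pooled_all_assessments": float(pooled.iloc[0]) if len(pooled) else None,
        "prevalence": float(y_all.mean()),
        "note": "assessment-level pooling; observations are clustered within subjects",
    }
    return EvalReport(
        predictions=preds,
        reliability=reliability,
        netbenefit=nb,
        auroc_table=auroc_table,
        conversion=conversion,
        summary=summary,
    )
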