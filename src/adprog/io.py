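"""Cohort container and long-format CSV readers/writers.

A cohort bundles three long-format tables:

* ``covariates``: one row per subject — subject_id, site_id, age (years at
  baseline), apoe4 (0/1).
* ``observations``: subject_id, site_id, time_years, channel, value,
  censored (0/1), se (optional per-row extra standard error, e.g. from IRT
  trait scoring; 0 when absent).
* ``diagnoses``: subject_id, time_years, label in {CN, MCI, AD}.

Times are decimal years from each subject's first observation; readers
re-anchor them.  Screening labels used at enrolment (SMC, EMCI, LMCI) are
mapped onto the three modelled labels (SMC->CN, EMCI/LMCI->MCI by default).
Malformed rows are rejected with a logged report, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import LABELS
from .dynamics import CHANNELS

logger = logging.getLogger("adprog")

DEFAULT_LABEL_MAP = {"CN": "CN", "SMC": "CN", "EMCI": "MCI", "LMCI": "MCI", "MCI": "MCI", "AD": "AD"}

OBS_COLUMNS = ["subject_id", "site_id", "time_years", "channel", "value", "censored"]
DIAG_COLUMNS = ["subject_id", "time_years", "label"]
COV_COLUMNS = ["subject_id", "site_id", "age", "apoe4"]


@dataclass
class SubjectRecord:
    """All data for one subject (a view extracted from a cohort)."""

    subject_id: str
    site_id: str
    age: float
    apoe4: int
    observations: pd.DataFrame
    diagnoses: pd.DataFrame


@dataclass
class Cohort:
    covariates: pd.DataFrame
    observations: pd.DataFrame
    diagnoses: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covariates = self.covariates.reset_index(drop=True)
        if "se" not in self.observations.columns:
            self.observations = self.observations.assign(se=0.0)
        self.validate()

    # -- basic accessors ----------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.covariates["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def sites(self) -> list[str]:
        return sorted(self.covariates["site_id"].astype(str).unique())

    def subject(self, subject_id: str) -> SubjectRecord:
        row = self.covariates.loc[self.covariates["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        row = row.iloc[0]
        return SubjectRecord(
            subject_id=subject_id,
            site_id=str(row["site_id"]),
            age=float(row["age"]),
            apoe4=int(row["apoe4"]),
            observations=self.observations.loc[self.observations["subject_id"] == subject_id].reset_index(drop=True),
            diagnoses=self.diagnoses.loc[self.diagnoses["subject_id"] == subject_id].reset_index(drop=True),
        )

    def subset(self, subject_ids: list[str]) -> "Cohort":
        keep = set(subject_ids)
        return Cohort(
            covariates=self.covariates[self.covariates["subject_id"].isin(keep)].copy(),
            observations=self.observations[self.observations["subject_id"].isin(keep)].copy(),
            diagnoses=self.diagnoses[self.diagnoses["subject_id"].isin(keep)].copy(),
            metadata=dict(self.metadata),
        )

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        known = set(self.covariates["subject_id"])
        for name, df in (("observations", self.observations), ("diagnoses", self.diagnoses)):
            orphans = set(df["subject_id"]) - known
            if orphans:
                raise ValueError(f"{name} reference unknown subjects: {sorted(orphans)[:5]}")
            if not np.all(np.isfinite(df["time_years"].to_numpy(float))):
                raise ValueError(f"{name} contain non-finite times")
        bad_chan = set(self.observations["channel"]) - set(CHANNELS)
        if bad_chan:
            raise ValueError(f"unknown observation channels: {sorted(bad_chan)}")
        bad_lab = set(self.diagnoses["label"]) - set(LABELS)
        if bad_lab:
            raise ValueError(f"unknown diagnosis labels: {sorted(bad_lab)}")
        if not set(self.covariates["apoe4"].astype(int)) <= {0, 1}:
            raise ValueError("apoe4 must be 0/1")

    def anchor_times(self) -> "Cohort":
        """Shift each subject's clock so t=0 is the first observation."""
        t0 = self.observations.groupby("subject_id")["time_years"].min()
        obs = self.observations.copy()
        obs["time_years"] = obs["time_years"] - obs["subject_id"].map(t0).fillna(0.0)
        dia = self.diagnoses.copy()
        dia["time_years"] = dia["time_years"] - dia["subject_id"].map(t0).fillna(0.0)
        return Cohort(self.covariates.copy(), obs, dia, dict(self.metadata))

    # -- serialization ------------------------------------------------------
    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        obs = self.observations.copy()
        obs["censored"] = obs["censored"].astype(int)
        obs.to_csv(directory / "observations.csv", index=False, float_format="%.10g")
        self.diagnoses.to_csv(directory / "diagnoses.csv", index=False, float_format="%.10g")
        self.covariates.to_csv(directory / "covariates.csv", index=False, float_format="%.10g")
        with open(directory / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def read_cohort(
    directory: str | Path | None = None,
    *,
    observations: str | Path | None = None,
    diagnoses: str | Path | None = None,
    covariates: str | Path | None = None,
    label_map: dict[str, str] | None = None,
    anchor: bool = True,
) -> Cohort:
    """Load and validate a cohort from CSV files.

    Either a directory holding observations.csv / diagnoses.csv /
    covariates.csv, or the three paths explicitly.  Rows failing validation
    (unknown channel, non-numeric value, duplicate subject/time/channel) are
    rejected; the rejection report is logged and stored in metadata.
    """
    if directory is not None:
        directory = Path(directory)
        observations = directory / "observations.csv"
        diagnoses = directory / "diagnoses.csv"
        covariates = directory / "covariates.csv"
    if observations is None or diagnoses is None or covariates is None:
        raise ValueError("need either a directory or all three file paths")
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)

    obs = pd.read_csv(observations, dtype={"subject_id": str, "site_id": str})
    dia = pd.read_csv(diagnoses, dtype={"subject_id": str})
    cov = pd.read_csv(covariates, dtype={"subject_id": str, "site_id": str})
    for name, df, req in (
        ("observations", obs, OBS_COLUMNS),
        ("diagnoses", dia, DIAG_COLUMNS),
        ("covariates", cov, COV_COLUMNS),
    ):
        missing = [c for c in req if c not in df.columns]
        if missing:
            raise ValueError(f"{name} file is missing required columns {missing}")

    rejections: list[str] = []

    bad = ~obs["channel"].isin(CHANNELS)
    for idx in obs.index[bad]:
        rejections.append(f"observations line {idx + 2}: unknown channel {obs.at[idx, 'channel']!r}")
    obs = obs[~bad]
    values = pd.to_numeric(obs["value"], errors="coerce")
    bad = values.isna()
    for idx in obs.index[bad]:
        rejections.append(f"observations line {idx + 2}: non-numeric value {obs.at[idx, 'value']!r}")
    obs = obs[~bad].assign(value=values[~bad])
    dup = obs.duplicated(subset=["subject_id", "time_years", "channel"], keep="first")
    for idx in obs.index[dup]:
        rejections.append(f"observations line {idx + 2}: duplicate (subject, time, channel) row")
    obs = obs[~dup]

    dia = dia.assign(label=dia["label"].map(lambda lab: label_map.get(str(lab), str(lab))))
    bad = ~dia["label"].isin(LABELS)
    for idx in dia.index[bad]:
        rejections.append(f"diagnoses line {idx + 2}: unknown label {dia.at[idx, 'label']!r}")
    dia = dia[~bad]

    obs = obs.assign(censored=obs["censored"].astype(int).astype(bool)).reset_index(drop=True)
    if "se" not in obs.columns:
        obs["se"] = 0.0
    cohort = Cohort(
        covariates=cov,
        observations=obs,
        diagnoses=dia.reset_index(drop=True),
        metadata={
            "source_files": [str(observations), str(diagnoses), str(covariates)],
            "n_rejected": len(rejections),
            "rejections": rejections[:100],
        },
    )
    if anchor:
        cohort = cohort.anchor_times()
    logger.info(
        "read cohort: %d subjects, %d observation rows, %d diagnoses, %d rejected rows",
        cohort.n_subjects, len(cohort.observations), len(cohort.diagnoses), len(rejections),
    )
    for line in rejections[:20]:
        logger.warning("rejected: %s", line)
    return cohort


def years_from_dates(dates: pd.Series, reference: pd.Timestamp | None = None) -> pd.Series:
    """Convert a date column to decimal years from a reference date."""
    d = pd.to_datetime(dates)
    ref = d.min() if reference is None else pd.Timestamp(reference)
    return (d - ref).dt.days / 365.25
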