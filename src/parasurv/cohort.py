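"""Subject-level right-censored survival data containers.

A :class:`SurvivalCohort` is the universal input of every analysis stage:
per-subject follow-up time in days, a 0/1 death indicator, and a covariate
table (continuous columns plus a categorical tumour grade with levels 1-3).
A :class:`CohortSpec` is the generative truth used by the simulator: the
covariate distribution, the proportional-hazards coefficients, the Weibull
baseline (shape gamma, scale lambda per day^gamma), and the censoring model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError

GRADE_LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class CohortSpec:
    """Generative truth for a synthetic survival cohort.

    ``beta_true`` is ordered (age, grade2, grade3, rad_1..rad_k) and applies
    to age standardized by (``age_mean``, ``age_sd``) — i.e. per-SD for age —
    to the two grade indicators (grade 1 reference), and to the radiomic-like
    features on their generated scale (standard normal marginals with
    exchangeable correlation ``radiomic_corr``).

    Censoring is the minimum of an administrative cutoff ``admin_censor_time``
    (days) and an exponential dropout time with per-day hazard
    ``dropout_rate``, independent of the event time.
    """

    n_subjects: int
    age_mean: float = 66.72
    age_sd: float = 11.43
    grade_probs: tuple[float, float, float] = (123 / 411, 130 / 411, 158 / 411)
    n_radiomic: int = 3
    radiomic_corr: float = 0.3
    beta_true: tuple[float, ...] = (0.5620, 0.2038, 1.9327, 0.2676, 0.4012, 0.1636)
    gamma_true: float = 0.9929
    lambda_true: float = 3.0447e-05
    admin_censor_time: float = 2559.1
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.grade_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigError("grade_probs must be 3 non-negative values summing to 1")
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be at least 2")
        if self.gamma_true <= 0 or self.lambda_true <= 0:
            raise ConfigError("gamma_true and lambda_true must be positive")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be positive")
        if self.n_radiomic < 0:
            raise ConfigError("n_radiomic must be non-negative")
        if not (0 <= self.radiomic_corr < 1):
            raise ConfigError("radiomic_corr must lie in [0, 1)")
        if self.dropout_rate < 0:
            raise ConfigError("dropout_rate must be non-negative")
        if self.admin_censor_time <= 0:
            raise ConfigError("admin_censor_time must be positive")
        expected = 3 + self.n_radiomic  # age + 2 grade indicators + radiomics
        if len(self.beta_true) != expected:
            raise ConfigError(
                f"beta_true must have {expected} entries "
                f"(age, grade2, grade3, {self.n_radiomic} radiomic), "
                f"got {len(self.beta_true)}"
            )

    @property
    def covariate_labels(self) -> list[str]:
        return ["age", "grade2", "grade3"] + [
            f"rad_{i + 1}" for i in range(self.n_radiomic)
        ]

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "grade_probs": list(self.grade_probs),
            "n_radiomic": self.n_radiomic,
            "radiomic_corr": self.radiomic_corr,
            "beta_true": list(self.beta_true),
            "gamma_true": self.gamma_true,
            "lambda_true": self.lambda_true,
            "admin_censor_time": self.admin_censor_time,
            "dropout_rate": self.dropout_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("grade_probs", "beta_true"):
            if key in d:
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid cohort spec: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SurvivalCohort:
    """Right-censored survival data: times (days), 0/1 events, covariates.

    ``covariates`` holds one named column per covariate; ``grade`` (if
    present) is categorical with levels 1-3. Missing covariate values are
    tolerated at construction (the pipeline's drop-incomplete step removes
    them); times and events must be complete and valid.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    subject_id: np.ndarray = field(default=None)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1:
            raise DataError("time must be a 1-D vector")
        n = self.time.shape[0]
        if self.event.shape != (n,) or len(self.covariates) != n:
            raise DataError("time, event and covariate rows must have equal length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise DataError("all follow-up times must be positive and finite")
        if not np.all(np.isin(self.event, (0, 1))):
            raise DataError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)
        if self.subject_id is None:
            self.subject_id = np.arange(n)
        else:
            self.subject_id = np.asarray(self.subject_id)
            if self.subject_id.shape != (n,):
                raise DataError("subject_id length mismatch")
        self.covariates = self.covariates.reset_index(drop=True)

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def design_matrix(self, covariates: Sequence[str]) -> np.ndarray:
        missing = [c for c in covariates if c not in self.covariates.columns]
        if missing:
            raise DataError(f"covariates not in cohort: {missing}")
        mat = self.covariates.loc[:, list(covariates)].to_numpy(dtype=float)
        if np.any(~np.isfinite(mat)):
            raise DataError(
                "covariate matrix contains missing/non-finite values; "
                "run drop_incomplete first"
            )
        return mat

    def subset(self, index) -> "SurvivalCohort":
        index = np.asarray(index)
        return SurvivalCohort(
            time=self.time[index],
            event=self.event[index],
            covariates=self.covariates.iloc[index].reset_index(drop=True),
            subject_id=self.subject_id[index],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_id, "time_days": self.time,
                           "event": self.event})
        return pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalCohort":
        required = {"time_days", "event"}
        if not required.issubset(df.columns):
            raise DataError(f"cohort table needs columns {sorted(required)}")
        cov_cols = [c for c in df.columns if c not in ("subject_id", "time_days", "event")]
        subject_id = df["subject_id"].to_numpy() if "subject_id" in df.columns else None
        return cls(
            time=df["time_days"].to_numpy(dtype=float),
            event=df["event"].to_numpy(),
            covariates=df.loc[:, cov_cols].copy(),
            subject_id=subject_id,
        )

    @classmethod
    def read_csv(cls, path) -> "SurvivalCohort":
        return cls.from_frame(pd.read_csv(path))
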