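"""Core data containers and CSV ingestion for right-censored cohort data.

The central object is :class:`SurvivalSample`: follow-up times ``T = min(T~, C)``
in years, event indicators ``δ = I{T~ ≤ C}``, and two covariate matrices with
distinct roles — ``x`` enters the incidence (susceptibility) submodel and ``z``
the latency (time-to-diagnosis) submodel.  The two sets may be equal,
overlapping, or disjoint.

Cohort summary tables (births and diagnoses per birth-year cohort) are handled
by :class:`CohortTable` / :func:`cohort_summary`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalSample",
    "CohortTable",
    "load_survival_csv",
    "write_survival_csv",
    "load_cohort_csv",
    "cohort_summary",
    "prevalence_percent",
    "SchemaError",
    "ValidationError",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """Input values violate the data contract (e.g. negative times)."""


def _as_matrix(arr, n: int, what: str) -> np.ndarray:
    m = np.asarray(arr, dtype=float)
    if m.ndim == 1:
        m = m.reshape(-1, 1)
    if m.ndim != 2 or m.shape[0] != n:
        raise ValidationError(f"{what} must have one row per subject (got shape {m.shape}, n={n})")
    return m


@dataclass
class SurvivalSample:
    """Right-censored outcomes with separate incidence and latency covariates.

    Parameters
    ----------
    ids : array-like
        Subject identifiers.
    time : array-like of float
        Follow-up time in years, ``min(T~, C)``; finite and nonnegative.
    event : array-like of {0, 1}
        1 if the diagnosis was observed before censoring.  ``event == 1``
        implies the subject is known susceptible; ``event == 0`` leaves the
        latent susceptibility unknown.
    x, z : array-like
        Incidence and latency covariate matrices (no intercept column; the
        fitters add one to ``x``).  Either may have zero columns.
    x_names, z_names : list of str
        Column labels for ``x`` and ``z``.
    """

    ids: np.ndarray
    time: np.ndarray
    event: np.ndarray
    x: np.ndarray
    z: np.ndarray
    x_names: list = field(default_factory=list)
    z_names: list = field(default_factory=list)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = self.time.shape[0]
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValidationError("follow-up times must be finite and >= 0")
        ev = np.asarray(self.event, dtype=float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValidationError("event indicators must be 0 or 1")
        self.event = ev.astype(int)
        if self.ids.shape[0] != n or self.event.shape[0] != n:
            raise ValidationError("ids, time and event must have equal length")
        self.x = _as_matrix(self.x, n, "x") if np.size(self.x) else np.empty((n, 0))
        self.z = _as_matrix(self.z, n, "z") if np.size(self.z) else np.empty((n, 0))
        if len(self.x_names) != self.x.shape[1]:
            self.x_names = [f"x{j}" for j in range(self.x.shape[1])]
        if len(self.z_names) != self.z.shape[1]:
            self.z_names = [f"z{j}" for j in range(self.z.shape[1])]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalSample":
        """Row subset (used by the bootstrap); preserves covariate names."""
        return SurvivalSample(
            ids=self.ids[idx],
            time=self.time[idx],
            event=self.event[idx],
            x=self.x[idx],
            z=self.z[idx],
            x_names=list(self.x_names),
            z_names=list(self.z_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "time": self.time, "event": self.event})
        seen = {}
        for name, col in zip(self.x_names, self.x.T):
            df[name] = col
            seen[name] = True
        for name, col in zip(self.z_names, self.z.T):
            if name not in seen:
                df[name] = col
        return df


def load_survival_csv(path, incidence_cols, latency_cols) -> SurvivalSample:
    """Read a right-censored survival table from CSV.

    The file must carry ``time`` and ``event`` columns; ``incidence_cols`` and
    ``latency_cols`` name the covariates for the two submodels (they may
    overlap).  Rows with a missing value in any used column are dropped
    (complete-case analysis) and the number removed is logged.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    incidence_cols = list(incidence_cols)
    latency_cols = list(latency_cols)
    required = ["time", "event"] + incidence_cols + latency_cols
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    used = ["time", "event"] + sorted(set(incidence_cols) | set(latency_cols))
    n_raw = len(df)
    df = df.dropna(subset=used)
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("dropped %d of %d rows with missing values (complete-case)", n_dropped, n_raw)
    ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
    return SurvivalSample(
        ids=ids,
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(),
        x=df[incidence_cols].to_numpy(dtype=float) if incidence_cols else np.empty((len(df), 0)),
        z=df[latency_cols].to_numpy(dtype=float) if latency_cols else np.empty((len(df), 0)),
        x_names=incidence_cols,
        z_names=latency_cols,
    )


def write_survival_csv(sample: SurvivalSample, path, latent: pd.DataFrame | None = None) -> None:
    """Write a sample to CSV; an optional latent frame (test-only columns such
    as the susceptibility indicator) is joined column-wise."""
    df = sample.to_frame()
    if latent is not None:
        for c in latent.columns:
            df[c] = np.asarray(latent[c])
    df.to_csv(path, index=False, float_format="%.17g")  # exact float round-trip


# ---------------------------------------------------------------------------
# Cohort summary tables


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_percent(diagnoses: int, births: int, decimals: int = 2) -> float:
    """Percentage diagnosed, rounded half-up to ``decimals`` places."""
    if births < 0 or diagnoses < 0:
        raise ValidationError("counts must be nonnegative")
    if births == 0:
        if diagnoses > 0:
            raise ValidationError("diagnoses > 0 with births = 0")
        return 0.0
    return _round_half_up(100.0 * diagnoses / births, decimals)


@dataclass
class CohortTable:
    """Birth-year cohorts with counts of births and diagnoses.

    ``exposure_percent`` is an optional per-cohort exposure prevalence column
    carried through unchanged.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        for col in ("year", "births", "diagnoses"):
            if col not in df.columns:
                raise SchemaError(f"cohort table missing column {col!r}")
        births = df["births"].to_numpy()
        diag = df["diagnoses"].to_numpy()
        if np.any(births < 0) or np.any(diag < 0):
            raise ValidationError("counts must be nonnegative")
        if not (np.all(births == births.astype(int)) and np.all(diag == diag.astype(int))):
            raise ValidationError("counts must be integers")
        if np.any(diag > births):
            raise ValidationError("diagnoses cannot exceed births")


def load_cohort_csv(path) -> CohortTable:
    return CohortTable(pd.read_csv(path))


def cohort_summary(table: CohortTable) -> pd.DataFrame:
    """Per-cohort and total diagnosis percentages.

    The Total row aggregates the raw counts before dividing — it is not an
    average of the per-row percentages.
    """
    df = table.frame.copy()
    df["percent"] = [
        prevalence_percent(int(d), int(b)) for d, b in zip(df["diagnoses"], df["births"])
    ]
    total_births = int(df["births"].sum())
    total_diag = int(df["diagnoses"].sum())
    total = {
        "year": "Total",
        "births": total_births,
        "diagnoses": total_diag,
        "percent": prevalence_percent(total_diag, total_births),
    }
    out = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return out
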