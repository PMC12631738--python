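"""Containers for digitized Kaplan-Meier data and pseudo individual-patient data.

Pseudo-IPD is carried as a pandas DataFrame with columns ``time_months``
(float, >= 0) and ``event`` (1 = event, 0 = right-censored) — one row per
reconstructed or simulated patient.  Digitized curves and number-at-risk
tables are small frozen dataclasses wrapping numpy arrays, with the CSV
schemas used throughout the package:

* curves:      ``endpoint,arm,time_months,survival``
* risk tables: ``endpoint,arm,time_months,n_at_risk``
* pseudo-IPD:  ``time_months,event``
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "IPD_COLUMNS",
    "as_ipd",
    "read_ipd",
    "write_ipd",
    "DigitizedCurve",
    "RiskTable",
    "StepSurvival",
    "kaplan_meier",
    "read_curves",
    "write_curves",
    "read_risk_tables",
    "write_risk_tables",
]

IPD_COLUMNS = ("time_months", "event")

ENDPOINTS = ("OS", "PFS")


def as_ipd(records) -> pd.DataFrame:
    """Coerce ``[(time, event), ...]`` / arrays / DataFrame to the IPD frame."""
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, list(IPD_COLUMNS)].copy()
    else:
        arr = np.asarray(list(records), dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        df = pd.DataFrame(arr, columns=list(IPD_COLUMNS))
    df["time_months"] = df["time_months"].astype(float)
    df["event"] = df["event"].astype(int)
    if len(df):
        if not np.all(np.isfinite(df["time_months"])) or (df["time_months"] < 0).any():
            raise ValueError("IPD times must be finite and non-negative")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("IPD event flags must be 0 or 1")
    return df.reset_index(drop=True)


def read_ipd(path) -> pd.DataFrame:
    return as_ipd(pd.read_csv(path))


def write_ipd(ipd: pd.DataFrame, path) -> None:
    as_ipd(ipd).to_csv(path, index=False)


@dataclass(frozen=True)
class DigitizedCurve:
    """Coordinates read off a published KM plot for one endpoint and arm."""

    endpoint: str
    arm: str
    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        t, s = self.times, self.survival
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}")
        if t.ndim != 1 or t.shape != s.shape or t.size == 0:
            raise ValueError("times and survival must be matching non-empty 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if t[0] != 0.0 or s[0] != 1.0:
            raise ValueError("curve must start at (time=0, survival=1.0)")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RiskTable:
    """Number-at-risk table accompanying a published KM plot."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        t, n = self.times, self.counts
        if t.ndim != 1 or t.shape != n.shape or t.size == 0:
            raise ValueError("risk table must have matching non-empty times/counts")
        if t[0] != 0.0:
            raise ValueError("risk table must start at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk times must be strictly increasing")
        if np.any(n < 0):
            raise ValueError("at-risk counts must be non-negative")
        if np.any(np.diff(n) > 0):
            raise ValueError("at-risk counts must be non-increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class StepSurvival:
    """A right-continuous, non-increasing step function starting at (0, 1)."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        if self.times[0] != 0.0 or abs(self.survival[0] - 1.0) > 1e-12:
            raise ValueError("step survival must start at (0, 1)")
        if np.any(np.diff(self.times) < 0) or np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("step survival must be non-increasing over increasing times")

    def __call__(self, t) -> np.ndarray:
        """Evaluate the step function (value of the step whose left edge is <= t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, self.times.size - 1)
        return self.survival[idx]


def kaplan_meier(ipd) -> StepSurvival:
    """Product-limit estimate of the survival function of pseudo-IPD."""
    df = as_ipd(ipd)
    if len(df) == 0:
        raise ValueError("cannot estimate a survival curve from empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time_months"], event_observed=df["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    return StepSurvival(times, surv)


# -- CSV schemas -------------------------------------------------------------


def write_curves(curves, path) -> None:
    """Write a mapping {(endpoint, arm): DigitizedCurve} to the curve CSV schema."""
    rows = []
    for (endpoint, arm), c in curves.items():
        for t, s in zip(c.times, c.survival):
            rows.append({"endpoint": endpoint, "arm": arm, "time_months": t, "survival": s})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves(path) -> dict[tuple[str, str], DigitizedCurve]:
    df = pd.read_csv(path)
    required = {"endpoint", "arm", "time_months", "survival"}
    if not required.issubset(df.columns):
        raise ValueError(f"curve CSV must have columns {sorted(required)}")
    out = {}
    for (endpoint, arm), grp in df.groupby(["endpoint", "arm"], sort=False):
        grp = grp.sort_values("time_months")
        out[(endpoint, arm)] = DigitizedCurve(
            endpoint, arm, grp["time_months"].to_numpy(), grp["survival"].to_numpy()
        )
    return out


def write_risk_tables(tables, path) -> None:
    rows = []
    for (endpoint, arm), rt in tables.items():
        for t, n in zip(rt.times, rt.counts):
            rows.append({"endpoint": endpoint, "arm": arm, "time_months": t, "n_at_risk": n})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_risk_tables(path) -> dict[tuple[str, str], RiskTable]:
    df = pd.read_csv(path)
    required = {"endpoint", "arm", "time_months", "n_at_risk"}
    if not required.issubset(df.columns):
        raise ValueError(f"risk table CSV must have columns {sorted(required)}")
    out = {}
    for (endpoint, arm), grp in df.groupby(["endpoint", "arm"], sort=False):
        grp = grp.sort_values("time_months")
        out[(endpoint, arm)] = RiskTable(
            grp["time_months"].to_numpy(), grp["n_at_risk"].to_numpy()
        )
    return out
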