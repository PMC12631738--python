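"""Incremental cost-effectiveness comparison and uncertainty analysis.

* :func:`compare` — incremental cost, QALYs, LYs, the ICER (or a dominance
  label) and net monetary benefit at a willingness-to-pay threshold.
* :func:`run_dsa` — one-way deterministic sensitivity: every uncertain
  parameter is set to its low and high bound in turn (everything else at
  base), the full deterministic model is re-run, and the ICER span per
  parameter is ranked for a tornado diagram.
* :func:`run_psa` — probabilistic sensitivity: Monte-Carlo resampling of the
  non-fixed parameters with moment-matched Gamma (costs, disutilities) and
  Beta (utilities, incidences) distributions, yielding the incremental
  scatter and the cost-effectiveness acceptability curve.  Survival-curve
  parameters are held fixed, mirroring the deterministic extrapolation.
* :func:`run_scenario` — distribution-swap scenario: refit every curve with a
  forced family and report the ICER relative to base case.

Standard errors for sampling are derived from the printed ranges by treating
them as 95% intervals: sd = (high - low) / (2 * 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelBundle, ParamDistribution, parameter_specs
from .model import FittedBundle, evaluate, fit_bundle
from .valuation import ArmResult

__all__ = [
    "CEAResult",
    "TornadoEntry",
    "PSAResult",
    "ScenarioResult",
    "compare",
    "sample_param",
    "run_dsa",
    "run_psa",
    "run_scenario",
    "default_wtp_grid",
]

INTERVENTION = "PEM"
COMPARATOR = "TRAS"


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of intervention vs. comparator."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None  # undefined when delta_qaly == 0
    label: str | None  # "dominant", "dominated", or None
    nmb: float
    wtp: float


def compare(intervention: ArmResult, comparator: ArmResult, wtp: float) -> CEAResult:
    """Incremental deltas, ICER / dominance label, and NMB at ``wtp``."""
    dc = intervention.cost_total - comparator.cost_total
    dq = intervention.qaly_total - comparator.qaly_total
    dly = intervention.ly_total - comparator.ly_total
    nmb = wtp * dq - dc
    label = None
    if dc < 0 and dq > 0:
        label = "dominant"
    elif dc > 0 and dq < 0:
        label = "dominated"
    icer = dc / dq if dq != 0 else None
    return CEAResult(dc, dq, dly, icer, label, nmb, wtp)


def sample_param(dist: ParamDistribution, rng: np.random.Generator) -> float:
    """Draw one value from a parameter's moment-matched distribution.

    Gamma: shape = m^2/v, scale = v/m.  Beta: nu = m(1-m)/v - 1, alpha = m*nu,
    beta = (1-m)*nu.  Variance v = ((high-low)/(2*1.96))^2.  ``fixed`` returns
    the base value.
    """
    if dist.family == "fixed":
        return dist.base
    m = dist.base
    if dist.low is None or dist.high is None:
        raise ValueError(f"parameter {dist.name!r} has no range to sample from")
    sd = (dist.high - dist.low) / (2.0 * 1.959963984540054)
    if sd <= 0:
        return m
    v = sd * sd
    if dist.family == "gamma":
        if m <= 0:
            raise ValueError(f"gamma parameter {dist.name!r} needs a positive base")
        shape = m * m / v
        scale = v / m
        return float(rng.gamma(shape, scale))
    if dist.family == "beta":
        if not 0.0 < m < 1.0:
            raise ValueError(f"beta parameter {dist.name!r} needs base in (0, 1)")
        if v >= m * (1.0 - m):
            raise ValueError(
                f"beta parameter {dist.name!r}: variance {v:.4g} too large for mean {m}"
            )
        nu = m * (1.0 - m) / v - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    raise ValueError(f"unknown sampling family {dist.family!r}")


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity of the ICER to a single parameter."""

    name: str
    low: float
    high: float
    icer_at_low: float | None
    icer_at_high: float | None
    error: str | None = None

    @property
    def span(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return 0.0
        return abs(self.icer_at_high - self.icer_at_low)


def _icer(fitted: FittedBundle, overrides, wtp) -> CEAResult:
    res = evaluate(fitted, overrides)
    return compare(res[INTERVENTION], res[COMPARATOR], wtp)


def run_dsa(
    fitted: FittedBundle,
    wtp: float | None = None,
    params: list[ParamDistribution] | None = None,
) -> list[TornadoEntry]:
    """One-way DSA over every ranged parameter; entries sorted by descending span."""
    cfg = fitted.bundle.config
    wtp = wtp if wtp is not None else cfg.wtp
    specs = params if params is not None else [
        s for s in parameter_specs(cfg) if s.in_dsa
    ]
    entries = []
    for s in specs:
        icers = {}
        err = None
        for bound, value in (("low", s.low), ("high", s.high)):
            try:
                icers[bound] = _icer(fitted, {s.name: value}, wtp).icer
            except Exception as exc:  # annotated, never silently dropped
                icers[bound] = None
                err = f"{bound}: {exc}"
        entries.append(
            TornadoEntry(s.name, s.low, s.high, icers["low"], icers["high"], err)
        )
    return sorted(entries, key=lambda e: -e.span)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.name for e in entries],
            "low_value": [e.low for e in entries],
            "high_value": [e.high for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "span": [e.span for e in entries],
            "error": [e.error for e in entries],
        }
    )


def default_wtp_grid() -> np.ndarray:
    """0 to 60,000 USD/QALY in 500-unit steps (spans 1-3x per-capita GDP)."""
    return np.arange(0.0, 60000.0 + 1e-9, 500.0)


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo samples plus the acceptability curve."""

    samples: pd.DataFrame  # one row per iteration: parameters, deltas, icer
    ceac: pd.DataFrame  # columns: wtp, probability

    def acceptability_at(self, wtp: float) -> float:
        """Fraction of iterations cost-effective at ``wtp`` (positive NMB)."""
        return float(
            np.mean(wtp * self.samples["delta_qaly"] - self.samples["delta_cost"] > 0)
        )


def run_psa(
    fitted: FittedBundle,
    n_iter: int = 1000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n_iter`` Monte-Carlo draws."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cfg = fitted.bundle.config
    specs = [s for s in parameter_specs(cfg) if s.in_psa]
    # fail fast on infeasible sampling configurations
    probe = np.random.default_rng(0)
    for s in specs:
        sample_param(s, probe)
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        overrides = {s.name: sample_param(s, rng) for s in specs}
        res = evaluate(fitted, overrides)
        cea = compare(res[INTERVENTION], res[COMPARATOR], cfg.wtp)
        row = {"iteration": it, **overrides}
        row["delta_cost"] = cea.delta_cost
        row["delta_qaly"] = cea.delta_qaly
        row["icer"] = cea.icer
        rows.append(row)
    samples = pd.DataFrame(rows)
    dq = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    prob = [(float(np.mean(w * dq - dc > 0))) for w in grid]
    ceac = pd.DataFrame({"wtp": grid, "probability": prob})
    return PSAResult(samples, ceac)


@dataclass(frozen=True)
class ScenarioResult:
    """ICER under a forced survival family, against the base case."""

    family: str
    base: CEAResult
    scenario: CEAResult

    @property
    def relative_change(self) -> float:
        """Signed relative ICER change vs. base, e.g. -0.053 for a 5.3% drop."""
        return (self.scenario.icer - self.base.icer) / self.base.icer


def run_scenario(
    fitted: FittedBundle, family_override: str, wtp: float | None = None
) -> ScenarioResult:
    """Refit all curves with ``family_override`` and recompute the comparison."""
    cfg = fitted.bundle.config
    wtp = wtp if wtp is not None else cfg.wtp
    base = _icer(fitted, None, wtp)
    refit = fit_bundle(fitted.bundle, family_override=family_override)
    scen = _icer(refit, None, wtp)
    return ScenarioResult(family_override, base, scen)
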