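"""Pseudo individual-patient data from digitized KM curves and risk tables.

The reconstruction follows the standard iterative interval-allocation scheme:
within each interval between consecutive number-at-risk times, events are
placed at the digitized drop times (counts chosen so that the running
product-limit estimate tracks the digitized survival values as closely as
integer counts allow) and censorings are spread deterministically at evenly
spaced times inside the interval, their number iterated until the count of
subjects still under observation at the next risk time reproduces the
published number at risk.  Residual off-by-one discrepancies from integer
rounding are closed by a repair pass that shifts single events at the
digitized times where the change distorts the running estimate least, so the
at-risk counts are honored exactly whenever they are feasible.

Conventions (fully determined by the two inputs; no randomness anywhere):

* A digitized point at exactly a risk-table time belongs to the interval that
  *starts* there, so its event count is computed against the freshly matched
  at-risk number — this makes a reconstructed at-risk count (records with
  time >= t) agree with the published table.
* Beyond the last risk time, remaining drops are allocated the same way and
  every subject still at risk is censored at the last digitized time.
* Event counts are rounded half away from zero; when two allocations fit the
  digitized curve equally well the one with fewer events is used
  (conservative survival).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kmdata import DigitizedCurve, RiskTable, as_ipd, kaplan_meier

__all__ = ["reconstruct_ipd", "kaplan_meier"]

_MAX_ITER = 400


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _merge(event_times, censor_times):
    """Points in time order; at equal times events precede censorings."""
    points = [(t, 0, i) for i, t in enumerate(event_times)] + [
        (t, 1, -1) for t in censor_times
    ]
    points.sort(key=lambda p: (p[0], p[1]))
    return points


def _walk_interval(n0, km0, event_times, event_targets, censor_times):
    """Greedy event allocation along one interval given fixed censor times.

    Returns (n_end, km_end, event_counts).
    """
    n, km = n0, km0
    d = np.zeros(len(event_times), dtype=int)
    for t, is_censor, i in _merge(event_times, censor_times):
        if is_censor:
            n -= 1
            continue
        target = event_targets[i]
        if n <= 0 or km <= 0:
            continue
        di = _round_half_away(n * (1.0 - target / km))
        di = min(max(di, 0), n)
        # tie rule: if removing one event matches the target equally well,
        # prefer the smaller event count
        if di > 0:
            with_di = km * (1.0 - di / n)
            with_less = km * (1.0 - (di - 1) / n)
            if abs(with_less - target) <= abs(with_di - target) + 1e-15:
                di -= 1
        if di > 0:
            km *= 1.0 - di / n
            n -= di
            d[i] = di
    return n, km, d


def _replay(n0, km0, event_times, event_targets, censor_times, d):
    """Replay an interval with *fixed* event counts.

    Returns (n_end, km_end, max |KM - target|, feasible).
    """
    n, km = n0, km0
    err = 0.0
    for t, is_censor, i in _merge(event_times, censor_times):
        if is_censor:
            n -= 1
            continue
        di = int(d[i])
        if di > max(n, 0):
            return n, km, np.inf, False
        if di > 0:
            km *= 1.0 - di / n
            n -= di
        err = max(err, abs(km - event_targets[i]))
    return n, km, err, n >= 0


def _repair(n0, km0, event_times, event_targets, censor_times, d, target_n):
    """Shift single events until the end-of-interval count equals target_n.

    Each adjustment picks the digitized time where the +/-1 change leaves the
    smallest sup-norm deviation from the digitized curve.
    """
    d = d.copy()
    n_end, km_end, _, _ = _replay(n0, km0, event_times, event_targets, censor_times, d)
    guard = 0
    while n_end != target_n and guard < 10 * (len(d) + 1) * (abs(n_end - target_n) + 1):
        guard += 1
        delta = -1 if n_end < target_n else 1  # too few at risk -> remove events
        best = None
        for i in range(len(d)):
            if delta < 0 and d[i] <= 0:
                continue
            trial = d.copy()
            trial[i] += delta
            ne, ke, err, ok = _replay(
                n0, km0, event_times, event_targets, censor_times, trial
            )
            if not ok:
                continue
            if best is None or err < best[0]:
                best = (err, i, trial, ne, ke)
        if best is None:
            break
        _, _, d, n_end, km_end = best
    return d, n_end, km_end


def reconstruct_ipd(curve: DigitizedCurve, risk: RiskTable) -> pd.DataFrame:
    """Reconstruct pseudo-IPD whose KM estimate reproduces ``curve`` and whose
    at-risk counts reproduce ``risk``.

    Returns the IPD frame (``time_months``, ``event``) with exactly
    ``risk.counts[0]`` rows.
    """
    if len(risk) < 2:
        raise ValueError("risk table must have at least two entries")
    if risk.times[-1] > curve.times[-1] + 1e-9:
        raise ValueError("risk table extends beyond the digitized curve")

    t = curve.times
    s = curve.survival
    rt = risk.times
    rn = risk.counts
    if rn[0] <= 0:
        raise ValueError("initial number at risk must be positive")

    times_out: list[float] = []
    events_out: list[int] = []
    cur_n = int(rn[0])
    cur_km = 1.0

    boundaries = list(rt) + [np.inf]
    for k in range(len(rt)):
        lo, hi = boundaries[k], boundaries[k + 1]
        # digitized points in [lo, hi); skip the t=0 anchor
        mask = (t >= lo) & (t < hi) & (t > 0)
        ev_times = t[mask]
        ev_targets = s[mask]
        last = k == len(rt) - 1

        if last:
            n_end, km_end, d = _walk_interval(cur_n, cur_km, ev_times, ev_targets, [])
            for ti, di in zip(ev_times, d):
                times_out.extend([ti] * di)
                events_out.extend([1] * di)
            # censor everyone still under observation at the end of the curve
            t_final = max(float(t[-1]), float(rt[-1]))
            times_out.extend([t_final] * n_end)
            events_out.extend([0] * n_end)
            cur_n, cur_km = 0, km_end
            break

        target_n = int(rn[k + 1])
        if target_n > cur_n:
            raise ValueError(
                f"risk table increases from {cur_n} to {target_n} at t={rt[k + 1]}"
            )
        width = boundaries[k + 1] - lo

        def censor_grid(nc: int) -> np.ndarray:
            return lo + (np.arange(nc) + 0.5) * width / nc if nc > 0 else np.array([])

        # iterate the censor count toward the published at-risk number
        n_noc, _, _ = _walk_interval(cur_n, cur_km, ev_times, ev_targets, [])
        nc = max(0, min(n_noc - target_n, cur_n))
        tried: set[int] = set()
        best = None
        for _ in range(_MAX_ITER):
            if nc in tried:
                break
            tried.add(nc)
            n_end, km_end, d = _walk_interval(
                cur_n, cur_km, ev_times, ev_targets, censor_grid(nc)
            )
            err = n_end - target_n
            cand = (abs(err), nc, n_end, km_end, d)
            if best is None or cand[:2] < best[:2]:
                best = cand
            if err == 0:
                break
            nc = max(0, min(nc + err, cur_n))
        _, nc, n_end, km_end, d = best
        cg = censor_grid(nc)
        if n_end != target_n:
            # close residual integer-rounding drift by shifting single events
            d, n_end, km_end = _repair(
                cur_n, cur_km, ev_times, ev_targets, cg, d, target_n
            )
        for ti, di in zip(ev_times, d):
            times_out.extend([ti] * di)
            events_out.extend([1] * di)
        times_out.extend(cg.tolist())
        events_out.extend([0] * nc)
        cur_n, cur_km = n_end, km_end

    ipd = as_ipd(zip(times_out, events_out))
    return ipd.sort_values(["time_months", "event"], ascending=[True, False]).reset_index(
        drop=True
    )
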