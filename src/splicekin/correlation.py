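"""Correlation-function estimation from dual-color traces.

The estimator is ``G_ab(tau) = <da(t) db(t+tau)> / (<a><b>)`` with time
averages over the overlapping parts of the shifted series (ends are not
wrapped).  Delays are laid out on a multi-tau grid: the first block of lags
is evaluated at full resolution, then the signals are repeatedly
down-sampled by 2 and the upper half-block re-evaluated, giving
quasi-logarithmic delay spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .trace_simulator import DualColorTrace

__all__ = [
    "CorrelationCurve",
    "CorrelationSet",
    "photobleach_correct",
    "multitau_correlate",
    "correlate_trace",
    "average_correlations",
]

logger = logging.getLogger(__name__)

DEFAULT_BLOCK = 16
DEFAULT_BASELINE_WINDOW = (300.0, 500.0)


@dataclass
class CorrelationCurve:
    delays: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    sem: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")


@dataclass
class CorrelationSet:
    """The four correlation curves of one trace or trace set.

    ``Grg`` is red-leading-green at positive delay; ``Ggr`` is the same
    cross-correlation read at negative delay (``Grg(-tau) = Ggr(tau)``).
    """
    Grr: CorrelationCurve
    Ggg: CorrelationCurve
    Grg: CorrelationCurve
    Ggr: CorrelationCurve
    norm_constant: float = float("nan")
    #: bootstrap replicate values per curve (n_reps, n_delays); kept by
    #: average_correlations so fits can propagate the full covariance
    boot: Optional[dict] = None

    def curves(self) -> dict[str, CorrelationCurve]:
        return {"Grr": self.Grr, "Ggg": self.Ggg,
                "Grg": self.Grg, "Ggr": self.Ggr}


# ---------------------------------------------------------------------------
# Photobleaching correction
# ---------------------------------------------------------------------------

def photobleach_correct(trace: DualColorTrace, poly_order: int = 3) -> DualColorTrace:
    """Divide both channels by a low-order polynomial fit to the per-frame
    nucleus intensity s.d., rescaled to preserve the initial amplitude.

    If the trace has no nucleus_sd series the trace is returned unchanged
    (with a logged warning).
    """
    if trace.nucleus_sd is None:
        logger.warning("photobleach_correct: trace has no nucleus_sd; "
                       "returning trace unchanged")
        return trace
    coeffs = np.polyfit(trace.t, trace.nucleus_sd, poly_order)
    fit = np.polyval(coeffs, trace.t)
    correction = fit / fit[0]
    # guard against a pathological fit crossing zero
    correction = np.where(correction > 1e-6, correction, 1e-6)
    return DualColorTrace(t=trace.t.copy(),
                          red=trace.red / correction,
                          green=trace.green / correction,
                          nucleus_sd=trace.nucleus_sd / correction)


# ---------------------------------------------------------------------------
# Multi-tau correlator
# ---------------------------------------------------------------------------

def _coarsen(x: np.ndarray) -> np.ndarray:
    n = len(x) // 2 * 2
    return 0.5 * (x[0:n:2] + x[1:n:2])


def multitau_correlate(a: Sequence[float], b: Sequence[float], dt: float,
                       m: int = DEFAULT_BLOCK,
                       max_lag: Optional[float] = None) -> CorrelationCurve:
    """Multi-tau estimate of ``G_ab``; per-delay weight is the number of
    overlapping sample pairs (in original samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("series must have equal length >= 2")
    ma, mb = a.mean(), b.mean()
    if ma == 0 or mb == 0:
        raise ValueError("zero-mean channel: correlation normalization "
                         "undefined")
    norm = ma * mb
    da, db = a - ma, b - mb

    delays, values, weights = [], [], []
    stage = 0
    while True:
        scale = 2 ** stage
        n = len(da)
        lags = range(0, m) if stage == 0 else range(m // 2, m)
        for k in lags:
            overlap = n - k
            if overlap < 2:
                break
            delay = k * dt * scale
            if max_lag is not None and delay > max_lag:
                break
            delays.append(delay)
            values.append(float(np.dot(da[:overlap], db[k:]) / overlap / norm))
            weights.append(overlap * scale)
        da, db = _coarsen(da), _coarsen(db)
        stage += 1
        next_delay = (m // 2) * dt * 2 ** stage
        if len(da) <= m or (max_lag is not None and next_delay > max_lag):
            break
    return CorrelationCurve(np.array(delays), np.array(values),
                            np.array(weights))


def direct_correlate(a: Sequence[float], b: Sequence[float], dt: float,
                     lags: Sequence[int]) -> CorrelationCurve:
    """Direct O(n^2) estimator at integer lags (oracle for the multi-tau
    correlator's first block)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ma, mb = a.mean(), b.mean()
    da, db = a - ma, b - mb
    vals, w = [], []
    for k in lags:
        overlap = len(a) - k
        vals.append(float(np.dot(da[:overlap], db[k:]) / overlap / (ma * mb)))
        w.append(overlap)
    return CorrelationCurve(np.asarray(lags, float) * dt, np.array(vals),
                            np.array(w))


def correlate_trace(trace: DualColorTrace, m: int = DEFAULT_BLOCK,
                    max_lag: Optional[float] = None) -> CorrelationSet:
    """The two auto- and two cross-correlation halves of one trace."""
    dt = trace.dt
    r, g = trace.red, trace.green
    return CorrelationSet(
        Grr=multitau_correlate(r, r, dt, m, max_lag),
        Ggg=multitau_correlate(g, g, dt, m, max_lag),
        Grg=multitau_correlate(r, g, dt, m, max_lag),
        Ggr=multitau_correlate(g, r, dt, m, max_lag),
    )


# ---------------------------------------------------------------------------
# Averaging, baseline, normalization, bootstrap
# ---------------------------------------------------------------------------

def _norm_delay_index(delays: np.ndarray) -> int:
    """Index of the smallest positive delay (the Delta-t used for the
    G_rg(0) estimate)."""
    pos = np.flatnonzero(delays > 0)
    if len(pos) == 0:
        raise ValueError("no positive delays on the grid")
    return int(pos[0])


def _combine(sets: list[CorrelationSet], idx: np.ndarray,
             baseline_window: tuple[float, float],
             normalize: bool) -> tuple[dict[str, np.ndarray], float]:
    out: dict[str, np.ndarray] = {}
    delays_ref = None
    for name in ("Grr", "Ggg", "Grg", "Ggr"):
        curves = [getattr(sets[i], name) for i in idx]
        delays = curves[0].delays
        if delays_ref is None:
            delays_ref = delays
        vals = np.stack([c.values for c in curves])
        wts = np.stack([c.weights for c in curves])
        wsum = wts.sum(axis=0)
        avg = (vals * wts).sum(axis=0) / np.where(wsum > 0, wsum, 1.0)
        in_win = (delays >= baseline_window[0]) & (delays <= baseline_window[1])
        if in_win.any():
            avg = avg - avg[in_win].mean()
        out[name] = avg
    norm = 1.0
    if normalize:
        i = _norm_delay_index(delays_ref)
        norm = 0.5 * (out["Grg"][i] + out["Ggr"][i])
        if norm <= 0:
            raise ValueError("non-positive G_rg(0) estimate; cannot normalize")
        for name in out:
            out[name] = out[name] / norm
    return out, float(norm)


def average_correlations(sets: Sequence[CorrelationSet], n_boot: int = 1000,
                         baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
                         normalize: bool = True,
                         rng_seed=0) -> CorrelationSet:
    """Overlap-weighted average of per-trace correlation sets.

    A constant baseline (mean over ``baseline_window``) is subtracted per
    curve, then all four curves are divided by the cross-correlation
    estimate ``(Grg(dt) + Ggr(dt))/2``; both normalizations are re-applied
    inside each bootstrap replicate (resampling whole traces).
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least 2 correlation sets to average")
    grid = sets[0].Grr.delays
    for s in sets:
        for c in s.curves().values():
            if len(c.delays) != len(grid) or not np.allclose(c.delays, grid):
                raise ValueError("all correlation sets must share one delay grid")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    all_idx = np.arange(len(sets))
    avg, norm = _combine(sets, all_idx, baseline_window, normalize)

    sems: dict[str, Optional[np.ndarray]] = {k: None for k in avg}
    boot_arrays: Optional[dict[str, np.ndarray]] = None
    if n_boot > 0:
        boots: dict[str, list[np.ndarray]] = {k: [] for k in avg}
        for _ in range(n_boot):
            idx = rng.integers(0, len(sets), len(sets))
            try:
                rep, _ = _combine(sets, idx, baseline_window, normalize)
            except ValueError:
                continue  # degenerate replicate (non-positive normalization)
            for k, v in rep.items():
                boots[k].append(v)
        if all(len(r) >= 2 for r in boots.values()):
            boot_arrays = {k: np.stack(r) for k, r in boots.items()}
            sems = {k: a.std(axis=0, ddof=1) for k, a in boot_arrays.items()}

    wsum = {name: np.stack([getattr(s, name).weights for s in sets]).sum(axis=0)
            for name in avg}
    curves = {name: CorrelationCurve(grid.copy(), avg[name], wsum[name],
                                     sems[name])
              for name in avg}
    return CorrelationSet(norm_constant=norm, boot=boot_arrays, **curves)
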