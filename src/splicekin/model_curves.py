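"""Expected correlation functions for a kinetic model.

For Poisson transcript initiation the covariance of the two trace channels
is, by Campbell's theorem, the single-transcript expectation
``E[ integral f_a(t) f_b(t+tau) dt ]`` over the joint law of the scheme's
event times, where ``f_a`` and ``f_b`` are the ramp/plateau/drop profiles.
The expectation is evaluated by quasi-Monte Carlo (Sobol draws, inverse
transform), with the overlap integral of each pair of trapezoidal profiles
computed in closed form (2-point Gauss-Legendre on the breakpoint
partition, exact for the piecewise-quadratic integrand).  Common random
numbers across parameter values keep the fitting objective smooth.

The predictions are passed through the same baseline-subtraction and
``(Grg(dt)+Ggr(dt))/2`` normalization as measured correlation sets, so the
two are directly comparable and the initiation rate drops out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import qmc

from .correlation import (DEFAULT_BASELINE_WINDOW, CorrelationSet,
                          _norm_delay_index)
from .kinetic_models import VARIANTS, GeneLayout, KineticModel
from .trace_simulator import event_times_from_draws

__all__ = ["ModelCurvePrediction", "CurvePredictor", "predict_correlations",
           "slope_change_at_zero"]

_SQRT3 = np.sqrt(3.0)


@dataclass
class ModelCurvePrediction:
    model: KineticModel
    delays: np.ndarray
    Grr: np.ndarray
    Ggg: np.ndarray
    Grg: np.ndarray
    Ggr: np.ndarray
    eval_method: str = "piecewise_mc"
    mc_se: Optional[dict[str, np.ndarray]] = None
    norm_constant: float = 1.0

    def curves(self) -> dict[str, np.ndarray]:
        return {"Grr": self.Grr, "Ggg": self.Ggg,
                "Grg": self.Grg, "Ggr": self.Ggr}


def _trapezoid_eval(t: np.ndarray, s: np.ndarray, p: np.ndarray,
                    d: np.ndarray) -> np.ndarray:
    """Ramp from s to p, plateau at 1, instantaneous drop at d."""
    return np.clip((t - s) / (p - s), 0.0, 1.0) * (t < d)


def _overlap_integrals(sa, pa, da, sb, pb, db, tau: float) -> np.ndarray:
    """Exact per-draw integral of T_a(t) * T_b(t + tau) dt."""
    brk = np.stack([sa, pa, da, sb - tau, pb - tau, db - tau], axis=-1)
    brk.sort(axis=-1)
    total = np.zeros(brk.shape[0])
    for j in range(5):
        x0, x1 = brk[:, j], brk[:, j + 1]
        h = x1 - x0
        mid = 0.5 * (x0 + x1)
        off = h / (2.0 * _SQRT3)
        for x in (mid - off, mid + off):
            total += 0.5 * h * (_trapezoid_eval(x, sa, pa, da)
                                * _trapezoid_eval(x + tau, sb, pb, db))
    return total


class CurvePredictor:
    """Evaluates model correlation curves on a fixed delay grid with a fixed
    set of low-discrepancy draws (common random numbers across calls)."""

    def __init__(self, layout: GeneLayout, delays: Sequence[float],
                 n_draws: int = 4096, seed: int = 0,
                 baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
                 normalize: bool = True):
        self.layout = layout
        self.delays = np.asarray(delays, dtype=float)
        self.n_draws = int(n_draws)
        self.baseline_window = baseline_window
        self.normalize = normalize
        sampler = qmc.Sobol(d=3, scramble=True, seed=seed)
        u = sampler.random(self.n_draws)
        # keep u strictly inside (0, 1) for the inverse transforms
        self._u = np.clip(u, 1e-12, 1.0 - 1e-12)

    def _draws(self, model: KineticModel) -> tuple[np.ndarray, ...]:
        return (model.pause_3ss.ppf(self._u[:, 0]),
                model.splice.ppf(self._u[:, 1]),
                model.release.ppf(self._u[:, 2]))

    def predict(self, model: KineticModel) -> ModelCurvePrediction:
        if model.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {model.variant!r}")
        pause, splice, rel = self._draws(model)
        ev = event_times_from_draws(model, self.layout,
                                    np.zeros(self.n_draws), pause, splice, rel)
        red = (ev["t_pp7_start"], ev["t_pp7_end"], ev["t_red_drop"])
        grn = (ev["t_ms2_start"], ev["t_ms2_end"], ev["t_green_drop"])
        # expected per-transcript occupancy of each label: the <a><b>
        # denominator of the measured estimator scales each curve by the
        # product of channel means, which differs between autos and crosses
        occ_r = ((red[1] - red[0]) / 2 + (red[2] - red[1])).mean()
        occ_g = ((grn[1] - grn[0]) / 2 + (grn[2] - grn[1])).mean()
        denom = {"Grr": occ_r * occ_r, "Ggg": occ_g * occ_g,
                 "Grg": occ_r * occ_g, "Ggr": occ_r * occ_g}

        combos = {"Grr": (red, red, 1.0), "Ggg": (grn, grn, 1.0),
                  "Grg": (red, grn, 1.0), "Ggr": (red, grn, -1.0)}
        values: dict[str, np.ndarray] = {}
        ses: dict[str, np.ndarray] = {}
        for name, (fa, fb, sign) in combos.items():
            vals = np.empty_like(self.delays)
            se = np.empty_like(self.delays)
            for i, tau in enumerate(self.delays):
                per_draw = _overlap_integrals(*fa, *fb, sign * tau)
                vals[i] = per_draw.mean()
                se[i] = per_draw.std(ddof=1) / np.sqrt(self.n_draws)
            values[name] = vals / denom[name]
            ses[name] = se / denom[name]

        in_win = (np.zeros(len(self.delays), dtype=bool)
                  if self.baseline_window is None else
                  ((self.delays >= self.baseline_window[0])
                   & (self.delays <= self.baseline_window[1])))
        if in_win.any():
            for name in values:
                values[name] = values[name] - values[name][in_win].mean()
        norm = 1.0
        if self.normalize:
            i = _norm_delay_index(self.delays)
            norm = 0.5 * (values["Grg"][i] + values["Ggr"][i])
            # scheme III makes the cross-correlation vanish near zero delay,
            # so the G_rg(0) convention is degenerate; fall back to the
            # red autocorrelation at dt (the same convention such data
            # would have to use)
            if norm <= 1e-6 * values["Grr"][i]:
                norm = values["Grr"][i]
            if norm <= 0:
                raise ValueError("degenerate prediction: cannot normalize")
            for name in values:
                values[name] = values[name] / norm
            ses = {k: v / norm for k, v in ses.items()}
        return ModelCurvePrediction(model=model, delays=self.delays.copy(),
                                    mc_se=ses, norm_constant=float(norm),
                                    **values)


def predict_correlations(model: KineticModel, layout: GeneLayout,
                         delays: Sequence[float], n_draws: int = 4096,
                         seed: int = 0, normalize: bool = True,
                         baseline_window=DEFAULT_BASELINE_WINDOW) -> ModelCurvePrediction:
    """One-shot expected correlation curves for ``model`` on ``delays``."""
    return CurvePredictor(layout, delays, n_draws=n_draws, seed=seed,
                          normalize=normalize,
                          baseline_window=baseline_window).predict(model)


def slope_change_at_zero(curves: Union[ModelCurvePrediction, CorrelationSet],
                         window: tuple[float, float] = (0.0, 40.0)
                         ) -> tuple[float, float, float]:
    """Short-delay slopes of the cross-correlation on either side of zero.

    Returns ``(slope_pos, slope_neg, fraction)`` where the slope ratio
    estimates the pre-release splicing fraction.  Slopes are line fits over
    positive delays within ``window`` (zero excluded); both are reported as
    slopes along increasing delay through zero, i.e. the negative-side slope
    is ``-dGgr/dtau`` in Ggr's own delay coordinate.
    """
    if isinstance(curves, CorrelationSet):
        delays = curves.Grg.delays
        grg, ggr = curves.Grg.values, curves.Ggr.values
    else:
        delays, grg, ggr = curves.delays, curves.Grg, curves.Ggr
    mask = (delays > max(window[0], 0.0)) & (delays <= window[1])
    if mask.sum() < 3:
        raise ValueError("need >= 3 short-delay points per side for slopes")
    x = delays[mask]
    slope_pos = float(np.polyfit(x, grg[mask], 1)[0])
    slope_neg = float(-np.polyfit(x, ggr[mask], 1)[0])
    if slope_neg <= 0:
        raise ValueError("negative-side slope is not positive; "
                         "slope ratio undefined")
    return slope_pos, slope_neg, float(np.clip(slope_pos / slope_neg, 0.0, 1.0))
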