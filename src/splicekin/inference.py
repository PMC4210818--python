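"""Model fitting, BIC comparison, the slope-ratio pre-release estimator and
z-tests.

All four correlation curves are fitted jointly by weighted least squares
(cross-correlation residuals weighted 2x relative to the autocorrelations),
using delays up to ``max_delay``.  Parameters are optimized in log space to
enforce positivity; standard errors come from the Gauss-Newton covariance
scaled by the residual variance, and derived quantities carry delta-method
errors.  The BIC is ``n*ln(rss/n) + k*ln(n)`` with the weighted residual sum
of squares, identical across models, so only rankings and differences are
meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .correlation import CorrelationSet, _combine, _norm_delay_index
from .kinetic_models import (VARIANTS, DerivedQuantities, GeneLayout,
                             KineticModel, derived_quantities, make_model)
from .model_curves import CurvePredictor, ModelCurvePrediction

__all__ = ["FitResult", "SlopeEstimate", "fit_model", "compare_models",
           "slope_prerelease", "z_test"]

logger = logging.getLogger(__name__)

DEFAULT_MAX_DELAY = 400.0
DEFAULT_SLOPE_WINDOW = (10.0, 40.0)

#: optimizer bounds per parameter kind (natural scale)
_BOUNDS = {
    "v": (0.2, 12.0),            # kb/min
    "pause_3ss.mean": (1.0, 5000.0),
    "splice.mean": (1.0, 5000.0),
    "splice.shape": (0.5, 50.0),
    "release.mean": (1.0, 5000.0),
}

#: documented multi-start grid (log-spaced), covering the fitted conditions
_START_GRID = {
    "v": (1.0, 2.0, 4.0),
    "pause_3ss.mean": (30.0, 300.0),
    "splice.mean": (100.0, 283.0, 800.0),
    "splice.shape": (2.0,),
    "release.mean": (30.0, 95.0, 300.0),
}


@dataclass
class FitResult:
    model: KineticModel
    se: dict[str, float]
    rss: float
    n_points: int
    k_params: int
    bic: float
    derived: DerivedQuantities
    success: bool = True
    message: str = ""
    at_bound: tuple = ()

    @property
    def variant(self) -> str:
        return self.model.variant


@dataclass
class SlopeEstimate:
    fraction: float
    se: float
    slope_pos: float
    slope_neg: float
    slope_pos_se: float = float("nan")
    slope_neg_se: float = float("nan")
    diagnostic: str = ""


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _data_vectors(data: CorrelationSet, max_delay: float):
    """Masked data values and residual weights; tau = 0 is excluded (the
    autocorrelation noise spike / shot-noise-dominated cross point)."""
    ys, ws, masks = [], [], {}
    for name, curve in data.curves().items():
        mask = (curve.delays > 0) & (curve.delays <= max_delay)
        masks[name] = mask
        ys.append(curve.values[mask])
        ws.append(np.full(mask.sum(), 2.0 if name in ("Grg", "Ggr") else 1.0))
    return np.concatenate(ys), np.concatenate(ws), masks


def _model_vector(pred: ModelCurvePrediction, masks) -> np.ndarray:
    return np.concatenate([pred.curves()[name][masks[name]]
                           for name in ("Grr", "Ggg", "Grg", "Ggr")])


def fit_model(data: CorrelationSet, variant: str, layout: GeneLayout,
              init_params: Optional[dict[str, float]] = None,
              max_delay: float = DEFAULT_MAX_DELAY,
              n_draws: int = 4096, mc_seed: int = 0,
              predictor: Optional[CurvePredictor] = None,
              use_sem_weights: bool = False) -> FitResult:
    """Fit one model variant to a normalized correlation set.

    ``init_params`` maps dotted free-parameter names (see
    ``VARIANTS[variant].free_params``) to starting values; missing entries
    get mid-range defaults.
    """
    spec = VARIANTS[variant]
    names = list(spec.free_params)
    base = make_model(variant, v=2.0, pause_mean=100.0, splice_mean=283.0,
                      splice_shape=2.0, release_mean=100.0)
    defaults = base.param_values()
    x0 = np.log([float((init_params or {}).get(n, defaults[n])) for n in names])

    grid = data.Grr.delays
    if predictor is None:
        predictor = CurvePredictor(layout, grid, n_draws=n_draws, seed=mc_seed)
    y, w, masks = _data_vectors(data, max_delay)
    if use_sem_weights:
        sems = np.concatenate([
            data.curves()[name].sem[masks[name]]
            if data.curves()[name].sem is not None
            else np.ones(masks[name].sum())
            for name in ("Grr", "Ggg", "Grg", "Ggr")])
        w = w / np.maximum(sems, 1e-12) ** 2
    sw = np.sqrt(w)

    lo = np.log([_BOUNDS[n][0] for n in names])
    hi = np.log([_BOUNDS[n][1] for n in names])
    x0 = np.clip(x0, lo, hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        model = base.with_params(**dict(zip(names, np.exp(x))))
        pred = predictor.predict(model)
        return sw * (_model_vector(pred, masks) - y)

    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                 method="trf", x_scale="jac",
                                 xtol=1e-10, ftol=1e-10)
    x = sol.x
    fitted = base.with_params(**dict(zip(names, np.exp(x))))
    rss = float(2.0 * sol.cost)
    n_points = len(y)
    k = len(names)
    bic = n_points * np.log(rss / n_points) + k * np.log(n_points)

    # covariance of log-params: sandwich form propagating the bootstrap
    # covariance of the correlation curves through the fit.  The full
    # cross-delay covariance (from the stored bootstrap replicates) matters:
    # neighbouring delay points are strongly correlated.  Falls back to a
    # diagonal-SEM sandwich, then to residual-variance scaling.
    J = sol.jac
    try:
        A_inv = np.linalg.inv(J.T @ J)
        sw_col = sw[:, None]
        if data.boot is not None:
            B = np.concatenate([data.boot[name][:, masks[name]]
                                for name in ("Grr", "Ggg", "Grg", "Ggr")],
                               axis=1)
            sigma = np.cov(B, rowvar=False)
            mid = J.T @ (sw_col * sigma * sw_col.T) @ J
            cov_log = A_inv @ mid @ A_inv
        elif all(c.sem is not None for c in data.curves().values()):
            sem_vec = np.concatenate([data.curves()[name].sem[masks[name]]
                                      for name in ("Grr", "Ggg", "Grg", "Ggr")])
            mid = J.T @ (w * sem_vec ** 2 * J.T).T
            cov_log = A_inv @ mid @ A_inv
        else:
            cov_log = rss / max(n_points - k, 1) * A_inv
    except np.linalg.LinAlgError:
        cov_log = np.full((k, k), np.nan)
    p = np.exp(x)
    cov = cov_log * np.outer(p, p)  # delta method for exp transform
    se = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}

    at_bound = tuple(n for i, n in enumerate(names)
                     if x[i] <= lo[i] + 1e-6 or x[i] >= hi[i] - 1e-6)
    if at_bound:
        logger.warning("fit_model(%s): parameters at bound: %s",
                       variant, at_bound)

    derived = _derived_with_se(fitted, layout, names, x, cov_log)
    return FitResult(model=fitted, se=se, rss=rss, n_points=n_points,
                     k_params=k, bic=float(bic), derived=derived,
                     success=bool(sol.success), message=sol.message,
                     at_bound=at_bound)


def _derived_with_se(model: KineticModel, layout: GeneLayout,
                     names: list[str], x_log: np.ndarray,
                     cov_log: np.ndarray) -> DerivedQuantities:
    """Derived quantities with delta-method SEs over the fitted covariance."""
    rng_seed = 1234  # common random numbers across gradient evaluations

    def eval_derived(xl: np.ndarray) -> np.ndarray:
        m = model.with_params(**dict(zip(names, np.exp(xl))))
        frac = _point_prerelease(m, layout, rng_seed)
        from .kinetic_models import expected_label_ratio
        ratio = expected_label_ratio(m, layout, n_mc=50_000,
                                     rng=np.random.default_rng(rng_seed))
        return np.array([frac, ratio])

    f0 = eval_derived(x_log)
    grad = np.zeros((2, len(names)))
    h = 1e-4
    for i in range(len(names)):
        xp, xm = x_log.copy(), x_log.copy()
        xp[i] += h
        xm[i] -= h
        grad[:, i] = (eval_derived(xp) - eval_derived(xm)) / (2 * h)
    if np.all(np.isfinite(cov_log)):
        var = np.einsum("ij,jk,ik->i", grad, cov_log, grad)
        ses = np.sqrt(np.maximum(var, 0.0))
    else:
        ses = np.full(2, np.nan)
    from .kinetic_models import elongation_time
    return DerivedQuantities(
        pre_release_fraction=float(f0[0]), label_ratio=float(f0[1]),
        t_elong_3ss_to_end=elongation_time(layout.ss3, layout.polyA, model.v),
        pre_release_fraction_se=float(ses[0]), label_ratio_se=float(ses[1]))


def _point_prerelease(model: KineticModel, layout: GeneLayout,
                      seed: int) -> float:
    from .kinetic_models import pre_release_fraction
    return float(pre_release_fraction(model, layout, n_mc=50_000,
                                      rng=np.random.default_rng(seed)))


def _variant_starts(variant: str, max_starts: Optional[int] = None) -> list[dict]:
    names = VARIANTS[variant].free_params
    axes = [_START_GRID[n] for n in names]
    starts = [dict(zip(names, combo)) for combo in product(*axes)]
    if max_starts is not None and len(starts) > max_starts:
        idx = np.linspace(0, len(starts) - 1, max_starts).round().astype(int)
        starts = [starts[i] for i in idx]
    return starts


def compare_models(data: CorrelationSet, variants: Sequence[str],
                   layout: GeneLayout, max_delay: float = DEFAULT_MAX_DELAY,
                   n_draws: int = 4096, mc_seed: int = 0,
                   max_starts: Optional[int] = 6) -> list[FitResult]:
    """Fit each variant from a multi-start grid and rank ascending by BIC."""
    if len(variants) < 1:
        raise ValueError("need at least one variant")
    grid = data.Grr.delays
    predictor = CurvePredictor(layout, grid, n_draws=n_draws, seed=mc_seed)
    results = []
    for variant in variants:
        best = None
        for start in _variant_starts(variant, max_starts):
            try:
                fit = fit_model(data, variant, layout, init_params=start,
                                max_delay=max_delay, predictor=predictor)
            except Exception as exc:  # keep scanning other starts
                logger.warning("fit failed for %s from %s: %s",
                               variant, start, exc)
                continue
            if best is None or fit.rss < best.rss:
                best = fit
        if best is None:
            raise RuntimeError(f"all starts failed for variant {variant}")
        results.append(best)
    results.sort(key=lambda r: r.bic)
    return results


# ---------------------------------------------------------------------------
# Model-free slope-ratio estimator
# ---------------------------------------------------------------------------

def _derivative_constant(delays: np.ndarray, values: np.ndarray,
                         window: tuple[float, float]) -> float:
    """Two-point finite differences at interval midpoints; constant fit
    (mean) over midpoints inside the window."""
    mids = 0.5 * (delays[1:] + delays[:-1])
    deriv = np.diff(values) / np.diff(delays)
    mask = (mids >= window[0]) & (mids <= window[1])
    if mask.sum() < 1:
        raise ValueError("no derivative points inside the slope window")
    return float(deriv[mask].mean())


def _slopes_from_set(cs: CorrelationSet,
                     window: tuple[float, float]) -> tuple[float, float]:
    # Ggr carries the negative-delay half of the cross-correlation, so its
    # rising slope toward zero is -dGgr/dtau in its own delay coordinate
    pos = _derivative_constant(cs.Grg.delays, cs.Grg.values, window)
    neg = -_derivative_constant(cs.Ggr.delays, cs.Ggr.values, window)
    return pos, neg


def slope_prerelease(data: Union[CorrelationSet, Sequence[CorrelationSet]],
                     n_boot: int = 200,
                     window: tuple[float, float] = DEFAULT_SLOPE_WINDOW,
                     baseline_window=(300.0, 500.0),
                     rng_seed=0) -> SlopeEstimate:
    """Model-free pre-release fraction from the cross-correlation slopes.

    If ``data`` is a list of per-trace correlation sets, the averaging and
    normalization pipeline is re-run inside each bootstrap replicate
    (resampling traces) to get the SE; a single averaged set gives a point
    estimate without bootstrap error.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    if isinstance(data, CorrelationSet):
        pos, neg = _slopes_from_set(data, window)
        fractions = None
    else:
        sets = list(data)
        from .correlation import average_correlations
        avg = average_correlations(sets, n_boot=0,
                                   baseline_window=baseline_window)
        pos, neg = _slopes_from_set(avg, window)
        fractions, poss, negs = [], [], []
        for _ in range(n_boot):
            idx = rng.integers(0, len(sets), len(sets))
            try:
                rep, _ = _combine(sets, idx, baseline_window, True)
            except ValueError:
                continue
            grid = sets[0].Grg.delays
            p = _derivative_constant(grid, rep["Grg"], window)
            n = -_derivative_constant(grid, rep["Ggr"], window)
            poss.append(p)
            negs.append(n)
            if n > 0:
                fractions.append(np.clip(p / n, 0.0, 1.0))

    if neg <= 0:
        return SlopeEstimate(fraction=float("nan"), se=float("nan"),
                             slope_pos=pos, slope_neg=neg,
                             diagnostic="negative-side slope not positive; "
                                        "fraction undefined")
    frac = float(np.clip(pos / neg, 0.0, 1.0))
    if fractions:
        return SlopeEstimate(fraction=frac,
                             se=float(np.std(fractions, ddof=1)),
                             slope_pos=pos, slope_neg=neg,
                             slope_pos_se=float(np.std(poss, ddof=1)),
                             slope_neg_se=float(np.std(negs, ddof=1)))
    return SlopeEstimate(fraction=frac, se=float("nan"),
                         slope_pos=pos, slope_neg=neg)


# ---------------------------------------------------------------------------
# z-test
# ---------------------------------------------------------------------------

def z_test(p1: float, se1: float, p2: float, se2: float) -> float:
    """Two-sided normal p-value for the difference of two estimates."""
    if se1 < 0 or se2 < 0 or (se1 == 0 and se2 == 0):
        raise ValueError("standard errors must be positive")
    z = (p1 - p2) / np.hypot(se1, se2)
    return float(2.0 * stats.norm.sf(abs(z)))
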