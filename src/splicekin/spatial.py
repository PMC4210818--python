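"""Post-release spatial statistics on single-particle coordinate fields.

Colocalization pairing, transcription-site-referenced radial distributions
normalized by a uniform-in-nucleus null, Gaussian enrichment fits, the
diffusion-clock splicing time sigma^2/(4D), ratiometric nascent-transcript
counting and pre-mRNA fraction summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import shapely
from scipy import optimize
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

__all__ = [
    "PairedParticles",
    "RadialProfile",
    "GaussianEnrichment",
    "pair_colocalized",
    "radial_profile",
    "fit_enrichment",
    "post_release_splice_time",
    "count_nascent",
    "premrna_fraction",
    "uniform_points_in_polygon",
]

DEFAULT_PAIR_RADIUS_LIVE = 0.25   # μm
DEFAULT_PAIR_RADIUS_FISH = 0.20   # μm
DEFAULT_EXCLUSION_UM = 1.0        # detection-artifact depletion radius


@dataclass
class PairedParticles:
    colocalized: np.ndarray   # (n, 2, 2): [pair, (red, green), (x, y)]
    pair_distances: np.ndarray
    red_only: np.ndarray      # (m, 2)
    green_only: np.ndarray    # (k, 2)
    radius: float

    @property
    def n_colocalized(self) -> int:
        return len(self.colocalized)


@dataclass
class RadialProfile:
    bin_edges: np.ndarray
    density_ratio: np.ndarray
    sem: Optional[np.ndarray] = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])


@dataclass
class GaussianEnrichment:
    sigma: float
    height: float
    baseline: float
    sigma_se: float = float("nan")
    height_se: float = float("nan")
    baseline_se: float = float("nan")
    identifiable: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def pair_colocalized(red_spots, green_spots,
                     radius: float = DEFAULT_PAIR_RADIUS_LIVE,
                     method: str = "greedy") -> PairedParticles:
    """Match red and green spots of one frame that lie within ``radius``.

    ``greedy`` takes candidate pairs nearest-first; ``mutual`` keeps only
    mutual nearest neighbors.  Each particle is used at most once.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    red = np.atleast_2d(np.asarray(red_spots, dtype=float)).reshape(-1, 2)
    green = np.atleast_2d(np.asarray(green_spots, dtype=float)).reshape(-1, 2)
    if len(red) == 0 or len(green) == 0:
        return PairedParticles(np.zeros((0, 2, 2)), np.zeros(0), red, green,
                               radius)

    tree_r, tree_g = cKDTree(red), cKDTree(green)
    pairs = tree_r.query_ball_tree(tree_g, r=radius)
    candidates = [(np.hypot(*(red[i] - green[j])), i, j)
                  for i, js in enumerate(pairs) for j in js]
    if method == "mutual":
        nn_r = {i: min(js, key=lambda j: np.hypot(*(red[i] - green[j])))
                for i, js in enumerate(pairs) if js}
        gpairs = tree_g.query_ball_tree(tree_r, r=radius)
        nn_g = {j: min(is_, key=lambda i: np.hypot(*(green[j] - red[i])))
                for j, is_ in enumerate(gpairs) if is_}
        candidates = [(d, i, j) for d, i, j in candidates
                      if nn_r.get(i) == j and nn_g.get(j) == i]
    elif method != "greedy":
        raise ValueError(f"unknown pairing method {method!r}")

    used_r: set = set()
    used_g: set = set()
    matched, dists = [], []
    for d, i, j in sorted(candidates):
        if i in used_r or j in used_g:
            continue
        used_r.add(i)
        used_g.add(j)
        matched.append((red[i], green[j]))
        dists.append(d)
    coloc = (np.stack([np.stack(p) for p in matched])
             if matched else np.zeros((0, 2, 2)))
    red_only = red[[i for i in range(len(red)) if i not in used_r]]
    green_only = green[[j for j in range(len(green)) if j not in used_g]]
    return PairedParticles(coloc, np.asarray(dists), red_only, green_only,
                           radius)


# ---------------------------------------------------------------------------
# Radial distributions
# ---------------------------------------------------------------------------

def uniform_points_in_polygon(poly: Polygon, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ``n`` uniform points inside a polygon."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        k = max(int((n - len(out)) * 2.0), 100)
        xy = np.column_stack([rng.uniform(minx, maxx, k),
                              rng.uniform(miny, maxy, k)])
        keep = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
        out = np.vstack([out, xy[keep]])
    return out[:n]


def _distance_hist(points: np.ndarray, ts: np.ndarray,
                   edges: np.ndarray) -> np.ndarray:
    d = np.hypot(points[:, 0] - ts[0], points[:, 1] - ts[1])
    counts, _ = np.histogram(d, bins=edges)
    return counts.astype(float)


def radial_profile(particles, ts_position, nucleus,
                   n_null: int = 100_000, bins=None,
                   null_particles=None,
                   n_boot: int = 200, rng_seed=0) -> RadialProfile:
    """Particle-to-TS distance density normalized by a uniform-in-nucleus
    null (or by a reference particle population, FISH mode).

    ``particles`` may be a single ``(n, 2)`` array or a list of per-cell
    arrays (then ``ts_position``/``nucleus``/``null_particles`` are matching
    lists and the SEM is bootstrapped over cells).
    """
    single = not isinstance(particles, (list, tuple))
    cells = [particles] if single else list(particles)
    ts_list = [ts_position] if single else list(ts_position)
    nuc_list = [nucleus] if single else list(nucleus)
    null_list = ([null_particles] if single else list(null_particles)) \
        if null_particles is not None else None
    if all(len(np.atleast_2d(c)) == 0 for c in cells):
        raise ValueError("no particles given")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    if bins is None:
        bins = np.arange(0.0, 8.5, 0.5)
    edges = np.asarray(bins, dtype=float)

    obs = np.zeros((len(cells), len(edges) - 1))
    nul = np.zeros_like(obs)
    for c, (pts, ts, nuc) in enumerate(zip(cells, ts_list, nuc_list)):
        pts = np.atleast_2d(np.asarray(pts, dtype=float)).reshape(-1, 2)
        ts = np.asarray(ts, dtype=float)
        obs[c] = _distance_hist(pts, ts, edges)
        if null_list is not None:
            ref = np.atleast_2d(np.asarray(null_list[c], float)).reshape(-1, 2)
        else:
            poly = nuc if isinstance(nuc, Polygon) else Polygon(np.asarray(nuc))
            ref = uniform_points_in_polygon(poly, n_null, rng)
        nul[c] = _distance_hist(ref, ts, edges)

    def ratio(idx: np.ndarray) -> np.ndarray:
        o, u = obs[idx].sum(axis=0), nul[idx].sum(axis=0)
        o_tot, u_tot = o.sum(), u.sum()
        if o_tot == 0 or u_tot == 0:
            return np.full(len(o), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (o / o_tot) / (u / u_tot)
        return np.where(u > 0, r, np.nan)

    all_idx = np.arange(len(cells))
    dens = ratio(all_idx)
    sem = None
    if n_boot > 0 and len(cells) >= 2:
        reps = np.stack([ratio(rng.integers(0, len(cells), len(cells)))
                         for _ in range(n_boot)])
        sem = np.nanstd(reps, axis=0, ddof=1)
    elif n_boot > 0:
        # single cell: binomial error on the observed counts
        o = obs[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            sem = dens / np.sqrt(np.maximum(o, 1.0))
    return RadialProfile(bin_edges=edges, density_ratio=dens, sem=sem)


def fit_enrichment(profile: RadialProfile,
                   exclusion_um: float = DEFAULT_EXCLUSION_UM) -> GaussianEnrichment:
    """Weighted least-squares fit of ``y0 + h*exp(-r^2 / 2 sigma^2)`` to a
    radial profile, excluding the short-distance detection-artifact bins."""
    r = profile.bin_centers
    y = profile.density_ratio
    keep = (r >= exclusion_um) & np.isfinite(y)
    if keep.sum() < 4:
        raise ValueError("need >= 4 informative bins beyond the exclusion "
                         "radius")
    r, y = r[keep], y[keep]
    w = None
    if profile.sem is not None:
        s = profile.sem[keep]
        w = np.where(np.isfinite(s) & (s > 0), s, np.nanmax(s[s > 0])
                     if np.any(s > 0) else 1.0)

    def f(rr, y0, h, sigma):
        return y0 + h * np.exp(-rr ** 2 / (2.0 * sigma ** 2))

    span = max(y.max() - y.min(), 1e-9)
    p0 = (float(np.median(y)), float(span), float(r.mean()))
    try:
        popt, pcov = optimize.curve_fit(
            f, r, y, p0=p0, sigma=w, absolute_sigma=False,
            bounds=((-np.inf, 0.0, 1e-3), (np.inf, np.inf, 100.0)),
            maxfev=20_000)
    except RuntimeError as exc:
        raise RuntimeError(f"enrichment fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    y0, h, sigma = popt
    identifiable = bool(h > 2.0 * perr[1]) if np.isfinite(perr[1]) else False
    msg = "" if identifiable else ("enrichment height consistent with 0; "
                                   "sigma unidentifiable")
    return GaussianEnrichment(sigma=float(sigma), height=float(h),
                              baseline=float(y0), sigma_se=float(perr[2]),
                              height_se=float(perr[1]),
                              baseline_se=float(perr[0]),
                              identifiable=identifiable, message=msg)


def post_release_splice_time(sigma: float, D: float) -> float:
    """Mean post-release splicing time implied by the enrichment width:
    sigma^2 / (4 D)."""
    if sigma <= 0 or D <= 0:
        raise ValueError("sigma and D must be > 0")
    return sigma ** 2 / (4.0 * D)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_nascent(ts_intensity_red: float, ts_intensity_green: float,
                  single_red: Sequence[float],
                  single_green: Sequence[float]) -> tuple[float, float, float]:
    """Nascent-transcript counts per channel from the TS intensity divided by
    the mean single-RNA intensity, and their red/green ratio."""
    single_red = np.asarray(single_red, dtype=float)
    single_green = np.asarray(single_green, dtype=float)
    if len(single_red) < 10 or len(single_green) < 10:
        raise ValueError("need >= 10 single-RNA intensities per channel")
    mr, mg = single_red.mean(), single_green.mean()
    if mr <= 0 or mg <= 0:
        raise ValueError("mean single-RNA intensity must be > 0")
    n_red = ts_intensity_red / mr
    n_green = ts_intensity_green / mg
    if n_green == 0:
        raise ValueError("zero green count; ratio undefined")
    return float(n_red), float(n_green), float(n_red / n_green)


def premrna_fraction(paired: PairedParticles,
                     colocalized_intensity: Optional[Sequence[float]] = None,
                     single_rna_intensity: Optional[float] = None,
                     ts_threshold_fold: float = 2.0) -> float:
    """Fraction of nuclear transcripts that are unspliced:
    ``n_coloc / (n_coloc + n_green_only)``.

    Bicolor particles brighter than ``ts_threshold_fold`` times the single-RNA
    intensity are treated as transcription sites and excluded.  Red-only
    particles are excluded from the denominator (high false-positive rate).
    """
    n_coloc = paired.n_colocalized
    if colocalized_intensity is not None and single_rna_intensity is not None:
        inten = np.asarray(colocalized_intensity, dtype=float)
        if len(inten) != n_coloc:
            raise ValueError("intensity list must match colocalized pairs")
        n_coloc = int((inten <= ts_threshold_fold * single_rna_intensity).sum())
    denom = n_coloc + len(paired.green_only)
    if denom == 0:
        raise ValueError("no particles in the denominator")
    return n_coloc / denom
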