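"""Stochastic simulation of transcript event times, dual-color trace
rendering, and diffusing particle fields.

Each transcript's fluorescence is, per color, a linear ramp while its
cassette is transcribed, a plateau at one single-RNA equivalent, and an
instantaneous drop at the scheme-specific drop event.  Traces are sums of
transcript profiles sampled on a uniform grid with additive Gaussian noise
and optional multiplicative photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .kinetic_models import DelaySpec, GeneLayout, KineticModel

__all__ = [
    "TranscriptEvents",
    "DualColorTrace",
    "NoiseSpec",
    "ParticleField",
    "event_times_from_draws",
    "sample_event_arrays",
    "sample_transcript_events",
    "render_trace",
    "simulate_dataset",
    "simulate_particle_field",
]


@dataclass(frozen=True)
class TranscriptEvents:
    """Event times (s) for a single transcript."""
    t_init: float
    t_pp7_start: float
    t_pp7_end: float
    t_3ss: float
    t_ms2_start: float
    t_ms2_end: float
    t_polyA: float
    t_red_drop: float
    t_green_drop: float


@dataclass
class DualColorTrace:
    """Uniformly sampled red/green intensity series for one transcription site."""
    t: np.ndarray
    red: np.ndarray
    green: np.ndarray
    nucleus_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.nucleus_sd is not None:
            self.nucleus_sd = np.asarray(self.nucleus_sd, dtype=float)
        n = len(self.t)
        if len(self.red) != n or len(self.green) != n:
            raise ValueError("trace channels must have equal lengths")
        if self.nucleus_sd is not None and len(self.nucleus_sd) != n:
            raise ValueError("nucleus_sd length mismatch")
        if n >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0]):
                raise ValueError("sampling must be uniform")
        if not (np.all(np.isfinite(self.red)) and np.all(np.isfinite(self.green))):
            raise ValueError("intensities must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class NoiseSpec:
    additive_sd: float = 0.0
    photobleach_halflife: Optional[float] = None
    background_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")


@dataclass
class ParticleField:
    """Per-frame particle coordinates with channel labels, a TS track and a
    nucleus boundary."""
    particles: pd.DataFrame  # columns: frame, x_um, y_um, channel [, species]
    ts_track: pd.DataFrame   # columns: frame, x_um, y_um
    nucleus: np.ndarray      # polygon vertices, shape (n, 2)
    frame_interval: float

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        self.nucleus = np.asarray(self.nucleus, dtype=float)

    @property
    def nucleus_polygon(self) -> Polygon:
        return Polygon(self.nucleus)


# ---------------------------------------------------------------------------
# Event sampling
# ---------------------------------------------------------------------------

def event_times_from_draws(model: KineticModel, layout: GeneLayout,
                           t_init: np.ndarray, pause: np.ndarray,
                           splice: np.ndarray,
                           rel: np.ndarray) -> dict[str, np.ndarray]:
    """Event times given pre-drawn pause/splice/release delays.

    Implements each scheme's causal rules:

    * I  - red and green drop together at release.
    * II - splicing races release; red drops at whichever comes first.
    * III- elongation pauses at the 3'ss for the splice duration; red drops
      when splicing completes, before the green cassette is transcribed.
    * IV - splicing only after the gene end; IV.4 releases when both the
      splicing and processing clocks (independent exponentials) are done.
    * V  - release waits for splicing.
    """
    t_init = np.asarray(t_init, dtype=float)
    n = len(t_init)
    v = model.v_nt_s
    scheme = model.scheme

    pp7s = t_init + layout.pp7_start / v
    pp7e = t_init + layout.pp7_end / v
    ss3 = t_init + layout.ss3 / v

    # delay applied to every event downstream of the 3'ss
    if scheme == "III":
        post_delay = splice
    elif scheme in ("I", "II"):
        post_delay = pause
    else:
        post_delay = np.zeros(n)

    ms2s = t_init + layout.ms2_start / v + post_delay
    ms2e = t_init + layout.ms2_end / v + post_delay
    polya = t_init + layout.polyA / v + post_delay

    if scheme == "I":
        red = green = polya + rel
    elif scheme == "II":
        release = polya + rel
        # the splicing clock starts once the 3'ss is transcribed, regardless
        # of any downstream elongation pause
        red = np.minimum(ss3 + splice, release)
        green = release
    elif scheme == "III":
        red = ss3 + splice
        green = polya
    elif scheme == "IV":
        red = polya + splice
        if model.variant == "IV.4":
            green = polya + np.maximum(splice, rel)
        else:
            green = red + rel
    elif scheme == "V":
        # release machinery engages only once the intron is removed (and
        # transcription is finished), so the green drop is strictly after
        # the red drop for a.s.-positive release delays
        red = ss3 + splice
        green = np.maximum(red, polya) + rel
    else:  # pragma: no cover
        raise ValueError(f"unknown scheme {scheme!r}")

    return {
        "t_init": t_init, "t_pp7_start": pp7s, "t_pp7_end": pp7e,
        "t_3ss": ss3, "t_ms2_start": ms2s, "t_ms2_end": ms2e,
        "t_polyA": polya, "t_red_drop": red, "t_green_drop": green,
    }


def sample_event_arrays(model: KineticModel, layout: GeneLayout,
                        t_init: np.ndarray,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorized event-time draws for ``len(t_init)`` transcripts."""
    n = len(np.asarray(t_init))
    return event_times_from_draws(
        model, layout, t_init,
        model.pause_3ss.sample(rng, n),
        model.splice.sample(rng, n),
        model.release.sample(rng, n),
    )


def sample_transcript_events(model: KineticModel, layout: GeneLayout,
                             rng_seed=0) -> TranscriptEvents:
    """Draw the event times of a single transcript initiated at t = 0."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    ev = sample_event_arrays(model, layout, np.zeros(1), rng)
    return TranscriptEvents(**{k: float(a[0]) for k, a in ev.items()})


# ---------------------------------------------------------------------------
# Trace rendering
# ---------------------------------------------------------------------------

def _profile_sum(t: np.ndarray, start: np.ndarray, plateau: np.ndarray,
                 drop: np.ndarray) -> np.ndarray:
    """Sum of ramp/plateau/drop profiles over transcripts, sampled at ``t``."""
    if len(start) == 0:
        return np.zeros_like(t)
    total = np.zeros_like(t)
    tt = t[None, :]
    for lo in range(0, len(start), 256):  # chunked to bound memory
        s = start[lo:lo + 256, None]
        p = plateau[lo:lo + 256, None]
        d = drop[lo:lo + 256, None]
        ramp = np.clip((tt - s) / (p - s), 0.0, 1.0)
        total += (ramp * (tt < d)).sum(axis=0)
    return total


def render_trace(events, duration: float, dt: float = 10.0,
                 noise: Optional[NoiseSpec] = None,
                 rng_seed=0) -> DualColorTrace:
    """Render the summed dual-color trace of a set of transcripts.

    ``events`` is a list of :class:`TranscriptEvents` or the dict of arrays
    from :func:`sample_event_arrays`.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    noise = noise or NoiseSpec()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    t = np.arange(0.0, duration, dt)

    if isinstance(events, dict):
        ev = events
    else:
        keys = ("t_pp7_start", "t_pp7_end", "t_red_drop",
                "t_ms2_start", "t_ms2_end", "t_green_drop")
        ev = {k: np.array([getattr(e, k) for e in events]) for k in keys}

    red = _profile_sum(t, ev["t_pp7_start"], ev["t_pp7_end"], ev["t_red_drop"])
    green = _profile_sum(t, ev["t_ms2_start"], ev["t_ms2_end"],
                         ev["t_green_drop"])

    if noise.photobleach_halflife:
        bleach = np.exp(-t * np.log(2.0) / noise.photobleach_halflife)
    else:
        bleach = np.ones_like(t)
    red = (red + noise.background_offset) * bleach
    green = (green + noise.background_offset) * bleach
    if noise.additive_sd > 0:
        red = red + rng.normal(0.0, noise.additive_sd, len(t))
        green = green + rng.normal(0.0, noise.additive_sd, len(t))
    return DualColorTrace(t=t, red=red, green=green, nucleus_sd=bleach.copy())


def _steady_state_warmup(model: KineticModel, layout: GeneLayout) -> float:
    """Pre-roll long enough that transcripts initiated before t=0 are at
    steady state."""
    transit = layout.polyA / model.v_nt_s
    tails = (model.pause_3ss.mean + model.splice.mean + model.release.mean)
    return transit + 8.0 * tails + 100.0


def simulate_dataset(model: KineticModel, layout: GeneLayout,
                     n_traces: int = 21, duration: float = 5000.0,
                     dt: float = 10.0, noise: Optional[NoiseSpec] = None,
                     rng_seed=0) -> list[DualColorTrace]:
    """Independent traces with Poisson transcript initiation at
    ``model.k_init``."""
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    warmup = _steady_state_warmup(model, layout)
    traces = []
    for _ in range(n_traces):
        n_tx = rng.poisson(model.k_init * (duration + warmup))
        t_init = np.sort(rng.uniform(-warmup, duration, n_tx))
        ev = sample_event_arrays(model, layout, t_init, rng)
        traces.append(render_trace(ev, duration, dt, noise, rng))
    return traces


# ---------------------------------------------------------------------------
# Particle fields
# ---------------------------------------------------------------------------

def circle_polygon(radius: float, center=(0.0, 0.0), n: int = 64) -> np.ndarray:
    """Vertices of a regular polygon approximating a circle (μm)."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def _reflect_into(poly: Polygon, xy: np.ndarray) -> np.ndarray:
    """Reflect points lying outside ``poly`` across the nearest boundary
    point; fall back to nudging toward the centroid for corner cases."""
    inside = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
    if inside.all():
        return xy
    out = xy.copy()
    boundary = poly.exterior
    centroid = np.asarray(poly.centroid.coords[0])
    for i in np.flatnonzero(~inside):
        p = Point(out[i])
        q = boundary.interpolate(boundary.project(p))
        cand = 2.0 * np.asarray(q.coords[0]) - out[i]
        if poly.contains(Point(cand)):
            out[i] = cand
        else:
            out[i] = np.asarray(q.coords[0]) * 0.99 + centroid * 0.01
    return out


def simulate_particle_field(D: float, splice_lifetime: DelaySpec,
                            emission_rate: float,
                            nucleus: np.ndarray,
                            n_frames: int = 50,
                            frame_interval: float = 3.26,
                            rng_seed=0,
                            ts_position=None,
                            loc_jitter_sd: float = 0.0,
                            substep: int = 4) -> ParticleField:
    """Brownian pre-mRNA/mRNA particles emitted at a transcription site.

    Pre-mRNA particles (visible in both channels) are emitted at the TS at
    ``emission_rate`` (particles/s), diffuse with per-axis displacement
    variance 2*D*t, and convert to mRNA (green-only) after their splice
    lifetime.  Particles are reflected at the nucleus boundary.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    nucleus = np.asarray(nucleus, dtype=float)
    poly = Polygon(nucleus)
    if ts_position is None:
        ts_position = np.asarray(poly.centroid.coords[0])
    ts_position = np.asarray(ts_position, dtype=float)

    pos = np.zeros((0, 2))
    birth = np.zeros(0)
    lifetime = np.zeros(0)
    rows = []
    ts_rows = []
    dt_sub = frame_interval / substep
    step_sd = np.sqrt(2.0 * D * dt_sub)
    for f in range(n_frames):
        t_frame = f * frame_interval
        # emit new pre-mRNA at the TS
        k = rng.poisson(emission_rate * frame_interval)
        if k:
            pos = np.vstack([pos, np.tile(ts_position, (k, 1))])
            birth = np.concatenate([birth, np.full(k, t_frame)])
            lifetime = np.concatenate([lifetime, splice_lifetime.sample(rng, k)])
        # diffuse (substeps keep boundary reflections accurate)
        for _ in range(substep):
            if len(pos):
                pos = _reflect_into(poly, pos + rng.normal(0, step_sd, pos.shape))
        age = t_frame + frame_interval - birth
        is_pre = age < lifetime
        n_now = len(pos)
        if n_now:
            species = np.where(is_pre, "pre", "mrna")
            # green record for every particle, plus a red record for pre-mRNA
            xy_g = pos + (rng.normal(0, loc_jitter_sd, pos.shape)
                          if loc_jitter_sd else 0.0)
            xy_r = pos[is_pre] + (rng.normal(0, loc_jitter_sd,
                                             (int(is_pre.sum()), 2))
                                  if loc_jitter_sd else 0.0)
            rows.append(pd.DataFrame({
                "frame": f,
                "x_um": np.concatenate([xy_r[:, 0], xy_g[:, 0]]),
                "y_um": np.concatenate([xy_r[:, 1], xy_g[:, 1]]),
                "channel": ["red"] * len(xy_r) + ["green"] * n_now,
                "species": np.concatenate([species[is_pre], species]),
            }))
        ts_rows.append((f, ts_position[0], ts_position[1]))

    if rows:
        particles = pd.concat(rows, ignore_index=True)
    else:
        particles = pd.DataFrame(columns=["frame", "x_um", "y_um",
                                          "channel", "species"])
    ts_track = pd.DataFrame(ts_rows, columns=["frame", "x_um", "y_um"])
    return ParticleField(particles=particles, ts_track=ts_track,
                         nucleus=nucleus, frame_interval=frame_interval)
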