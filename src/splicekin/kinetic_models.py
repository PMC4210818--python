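"""Domain types for the reporter geometry and the mechanistic kinetic models.

The reporter carries two stem-loop cassettes read out in two colors: an
intronic cassette (red) and a 3'UTR cassette (green).  A transcript's red
signal disappears when the intron is excised or the transcript leaves the
transcription site, whichever the scheme dictates; the green signal
disappears at transcript release.  Five causal schemes (I-V), each with a
few choices of delay distributions, give 21 model variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "DelaySpec",
    "GeneLayout",
    "KineticModel",
    "DerivedQuantities",
    "VARIANTS",
    "SCHEMES",
    "dirac",
    "exponential",
    "gamma_delay",
    "default_reporter_layout",
    "elongation_time",
    "implied_elongation_rate",
    "coat_protein_binding_time",
    "pre_release_fraction",
    "expected_label_ratio",
    "kb_per_min_to_nt_per_s",
]

#: nt/s per kb/min
_KBMIN_TO_NTS = 1000.0 / 60.0


def kb_per_min_to_nt_per_s(v: float) -> float:
    """Convert an elongation rate from kb/min to nt/s."""
    return v * _KBMIN_TO_NTS


# ---------------------------------------------------------------------------
# Delay distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DelaySpec:
    """A non-negative random delay: Dirac (deterministic), exponential or gamma.

    ``shape`` is only meaningful for the gamma family; gamma with shape=1 is
    the exponential distribution.
    """

    family: str
    mean: float
    shape: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("dirac", "exponential", "gamma"):
            raise ValueError(f"unknown delay family {self.family!r}")
        if self.mean < 0:
            raise ValueError("delay mean must be >= 0")
        if self.family == "gamma":
            if self.shape is None or self.shape <= 0:
                raise ValueError("gamma delay requires a positive shape")

    @property
    def var(self) -> float:
        if self.family == "dirac":
            return 0.0
        if self.family == "exponential":
            return self.mean ** 2
        return self.mean ** 2 / self.shape

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "dirac" or self.mean == 0:
            return np.full(n, self.mean)
        if self.family == "exponential":
            return rng.exponential(self.mean, n)
        return rng.gamma(self.shape, self.mean / self.shape, n)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF, used for common-random-number / quasi-MC evaluation."""
        u = np.asarray(u, dtype=float)
        if self.family == "dirac" or self.mean == 0:
            return np.full_like(u, self.mean)
        if self.family == "exponential":
            return -self.mean * np.log1p(-u)
        return stats.gamma.ppf(u, self.shape, scale=self.mean / self.shape)


def dirac(mean: float) -> DelaySpec:
    return DelaySpec("dirac", mean)


def exponential(mean: float) -> DelaySpec:
    return DelaySpec("exponential", mean)


def gamma_delay(mean: float, shape: float) -> DelaySpec:
    return DelaySpec("gamma", mean, shape)


DIRAC0 = dirac(0.0)


# ---------------------------------------------------------------------------
# Gene layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLayout:
    """Nucleotide landmarks of the reporter (0-based, transcription start = 0).

    Intervals are half-open; e.g. the red cassette spans
    ``[pp7_start, pp7_end)``.
    """

    pp7_start: int
    pp7_end: int
    ss3: int
    ms2_start: int
    ms2_end: int
    polyA: int
    n_loops_red: int = 24
    n_loops_green: int = 24

    def __post_init__(self) -> None:
        if not (self.pp7_start < self.pp7_end <= self.ss3 < self.ms2_start
                < self.ms2_end <= self.polyA):
            raise ValueError("layout landmarks out of order")

    @property
    def pp7_length(self) -> int:
        return self.pp7_end - self.pp7_start

    @property
    def ms2_length(self) -> int:
        return self.ms2_end - self.ms2_start

    @property
    def cassette_separation(self) -> float:
        """Midpoint-to-midpoint distance between the two cassettes (nt)."""
        return ((self.ms2_start + self.ms2_end)
                - (self.pp7_start + self.pp7_end)) / 2.0

    def to_dict(self) -> dict:
        return {
            "pp7_start": self.pp7_start, "pp7_end": self.pp7_end,
            "ss3": self.ss3, "ms2_start": self.ms2_start,
            "ms2_end": self.ms2_end, "polyA": self.polyA,
            "n_loops_red": self.n_loops_red,
            "n_loops_green": self.n_loops_green,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneLayout":
        return cls(**d)


#: two-loop repeat unit lengths (nt), multimerized 12x into each cassette
PP7_REPEAT_NT = 121
MS2_REPEAT_NT = 109

#: distance from the red-cassette end to the 3' splice site of the intron
#: hosting it (371 nt to the branch point plus ~30 nt to the splice site)
_PP7_END_TO_3SS = 401

#: 3'ss-to-poly(A) distance calibrated so that at 2.60 kb/min the 3'ss-to-end
#: elongation time is 55 s
SS3_TO_POLYA_NT = 2383

#: midpoint-to-midpoint cassette separation of the default reporter
CASSETTE_SEPARATION_NT = 2573

#: red cassette begins 463 nt into the host intron (downstream of its 5'ss)
_PP7_START = 463


def default_reporter_layout() -> GeneLayout:
    """The default two-color reporter geometry.

    Cassette lengths are 12x the 121/109-nt two-loop repeat units (121 and
    109 nt); the cassette midpoints are 2573 nt apart and the 3'ss-to-poly(A)
    distance is 2383 nt (55 s at 2.60 kb/min).
    """
    pp7_start = _PP7_START
    pp7_end = pp7_start + 12 * PP7_REPEAT_NT
    ss3 = pp7_end + _PP7_END_TO_3SS
    pp7_mid = (pp7_start + pp7_end) / 2.0
    ms2_len = 12 * MS2_REPEAT_NT
    ms2_mid = pp7_mid + CASSETTE_SEPARATION_NT
    ms2_start = int(round(ms2_mid - ms2_len / 2.0))
    ms2_end = ms2_start + ms2_len
    polyA = ss3 + SS3_TO_POLYA_NT
    return GeneLayout(pp7_start, pp7_end, ss3, ms2_start, ms2_end, polyA)


def elongation_time(from_nt: float, to_nt: float, v: float) -> float:
    """Time (s) for the polymerase to travel ``from_nt`` -> ``to_nt`` at
    ``v`` kb/min."""
    if v <= 0:
        raise ValueError("elongation rate must be > 0")
    if to_nt < from_nt:
        raise ValueError("to_nt must be >= from_nt")
    return (to_nt - from_nt) / kb_per_min_to_nt_per_s(v)


def implied_elongation_rate(distance_nt: float, delay_s: float) -> float:
    """Elongation rate (kb/min) implied by traversing ``distance_nt`` in
    ``delay_s`` seconds."""
    if delay_s <= 0:
        raise ValueError("delay must be > 0")
    return distance_nt / delay_s / _KBMIN_TO_NTS


def coat_protein_binding_time(k_on: float, concentration: float) -> float:
    """Mean waiting time (s) for a coat protein at ``concentration`` (uM) to
    bind a completed stem loop, given the on-rate ``k_on`` (uM^-1 s^-1)."""
    if k_on <= 0 or concentration <= 0:
        raise ValueError("on-rate and concentration must be > 0")
    return 1.0 / (k_on * concentration)


# ---------------------------------------------------------------------------
# Model variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """Which delay distributions a variant activates, and their families."""
    scheme: str
    pause: Optional[str] = None    # pause after the 3'ss (schemes I/II)
    splice: Optional[str] = None   # intron-excision delay
    release: Optional[str] = None  # 3'-end dwell / post-splicing release

    @property
    def free_params(self) -> tuple:
        names = ["v"]
        if self.pause:
            names.append("pause_3ss.mean")
        if self.splice:
            names.append("splice.mean")
        if self.splice == "gamma":
            names.append("splice.shape")
        if self.release:
            names.append("release.mean")
        return tuple(names)

    @property
    def k_params(self) -> int:
        return len(self.free_params)


VARIANTS: dict[str, VariantSpec] = {
    # Scheme I: splicing strictly post-release; both colors drop together.
    "I.1": VariantSpec("I"),
    "I.2": VariantSpec("I", pause="exponential"),
    "I.3": VariantSpec("I", release="exponential"),
    "I.4": VariantSpec("I", pause="exponential", release="exponential"),
    # Scheme II: splicing independent of elongation/release; red drops at
    # whichever of splicing or release happens first.
    "II.1": VariantSpec("II", splice="dirac"),
    "II.2": VariantSpec("II", splice="exponential"),
    "II.3": VariantSpec("II", pause="exponential", splice="dirac"),
    "II.4": VariantSpec("II", splice="dirac", release="exponential"),
    "II.5": VariantSpec("II", pause="exponential", splice="dirac",
                        release="exponential"),
    "II.6": VariantSpec("II", splice="exponential", release="dirac"),
    "II.7": VariantSpec("II", splice="exponential", release="exponential"),
    "II.8": VariantSpec("II", splice="gamma", release="exponential"),
    # Scheme III: obligatory pause at the 3'ss until splicing completes; the
    # red signal always falls before the green signal rises.
    "III.1": VariantSpec("III", splice="exponential"),
    "III.2": VariantSpec("III", splice="dirac"),
    # Scheme IV: splicing only after the 3' end of the gene is reached.
    "IV.1": VariantSpec("IV", release="exponential"),
    "IV.2": VariantSpec("IV", splice="exponential", release="exponential"),
    "IV.3": VariantSpec("IV", splice="gamma", release="exponential"),
    # IV.4: splicing and 3'-end processing are independent exponentials from
    # the gene end; release happens when both are complete.
    "IV.4": VariantSpec("IV", splice="exponential", release="exponential"),
    # Scheme V: release only after splicing is complete.
    "V.1": VariantSpec("V", splice="dirac", release="exponential"),
    "V.2": VariantSpec("V", splice="exponential", release="exponential"),
    "V.3": VariantSpec("V", splice="gamma", release="exponential"),
}

SCHEMES = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class KineticModel:
    """One of the 21 kinetic model variants, fully parameterized.

    Delay specs not used by the variant must stay at Dirac(0).  ``k_init``
    is the Poisson transcript-initiation rate (transcripts/s); it scales the
    raw correlation amplitude and is not a fitted parameter.
    """

    variant: str
    v: float  # elongation rate, kb/min
    pause_3ss: DelaySpec = DIRAC0
    splice: DelaySpec = DIRAC0
    release: DelaySpec = DIRAC0
    k_init: float = 0.02

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")
        if self.v <= 0:
            raise ValueError("elongation rate must be > 0")
        spec = VARIANTS[self.variant]
        for name, fam in (("pause_3ss", spec.pause), ("splice", spec.splice),
                          ("release", spec.release)):
            d: DelaySpec = getattr(self, name)
            if fam is None:
                if not (d.family == "dirac" and d.mean == 0):
                    raise ValueError(
                        f"{self.variant}: {name} is inactive, must be Dirac(0)")
            elif d.family != fam:
                raise ValueError(
                    f"{self.variant}: {name} must be {fam}, got {d.family}")

    @property
    def scheme(self) -> str:
        return VARIANTS[self.variant].scheme

    @property
    def v_nt_s(self) -> float:
        return kb_per_min_to_nt_per_s(self.v)

    def with_params(self, **values: float) -> "KineticModel":
        """Return a copy with dotted free-parameter values replaced
        (e.g. ``with_params(**{"splice.mean": 300.0})``)."""
        out = {}
        for key, val in values.items():
            if key == "v":
                out["v"] = val
                continue
            field_name, attr = key.split(".")
            spec = out.get(field_name, getattr(self, field_name))
            out[field_name] = replace(spec, **{attr: val})
        return replace(self, **out)

    def param_values(self) -> dict[str, float]:
        vals = {}
        for name in VARIANTS[self.variant].free_params:
            if name == "v":
                vals["v"] = self.v
            else:
                field_name, attr = name.split(".")
                vals[name] = getattr(getattr(self, field_name), attr)
        return vals

    def to_dict(self) -> dict:
        d = {"variant": self.variant, "v": self.v, "k_init": self.k_init}
        for name in ("pause_3ss", "splice", "release"):
            spec: DelaySpec = getattr(self, name)
            d[name] = {"family": spec.family, "mean": spec.mean}
            if spec.shape is not None:
                d[name]["shape"] = spec.shape
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        kwargs = {"variant": d["variant"], "v": d["v"]}
        if "k_init" in d:
            kwargs["k_init"] = d["k_init"]
        for name in ("pause_3ss", "splice", "release"):
            if name in d:
                kwargs[name] = DelaySpec(**d[name])
        return cls(**kwargs)


def make_model(variant: str, v: float, pause_mean: float = 0.0,
               splice_mean: float = 0.0, splice_shape: float = 2.0,
               release_mean: float = 0.0, k_init: float = 0.02) -> KineticModel:
    """Build a model for ``variant`` from plain means (families follow the
    variant's definition)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    spec = VARIANTS[variant]
    kwargs: dict = {"variant": variant, "v": v, "k_init": k_init}
    if spec.pause:
        kwargs["pause_3ss"] = DelaySpec(spec.pause, pause_mean)
    if spec.splice:
        shape = splice_shape if spec.splice == "gamma" else None
        kwargs["splice"] = DelaySpec(spec.splice, splice_mean, shape)
    if spec.release:
        kwargs["release"] = DelaySpec(spec.release, release_mean)
    return KineticModel(**kwargs)


@dataclass(frozen=True)
class DerivedQuantities:
    pre_release_fraction: float
    label_ratio: float
    t_elong_3ss_to_end: float
    pre_release_fraction_se: float = 0.0
    label_ratio_se: float = 0.0


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def _check_nonneg(model: KineticModel) -> None:
    for name in ("pause_3ss", "splice", "release"):
        if getattr(model, name).mean < 0:
            raise ValueError(f"{name} mean must be >= 0")


def pre_release_fraction(model: KineticModel, layout: GeneLayout,
                         n_mc: int = 200_000,
                         rng: Optional[np.random.Generator] = None,
                         return_se: bool = False):
    """Probability that intron excision precedes transcript release.

    Model II.4 (Dirac splicing, exponential 3'-end dwell) has the closed form
    ``exp(-(T_splice - t_elong(3'ss -> polyA)) / tau_release)``; other
    variants are evaluated by Monte Carlo over the scheme's event times.
    """
    _check_nonneg(model)
    scheme = model.scheme
    t_el = elongation_time(layout.ss3, layout.polyA, model.v)
    if scheme == "I":
        frac, se = 0.0, 0.0
    elif scheme in ("III", "V"):
        # splicing completes before (III) or gates (V) release by construction
        frac, se = 1.0, 0.0
    elif scheme == "IV" and model.variant != "IV.4":
        # release only happens after splicing (strictly, for a.s.-positive dwell)
        frac, se = 1.0, 0.0
    elif model.variant == "IV.4":
        # splice delay S and processing delay R race from the gene end;
        # release waits for both, so splicing is strictly first iff S < R
        ts, tr = model.splice.mean, model.release.mean
        frac, se = tr / (ts + tr), 0.0
    elif model.variant == "II.4":
        a = model.splice.mean - t_el
        if a <= 0:
            frac, se = 1.0, 0.0
        elif model.release.mean == 0:
            frac, se = 0.0, 0.0
        else:
            frac = float(np.clip(np.exp(-a / model.release.mean), 0.0, 1.0))
            se = 0.0
    else:  # generic scheme II: MC over pause/splice/release draws
        rng = np.random.default_rng(0) if rng is None else rng
        p = model.pause_3ss.sample(rng, n_mc)
        s = model.splice.sample(rng, n_mc)
        r = model.release.sample(rng, n_mc)
        hits = s < t_el + p + r
        frac = float(hits.mean())
        se = float(np.sqrt(frac * (1 - frac) / n_mc))
    if return_se:
        return frac, se
    return frac


def _occupancy_closed_form_II4(model: KineticModel,
                               layout: GeneLayout) -> tuple[float, float]:
    """Expected per-transcript red/green label occupancies (s) for model II.4."""
    v = model.v_nt_s
    ts, tr = model.splice.mean, model.release.mean
    a = ts - (layout.polyA - layout.ss3) / v
    if a <= 0:
        # splicing completes during elongation: the red plateau always ends
        # ts seconds after the 3'ss is transcribed
        red = (layout.pp7_length / (2 * v)
               + (layout.ss3 - layout.pp7_end) / v + ts)
    else:
        # red drop is min(splicing, release), i.e. min(a, R) past the gene end
        e_min = tr * (1.0 - np.exp(-a / tr)) if tr > 0 else 0.0
        red = (layout.pp7_length / (2 * v)
               + (layout.polyA - layout.pp7_end) / v + e_min)
    green = (layout.ms2_length / (2 * v)
             + (layout.polyA - layout.ms2_end) / v + tr)
    return red, green


def label_occupancies_mc(model: KineticModel, layout: GeneLayout, n: int,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-transcript time-integrated red/green intensities (MC draws).

    Each cassette contributes a half-weight ramp during its own transcription
    and full weight from cassette completion to its drop event.
    """
    from .trace_simulator import sample_event_arrays  # local import, no cycle
    ev = sample_event_arrays(model, layout, np.zeros(n), rng)
    red = (ev["t_pp7_end"] - ev["t_pp7_start"]) / 2 + (
        ev["t_red_drop"] - ev["t_pp7_end"])
    green = (ev["t_ms2_end"] - ev["t_ms2_start"]) / 2 + (
        ev["t_green_drop"] - ev["t_ms2_end"])
    return red, green


def expected_label_ratio(model: KineticModel, layout: GeneLayout,
                         n_mc: int = 200_000,
                         rng: Optional[np.random.Generator] = None,
                         return_se: bool = False):
    """Expected red-to-green ratio of time-integrated label per transcript.

    By Little's law this equals the steady-state ratio of red- to
    green-labeled RNA equivalents at the transcription site.  Model II.4 has
    a closed form; other variants use Monte Carlo.
    """
    _check_nonneg(model)
    if model.variant == "II.4":
        red, green = _occupancy_closed_form_II4(model, layout)
        if green <= 0:
            raise ValueError("green occupancy expectation is 0")
        ratio, se = red / green, 0.0
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        red, green = label_occupancies_mc(model, layout, n_mc, rng)
        mg = green.mean()
        if mg <= 0:
            raise ValueError("green occupancy expectation is 0")
        ratio = float(red.mean() / mg)
        # delta-method SE of a ratio of correlated means
        cov = np.cov(red, green) / n_mc
        g = np.array([1.0 / mg, -red.mean() / mg ** 2])
        se = float(np.sqrt(g @ cov @ g))
    if return_se:
        return ratio, se
    return ratio


def derived_quantities(model: KineticModel, layout: GeneLayout,
                       n_mc: int = 200_000,
                       rng: Optional[np.random.Generator] = None) -> DerivedQuantities:
    frac, fse = pre_release_fraction(model, layout, n_mc, rng, return_se=True)
    ratio, rse = expected_label_ratio(model, layout, n_mc, rng, return_se=True)
    return DerivedQuantities(frac, ratio,
                             elongation_time(layout.ss3, layout.polyA, model.v),
                             fse, rse)
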