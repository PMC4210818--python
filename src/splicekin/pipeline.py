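"""Pipeline orchestration: staged runs writing versioned plain-text
artifacts plus a manifest, and deterministic fixture generation."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import io as skio
from .config import RunConfig, dump_config
from .correlation import average_correlations, correlate_trace, photobleach_correct
from .inference import compare_models, slope_prerelease
from .kinetic_models import exponential, make_model
from .model_curves import slope_change_at_zero
from .spatial import (fit_enrichment, pair_colocalized,
                      post_release_splice_time, radial_profile)
from .trace_simulator import (NoiseSpec, circle_polygon, simulate_dataset,
                              simulate_particle_field)

__all__ = ["run_pipeline", "generate_fixtures", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "correlate", "fit", "slope", "simulate-particles",
          "spatial")

_STAGE_SEED_OFFSET = {name: i for i, name in enumerate(STAGES)}


def _stage_seed(base_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([base_seed, _STAGE_SEED_OFFSET[stage]])
    return int(ss.generate_state(1)[0])


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}, which does not exist in "
            f"{path.parent}; run the '{produced_by}' stage first")
    return path


def _load_traces(out: Path, stage: str):
    paths = sorted(out.glob("trace_*.tsv"))
    if not paths:
        raise FileNotFoundError(
            f"stage '{stage}' needs trace_*.tsv files in {out}; run the "
            f"'simulate' stage first")
    return [skio.read_trace_tsv(p) for p in paths]


def run_pipeline(cfg: RunConfig, stages: Sequence[str],
                 out_dir: Union[str, Path]) -> Path:
    """Execute the requested stages in order, writing artifacts and a
    manifest into ``out_dir``.  Re-running with the same config and seed
    reproduces the outputs exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")

    written: list[str] = []
    seeds = {stage: _stage_seed(cfg.seed, stage) for stage in stages}

    for stage in stages:
        logger.info("running stage %s", stage)
        if stage == "simulate":
            noise = NoiseSpec(additive_sd=cfg.acquisition.additive_sd,
                              photobleach_halflife=cfg.acquisition.photobleach_halflife,
                              background_offset=cfg.acquisition.background_offset)
            traces = simulate_dataset(
                cfg.model, cfg.layout, cfg.acquisition.n_traces,
                cfg.acquisition.duration, cfg.acquisition.dt, noise,
                rng_seed=seeds[stage])
            for i, tr in enumerate(traces):
                name = f"trace_{i:03d}.tsv"
                skio.write_trace_tsv(tr, out / name)
                written.append(name)

        elif stage == "correlate":
            traces = _load_traces(out, stage)
            corrected = [photobleach_correct(
                t, cfg.correlation.photobleach_poly_order) for t in traces]
            sets = [correlate_trace(t, m=cfg.correlation.block_size)
                    for t in corrected]
            avg = average_correlations(
                sets, n_boot=cfg.correlation.n_boot,
                baseline_window=cfg.correlation.baseline_window,
                normalize=cfg.correlation.normalize, rng_seed=seeds[stage])
            skio.write_correlation_json(avg, out / "correlation.json")
            skio.write_correlation_tsv(avg, out / "correlation.tsv")
            written += ["correlation.json", "correlation.tsv"]

        elif stage == "fit":
            path = _require(out / "correlation.json", stage, "correlate")
            data = skio.read_correlation_json(path)
            results = compare_models(
                data, cfg.fit.variants, cfg.layout,
                max_delay=cfg.fit.max_delay, n_draws=cfg.fit.n_draws,
                max_starts=cfg.fit.max_starts)
            best = results[0]
            skio.write_json(skio.fit_result_to_dict(best), out / "fit.json")
            lines = ["variant\tbic\tdelta_bic\trss\tk_params\tparams"]
            for r in results:
                params = ";".join(f"{k}={v:.6g}"
                                  for k, v in r.model.param_values().items())
                lines.append(f"{r.variant}\t{r.bic:.6g}\t"
                             f"{r.bic - best.bic:.6g}\t{r.rss:.6g}\t"
                             f"{r.k_params}\t{params}")
            (out / "comparison.tsv").write_text("\n".join(lines) + "\n")
            written += ["fit.json", "comparison.tsv"]

        elif stage == "slope":
            traces = _load_traces(out, stage)
            corrected = [photobleach_correct(
                t, cfg.correlation.photobleach_poly_order) for t in traces]
            sets = [correlate_trace(t, m=cfg.correlation.block_size)
                    for t in corrected]
            est = slope_prerelease(
                sets, n_boot=cfg.fit.n_boot, window=cfg.fit.slope_window,
                baseline_window=cfg.correlation.baseline_window,
                rng_seed=seeds[stage])
            skio.write_json({
                "fraction": est.fraction, "se": est.se,
                "slope_pos": est.slope_pos, "slope_neg": est.slope_neg,
                "slope_pos_se": est.slope_pos_se,
                "slope_neg_se": est.slope_neg_se,
                "diagnostic": est.diagnostic}, out / "slope.json")
            written.append("slope.json")

        elif stage == "simulate-particles":
            sp = cfg.spatial
            nucleus = circle_polygon(sp.nucleus_radius)
            field = simulate_particle_field(
                sp.D, exponential(sp.splice_lifetime_mean), sp.emission_rate,
                nucleus, sp.n_frames, sp.frame_interval,
                rng_seed=seeds[stage])
            skio.write_particles_csv(field, out / "particles.csv",
                                     out / "ts_track.csv", out / "nucleus.csv")
            written += ["particles.csv", "ts_track.csv", "nucleus.csv"]

        elif stage == "spatial":
            sp = cfg.spatial
            particles = skio.read_particles_csv(
                _require(out / "particles.csv", stage, "simulate-particles"))
            ts_track = skio.read_ts_track_csv(
                _require(out / "ts_track.csv", stage, "simulate-particles"))
            nucleus = skio.read_nucleus_csv(
                _require(out / "nucleus.csv", stage, "simulate-particles"))
            result = spatial_analysis(particles, ts_track, nucleus, sp,
                                      rng_seed=seeds[stage])
            skio.write_json(result["summary"], out / "spatial.json")
            prof = result["profile"]
            lines = ["r_lo_um\tr_hi_um\tdensity_ratio\tsem"]
            for lo, hi, v, s in zip(prof.bin_edges[:-1], prof.bin_edges[1:],
                                    prof.density_ratio,
                                    prof.sem if prof.sem is not None
                                    else np.full(len(prof.density_ratio), np.nan)):
                lines.append(f"{lo:.6g}\t{hi:.6g}\t{v:.6g}\t{s:.6g}")
            (out / "radial_profile.tsv").write_text("\n".join(lines) + "\n")
            written += ["spatial.json", "radial_profile.tsv"]

    dump_config(cfg, out / "config.yaml")
    manifest = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                "stage_seeds": seeds, "stages": list(stages),
                "files": sorted(set(written))}
    skio.write_json(manifest, out / "manifest.json")
    return out


def spatial_analysis(particles, ts_track, nucleus, sp, rng_seed=0) -> dict:
    """Pair spots per frame, build the pre-mRNA radial profile and the
    Gaussian enrichment fit, and convert sigma to a splicing time."""
    coloc_xy, green_only_xy = [], []
    ts_by_frame = {int(r.frame): (r.x_um, r.y_um)
                   for r in ts_track.itertuples()}
    for frame, group in particles.groupby("frame"):
        red = group[group.channel == "red"][["x_um", "y_um"]].to_numpy()
        green = group[group.channel == "green"][["x_um", "y_um"]].to_numpy()
        paired = pair_colocalized(red, green, sp.pair_radius)
        if paired.n_colocalized:
            coloc_xy.append(paired.colocalized.mean(axis=1))
        if len(paired.green_only):
            green_only_xy.append(paired.green_only)
    coloc = np.concatenate(coloc_xy) if coloc_xy else np.zeros((0, 2))
    mrna = np.concatenate(green_only_xy) if green_only_xy else np.zeros((0, 2))
    ts = np.array([np.mean([v[0] for v in ts_by_frame.values()]),
                   np.mean([v[1] for v in ts_by_frame.values()])])
    bins = np.arange(0.0, sp.bins_max_um + sp.bin_width_um, sp.bin_width_um)
    null = mrna if sp.mode == "fish" else None
    profile = radial_profile(coloc, ts, nucleus, n_null=sp.n_null, bins=bins,
                             null_particles=null, rng_seed=rng_seed)
    summary = {"n_colocalized": int(len(coloc)), "n_green_only": int(len(mrna)),
               "mode": sp.mode}
    try:
        enr = fit_enrichment(profile, exclusion_um=sp.exclusion_um)
        summary.update({
            "sigma_um": enr.sigma, "sigma_se": enr.sigma_se,
            "height": enr.height, "baseline": enr.baseline,
            "identifiable": enr.identifiable,
            "post_release_splice_time_s":
                post_release_splice_time(enr.sigma, sp.D)
                if enr.identifiable else None,
        })
    except (ValueError, RuntimeError) as exc:
        summary["enrichment_error"] = str(exc)
    denom = len(coloc) + len(mrna)
    if denom:
        summary["premrna_fraction"] = len(coloc) / denom
    return {"summary": summary, "profile": profile}


#: representative variant per scheme used for the packaged fixtures
_FIXTURE_MODELS = {
    "I": make_model("I.3", v=2.6, release_mean=116.1, k_init=0.03),
    "II": make_model("II.4", v=2.6, splice_mean=267.0, release_mean=116.1,
                     k_init=0.03),
    "III": make_model("III.1", v=2.6, splice_mean=150.0, k_init=0.03),
    "IV": make_model("IV.2", v=2.6, splice_mean=60.0, release_mean=116.1,
                     k_init=0.03),
    "V": make_model("V.2", v=2.6, splice_mean=150.0, release_mean=116.1,
                    k_init=0.03),
}


def generate_fixtures(seed: int, out_dir: Union[str, Path],
                      n_traces: int = 3, n_frames: int = 200) -> Path:
    """Small deterministic datasets used by the test suite: a few traces per
    scheme and one particle field per diffusion regime."""
    from .config import RunConfig  # layout default
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = RunConfig().layout
    for k, (scheme, model) in enumerate(_FIXTURE_MODELS.items()):
        traces = simulate_dataset(model, layout, n_traces,
                                  duration=n_frames * 10.0, dt=10.0,
                                  noise=NoiseSpec(additive_sd=0.1),
                                  rng_seed=_stage_seed(seed, "simulate") + k)
        for i, tr in enumerate(traces):
            skio.write_trace_tsv(tr, out / f"scheme_{scheme}_trace_{i}.tsv")
    nucleus = circle_polygon(8.0)
    for name, lifetime in (("control", 12.7), ("slow", 60.0)):
        field = simulate_particle_field(
            0.12, exponential(lifetime), emission_rate=0.2, nucleus=nucleus,
            n_frames=50, frame_interval=3.26,
            rng_seed=_stage_seed(seed, "simulate-particles"))
        skio.write_particles_csv(field, out / f"particles_{name}.csv",
                                 out / f"ts_track_{name}.csv",
                                 out / f"nucleus_{name}.csv")
    return out
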