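"""Plain-text readers and writers for traces, correlation sets, particle
fields and fit results.  All schemas are documented in FORMATS.md."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .correlation import CorrelationCurve, CorrelationSet
from .trace_simulator import DualColorTrace, ParticleField

__all__ = [
    "write_trace_tsv", "read_trace_tsv",
    "write_correlation_json", "read_correlation_json",
    "write_correlation_tsv",
    "write_particles_csv", "read_particles_csv",
    "write_nucleus_csv", "read_nucleus_csv",
    "write_ts_track_csv", "read_ts_track_csv",
    "fit_result_to_dict", "write_json",
]

_FLOAT_FMT = "%.12g"


def write_trace_tsv(trace: DualColorTrace, path: Union[str, Path]) -> None:
    cols = {"time_s": trace.t, "red": trace.red, "green": trace.green}
    if trace.nucleus_sd is not None:
        cols["nucleus_sd"] = trace.nucleus_sd
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format=_FLOAT_FMT)


def read_trace_tsv(path: Union[str, Path]) -> DualColorTrace:
    df = pd.read_csv(path, sep="\t")
    return DualColorTrace(
        t=df["time_s"].to_numpy(), red=df["red"].to_numpy(),
        green=df["green"].to_numpy(),
        nucleus_sd=df["nucleus_sd"].to_numpy() if "nucleus_sd" in df else None)


def _curve_to_dict(c: CorrelationCurve) -> dict:
    d = {"delays": c.delays.tolist(), "values": c.values.tolist(),
         "weights": c.weights.tolist()}
    if c.sem is not None:
        d["sem"] = np.asarray(c.sem).tolist()
    return d


def _curve_from_dict(d: dict) -> CorrelationCurve:
    return CorrelationCurve(np.array(d["delays"]), np.array(d["values"]),
                            np.array(d["weights"]),
                            np.array(d["sem"]) if "sem" in d else None)


def write_correlation_json(cs: CorrelationSet, path: Union[str, Path]) -> None:
    payload = {name: _curve_to_dict(curve) for name, curve in cs.curves().items()}
    payload["norm_constant"] = cs.norm_constant
    Path(path).write_text(json.dumps(payload, indent=1))


def read_correlation_json(path: Union[str, Path]) -> CorrelationSet:
    d = json.loads(Path(path).read_text())
    return CorrelationSet(norm_constant=d.get("norm_constant", float("nan")),
                          **{k: _curve_from_dict(d[k])
                             for k in ("Grr", "Ggg", "Grg", "Ggr")})


def write_correlation_tsv(cs: CorrelationSet, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"delay_s": cs.Grr.delays,
                       "grr": cs.Grr.values, "ggg": cs.Ggg.values,
                       "grg": cs.Grg.values, "ggr": cs.Ggr.values})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_prediction_json(pred, path: Union[str, Path]) -> None:
    """Model-curve predictions in the CorrelationSet JSON schema, tagged
    with the generating model."""
    payload = {}
    for name, values in pred.curves().items():
        d = {"delays": pred.delays.tolist(), "values": values.tolist(),
             "weights": np.ones(len(pred.delays)).tolist()}
        if pred.mc_se is not None:
            d["sem"] = pred.mc_se[name].tolist()
        payload[name] = d
    payload["norm_constant"] = pred.norm_constant
    payload["model"] = pred.model.to_dict()
    payload["eval_method"] = pred.eval_method
    Path(path).write_text(json.dumps(payload, indent=1))


def write_particles_csv(field: ParticleField, particles_path, ts_path=None,
                        nucleus_path=None) -> None:
    field.particles.to_csv(particles_path, index=False,
                           float_format=_FLOAT_FMT)
    if ts_path is not None:
        field.ts_track.to_csv(ts_path, index=False, float_format=_FLOAT_FMT)
    if nucleus_path is not None:
        write_nucleus_csv(field.nucleus, nucleus_path)


def read_particles_csv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_nucleus_csv(vertices: np.ndarray, path: Union[str, Path]) -> None:
    pd.DataFrame(np.asarray(vertices), columns=["x_um", "y_um"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_nucleus_csv(path: Union[str, Path]) -> np.ndarray:
    return pd.read_csv(path)[["x_um", "y_um"]].to_numpy()


def write_ts_track_csv(ts_track: pd.DataFrame, path: Union[str, Path]) -> None:
    ts_track.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_ts_track_csv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def fit_result_to_dict(fit) -> dict:
    return {
        "variant": fit.model.variant,
        "params": {k: float(v) for k, v in fit.model.param_values().items()},
        "se": {k: float(v) for k, v in fit.se.items()},
        "rss": fit.rss, "n_points": fit.n_points,
        "k_params": fit.k_params, "bic": fit.bic,
        "success": fit.success, "message": fit.message,
        "at_bound": list(fit.at_bound),
        "derived": {
            "pre_release_fraction": fit.derived.pre_release_fraction,
            "pre_release_fraction_se": fit.derived.pre_release_fraction_se,
            "label_ratio": fit.derived.label_ratio,
            "label_ratio_se": fit.derived.label_ratio_se,
            "t_elong_3ss_to_end": fit.derived.t_elong_3ss_to_end,
        },
    }


def write_json(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
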