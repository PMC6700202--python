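"""Named pipeline stages dispatched by :func:`mitoloc.io.run_pipeline`.

Each stage is a function ``stage(context, stage_index, **params)``; the
context dict carries the shared seed, the output directory and the in-memory
outputs of earlier stages (so a simulate stage can feed an analyze stage
without touching disk, while everything is still written out for audit).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict

import numpy as np
import pandas as pd

from . import synthetic
from .core import PipelineError
from .ibm_index import (IBMIndexParams, compute_templates,
                        ibm_association_index, ibm_index_timecourse)
from .io import (config_to_dataclass, read_image, write_image, write_trace,
                 write_paths_csv, _jsonable)
from .morphometrics import area_weighted_ff, particle_descriptors, yen_threshold
from .profiles import axis_cross_sections, fit_double_gaussian, interlabel_distance
from .tem import cj_width_curve, sample_orthogonal_profiles, width_from_profile
from .trace_kinetics import max_slope
from .preprocess import bleach_correct_exponential


def _out(context: Dict[str, Any], stage_index: int, name: str) -> Path:
    return Path(context["out_dir"]) / f"stage{stage_index:02d}_{name}"


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_sim_pair(context, stage_index, **params):
    cfg = config_to_dataclass(synthetic.SIMPhantomConfig, params)
    ch_a, ch_b, gt = synthetic.generate_sim_pair(cfg, context["seed"])
    write_image(_out(context, stage_index, "chA.tif"), ch_a)
    write_image(_out(context, stage_index, "chB.tif"), ch_b)
    _write_json(_out(context, stage_index, "ground_truth.json"), gt)
    context["sim_pair"] = (ch_a, ch_b, gt)
    return gt


def simulate_tem(context, stage_index, **params):
    preset = params.pop("preset", None)
    if preset and preset != "custom":
        cfg = synthetic.TEMPhantomConfig.from_preset(preset, **params)
    else:
        cfg = config_to_dataclass(synthetic.TEMPhantomConfig, params)
    img, path, gt = synthetic.generate_tem_cristae(cfg, context["seed"])
    write_image(_out(context, stage_index, "tem.tif"), img)
    write_paths_csv(_out(context, stage_index, "centerline.csv"), [path])
    _write_json(_out(context, stage_index, "ground_truth.json"),
                dict(d_nm=gt.profile.d_nm, w_nm=gt.profile.w_nm,
                     unresolvable=gt.unresolvable, config=gt.config))
    context["tem"] = (img, path, gt)
    return gt


def simulate_beads(context, stage_index, **params):
    cfg = config_to_dataclass(synthetic.BeadFieldConfig, params)
    st_a, st_b, gt = synthetic.generate_bead_field(cfg, context["seed"])
    write_image(_out(context, stage_index, "beads_chA.tif"), st_a)
    write_image(_out(context, stage_index, "beads_chB.tif"), st_b)
    _write_json(_out(context, stage_index, "ground_truth.json"),
                dict(coords_a_px=gt.coords_a_px, coords_b_px=gt.coords_b_px))
    context["beads"] = (st_a, st_b, gt)
    return gt


def simulate_trace(context, stage_index, **params):
    cfg = config_to_dataclass(synthetic.TracePhantomConfig, params)
    trace, gt = synthetic.generate_trace(cfg, context["seed"])
    write_trace(_out(context, stage_index, "trace.csv"), trace)
    _write_json(_out(context, stage_index, "ground_truth.json"),
                dict(tau_s=gt.tau_s, onset_s=gt.onset_s,
                     max_slope_pct_per_s=gt.max_slope_pct_per_s,
                     t_at_max_slope_s=gt.t_at_max_slope_s))
    context["trace"] = (trace, gt)
    return gt


def _resolve_pair(context, params, key):
    if "object" in params and "reference" in params:
        nmpp = params.get("nm_per_px")
        return (read_image(params["object"], nmpp),
                read_image(params["reference"], nmpp))
    if key in context:
        ch_a, ch_b, _ = context[key]
        return ch_b, ch_a   # object = inner-shell channel, reference = outer
    raise PipelineError(f"stage needs 'object'/'reference' paths or a prior "
                        f"simulate stage providing '{key}'")


def ibm_index_stage(context, stage_index, **params):
    obj, ref = _resolve_pair(context, params, "sim_pair")
    for k in ("object", "reference", "nm_per_px"):
        params.pop(k, None)
    ibm_params = config_to_dataclass(IBMIndexParams, params)
    if hasattr(obj, "frames"):  # stacks -> time course
        df = ibm_index_timecourse(obj, ref, ibm_params)
        df.to_csv(_out(context, stage_index, "ibm_index_timecourse.csv"),
                  index=False)
        return df
    tpl = compute_templates(ref, ibm_params)
    res = ibm_association_index(obj, tpl, ibm_params)
    _write_json(_out(context, stage_index, "ibm_index.json"), res)
    return res


def distance_stage(context, stage_index, n_profiles: int = 7,
                   half_extent_nm: float = 400.0, rss_gate: float = 0.2,
                   **params):
    if "sim_pair" not in context:
        raise PipelineError("distance stage requires a prior simulate_sim_pair")
    ch_a, ch_b, gt = context["sim_pair"]
    prof_a = axis_cross_sections(ch_a, gt.tube_axis_px, n_profiles, half_extent_nm)
    prof_b = axis_cross_sections(ch_b, gt.tube_axis_px, n_profiles, half_extent_nm)
    fits_a = [fit_double_gaussian(p) for p in prof_a]
    fits_b = [fit_double_gaussian(p) for p in prof_b]
    dist = interlabel_distance(fits_a, fits_b, rss_gate=rss_gate)
    rows = [dict(profile_id=i,
                 d_a_nm=fa.peak_distance_nm, d_b_nm=fb.peak_distance_nm,
                 converged_a=fa.converged, converged_b=fb.converged)
            for i, (fa, fb) in enumerate(zip(fits_a, fits_b))]
    pd.DataFrame(rows).to_csv(_out(context, stage_index, "distance.csv"),
                              index=False)
    _write_json(_out(context, stage_index, "distance_summary.json"),
                dict(mean_nm=dist.mean_nm, sd_nm=dist.sd_nm, n=dist.n,
                     n_rejected=dist.n_rejected))
    return dist


def cj_width_stage(context, stage_index, **params):
    if "tem" not in context:
        raise PipelineError("cj_width stage requires a prior simulate_tem")
    img, path, _ = context["tem"]
    profiles = sample_orthogonal_profiles(img, path, **params)
    widths = [width_from_profile(p) for p in profiles]
    curve = cj_width_curve([widths])
    pd.DataFrame(dict(d_nm=curve.d_nm, w_nm=curve.w_nm)).to_csv(
        _out(context, stage_index, "cj_width.csv"), index=False)
    return curve


def morphology_stage(context, stage_index, **params):
    if "image" in params:
        img = read_image(params.pop("image"), params.pop("nm_per_px", None))
    elif "sim_pair" in context:
        img = context["sim_pair"][0]
    else:
        raise PipelineError("morphology stage needs an 'image' path or a "
                            "prior simulate_sim_pair")
    mask = yen_threshold(img)
    stats = particle_descriptors(mask, img.nm_per_px, **params)
    stats.table.to_csv(_out(context, stage_index, "particles.csv"), index=False)
    _write_json(_out(context, stage_index, "morphology_summary.json"),
                dict(count=stats.count,
                     area_weighted_ff=area_weighted_ff(stats)))
    return stats


def trace_kinetics_stage(context, stage_index, bleach_correct: bool = True,
                         slope_window_pts: int = 5, **params):
    if "trace" not in context:
        raise PipelineError("trace_kinetics stage requires a prior simulate_trace")
    trace, _ = context["trace"]
    if bleach_correct:
        trace = bleach_correct_exponential(trace).trace
    slope, t_at = max_slope(trace, slope_window_pts=slope_window_pts)
    result = dict(max_slope_pct_per_s=slope, t_max_slope_s=t_at)
    _write_json(_out(context, stage_index, "kinetics.json"), result)
    return result


STAGES = {
    "simulate_sim_pair": simulate_sim_pair,
    "simulate_tem": simulate_tem,
    "simulate_beads": simulate_beads,
    "simulate_trace": simulate_trace,
    "ibm_index": ibm_index_stage,
    "distance": distance_stage,
    "cj_width": cj_width_stage,
    "morphology": morphology_stage,
    "trace_kinetics": trace_kinetics_stage,
}
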