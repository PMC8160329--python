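"""Configuration-driven orchestration of the analysis stages.

A single :class:`RunConfig` (built in code or loaded from YAML) drives
synthetic-data generation and every analysis stage; all randomness flows
from one root seed and every output directory carries a provenance record
(package version, seed, config hash) so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger("oxyflow")

ALL_STAGES = ("linescan", "movie", "volume", "hemo", "oxygen")


@dataclass
class RunConfig:
    """What to run, where to write, and the parameters of each stage."""

    outdir: str = "oxyflow_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    linescan: dict = field(default_factory=dict)  # LineScanTruth overrides
    movie: dict = field(default_factory=dict)  # MovieTruth overrides
    volume: dict = field(default_factory=dict)  # NetworkTruth overrides
    hemo: dict = field(default_factory=dict)  # HemoTruth overrides
    oxygen: dict = field(default_factory=dict)  # OxygenModelSpec fields
    inputs: dict = field(default_factory=dict)  # stage → existing file path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for stage, p in cfg.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input for stage {stage!r} not found: {p}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_linescan(cfg: RunConfig, outdir: Path) -> dict:
    from . import io, linescan, synth

    if "linescan" in cfg.inputs:
        kym = io.load_image(cfg.inputs["linescan"])
    else:
        truth = synth.LineScanTruth(seed=cfg.seed, **cfg.linescan)
        kym = synth.make_linescan(truth)
        io.save_kymograph(outdir / "linescan.tif", kym)
    vel = linescan.estimate_velocity(kym)
    flux = linescan.count_flux(kym)
    hct = linescan.estimate_hematocrit(kym)
    diam = linescan.diameter_from_linescan(kym)
    vel.to_frame().to_csv(outdir / "linescan_velocity.csv", index=False)
    flux.to_frame().to_csv(outdir / "linescan_flux.csv", index=False)
    hct.to_frame().to_csv(outdir / "linescan_hematocrit.csv", index=False)
    np.savetxt(outdir / "linescan_diameter.csv",
               np.column_stack([diam.t, diam.values]), delimiter=",",
               header="t,diameter_um", comments="")
    return {
        "velocity_um_s": float(np.nanmean(vel.good_values())),
        "flux_rbc_s": float(np.nanmean(flux.good_values())),
        "hematocrit": float(np.nanmean(hct.good_values())),
        "diameter_um": float(np.nanmean(diam.values)),
    }


def _stage_movie(cfg: RunConfig, outdir: Path) -> dict:
    from . import io, nvc, synth, vesselgeom
    from .traces import FluorescenceTrace

    if "movie" in cfg.inputs:
        movie = io.load_image(cfg.inputs["movie"])
        roi_traces = None
    else:
        truth = synth.MovieTruth(seed=cfg.seed, **cfg.movie)
        movie, roi_traces, _ = synth.make_movie(truth)
        io.save_movie(outdir / "movie.tif", movie)
    diam = vesselgeom.frame_diameter_trace(movie)
    out = {"diameter_um": float(np.nanmean(diam.values))}
    if roi_traces is not None:
        net = FluorescenceTrace(values=roi_traces.mean(axis=1).to_numpy(),
                                frame_rate=movie.frame_rate, roi_id="net")
        try:
            events = nvc.detect_calcium_events(net)
        except ValueError:
            events = []
        records = []
        for ev in events:
            i0 = int(round((ev.peak_time - ev.pre_s) * diam.rate))
            i1 = int(round((ev.peak_time + ev.post_s) * diam.rate))
            if i0 < 0 or i1 >= diam.values.size:
                continue
            rec = nvc.classify_response(diam.values[i0:i1 + 1], diam.rate,
                                        calcium_peak=ev.peak_dff)
            records.append({"peak_time": ev.peak_time, "peak_dff": ev.peak_dff,
                            "responsive": bool(rec.responsive),
                            "nvc_index": rec.nvc_index})
        with open(outdir / "movie_events.json", "w") as fh:
            json.dump(records, fh, indent=1)
        out["n_events"] = len(records)
    return out


def _stage_volume(cfg: RunConfig, outdir: Path) -> dict:
    from . import io, synth, vesselgeom

    if "volume" in cfg.inputs:
        vol = io.load_image(cfg.inputs["volume"])
    else:
        truth = synth.NetworkTruth(seed=cfg.seed, **cfg.volume)
        vol, _ = synth.make_volume(truth)
        io.save_volume(outdir / "volume.tif", vol)
    skel = vesselgeom.skeletonize_volume(vol)
    dens = vesselgeom.capillary_density(skel)
    prof = vesselgeom.diameter_depth_profile(skel)
    prof.to_csv(outdir / "diameter_by_depth.csv", index=False)
    side = min(100.0, min(vol.extent) / 3)
    dist = vesselgeom.tissue_distance_distribution(vol, substack_um=side,
                                                   n_substacks=2, seed=cfg.seed)
    with open(outdir / "distance_centiles.json", "w") as fh:
        json.dump({str(k): v for k, v in dist.centiles.items()}, fh, indent=1)
    return {"density_m_mm3": dens,
            "median_distance_um": dist.centiles[50]}


def _stage_hemo(cfg: RunConfig, outdir: Path) -> dict:
    from . import hemo, io, synth

    if "hemo" in cfg.inputs:
        trace = io.load_hemo(cfg.inputs["hemo"])
    else:
        params = dict(cfg.hemo)
        dur = params.get("duration", 120.0)
        params.setdefault("cmro2_event_times",
                          tuple(dur * f for f in (0.25, 0.5, 0.75)))
        params.setdefault("noise_sd", 0.01)
        truth = synth.HemoTruth(seed=cfg.seed, **params)
        trace = synth.make_hemo(truth)
        io.save_hemo(outdir / "hemo.csv", trace)
    hemo.derive_channels(trace)
    rest = hemo.segment_rest(trace)
    summary = hemo.baseline_summary([trace], [rest])
    summary.to_csv(outdir / "hemo_baselines.csv")
    try:
        events = hemo.detect_metabolic_events(trace)
    except ValueError:  # e.g. a featureless session
        events = []
    with open(outdir / "hemo_events.json", "w") as fh:
        json.dump([{"peak_time": e.peak_time, "cmro2_peak": e.cmro2_peak,
                    "hbt_peak": e.hbt_peak, "nvc_index": e.nvc_index}
                   for e in events], fh, indent=1)
    return {"rest_fraction": float(rest.mean()), "n_events": len(events)}


def _stage_oxygen(cfg: RunConfig, outdir: Path) -> dict:
    from . import oxymodel

    params = {"c_cap": 14.0, "r_max": 14.4, "vmax_mm_min": 2.0}
    params.update(cfg.oxygen)
    spec = oxymodel.OxygenModelSpec(**params)
    prof = oxymodel.steady_profile(spec)
    np.savetxt(outdir / "oxygen_profile.csv",
               np.column_stack([prof.r, prof.c, prof.vo2_frac]), delimiter=",",
               header="r_um,c_uM,vo2_frac", comments="")
    return {"midpoint_c_uM": prof.midpoint_c,
            "midpoint_vo2_frac": prof.midpoint_vo2_frac}


_STAGE_FNS = {
    "linescan": _stage_linescan,
    "movie": _stage_movie,
    "volume": _stage_volume,
    "hemo": _stage_hemo,
    "oxygen": _stage_oxygen,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns a summary bundle.

    Each stage writes its tables next to a ``provenance.json`` recording
    the package version, seed and config hash.  A failing stage is logged
    and recorded in the bundle; completed results are preserved.
    """
    from . import __version__

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
              "version": __version__, "stages": {}}
    unknown = set(cfg.stages) - set(_STAGE_FNS)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for stage in cfg.stages:
        try:
            bundle["stages"][stage] = _STAGE_FNS[stage](cfg, outdir)
        except Exception as exc:  # preserve partial results
            log.exception("stage %s failed", stage)
            bundle["stages"][stage] = {"error": str(exc)}
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(bundle, fh, indent=1, default=str)
    return bundle
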