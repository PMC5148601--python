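"""End-to-end orchestration: simulate -> analyze -> report.

A run is fully reproducible from its configuration and seeds.  The
configuration is YAML-serializable; ``run_simulate`` writes event tables,
stimulus descriptions, and ground truth to a directory, and
``run_analysis`` executes every applicable stage per stimulus class,
isolating per-unit failures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._util import child_seeds
from . import io as ebio
from .stimuli import generate_fra_protocol, generate_rgs, synthesize_modulated
from .simulate import UnitConfig, InhibitionConfig, Silence, simulate_unit
from .events import fit_threshold_epsp, failure_fraction
from .tuning import build_fra, estimate_cf_threshold, q_values, rate_level
from .temporal import (build_psth, sparsity, vector_strength, corr_norm,
                       raised_sine_envelope, shuffled_autocorrelogram,
                       reproducibility, temporal_dispersion, modulation_depth,
                       trains_from_events)
from .removal import compare_transformations

log = logging.getLogger("endbulb")

DEFAULTS = {
    "n_units": 1,
    "seed": 0,
    "spont_duration_s": 10.0,
    "fra": {"enabled": True, "freq_lo_factor": 0.25, "freq_hi_factor": 4.0,
            "level_lo": 0.0, "level_hi": 90.0, "repetitions": 5},
    "sam": {"enabled": True, "mod_freqs_hz": [50, 100, 200, 400],
            "duration_s": 0.2, "n_trials": 50, "level_db": 50.0},
    "rgs": {"enabled": True, "duration_s": 30.0, "iei_tau_s": 0.010,
            "n_trials": 20, "level_db": 60.0},
    "removal": {"enabled": True, "psth_bin_s": 0.010},
    "metrics": {"psth_bin_s": 0.010, "csi_threshold_hz": 15.0,
                "fdr_q": 0.01, "preact_tau_s": 0.060},
    "unit": {},           # overrides for UnitConfig fields
    "inhibition": {},     # overrides for InhibitionConfig fields
}


def default_config() -> dict:
    return json.loads(json.dumps(DEFAULTS))


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for k, v in user.items():
        if k not in cfg:
            raise ValueError(f"unknown config key {k!r}")
        if isinstance(cfg[k], dict) and isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _unit_config(cfg: dict, unit_seed: int) -> UnitConfig:
    inh = InhibitionConfig(**cfg.get("inhibition", {}))
    fields = dict(cfg.get("unit", {}))
    fields["inhibition"] = inh
    fields["seed"] = unit_seed
    return UnitConfig(**fields)


def run_simulate(cfg: dict, out_dir, force: bool = False) -> Path:
    """Simulate the configured units against all enabled stimulus classes.

    Writes, per unit, TSV event tables per condition, stimulus JSON, the
    unit config, and ground-truth summaries.  Refuses to write into an
    existing non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    unit_seeds = child_seeds(cfg["seed"], cfg["n_units"])
    for u, u_seed in enumerate(unit_seeds):
        t0 = time.time()
        udir = out / f"unit{u:02d}"
        udir.mkdir(exist_ok=True)
        config = _unit_config(cfg, int(u_seed))
        (udir / "unit_config.json").write_text(config.to_json())
        stage_seeds = child_seeds(int(u_seed), 8)

        ev, truth = simulate_unit(config, Silence(cfg["spont_duration_s"]),
                                  n_trials=1, seed=int(stage_seeds[0]),
                                  condition="spont")
        ebio.write_events_tsv(ev, udir / "events_spont.tsv", f"unit{u:02d}")

        if cfg["fra"]["enabled"]:
            fra_cfg = cfg["fra"]
            protocol = generate_fra_protocol(
                config.cf * fra_cfg["freq_lo_factor"],
                config.cf * fra_cfg["freq_hi_factor"],
                fra_cfg["level_lo"], fra_cfg["level_hi"],
                repetitions=fra_cfg["repetitions"], seed=int(stage_seeds[1]))
            (udir / "fra_protocol.json").write_text(protocol.to_json())
            ev, _ = simulate_unit(config, protocol, seed=int(stage_seeds[2]),
                                  condition="fra")
            ebio.write_events_tsv(ev, udir / "events_fra.tsv", f"unit{u:02d}")

        if cfg["sam"]["enabled"]:
            sam_cfg = cfg["sam"]
            frames = []
            for fm in sam_cfg["mod_freqs_hz"]:
                stim = synthesize_modulated("AM", config.cf, fm,
                                            sam_cfg["duration_s"])
                ev, _ = simulate_unit(config, stim,
                                      n_trials=sam_cfg["n_trials"],
                                      seed=int(stage_seeds[3]) + int(fm),
                                      level_db=sam_cfg["level_db"],
                                      condition=f"sam{fm}")
                frames.append(ev)
            ebio.write_events_tsv(pd.concat(frames, ignore_index=True),
                                  udir / "events_sam.tsv", f"unit{u:02d}")

        if cfg["rgs"]["enabled"]:
            rgs_cfg = cfg["rgs"]
            rgs = generate_rgs(config.cf, rgs_cfg["duration_s"],
                               rgs_cfg["iei_tau_s"], seed=int(stage_seeds[4]),
                               level=rgs_cfg["level_db"])
            (udir / "rgs_stimulus.json").write_text(rgs.to_json())
            ev, truth = simulate_unit(config, rgs,
                                      n_trials=rgs_cfg["n_trials"],
                                      seed=int(stage_seeds[5]),
                                      level_db=rgs_cfg["level_db"],
                                      condition="rgs")
            ebio.write_events_tsv(ev, udir / "events_rgs.tsv", f"unit{u:02d}")
            np.savetxt(udir / "ground_truth_g.tsv",
                       np.column_stack([truth.conductance,
                                        truth.effective_threshold,
                                        truth.p_ap]),
                       delimiter="\t", header="g\ttheta_Vps\tp_ap")
        log.info("unit %d simulated in %.1f s", u, time.time() - t0)
    return out


def run_analysis(data_dir, cfg: Optional[dict] = None) -> dict:
    """Analyze a simulated (or imported) data directory.

    Executes all stages whose inputs exist per unit; failures are isolated
    per unit and recorded as diagnostics.  Returns the result bundle as a
    nested dict (JSON-serializable).
    """
    data = Path(data_dir)
    if cfg is None:
        cfg_path = data / "config.yaml"
        cfg = load_config(cfg_path) if cfg_path.exists() else default_config()
    bundle = {"config_hash": config_hash(cfg), "units": {}}
    mcfg = cfg["metrics"]
    for udir in sorted(data.glob("unit*")):
        res: dict = {"diagnostics": []}
        try:
            res.update(_analyze_unit(udir, cfg, mcfg))
        except Exception as err:  # isolate unit failures
            res["diagnostics"].append(f"unit failed: {err}")
            log.exception("analysis failed for %s", udir)
        bundle["units"][udir.name] = res
    return bundle


def _analyze_unit(udir: Path, cfg: dict, mcfg: dict) -> dict:
    from .stimuli import ToneProtocol
    res: dict = {"diagnostics": []}
    spont_path = udir / "events_spont.tsv"
    if spont_path.exists():
        ev = ebio.read_events_tsv(spont_path)
        frac, ci, n = failure_fraction(ev)
        res["spont"] = {"failure_fraction": frac, "ci": list(ci), "n": n}
        try:
            res["spont"]["threshold_epsp_Vps"] = fit_threshold_epsp(ev).d
        except ValueError as err:
            res["diagnostics"].append(f"spont threshold fit: {err}")

    fra_path = udir / "events_fra.tsv"
    if fra_path.exists() and (udir / "fra_protocol.json").exists():
        ev = ebio.read_events_tsv(fra_path)
        protocol = ToneProtocol.from_json((udir / "fra_protocol.json").read_text())
        fra_block: dict = {}
        for metric in ("input_rate", "output_rate", "threshold_epsp"):
            try:
                fra = build_fra(ev, protocol, metric)
                summ = estimate_cf_threshold(fra)
                summ = q_values(fra, summ)
                fra_block[metric] = {
                    "cf_hz": summ.cf, "threshold_db": summ.threshold,
                    "q10": summ.q10, "q40": summ.q40,
                    "asymmetry_index": summ.asymmetry_index}
            except ValueError as err:
                fra_block[metric] = None
                res["diagnostics"].append(f"FRA {metric}: {err}")
        if fra_block.get("input_rate"):
            rl = rate_level(ev, protocol, fra_block["input_rate"]["cf_hz"])
            fra_block["rlg_input"] = rl.rlg
            rl_out = rate_level(ev, protocol, fra_block["input_rate"]["cf_hz"],
                                output=True)
            fra_block["rlg_output"] = rl_out.rlg
        res["fra"] = fra_block

    sam_path = udir / "events_sam.tsv"
    if sam_path.exists():
        ev = ebio.read_events_tsv(sam_path)
        sam_block = {}
        for cond, sub in ev.groupby("condition"):
            fm = float(str(cond).replace("sam", ""))
            duration = cfg["sam"]["duration_s"]
            block = {}
            for stream, ap_only in (("input", False), ("output", True)):
                trains = trains_from_events(sub, ap_only=ap_only)
                vs, p, n = vector_strength(trains, fm, duration=duration)
                bin_w = min(1.0 / fm / 8, 0.002)
                psth = build_psth(trains, duration, bin_width=bin_w)
                env = raised_sine_envelope(fm, 1.0, len(psth.rate), bin_w)
                block[stream] = {
                    "vector_strength": vs, "rayleigh_p": p, "n_spikes": n,
                    "corr_norm": corr_norm(psth, env)}
            sam_block[f"{fm:g}"] = block
        res["sam"] = sam_block

    rgs_path = udir / "events_rgs.tsv"
    if rgs_path.exists():
        ev = ebio.read_events_tsv(rgs_path)
        duration = cfg["rgs"]["duration_s"]
        rgs_block = {}
        for stream, ap_only in (("input", False), ("output", True)):
            trains = trains_from_events(ev, ap_only=ap_only)
            psth = build_psth(trains, duration,
                              bin_width=mcfg["psth_bin_s"])
            entry = {
                "sparsity_variance": sparsity(psth, "variance"),
                "sparsity_kurtosis": sparsity(psth, "kurtosis"),
                "sparsity_csi": sparsity(psth, "csi",
                                         mcfg["csi_threshold_hz"]),
            }
            try:
                sac = shuffled_autocorrelogram(trains, duration)
                entry["reproducibility"] = reproducibility(sac)
                entry["dispersion_ms"] = temporal_dispersion(sac) * 1e3
            except ValueError as err:
                res["diagnostics"].append(f"RGS SAC ({stream}): {err}")
            rgs_block[stream] = entry
        res["rgs"] = rgs_block
        if cfg["removal"]["enabled"]:
            cmp_res = compare_transformations(
                ev, duration, psth_bin=cfg["removal"]["psth_bin_s"],
                seed=cfg["seed"])
            res["removal"] = {
                "metrics": cmp_res.metrics.to_dict(),
                "rates_hz": cmp_res.rates}
    return res


def write_bundle(bundle: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(bundle, indent=1, default=default,
                                     allow_nan=True))
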