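"""End-to-end orchestration: simulate → analyze → statistics → images → report.

A single run configuration (nested dict, typically loaded from YAML) drives
both conditions and the imaging time course. One master seed is expanded into
fixed per-stage sub-seeds so stages can be rerun independently and the whole
report is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .afm import timecourse_summary
from .curves import RuptureEvent, analyze_curves
from .rupture_stats import (ConditionSummary, MixtureFit, TetherCorrection,
                            compare_conditions, discard_highest,
                            fit_double_gaussian, plot_histogram_fit,
                            summarize_condition, tether_correction)
from .synthetic import (MixtureParams, SimulationConfig, fig_timecourse_features,
                        simulate_experiment, simulate_topograph)

__all__ = ["ConditionResult", "analyze_condition", "default_config",
           "load_config", "run_full"]

# fixed sub-seed offsets per stage (master seed + offset)
_SEED_OFFSETS = {"curves": 101, "images": 301}


@dataclass
class ConditionResult:
    """Everything one condition produces on the force-spectroscopy side."""

    label: str
    events: list[RuptureEvent]
    correction: TetherCorrection
    retained_forces: np.ndarray
    fit: MixtureFit
    summary: ConditionSummary
    truth: object = field(default=None, repr=False)


def analyze_condition(config: SimulationConfig, label: str = "",
                      bin_width: float = 10.0) -> ConditionResult:
    """Simulate one condition and run the full force pipeline on it.

    Steps: simulate curves → detect/fit rupture events → yield → Poisson
    multiple-tether correction (discard the p×n highest forces) → binned
    two-Gaussian fit → Table-shaped summary.
    """
    curves, truth = simulate_experiment(config)
    events = analyze_curves(
        curves,
        noise_sd=config.force_noise_sd if config.force_noise_sd > 0 else None,
        spring_constant=config.spring_constant,
        temperature=config.temperature,
    )
    specific = [e for e in events if e.specific]
    curves_with = {e.curve_id for e in specific}
    corr = tether_correction(config.n_curves, len(curves_with))
    forces = np.array([e.rupture_force for e in specific])
    retained = discard_highest(forces, corr.p_multi) if len(forces) else forces
    fit = fit_double_gaussian(retained, bin_width=bin_width)
    summary = summarize_condition(retained, fit,
                                  yield_percent=corr.yield_percent, label=label)
    return ConditionResult(label=label, events=events, correction=corr,
                           retained_forces=retained, fit=fit, summary=summary,
                           truth=truth)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Demo configuration: control and Cu2+ conditions, 1000 curves each,
    plus the 1/6/24 h imaging time course."""
    return {
        "seed": 0,
        "n_curves": 1000,
        "lambda": 0.155,
        "force_noise_sd": 3.0,
        "bin_width": 10.0,
        "conditions": {
            "control": {"mixture": [0.5, 66.0, 20.0, 132.0, 30.0]},
            "copper": {"mixture": [0.35, 83.0, 20.0, 164.0, 30.0]},
        },
        "images": {
            "enabled": True,
            "times_h": [1, 6, 24],
            "image_size": [500, 500],
            "pixel_size_nm": 10.0,
            "noise_sd_nm": 0.3,
            "tilt_nm_per_nm": 5.0e-4,
        },
    }


def load_config(path) -> dict:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sim_config(cfg: dict, label: str, seed: int) -> SimulationConfig:
    spec = cfg["conditions"][label]
    mix = MixtureParams(*spec["mixture"])
    base = SimulationConfig(
        seed=seed,
        n_curves=int(cfg.get("n_curves", 1000)),
        specific_event_probability=float(spec.get("lambda", cfg.get("lambda", 0.155))),
        mixture=mix,
        force_noise_sd=float(cfg.get("force_noise_sd", 3.0)),
    )
    return replace(base, **{k: v for k, v in spec.items()
                            if k not in ("mixture", "lambda")})


def run_full(config: dict, outdir, seed: int | None = None,
             make_plots: bool = True) -> dict:
    """Run every stage and write the report bundle into ``outdir``.

    Emits summary.tsv (one Table-shaped row per condition), comparison.json
    (first two conditions; absent, with a logged warning, when only one is
    configured), events_<label>.tsv, timecourse.tsv, optional histogram PNGs
    and run.log with ISO timestamps, config hash and version.

    Returns {"summaries": {label: ConditionSummary}, "comparison": dict|None,
    "timecourse": DataFrame|None}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = {**config, "seed": int(seed)}
    master = int(config.get("seed", 0))
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")

    cfg_hash = hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]
    log(f"smforce {__version__} run start; config sha256/16={cfg_hash}; "
        f"seed={master}")

    from .io import write_events  # late import: io imports synthetic

    results: dict[str, ConditionResult] = {}
    for i, label in enumerate(config["conditions"]):
        sub = master + _SEED_OFFSETS["curves"] + 97 * i
        log(f"[curves:{label}] simulate+analyze n={config.get('n_curves')} "
            f"sub-seed={sub}")
        try:
            res = analyze_condition(
                _sim_config(config, label, sub), label=label,
                bin_width=float(config.get("bin_width", 10.0)))
        except Exception as exc:  # stage-tagged diagnostics
            log(f"[curves:{label}] FAILED: {exc}")
            (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(f"stage curves:{label} failed: {exc}") from exc
        results[label] = res
        write_events(res.events, outdir / f"events_{label}.tsv")
        if make_plots:
            plot_histogram_fit(res.fit, outdir / f"histogram_{label}.png",
                               title=label)
        log(f"[curves:{label}] yield={res.correction.yield_percent:.1f}% "
            f"p_multi={res.correction.p_multi:.3f} "
            f"discarded={res.correction.n_discarded} "
            f"peaks=({res.fit.mu1:.1f},{res.fit.mu2:.1f}) pN")

    rows = []
    for label, res in results.items():
        s = res.summary
        rows.append({
            "condition": label,
            "peak1_pN": round(s.mu1, 4), "peak1_SE_pN": round(s.se1, 4),
            "peak2_pN": round(s.mu2, 4), "peak2_SE_pN": round(s.se2, 4),
            "mean_rupture_force_pN": round(s.mean_force, 4),
            "yield_percent": round(s.yield_percent, 4),
            "area_fraction1": round(s.area_fraction1, 4),
            "n_events": s.n_events,
        })
    pd.DataFrame(rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)

    comparison = None
    labels = list(results)
    if len(labels) >= 2:
        comparison = compare_conditions(results[labels[0]].summary,
                                        results[labels[1]].summary)
        with open(outdir / "comparison.json", "w") as fh:
            json.dump({"control": labels[0], "treated": labels[1],
                       **{k: (None if isinstance(v, float) and math.isnan(v)
                              else v) for k, v in comparison.items()}},
                      fh, indent=2)
        log(f"[compare] {labels[1]}-{labels[0]}: "
            f"dmu1={comparison['delta_mu1_pN']:.1f} "
            f"dmu2={comparison['delta_mu2_pN']:.1f} pN")
    else:
        log("[compare] WARNING: fewer than two conditions, comparison skipped")

    tc = None
    img_cfg = config.get("images", {})
    if img_cfg.get("enabled", False):
        labeled = []
        rng = np.random.default_rng(master + _SEED_OFFSETS["images"])
        for cond in ("control", "copper"):
            for t in img_cfg.get("times_h", [1, 6, 24]):
                feats = fig_timecourse_features(cond, t, rng)
                topo = simulate_topograph(
                    feats,
                    image_size=tuple(img_cfg.get("image_size", (500, 500))),
                    pixel_size=float(img_cfg.get("pixel_size_nm", 10.0)),
                    noise_sd=float(img_cfg.get("noise_sd_nm", 0.3)),
                    tilt=(float(img_cfg.get("tilt_nm_per_nm", 5e-4)), 0.0),
                    seed=rng,
                    metadata={"condition": cond, "time_h": t},
                )
                labeled.append((cond, f"{t} h", topo))
        tc = timecourse_summary(labeled)
        tc.to_csv(outdir / "timecourse.tsv", sep="\t", index=False)
        log(f"[images] time course over {len(labeled)} images written")

    log("run complete")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return {"summaries": {l: r.summary for l, r in results.items()},
            "results": results, "comparison": comparison, "timecourse": tc}
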