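"""End-to-end orchestration: reduce -> deposit -> pbpk -> correlate.

One YAML config drives the full in vitro-in silico chain for a set of
formulations: impactor reduction to aerodynamic descriptors, regional lung
deposition with the flow-matched breathing pattern, the salbutamol PBPK
simulation, a combined outcomes table, and (when a property table is given)
the Pearson screening matrix with its heatmap.  Every stage persists its
table so it can be re-run independently, and a manifest is written first so
every output references the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deposition import AirwayTree, BreathingPattern, discretize_lognormal, regional_deposition
from .errors import ConfigurationError
from .impactor import read_runs_csv, reduce_runs
from .pbpk import SimpleDeposition, build_model, load_config, pk_descriptors, simulate
from .stats import correlation_heatmap, pearson_matrix
from .synth import SynthSpec, gen_ngi_run

#: default single-breath manoeuvre for device testing: 4.0 L inhaled, 10 s
#: breath-hold, exhalation equal to the breath-hold; inhale time follows from
#: the test flow (8.6 / 4.0 / 2.4 s at 28 / 60 / 100 L/min)
DEFAULT_INHALED_ML = 4000.0
DEFAULT_HOLD_S = 10.0


def breathing_for_flow(flow_lpm: float, inhaled_mL: float = DEFAULT_INHALED_ML, hold_s: float = DEFAULT_HOLD_S) -> BreathingPattern:
    """Infer the breathing pattern from the device test flow."""
    inhale_s = inhaled_mL / (flow_lpm * 1000.0 / 60.0)
    return BreathingPattern(
        inhaled_volume=inhaled_mL, inhale_time=inhale_s, breath_hold=hold_s, exhale_time=hold_s
    )


def _manifest(cfg_text: str, cfg: dict, outdir: Path) -> dict:
    man = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "package": "aeropk",
        "version": __version__,
        "seed": cfg.get("seed", 0),
        "inputs": sorted(
            str(f.get("runs_csv")) for f in cfg.get("formulations", []) if f.get("runs_csv")
        ),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(man, indent=2))
    return man


def run_pipeline(config_path) -> Path:
    """Run the full chain described by a YAML config; returns the output dir."""
    cfg_text = Path(config_path).read_text()
    cfg = yaml.safe_load(cfg_text)
    outdir = Path(cfg.get("output_dir", "aeropk_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    _manifest(cfg_text, cfg, outdir)
    seed = int(cfg.get("seed", 0))
    density = float(cfg.get("particle_density_g_mL", 1.33))
    drug, lungp, sysp = load_config(cfg.get("pbpk_config"))
    tree = AirwayTree.default()

    summaries, outcome_rows = [], []
    for i, form in enumerate(cfg.get("formulations", [])):
        name = form.get("name", f"formulation_{i + 1}")
        try:
            if "runs_csv" in form:
                tables = read_runs_csv(form["runs_csv"])
            elif "synth" in form:
                spec = SynthSpec(seed=seed + i, **form["synth"])
                tables = gen_ngi_run(spec)
            else:
                raise ConfigurationError("formulation needs runs_csv or synth")
            per_run = reduce_runs(tables, per_replicate=True)
            mean = per_run[["ED_mg", "FPM_mg", "FPF_pct", "MMAD_um", "GSD"]].mean()
            sd = per_run[["ED_mg", "FPM_mg", "FPF_pct", "MMAD_um", "GSD"]].std()
            summaries.append(
                {"formulation": name, "n": len(per_run)}
                | {f"{k}_mean": v for k, v in mean.items()}
                | {f"{k}_sd": v for k, v in sd.items()}
            )

            flow = float(form.get("flow_lpm", 60.0))
            breath = breathing_for_flow(flow)
            aero = discretize_lognormal(mean["MMAD_um"], max(mean["GSD"], 1.0), 128, density)
            dep = regional_deposition(aero, tree, breath)

            dose_ug = float(form.get("dose_ug", cfg.get("dose_ug", mean["ED_mg"] * 1000.0)))
            model = build_model(SimpleDeposition(dep.ET, dep.TB, dep.AL), dose_ug, drug, lungp, sysp)
            prof = simulate(model)
            pk = pk_descriptors(prof, sysp.plasma_volume)
            prof_df = pd.DataFrame(
                {"t_h": prof.times, "Cp_ug_per_mL": prof.plasma_conc, "urine_ug": prof.cumulative_urine}
            )
            prof_df.to_csv(outdir / f"profile_{name}.csv", index=False)
            outcome_rows.append(
                {
                    "formulation": name,
                    "ED": mean["ED_mg"],
                    "FPM": mean["FPM_mg"],
                    "FPF": mean["FPF_pct"],
                    "MMAD": mean["MMAD_um"],
                    "Lung": 100.0 * dep.lung,
                    "Ext": 100.0 * dep.ET,
                    "Cmax": pk.Cmax,
                    "tmax": pk.tmax,
                    "AUC_0_12": pk.AUC_0_12,
                    "ConcU": pk.ConcU_30min,
                }
            )
        except Exception as exc:  # abort with the stage and offending input
            raise ConfigurationError(f"pipeline failed for formulation {name!r}: {exc}") from exc

    pd.DataFrame(summaries).to_csv(outdir / "aerodynamic_summary.csv", index=False)
    outcomes = pd.DataFrame(outcome_rows).set_index("formulation")
    outcomes.to_csv(outdir / "outcomes.csv")

    if cfg.get("props_csv"):
        props = pd.read_csv(cfg["props_csv"], index_col=0).loc[outcomes.index]
        r = pearson_matrix(props, outcomes)
        r.to_csv(outdir / "rmatrix.csv")
        correlation_heatmap(r, outdir / "rmatrix.png")
    return outdir
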