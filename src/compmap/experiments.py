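"""Reproducible experiment recipes tying the modules together.

Each recipe regenerates one benchmark figure's quantities from a seeded
config and returns tidy tables; ``run_experiment`` validates the config,
dispatches, writes outputs and a manifest (config hash, seed). Recipe
problem sizes default to desk-scale settings that run on one CPU; the
protocol functions they call expose the full-size parameters.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import policy as pol
from . import replay as rep
from . import replay_analysis as ana
from . import synthetic_population as syn

SCHEMA = {
    "generalization": {"seed": int, "grid": int, "n_rounds": int, "hidden": list},
    "latent_learning": {"seed": int, "n_worlds": int},
    "replay_visits": {"seed": int, "n_worlds": int},
    "homing": {"seed": int, "n_seeds": int},
    "session_changes": {"seed": int, "n_cells_scale": float},
    "home_shift": {"seed": int},
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    if "experiment" not in config:
        raise ConfigError("missing field: experiment")
    exp = config["experiment"]
    if exp not in SCHEMA:
        raise ConfigError(f"unknown experiment: {exp}")
    out = dict(config)
    out.setdefault("seed", 0)
    for key in config:
        if key not in SCHEMA[exp] and key not in ("experiment", "seed"):
            raise ConfigError(f"unknown field for {exp}: {key}")
    return out


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------


def run_generalization(config: dict) -> dict:
    """Traditional vs compositional policy success, within and across
    reward-only discrete environments."""
    rng = np.random.default_rng(config.get("seed", 0))
    g = int(config.get("grid", 6))
    world_cfg = {"width": g, "height": g, "n_walls": 0}
    hidden = tuple(config.get("hidden", (256, 128, 64)))
    spec = pol.PolicyNetworkSpec(hidden=hidden)
    rows = []
    for mode in ("compositional", "traditional"):
        layout = pol.RepresentationLayout(
            mode=mode, discrete=True, max_dist=g - 1, n_walls=0, grid_shape=(g, g)
        )
        within = pol.single_environment_protocol(world_cfg, layout, spec, rng)
        across, baseline, succ, base = pol.multi_environment_protocol(
            world_cfg,
            layout,
            spec,
            rng,
            n_rounds=int(config.get("n_rounds", 4)),
        )
        rows.append(
            dict(
                mode=mode,
                within_env=within,
                across_env=across,
                random_baseline=baseline,
            )
        )
        for s, b in zip(succ, base):
            rows.append(
                dict(mode=mode, within_env=np.nan, across_env=s, random_baseline=b)
            )
    return {"summary": pd.DataFrame(rows)}


def run_latent_learning(config: dict) -> dict:
    rng = np.random.default_rng(config.get("seed", 0))
    latent, nonlatent = pol.latent_learning_experiment(
        rng=rng, n_worlds=int(config.get("n_worlds", 25))
    )
    return {
        "curves": pd.DataFrame(
            {
                "encounter": np.arange(1, len(latent) + 1),
                "latent": latent,
                "nonlatent": nonlatent,
            }
        )
    }


def run_replay_visits(config: dict) -> dict:
    rng = np.random.default_rng(config.get("seed", 0))
    df = rep.replay_visit_curve(
        rng=rng, n_worlds=int(config.get("n_worlds", 25))
    )
    return {"curves": df}


def run_homing(config: dict) -> dict:
    rng = np.random.default_rng(config.get("seed", 0))
    df = rep.homing_experiment(rng=rng, n_seeds=int(config.get("n_seeds", 10)))
    return {"errors": df}


def run_session_changes(config: dict) -> dict:
    """Build the 600-cell population, simulate one session, run the
    decoding/alignment pipeline, and summarize home vs elsewhere changes."""
    rng = np.random.default_rng(config.get("seed", 0))
    pcfg = syn.PopulationConfig()
    ent = syn.build_entorhinal_populations(pcfg, (60.0, 60.0), (140.0, 120.0), rng)
    pop = syn.build_conjunctive_population(ent)
    session = syn.simulate_replay_session(pop, rng)
    result = ana.analyze_synthetic_session(session, rng)
    rows = []
    for lab, summ in result.summaries.items():
        rows.append(
            dict(
                group=lab,
                roi_mean_hz=summ.roi_mean,
                roi_sem_hz=summ.roi_sem,
                n=len(summ.roi_values),
            )
        )
    return {"roi": pd.DataFrame(rows), "_analysis": result, "_session": session}


def run_home_shift(config: dict) -> dict:
    """Day-2 cumulative change maps and their home-shift correlations."""
    rng = np.random.default_rng(config.get("seed", 0))
    pcfg = syn.PopulationConfig()
    home1, home2 = (60.0, 60.0), (140.0, 120.0)
    ent = syn.build_entorhinal_populations(pcfg, home1, home2, rng)
    pop = syn.build_conjunctive_population(ent)
    changes = syn.day2_change_maps(pop, rng)
    labels = pop.labels
    rows = []
    for c in range(pop.n_cells):
        r = ana.home_shift_correlation(changes[c], home2, home1, pcfg.bin_cm)
        rows.append(dict(cell=c, label=labels[c], correlation=r))
    return {"correlations": pd.DataFrame(rows)}


RECIPES = {
    "generalization": run_generalization,
    "latent_learning": run_latent_learning,
    "replay_visits": run_replay_visits,
    "homing": run_homing,
    "session_changes": run_session_changes,
    "home_shift": run_home_shift,
}


def run_experiment(config: dict, out_dir=None) -> dict:
    """Validate, run and (optionally) persist one experiment.

    Returns the recipe's tables; when ``out_dir`` is given, writes each table
    as CSV plus a ``manifest.json`` recording the config hash and seed.
    """
    config = validate_config(config)
    result = RECIPES[config["experiment"]](config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        public = {k: v for k, v in result.items() if not k.startswith("_")}
        for name, df in public.items():
            df.to_csv(out / f"{name}.csv", index=False)
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "experiment": config["experiment"],
                    "seed": config.get("seed", 0),
                    "config_sha256": digest,
                    "tables": sorted(public),
                },
                indent=2,
            )
        )
    return result


def make_fixtures(size: str, rng: np.random.Generator):
    """Bundled synthetic inputs for tests.

    ``tiny`` builds a reduced population (2 grid x 4 object-vector + 6
    sensory cells, 12 replays over 300 s) that runs the full pipeline in
    seconds; ``standard`` matches the full session (600 cells, 100 replays,
    3000 s).
    """
    if size == "tiny":
        pcfg = syn.PopulationConfig(n_grid=2, n_ovc=4, n_sensory=6)
        scfg = syn.SessionConfig(n_replays=12, t_end_s=300.0)
    elif size == "standard":
        pcfg = syn.PopulationConfig()
        scfg = syn.SessionConfig()
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    ent = syn.build_entorhinal_populations(pcfg, (60.0, 60.0), (140.0, 120.0), rng)
    pop = syn.build_conjunctive_population(ent)
    session = syn.simulate_replay_session(pop, rng, scfg)
    return pop, session
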