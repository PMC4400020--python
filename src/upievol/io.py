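"""Configuration parsing, presets and structured output writers.

Configurations travel as flat dictionaries (CLI flags or a YAML file, one key
per flag); :func:`parse_config` validates them into a :class:`RunConfig` and
:func:`config_to_dict` / :func:`config_from_dict` round-trip a configuration
losslessly, so the config echo written into every summary is sufficient to
reproduce the run bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .kernels import FitnessSpec
from .runner import RunConfig, RunSummary
from .scenarios import ScenarioSpec, build_scenario

__all__ = [
    "PRESETS",
    "parse_config",
    "config_to_dict",
    "config_from_dict",
    "write_outputs",
    "read_summary",
]

#: named parameter sets for headline runs
PRESETS: dict[str, dict] = {
    # neutral two-mating-type model; the uniparental allele fixes
    "linked-neutral": {
        "scenario": "linked",
        "n": 20,
        "mu": 1e-7,
        "cost": 0.2,
        "fitness": "concave",
    },
    # polymorphic equilibrium: no mating types, U x U biparental, concave cost
    "no-mating-types-concave": {
        "scenario": "no_mating_types",
        "n": 20,
        "mu": 1e-4,
        "cost": 0.2,
        "fitness": "concave",
        "uu_regime": "biparental",
    },
    # recombining loci, U x U biparental, linear cost: UPI reaches its 0.5 ceiling
    "recombination-linear": {
        "scenario": "recombination",
        "n": 20,
        "mu": 1e-4,
        "cost": 0.2,
        "fitness": "linear",
        "p_r": 0.5,
        "uu_regime": "biparental",
    },
    # vegetative segregation with few organelles: biparental inheritance is stable
    "mitosis-vegetative": {
        "scenario": "mitosis",
        "n": 4,
        "mu": 1e-4,
        "cost": 0.2,
        "fitness": "concave",
        "divisions": 20,
        "mitosis_timing": "before",
    },
}

_TIMING_ALIASES = {"before": "before_selection", "midway": "midway"}


def _scenario_kwargs(name: str, opts: dict) -> dict:
    """Extract the builder keyword arguments relevant to ``name``."""
    name = name.replace("-", "_")
    if name == "linked":
        return {}
    if name == "recombination":
        kw = {"p_r": opts["p_r"], "uu_regime": opts["uu_regime"]}
        if opts.get("p_b") is not None:
            kw["p_b"] = opts["p_b"]
        return kw
    if name == "no_mating_types":
        kw = {"uu_regime": opts["uu_regime"]}
        if opts.get("p_b") is not None:
            kw["p_b"] = opts["p_b"]
        return kw
    if name == "mitosis":
        timing = opts.get("mitosis_timing", "before")
        return {
            "d": opts.get("divisions", 0),
            "timing": _TIMING_ALIASES.get(timing, timing),
        }
    if name == "physarum":
        return {"p_b": opts["p_b"]}
    if name == "didymium":
        kw = {"p_u1": opts["p_u1"], "p_u2": opts["p_u2"], "p_b": opts["p_b"]}
        if opts.get("p_r") is not None:
            kw["p_r"] = opts["p_r"]
        return kw
    raise ValueError(f"unknown scenario {name!r}")


def parse_config(
    options: dict | None = None,
    config_file: str | Path | None = None,
    preset: str | None = None,
) -> RunConfig:
    """Build a validated :class:`RunConfig` from flag-style options.

    Precedence: explicit ``options`` override the config file, which overrides
    the preset.  Unspecified values take the model defaults: linked scenario,
    concave fitness, neutral direction, and a back-mutation rate equal to mu
    (neutral), mu/100 (deleterious) or 100 mu (advantageous).
    """
    merged: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        merged.update(PRESETS[preset])
    if config_file is not None:
        with open(config_file) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {config_file} must hold a mapping")
        merged.update(loaded)
    if options:
        merged.update({k: v for k, v in options.items() if v is not None})

    scenario_name = merged.get("scenario", "linked")
    try:
        scenario = build_scenario(scenario_name, **_scenario_kwargs(scenario_name, merged))
    except KeyError as exc:
        raise ValueError(
            f"scenario {scenario_name!r} requires option {exc.args[0]!r}"
        ) from None

    direction = merged.get("direction", "neutral")
    fitness = FitnessSpec(
        c_h=float(merged.get("cost", 0.2)),
        het_shape=merged.get("fitness", "concave"),
        direction=direction,
        s=float(merged.get("s", 0.0)),
        acc_shape=merged.get("acc_fitness", "concave"),
    )

    mu = float(merged["mu"])
    mu_b = merged.get("mu_back")
    if mu_b is None:
        if direction == "deleterious":
            mu_b = mu / 100.0
        elif direction == "advantageous":
            mu_b = 100.0 * mu
        # neutral: RunConfig defaults mu_b to mu
    kwargs = dict(
        n=int(merged["n"]),
        mu=mu,
        mu_b=None if mu_b is None else float(mu_b),
        scenario=scenario,
        fitness=fitness,
    )
    for key in (
        "intro_freq",
        "intro_placement",
        "eq_tol",
        "max_generations",
        "trace_every",
        "snapshot_every",
        "mitosis_order",
        "eq_metric",
    ):
        if merged.get(key) is not None:
            kwargs[key] = merged[key]
    return RunConfig(**kwargs)


def config_to_dict(config: RunConfig) -> dict:
    """Lossless, JSON/YAML-serializable echo of a configuration."""
    sc = config.scenario
    return {
        "n": config.n,
        "mu": config.mu,
        "mu_b": config.mu_b,
        "scenario": {"name": sc.name, **sc.params},
        "fitness": {
            "c_h": config.fitness.c_h,
            "het_shape": config.fitness.het_shape,
            "direction": config.fitness.direction,
            "s": config.fitness.s,
            "acc_shape": config.fitness.acc_shape,
        },
        "intro_freq": config.intro_freq,
        "intro_placement": config.intro_placement,
        "eq_tol": config.eq_tol,
        "max_generations": config.max_generations,
        "trace_every": config.trace_every,
        "snapshot_every": config.snapshot_every,
        "mitosis_order": config.mitosis_order,
        "eq_metric": config.eq_metric,
    }


def config_from_dict(d: dict) -> RunConfig:
    """Inverse of :func:`config_to_dict`."""
    sc = dict(d["scenario"])
    scenario = build_scenario(sc.pop("name"), **sc)
    fitness = FitnessSpec(**d["fitness"])
    return RunConfig(
        n=d["n"],
        mu=d["mu"],
        mu_b=d["mu_b"],
        scenario=scenario,
        fitness=fitness,
        intro_freq=d["intro_freq"],
        intro_placement=d["intro_placement"],
        eq_tol=d["eq_tol"],
        max_generations=d["max_generations"],
        trace_every=d["trace_every"],
        snapshot_every=d.get("snapshot_every", 0),
        mitosis_order=d["mitosis_order"],
        eq_metric=d.get("eq_metric", "per_type"),
    )


def summary_to_dict(summary: RunSummary) -> dict:
    return {
        "version": __version__,
        "generations_to_first_equilibrium": summary.generations_to_first_equilibrium,
        "generations_to_final_equilibrium": summary.generations_to_final_equilibrium,
        "burn_in_converged": summary.burn_in_converged,
        "converged": summary.converged,
        "equilibrium_allele_freqs": summary.equilibrium_allele_freqs,
        "equilibrium_genotype_freqs": summary.equilibrium_genotype_freqs,
        "equilibrium_upi_frequency": summary.equilibrium_upi_frequency,
        "fixation": summary.fixation,
        "config": config_to_dict(summary.config),
    }


def _snapshot_table(summary: RunSummary) -> pd.DataFrame:
    """Long-format distribution trace: one row per (generation, stage,
    entity, count); proportions within each (generation, stage) group sum
    to 1."""
    rows = []
    for gen, phase, gam, dip in summary.snapshots:
        for allele, v in gam.items():
            for count, prop in enumerate(v):
                rows.append((gen, phase, "gamete", allele, count, prop))
        for geno, v in dip.items():
            for count, prop in enumerate(v):
                rows.append((gen, phase, "post_mating", geno, count, prop))
    return pd.DataFrame(
        rows, columns=["generation", "phase", "stage", "entity", "count", "proportion"]
    )


def write_outputs(
    summary: RunSummary, out_dir: str | Path, fmt: str = "csv"
) -> dict[str, Path]:
    """Write the run summary, per-generation frequency trace and (when
    recorded) the full-distribution trace.

    Returns the paths written.  ``fmt`` selects the summary document format
    (``csv`` pairs with a JSON summary; ``json`` nests the trace into the
    summary file as records).
    """
    if fmt not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    doc = summary_to_dict(summary)
    if fmt == "json":
        doc["trace"] = summary.trace.to_dict(orient="records")
        paths["summary"] = out_dir / "summary.json"
        paths["summary"].write_text(json.dumps(doc, indent=2))
    else:
        paths["summary"] = out_dir / "summary.json"
        paths["summary"].write_text(json.dumps(doc, indent=2))
        paths["trace"] = out_dir / "trace.csv"
        summary.trace.to_csv(paths["trace"], index=False)
    if summary.snapshots:
        paths["distributions"] = out_dir / "distributions.csv"
        _snapshot_table(summary).to_csv(paths["distributions"], index=False)
    return paths


def read_summary(path: str | Path) -> dict:
    """Read back a summary document written by :func:`write_outputs`."""
    return json.loads(Path(path).read_text())
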