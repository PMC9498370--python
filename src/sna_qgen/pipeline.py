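"""End-to-end orchestration: inputs -> networks -> traits -> chains -> tables.

A run is driven by a config dict (usually loaded from YAML):

.. code-block:: yaml

    inputs:                 # either this block ...
      fights: fights.csv
      animals: animals.csv
      pedigree: pedigree.csv
      performance: performance.csv
    simulate:               # ... or this one (synthetic study)
      seed: 1
    model:
      sna_traits: [t_degree, t_weighted_degree, ...]   # default: all six
      performance_traits: [TDG, LDG, DFI, FE, FBW, HCW, BF, LD]
      sna_pairs: true       # all 15 within-network pairs
      cross_pairs: true     # all 6 x 8 network-by-performance pairs
    mcmc: {n_iter: 20000, burn_in: 2000, thin: 10, seed: 1}
    output: out/

Every stage logs its record counts; chain files and result tables land under
the output directory together with a manifest (config, seed, versions) that
makes reruns reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import platform

import numpy as np
import pandas as pd

from . import io_formats, network_traits, pedigree_kinship
from . import gibbs_animal_model as gam
from . import posterior_summary as ps
from . import synthetic_data

logger = logging.getLogger(__name__)

SNA_TRANSFORMED = [f"t_{t}" for t in network_traits.TRAITS]
PERF_TRAITS = list(io_formats.PERFORMANCE_TRAITS)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _load_inputs(cfg: dict, outdir: str):
    if "simulate" in cfg:
        sim_cfg = dict(cfg.get("simulate") or {})
        config = synthetic_data.SimulationConfig(**sim_cfg)
        study = synthetic_data.simulate_study(config)
        synthetic_data.write_study(study, os.path.join(outdir, "inputs"))
        logger.info("simulated study: %d fights, %d animals, pedigree %d",
                    len(study.fights), len(study.animals), study.pedigree.n)
        return (study.fights, study.animals, study.rosters, study.pedigree,
                study.performance)
    inputs = cfg.get("inputs")
    if not inputs:
        raise PipelineError("inputs", "config needs an 'inputs' or 'simulate' block")
    for key in ("fights", "animals", "pedigree", "performance"):
        if key not in inputs:
            raise PipelineError(key, f"missing input path for {key!r}")
        if not os.path.exists(inputs[key]):
            raise PipelineError(key, f"file not found: {inputs[key]}")
    animals = io_formats.read_animals(inputs["animals"])
    rosters = io_formats.rosters_from_animals(animals)
    fights = io_formats.read_fight_records(inputs["fights"], rosters)
    ped = io_formats.read_pedigree(inputs["pedigree"])
    performance = io_formats.read_performance(inputs["performance"])
    performance = io_formats.derive_feed_efficiency(performance)
    logger.info("loaded %d fights, %d animals, pedigree %d, %d performance rows",
                len(fights), len(animals), ped.n, len(performance))
    return fights, animals, rosters, ped, performance


def run_pipeline(cfg: dict, outdir: str | None = None) -> str:
    """Execute the full analysis; returns the output directory."""
    outdir = outdir or cfg.get("output", "out")
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "chains"), exist_ok=True)

    fights, animals, rosters, ped, performance = _load_inputs(cfg, outdir)

    # --- networks and traits
    try:
        traits = network_traits.traits_from_records(fights, rosters)
    except Exception as exc:
        raise PipelineError("network_traits", str(exc)) from exc
    traits.to_csv(os.path.join(outdir, "sna_traits.csv"),
                  float_format=io_formats.FLOAT_FMT)
    logger.info("scored %d animals on %d traits", len(traits),
                len(network_traits.TRAITS))

    # --- merged record table
    data = animals.join(traits.drop(columns="pen_id")).join(performance)
    data = data.reset_index().rename(columns={"index": "animal"})
    if "animal" not in data.columns:
        data = data.rename(columns={data.columns[0]: "animal"})

    # --- kinship
    try:
        F = pedigree_kinship.compute_inbreeding(ped)
        A_inv = pedigree_kinship.build_A_inverse(ped, F)
    except Exception as exc:
        raise PipelineError("pedigree", str(exc)) from exc

    # --- models
    model_cfg = cfg.get("model", {})
    sna = list(model_cfg.get("sna_traits", SNA_TRANSFORMED))
    perf = [t for t in model_cfg.get("performance_traits", PERF_TRAITS)
            if t in data.columns and data[t].notna().any()]
    pairs = []
    if model_cfg.get("sna_pairs", True):
        pairs += gam.all_pairs(sna)
    if model_cfg.get("cross_pairs", True):
        pairs += gam.cross_pairs(sna, perf)
    mcmc = cfg.get("mcmc", {})
    config = gam.GibbsConfig(
        n_iter=int(mcmc.get("n_iter", 20_000)),
        burn_in=int(mcmc.get("burn_in", 2_000)),
        thin=int(mcmc.get("thin", 10)),
        seed=int(mcmc.get("seed", 0)),
    )
    try:
        chains = gam.run_all_models(data, ped, A_inv, sna, pairs, config)
    except gam.GibbsError as exc:
        raise PipelineError("gibbs", str(exc)) from exc
    for name, chain in chains.items():
        io_formats.write_chain(chain.to_dataframe(),
                               os.path.join(outdir, "chains", f"{name}.csv"))

    # --- summaries
    uni = {tr: chains[tr] for tr in sna}
    h2 = ps.summarize_univariate(uni)
    sna_pair_chains = {p: chains["__".join(p)] for p in pairs
                       if p[0] in sna and p[1] in sna}
    cross_chains = {p: chains["__".join(p)] for p in pairs
                    if p[1] in perf}
    rg_sna = (ps.summarize_correlations(sna_pair_chains)
              if sna_pair_chains else _empty_rg())
    rg_cross = (ps.summarize_correlations(cross_chains)
                if cross_chains else _empty_rg())
    rp = ps.spearman_matrix(data.set_index("animal"), sna + perf)
    io_formats.write_results_tables(
        {"h2": h2, "rg_sna": rg_sna, "rg_sna_perf": rg_cross, "rp_spearman": rp},
        os.path.join(outdir, ""),
    )

    manifest = {
        "seed": config.seed,
        "mcmc": {"n_iter": config.n_iter, "burn_in": config.burn_in,
                 "thin": config.thin},
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "n_records": int(len(data)),
        "n_pedigree": int(ped.n),
        "models": sorted(chains),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _empty_rg() -> pd.DataFrame:
    return pd.DataFrame(columns=["trait_a", "trait_b", "rg_mean", "rg_sd",
                                 "rg_lo", "rg_hi", "significant"])


def report(outdir: str) -> str:
    """Markdown report over the written tables; bold = HPD95% excludes zero."""
    lines = ["# Social-network trait genetic analysis", ""]
    h2_path = os.path.join(outdir, "h2_table.csv")
    if os.path.exists(h2_path):
        h2 = pd.read_csv(h2_path)
        lines += ["## Heritabilities and pen effects", "",
                  "| trait | h2 (HPD95%) | c2 (HPD95%) | Vp (HPD95%) |",
                  "|---|---|---|---|"]
        for _, r in h2.iterrows():
            lines.append(
                f"| {r['trait']} "
                f"| {r['h2_mean']:.2f} ({r['h2_lo']:.3f}, {r['h2_hi']:.3f}) "
                f"| {r['c2_mean']:.2f} ({r['c2_lo']:.3f}, {r['c2_hi']:.3f}) "
                f"| {r['Vp_mean']:.3g} ({r['Vp_lo']:.3g}, {r['Vp_hi']:.3g}) |"
            )
        lines.append("")
    for fname, title in (("rg_sna.csv", "Genetic correlations among network traits"),
                         ("rg_sna_perf.csv",
                          "Genetic correlations with performance traits")):
        path = os.path.join(outdir, fname)
        if not os.path.exists(path):
            continue
        rg = pd.read_csv(path)
        lines += [f"## {title}", "",
                  "| trait pair | rg (HPD95%) |", "|---|---|"]
        for _, r in rg.iterrows():
            cell = f"{r['rg_mean']:.2f} ({r['rg_lo']:.2f}, {r['rg_hi']:.2f})"
            if bool(r.get("significant", False)):
                cell = f"**{cell}**"
            lines.append(f"| {r['trait_a']} - {r['trait_b']} | {cell} |")
        lines.append("")
    text = "\n".join(lines)
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write(text)
    return text
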