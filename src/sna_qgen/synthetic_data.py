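"""Synthetic study generator: pedigree, pens, fight networks and phenotypes.

Emulates the design of the source study — 900 focal pigs (450 females, 450
castrates), progeny of 116 sires and 391 dams inside a 4104-animal pedigree,
housed in 50 single-sex pens of 18 across 9 batches and 9 genetic lines —
with known ground-truth parameters, so every pipeline stage can be exercised
and validated without the (non-deposited) study data.

Fight networks are generated by an explicit behavioural stand-in model (the
study observed fights; it did not model their generation): every unordered
dyad in a pen fights with probability logistic(alpha + lambda (u_i + u_j)),
and a realized fight's total duration is LogNormal(mu + kappa (u_i + u_j),
sigma), floored at 1 s.  The latent aggressiveness u = breeding value +
environmental noise, so network traits computed from the fights carry a
heritable signal whose trait-level magnitude is emergent, not prescribed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import DyadicFightRecord
from .pedigree_kinship import PedigreeTable, compute_inbreeding


@dataclass
class SimulationConfig:
    """Study-design and generative parameters (defaults = study conditions)."""

    n_sires: int = 116
    n_dams: int = 391
    n_offspring: int = 900
    pedigree_total: int = 4104
    pen_size: int = 18
    n_pens: int = 50
    n_batches: int = 9
    n_lines: int = 9
    # latent aggressiveness u = a_u + eps, a_u additive genetic
    u_genetic_var: float = 1.0
    u_env_var: float = 1.0
    # fight incidence: P(edge) = logistic(alpha + lam * (u_i + u_j))
    alpha: float = -3.7
    lam: float = 0.5
    # fight duration: LogNormal(mu + kappa * (u_i + u_j), sigma), floored at 1 s
    mu: float = 1.8
    kappa: float = 0.35
    sigma: float = 1.5
    # mixing body weight covariate (kg, ~10-week-old pigs)
    mixing_weight_mean: float = 30.0
    mixing_weight_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pens * self.pen_size != self.n_offspring:
            raise ValueError("n_pens * pen_size must equal n_offspring")
        if self.n_founders < 2:
            raise ValueError("pedigree_total too small for the parent counts")

    @property
    def n_founders(self) -> int:
        return (self.pedigree_total - self.n_offspring
                - self.n_sires - self.n_dams)


#: performance-trait generative defaults: mean, phenotypic SD, h2, c2.
#: Scales follow the study's descriptives (TDG/LDG in g/d, DFI in g/d,
#: FBW/HCW in kg, BF/LD in mm); h2/c2 are typical pig literature values.
PERFORMANCE_DEFAULTS = {
    "TDG": (887.5, 117.4, 0.35, 0.05),
    "LDG": (695.9, 75.1, 0.30, 0.05),
    "DFI": (2280.0, 290.0, 0.30, 0.05),
    "FBW": (120.11, 12.03, 0.35, 0.05),
    "HCW": (94.10, 8.97, 0.35, 0.05),
    "BF": (17.97, 4.34, 0.45, 0.05),
    "LD": (62.24, 8.88, 0.40, 0.05),
}


@dataclass
class GroundTruth:
    """True simulation-side effects, for recovery checks."""

    breeding_values: pd.DataFrame    # pedigree-wide, one column per trait
    pen_effects: pd.DataFrame        # one row per pen
    fixed_effects: dict              # trait -> {term: effect}
    variance_components: dict        # trait -> (va, vc, ve)

    def true_h2(self, trait: str) -> float:
        va, vc, ve = self.variance_components[trait]
        return va / (va + vc + ve)

    def true_c2(self, trait: str) -> float:
        va, vc, ve = self.variance_components[trait]
        return vc / (va + vc + ve)


def simulate_pedigree(config: SimulationConfig, seed=None) -> PedigreeTable:
    """Three-generation pedigree: founder pool, sires/dams, focal offspring.

    Sires' and dams' parents are drawn from a founder pool sized so the total
    pedigree matches ``pedigree_total`` (founders without descendants stand in
    for the study pedigree's collateral ancestors).  Offspring are assigned
    dams nearly evenly (litters of ~n_offspring/n_dams) and each dam is mated
    to one randomly assigned sire.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    founders = [f"F{i + 1}" for i in range(config.n_founders)]
    sires = [f"S{i + 1}" for i in range(config.n_sires)]
    dams = [f"D{i + 1}" for i in range(config.n_dams)]
    pigs = [f"P{i + 1}" for i in range(config.n_offspring)]

    animals, sire_col, dam_col = [], [], []
    for f in founders:
        animals.append(f)
        sire_col.append("0")
        dam_col.append("0")
    for s in sires + dams:
        gp = rng.choice(config.n_founders, size=2, replace=False)
        animals.append(s)
        sire_col.append(founders[gp[0]])
        dam_col.append(founders[gp[1]])
    mate_of = rng.integers(0, config.n_sires, size=config.n_dams)
    dam_of = rng.permutation(np.arange(config.n_offspring) % config.n_dams)
    for k, pig in enumerate(pigs):
        d = dam_of[k]
        animals.append(pig)
        sire_col.append(sires[mate_of[d]])
        dam_col.append(dams[d])
    return PedigreeTable.from_records(animals, sire_col, dam_col)


def simulate_breeding_values(ped: PedigreeTable, G0, seed=0) -> np.ndarray:
    """Draw a ~ N(0, A (x) G0) by gene-dropping down the sorted pedigree.

    Founders are N(0, G0); each non-founder is the mean of its known parents'
    values plus a Mendelian-sampling deviation with variance d_i * G0, where
    d_i is the usual inbreeding-adjusted Mendelian variance.
    """
    rng = np.random.default_rng(seed)
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    t = G0.shape[0]
    if np.allclose(G0, 0):
        return np.zeros((ped.n, t))
    Lg = np.linalg.cholesky(G0 + 1e-12 * np.eye(t))
    F = compute_inbreeding(ped)
    a = np.zeros((ped.n, t))
    z = rng.standard_normal((ped.n, t))
    for i in range(ped.n):
        si, di = ped.sire[i], ped.dam[i]
        mean = np.zeros(t)
        d_var = 1.0
        if si:
            mean += 0.5 * a[si - 1]
            d_var -= 0.25 * (1.0 + F[si - 1])
        if di:
            mean += 0.5 * a[di - 1]
            d_var -= 0.25 * (1.0 + F[di - 1])
        a[i] = mean + np.sqrt(d_var) * (Lg @ z[i])
    return a


def assign_pens(ped: PedigreeTable, config: SimulationConfig, seed=0):
    """Assign sexes, single-sex pens, batches, lines and mixing weights.

    Returns ``(animals DataFrame indexed by animal, rosters dict)``.  Pens
    are single-sex (half female, half castrate pens); batches are contiguous
    pen groups ("mixed on the same day"); line follows the sire.
    """
    if config.n_offspring % config.pen_size:
        raise ValueError("offspring count not divisible by pen size")
    rng = np.random.default_rng(seed)
    offspring = [lab for i, lab in enumerate(ped.labels)
                 if ped.sire[i] and ped.dam[i] and lab.startswith("P")]
    if len(offspring) != config.n_offspring:
        # fall back: the last n_offspring animals of the sorted pedigree
        offspring = list(ped.labels[-config.n_offspring:])
    n = config.n_offspring
    half = n // 2
    perm = rng.permutation(n)
    sex = np.empty(n, dtype=object)
    sex[perm[:half]] = "female"
    sex[perm[half:]] = "castrate"

    # line follows the sire; sires are assigned lines round-robin
    index_of = ped.index_of
    sire_line = {}
    for lab in offspring:
        i = index_of[lab] - 1
        s = ped.sire[i]
        if s not in sire_line:
            sire_line[s] = f"L{len(sire_line) % config.n_lines + 1}"
    line = [sire_line[ped.sire[index_of[lab] - 1]] for lab in offspring]

    # single-sex pens, filled in a shuffled order within sex
    pens = np.empty(n, dtype=object)
    pen_labels = [f"PEN{k + 1:02d}" for k in range(config.n_pens)]
    pens_per_sex = config.n_pens // 2
    for sx, pen_block in (("female", pen_labels[:pens_per_sex]),
                          ("castrate", pen_labels[pens_per_sex:])):
        idx = np.flatnonzero(sex == sx)
        idx = rng.permutation(idx)
        for k, pen in enumerate(pen_block):
            block = idx[k * config.pen_size:(k + 1) * config.pen_size]
            pens[block] = pen

    # batches: near-equal contiguous groups of pens, interleaving sexes so
    # every batch holds pens of both sexes
    order = [p for pair in zip(pen_labels[:pens_per_sex],
                               pen_labels[pens_per_sex:]) for p in pair]
    sizes = np.full(config.n_batches, config.n_pens // config.n_batches)
    sizes[: config.n_pens % config.n_batches] += 1
    batch_of_pen = {}
    pos = 0
    for bi, size in enumerate(sizes):
        for p in order[pos:pos + size]:
            batch_of_pen[p] = f"B{bi + 1}"
        pos += size

    weight = rng.normal(config.mixing_weight_mean, config.mixing_weight_sd, size=n)
    weight = np.clip(weight, 1.0, None)

    animals = pd.DataFrame({
        "animal": offspring,
        "pen_id": pens,
        "line": line,
        "sex": sex,
        "batch": [batch_of_pen[p] for p in pens],
        "mixing_weight_kg": np.round(weight, 2),
    }).set_index("animal")
    from .io_formats import rosters_from_animals

    return animals, rosters_from_animals(animals)


def simulate_fight_network(rosters: dict, latent: dict,
                           config: SimulationConfig, seed=0) -> list:
    """Generate dyadic fight records per pen from latent aggressiveness.

    ``latent`` maps animal -> u_i.  Each dyad fights with probability
    logistic(alpha + lam (u_i + u_j)); realized total durations are
    LogNormal(mu + kappa (u_i + u_j), sigma) floored at 1 s (shorter bouts
    are not scored as reciprocal fights).
    """
    rng = np.random.default_rng(seed)
    records = []
    for pen_id in sorted(rosters):
        members = rosters[pen_id].members
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                usum = latent[a] + latent[b]
                if rng.random() < expit(config.alpha + config.lam * usum):
                    dur = rng.lognormal(config.mu + config.kappa * usum,
                                        config.sigma)
                    records.append(DyadicFightRecord(
                        pen_id, a, b, max(1.0, round(dur, 0))
                    ))
    return records


def simulate_phenotypes(ped: PedigreeTable, animals: pd.DataFrame,
                        variance_components: dict, seed=0,
                        means: dict | None = None,
                        fixed_effect_sd: float = 0.25) -> tuple:
    """Simulate y = Xb + Za + Wc + e for the phenotyped offspring.

    ``variance_components`` maps trait name to (va, vc, ve); traits are
    simulated independently of each other.  Fixed effects (line, sex, batch
    levels and the mixing-weight slope) are drawn once per trait with SD
    ``fixed_effect_sd`` * phenotypic SD.  Returns ``(phenotypes DataFrame
    indexed by animal, GroundTruth)``.
    """
    rng = np.random.default_rng(seed)
    means = means or {}
    index_of = ped.index_of
    rows = animals.index.to_list()
    rec_idx = np.array([index_of[a] - 1 for a in rows])
    pens = sorted(animals["pen_id"].unique())
    pen_pos = {p: k for k, p in enumerate(pens)}
    rec_pen = np.array([pen_pos[p] for p in animals["pen_id"]])

    pheno = pd.DataFrame(index=animals.index)
    bv_cols, pen_cols, fx, vcs = {}, {}, {}, {}
    for trait, (va, vc, ve) in variance_components.items():
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        a = simulate_breeding_values(ped, [[va]], seed=sub_seed)[:, 0]
        c = np.random.default_rng(sub_seed + 1).normal(0.0, np.sqrt(vc), len(pens))
        e = np.random.default_rng(sub_seed + 2).normal(
            0.0, np.sqrt(ve), len(rows))
        sdp = np.sqrt(va + vc + ve)
        frng = np.random.default_rng(sub_seed + 3)
        effects = {"intercept": means.get(trait, 0.0)}
        for factor in ("line", "sex", "batch"):
            for lev in sorted(animals[factor].unique())[1:]:
                effects[f"{factor}[{lev}]"] = frng.normal(0, fixed_effect_sd * sdp)
        effects["mixing_weight_kg"] = frng.normal(0, fixed_effect_sd * sdp
                                                  / animals["mixing_weight_kg"].std())
        xb = np.full(len(rows), effects["intercept"])
        for factor in ("line", "sex", "batch"):
            for lev in sorted(animals[factor].unique())[1:]:
                xb += effects[f"{factor}[{lev}]"] * (animals[factor] == lev).to_numpy()
        w = animals["mixing_weight_kg"].to_numpy(float)
        xb += effects["mixing_weight_kg"] * (w - w.mean())
        pheno[trait] = xb + a[rec_idx] + c[rec_pen] + e
        bv_cols[trait] = a
        pen_cols[trait] = c
        fx[trait] = effects
        vcs[trait] = (va, vc, ve)

    truth = GroundTruth(
        breeding_values=pd.DataFrame(bv_cols, index=ped.labels),
        pen_effects=pd.DataFrame(pen_cols, index=pens),
        fixed_effects=fx,
        variance_components=vcs,
    )
    return pheno, truth


def simulate_phenotypes_mv(ped: PedigreeTable, animals: pd.DataFrame,
                           G0, C0, R0, trait_names=("y1", "y2"), seed=0,
                           fixed_effect_sd: float = 0.25) -> tuple:
    """Simulate correlated traits jointly: y = Xb + Za + Wc + e with full
    2x2 (or t x t) covariance matrices G0, C0, R0.

    Breeding values are gene-dropped with the full G0 so genetic correlations
    between traits are exactly those implied by G0.  Returns ``(phenotypes,
    GroundTruth)`` like :func:`simulate_phenotypes`.
    """
    rng = np.random.default_rng(seed)
    G0 = np.atleast_2d(np.asarray(G0, float))
    C0 = np.atleast_2d(np.asarray(C0, float))
    R0 = np.atleast_2d(np.asarray(R0, float))
    t = G0.shape[0]
    trait_names = tuple(trait_names)[:t]
    index_of = ped.index_of
    rows = animals.index.to_list()
    rec_idx = np.array([index_of[a] - 1 for a in rows])
    pens = sorted(animals["pen_id"].unique())
    pen_pos = {p: k for k, p in enumerate(pens)}
    rec_pen = np.array([pen_pos[p] for p in animals["pen_id"]])

    a = simulate_breeding_values(ped, G0, seed=int(rng.integers(0, 2 ** 31 - 1)))
    jitter = 1e-12 * np.eye(t)
    c = rng.multivariate_normal(np.zeros(t), C0 + jitter, size=len(pens),
                                method="cholesky")
    e = rng.multivariate_normal(np.zeros(t), R0 + jitter, size=len(rows),
                                method="cholesky")
    sdp = np.sqrt(np.diag(G0) + np.diag(C0) + np.diag(R0))

    pheno = pd.DataFrame(index=animals.index)
    fx = {}
    w = animals["mixing_weight_kg"].to_numpy(float)
    for m, trait in enumerate(trait_names):
        effects = {"intercept": 0.0}
        xb = np.zeros(len(rows))
        for factor in ("line", "sex", "batch"):
            for lev in sorted(animals[factor].unique())[1:]:
                eff = rng.normal(0, fixed_effect_sd * sdp[m])
                effects[f"{factor}[{lev}]"] = eff
                xb += eff * (animals[factor] == lev).to_numpy()
        slope = rng.normal(0, fixed_effect_sd * sdp[m] / w.std())
        effects["mixing_weight_kg"] = slope
        xb += slope * (w - w.mean())
        pheno[trait] = xb + a[rec_idx, m] + c[rec_pen, m] + e[:, m]
        fx[trait] = effects
    truth = GroundTruth(
        breeding_values=pd.DataFrame(a, index=ped.labels, columns=trait_names),
        pen_effects=pd.DataFrame(c, index=pens, columns=trait_names),
        fixed_effects=fx,
        variance_components={
            tr: (G0[m, m], C0[m, m], R0[m, m])
            for m, tr in enumerate(trait_names)
        },
    )
    return pheno, truth


@dataclass
class SimulatedStudy:
    """Everything one study replicate comprises, plus its ground truth."""

    config: SimulationConfig
    pedigree: PedigreeTable
    animals: pd.DataFrame
    rosters: dict
    fights: list
    latent_aggressiveness: pd.Series
    performance: pd.DataFrame
    truth: GroundTruth


def simulate_study(config: SimulationConfig | None = None,
                   performance_traits: dict | None = None) -> SimulatedStudy:
    """One full synthetic study: pedigree, pens, fights and performance data."""
    config = config or SimulationConfig()
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2 ** 31 - 1, size=5)
    ped = simulate_pedigree(config, seed=int(seeds[0]))
    animals, rosters = assign_pens(ped, config, seed=int(seeds[1]))

    a_u = simulate_breeding_values(ped, [[config.u_genetic_var]],
                                   seed=int(seeds[2]))[:, 0]
    eps = np.random.default_rng(int(seeds[2]) + 7).normal(
        0.0, np.sqrt(config.u_env_var), ped.n)
    u_all = pd.Series(a_u + eps, index=ped.labels)
    latent = u_all.loc[animals.index]
    fights = simulate_fight_network(rosters, latent.to_dict(), config,
                                    seed=int(seeds[3]))

    perf_spec = performance_traits or PERFORMANCE_DEFAULTS
    vcs = {}
    means = {}
    for trait, (mean, sd, h2, c2) in perf_spec.items():
        vp = sd ** 2
        vcs[trait] = (h2 * vp, c2 * vp, (1 - h2 - c2) * vp)
        means[trait] = mean
    performance, truth = simulate_phenotypes(ped, animals, vcs,
                                             seed=int(seeds[4]), means=means)
    from .io_formats import derive_feed_efficiency

    if {"TDG", "DFI"} <= set(performance.columns):
        performance = derive_feed_efficiency(performance, recompute=True)

    return SimulatedStudy(
        config=config, pedigree=ped, animals=animals, rosters=rosters,
        fights=fights, latent_aggressiveness=latent,
        performance=performance, truth=truth,
    )


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write the four input CSVs plus ground_truth.csv; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    fights = pd.DataFrame(
        [(r.pen_id, r.animal_a, r.animal_b, r.duration) for r in study.fights],
        columns=["pen_id", "animal_a", "animal_b", "duration_s"],
    )
    paths["fights"] = os.path.join(outdir, "fights.csv")
    fights.to_csv(paths["fights"], index=False)
    paths["pedigree"] = os.path.join(outdir, "pedigree.csv")
    study.pedigree.to_dataframe().to_csv(paths["pedigree"], index=False)
    paths["animals"] = os.path.join(outdir, "animals.csv")
    study.animals.to_csv(paths["animals"])
    paths["performance"] = os.path.join(outdir, "performance.csv")
    study.performance.to_csv(paths["performance"])
    paths["ground_truth"] = os.path.join(outdir, "ground_truth.csv")
    truth_bv = study.truth.breeding_values.copy()
    truth_bv["latent_aggressiveness"] = pd.Series(
        study.latent_aggressiveness, index=truth_bv.index)
    truth_bv.to_csv(paths["ground_truth"])
    return paths
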