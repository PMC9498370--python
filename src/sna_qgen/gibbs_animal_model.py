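"""Bayesian animal model y = Xb + Za + Wc + e fitted by Gibbs sampling.

Univariate and bivariate linear mixed models with fixed effects (genetic
line, sex, batch and a mixing-weight covariate), an additive genetic effect
a ~ N(0, A (x) G0) structured by the pedigree relationship matrix through its
sparse inverse, an iid common-pen effect c ~ N(0, I (x) C0), and residual
e ~ N(0, I (x) R0).  Location effects are drawn single-site from their
Gaussian full conditionals; G0, C0 and R0 from inverse-Wishart full
conditionals.  Flat priors on the fixed effects and, by default, on the
covariance matrices (a proper weakly-informative inverse-Wishart option is
available; see :class:`PriorSpec`).

Records with one of two traits missing are handled by data augmentation
(drawn from the residual conditional each sweep); records missing every
trait are dropped at design assembly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._gibbs_kernel import gibbs_kernel

logger = logging.getLogger(__name__)

DEFAULT_FIXED = ("line", "sex", "batch")
DEFAULT_COVARIATES = ("mixing_weight_kg",)


@dataclass
class ModelSpec:
    """One analysis: 1 (univariate) or 2 (bivariate) response traits."""

    traits: tuple
    fixed: tuple = DEFAULT_FIXED
    covariates: tuple = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.fixed = tuple(self.fixed)
        self.covariates = tuple(self.covariates)
        if not 1 <= len(self.traits) <= 2:
            raise ValueError("ModelSpec supports 1 or 2 traits")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def name(self) -> str:
        return "__".join(self.traits)


@dataclass
class DesignAssembly:
    """Numeric design ready for the sampler."""

    y: np.ndarray            # (n, t), missing cells hold NaN
    miss: np.ndarray         # (n, t) uint8, 1 = missing
    X: np.ndarray            # (n, p) fixed-effect design, corner constraints
    x_names: list
    rec_animal: np.ndarray   # (n,) 0-based pedigree index per record
    rec_pen: np.ndarray      # (n,) 0-based pen index per record
    pen_ids: list
    animals: list            # record-level animal labels
    spec: ModelSpec
    n_pedigree: int

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_pens(self) -> int:
        return len(self.pen_ids)


@dataclass
class PriorSpec:
    """Inverse-Wishart priors for G0, C0, R0 (scale S, degrees of freedom nu)."""

    nu_g: float
    S_g: np.ndarray
    nu_c: float
    S_c: np.ndarray
    nu_r: float
    S_r: np.ndarray

    @classmethod
    def flat(cls, n_traits: int) -> "PriorSpec":
        """Flat (improper) prior on each covariance matrix: nu = -(t+1), S = 0.

        The full conditionals remain proper inverse-Wisharts whenever the
        effect counts exceed t + 1, and the prior density does not diverge at
        zero variance — unlike near-improper proper inverse-Wishart priors
        (tiny S), whose sigma^-2-type spike at the origin creates a
        quasi-absorbing region that can trap a chain at zero variance.  This
        matches the usual "flat priors on covariance components" convention
        of pedigree Gibbs samplers and is the package default.
        """
        t = n_traits
        Z = np.zeros((t, t))
        return cls(nu_g=-(t + 1), S_g=Z.copy(), nu_c=-(t + 1), S_c=Z.copy(),
                   nu_r=-(t + 1), S_r=Z.copy())

    @classmethod
    def weakly_informative(cls, n_traits: int, scale: float = 1e-6) -> "PriorSpec":
        """Proper inverse-Wishart prior: nu = t + 1, S = scale * I.

        Guarantees a proper joint posterior for bivariate models, at the cost
        of a prior that prefers near-zero variances when ``scale`` is tiny;
        see :meth:`flat` for why that matters.
        """
        t = n_traits
        S = scale * np.eye(t)
        return cls(nu_g=t + 1, S_g=S.copy(), nu_c=t + 1, S_c=S.copy(),
                   nu_r=t + 1, S_r=S.copy())


@dataclass
class GibbsConfig:
    """Chain length controls; saved draws = (n_iter - burn_in) / thin."""

    n_iter: int = 1_000_000
    burn_in: int = 100_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def study_scale(cls, seed: int = 0) -> "GibbsConfig":
        return cls(n_iter=1_000_000, burn_in=100_000, thin=20, seed=seed)

    @classmethod
    def test_preset(cls, seed: int = 0) -> "GibbsConfig":
        """Short chain for development runs: 20,000 / 2,000 / 10."""
        return cls(n_iter=20_000, burn_in=2_000, thin=10, seed=seed)

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class MCMCChain:
    """Thinned post-burn-in draws of the three covariance matrices."""

    traits: tuple
    G0: np.ndarray    # (n_saved, t, t)
    C0: np.ndarray
    R0: np.ndarray
    config: GibbsConfig

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_saved(self) -> int:
        return self.G0.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        t = self.n_traits
        cols = {"iter": self.config.burn_in
                + self.config.thin * np.arange(self.n_saved)}
        for name, arr in (("G0", self.G0), ("C0", self.C0), ("R0", self.R0)):
            for m in range(t):
                for l in range(m, t):
                    cols[f"{name}_{m + 1}{l + 1}"] = arr[:, m, l]
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, traits, config=None) -> "MCMCChain":
        t = len(tuple(traits))
        n = len(df)
        mats = {}
        for name in ("G0", "C0", "R0"):
            arr = np.empty((n, t, t))
            for m in range(t):
                for l in range(m, t):
                    arr[:, m, l] = arr[:, l, m] = df[f"{name}_{m + 1}{l + 1}"].to_numpy()
            mats[name] = arr
        if config is None:
            config = GibbsConfig(n_iter=n + 1, burn_in=0, thin=1)
        return cls(traits=tuple(traits), G0=mats["G0"], C0=mats["C0"],
                   R0=mats["R0"], config=config)


def assemble_design(data: pd.DataFrame, spec: ModelSpec, ped,
                    pen_ids=None) -> DesignAssembly:
    """Build y, X and the index maps from merged record-level data.

    ``data`` must hold one row per phenotyped animal with columns ``animal``,
    ``pen_id``, the fixed factors, covariates and trait columns.  Corner
    (reference-level) constraints drop the first level of each factor;
    covariates are centred.  Rows missing every requested trait are dropped.
    """
    for col in ("animal", "pen_id", *spec.fixed, *spec.covariates, *spec.traits):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    df = data.copy()
    y = df[list(spec.traits)].to_numpy(dtype=float)
    keep = ~np.all(np.isnan(y), axis=1)
    if not keep.any():
        raise ValueError("all responses missing")
    df = df.loc[keep].reset_index(drop=True)
    y = y[keep]
    miss = np.isnan(y).astype(np.uint8)

    parts = [np.ones((len(df), 1))]
    names = ["intercept"]
    for f in spec.fixed:
        levels = sorted(df[f].astype(str).unique())
        counts = df[f].astype(str).value_counts()
        thin_levels = counts[counts == 1]
        if len(thin_levels):
            logger.warning("factor %s has singleton levels: %s",
                           f, list(thin_levels.index))
        for lev in levels[1:]:  # first level is the reference
            parts.append((df[f].astype(str) == lev).to_numpy(float)[:, None])
            names.append(f"{f}[{lev}]")
    for cov in spec.covariates:
        vals = df[cov].to_numpy(dtype=float)
        parts.append((vals - np.nanmean(vals))[:, None])
        names.append(cov)
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("fixed-effect design is rank deficient (%d columns)",
                       X.shape[1])

    index_of = ped.index_of
    try:
        rec_animal = np.array([index_of[a] - 1 for a in df["animal"].astype(str)],
                              dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"animal {exc.args[0]!r} not in pedigree") from None
    if pen_ids is None:
        pen_ids = sorted(df["pen_id"].astype(str).unique())
    pen_index = {p: k for k, p in enumerate(pen_ids)}
    rec_pen = np.array([pen_index[p] for p in df["pen_id"].astype(str)],
                       dtype=np.int64)
    return DesignAssembly(
        y=y, miss=miss, X=X, x_names=names, rec_animal=rec_animal,
        rec_pen=rec_pen, pen_ids=list(pen_ids),
        animals=list(df["animal"].astype(str)), spec=spec, n_pedigree=ped.n,
    )


class GibbsError(RuntimeError):
    """Numerical failure inside the sampler (non-PD conditional or divergence)."""


def gibbs_run(assembly: DesignAssembly, A_inv: sp.spmatrix,
              priors: PriorSpec | None = None,
              config: GibbsConfig | None = None,
              sample_location: bool = True,
              start: dict | None = None) -> MCMCChain:
    """Run one chain and return the thinned post-burn-in draws.

    ``sample_location=False`` freezes b, a, c (and hence e) at their starting
    values so the variance draws are iid from their analytic inverse-Wishart
    full conditionals — used to validate conjugacy.  ``start`` may supply
    initial ``b``, ``a``, ``c``, ``G0``, ``C0``, ``R0``.
    """
    if config is None:
        config = GibbsConfig()
    t = assembly.spec.n_traits
    if priors is None:
        priors = PriorSpec.flat(t)
    q = assembly.n_pedigree
    A_inv = sp.csr_matrix(A_inv)
    if A_inv.shape != (q, q):
        raise ValueError("A_inv does not cover the pedigree")
    n = assembly.n_records

    rec_of_animal = np.full(q, -1, dtype=np.int64)
    for r, i in enumerate(assembly.rec_animal):
        if rec_of_animal[i] != -1:
            raise ValueError(f"animal index {i} has multiple records")
        rec_of_animal[i] = r
    order = np.argsort(assembly.rec_pen, kind="stable")
    pen_records = order.astype(np.int64)
    pen_counts = np.bincount(assembly.rec_pen, minlength=assembly.n_pens)
    pen_indptr = np.concatenate([[0], np.cumsum(pen_counts)]).astype(np.int64)

    vy = np.nanvar(assembly.y, axis=0)
    vy = np.where(vy > 0, vy, 1.0)
    start = start or {}
    b = np.asarray(start.get("b", np.zeros((assembly.X.shape[1], t))), float).copy()
    a = np.asarray(start.get("a", np.zeros((q, t))), float).copy()
    c = np.asarray(start.get("c", np.zeros((assembly.n_pens, t))), float).copy()
    G0 = np.asarray(start.get("G0", np.diag(vy / 3.0)), float).copy()
    C0 = np.asarray(start.get("C0", np.diag(vy / 3.0)), float).copy()
    R0 = np.asarray(start.get("R0", np.diag(vy / 3.0)), float).copy()
    if "b" not in start:
        b[0, :] = np.nanmean(assembly.y, axis=0)

    y = assembly.y.copy()
    y[np.isnan(y)] = 0.0
    sxx = (assembly.X ** 2).sum(axis=0)

    G0_d, C0_d, R0_d, err = gibbs_kernel(
        y, assembly.miss, assembly.X, sxx,
        assembly.rec_animal, assembly.rec_pen,
        A_inv.indptr.astype(np.int64), A_inv.indices.astype(np.int64),
        A_inv.data.astype(np.float64),
        rec_of_animal, pen_indptr, pen_records,
        b, a, c, G0, C0, R0,
        priors.S_g.astype(float), float(priors.nu_g),
        priors.S_c.astype(float), float(priors.nu_c),
        priors.S_r.astype(float), float(priors.nu_r),
        int(config.n_iter), int(config.burn_in), int(config.thin),
        int(config.seed) % (2 ** 31), 1 if sample_location else 0,
    )
    if err != 0:
        raise GibbsError(
            f"non-positive-definite conditional or divergent draw at iteration {err - 1}"
        )
    return MCMCChain(traits=assembly.spec.traits, G0=G0_d, C0=C0_d, R0=R0_d,
                     config=config)


def model_seeds(master_seed: int, n_models: int) -> np.ndarray:
    """Per-model seeds derived deterministically from one master seed."""
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2 ** 31 - 1, size=n_models)


def run_all_models(data: pd.DataFrame, ped, A_inv,
                   univariate_traits, pairs=None,
                   config: GibbsConfig | None = None,
                   fixed=DEFAULT_FIXED, covariates=DEFAULT_COVARIATES) -> dict:
    """Univariate chains per trait plus bivariate chains per requested pair.

    Per-model seeds are derived deterministically from ``config.seed`` so the
    whole batch is reproducible.  Returns ``{model_name: MCMCChain}``.
    """
    if config is None:
        config = GibbsConfig()
    pairs = [tuple(p) for p in (pairs or [])]
    specs = [ModelSpec((tr,), fixed, covariates) for tr in univariate_traits]
    specs += [ModelSpec(p, fixed, covariates) for p in pairs]
    seeds = model_seeds(config.seed, len(specs))
    chains = {}
    for spec, seed in zip(specs, seeds):
        cfg = GibbsConfig(n_iter=config.n_iter, burn_in=config.burn_in,
                          thin=config.thin, seed=int(seed))
        assembly = assemble_design(data, spec, ped)
        logger.info("fitting %s (%d records)", spec.name, assembly.n_records)
        chains[spec.name] = gibbs_run(assembly, A_inv, config=cfg)
    return chains


def all_pairs(traits) -> list:
    """All unordered within-set pairs, in canonical order."""
    return list(itertools.combinations(traits, 2))


def cross_pairs(traits_a, traits_b) -> list:
    return [(a, b) for a in traits_a for b in traits_b]
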