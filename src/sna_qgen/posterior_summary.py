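"""Posterior summaries: h2, c2, Vp, genetic correlations, HPD95%, diagnostics.

Ratios are computed draw by draw (never from posterior-mean components), so
posterior uncertainty propagates into the summaries.  "Significant" for a
correlation means its 95% highest-posterior-density interval excludes zero,
the convention used to bold estimates in the result tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gibbs_animal_model import MCMCChain


def derive_ratios(chain: MCMCChain) -> pd.DataFrame:
    """Per-draw h2, c2 and Vp for each trait; correlations for bivariate chains.

    Columns per trait i (1-based): ``h2_i``, ``c2_i``, ``Vp_i``; bivariate
    chains add ``rg`` (genetic), ``rc`` (pen) and ``re`` (residual)
    correlations.
    """
    t = chain.n_traits
    out = {}
    for m in range(t):
        va = chain.G0[:, m, m]
        vc = chain.C0[:, m, m]
        ve = chain.R0[:, m, m]
        vp = va + vc + ve
        if np.any(vp <= 0):
            raise ValueError("zero total variance in a draw")
        out[f"h2_{m + 1}"] = va / vp
        out[f"c2_{m + 1}"] = vc / vp
        out[f"Vp_{m + 1}"] = vp
    if t == 2:
        out["rg"] = chain.G0[:, 0, 1] / np.sqrt(chain.G0[:, 0, 0] * chain.G0[:, 1, 1])
        out["rc"] = chain.C0[:, 0, 1] / np.sqrt(chain.C0[:, 0, 0] * chain.C0[:, 1, 1])
        out["re"] = chain.R0[:, 0, 1] / np.sqrt(chain.R0[:, 0, 0] * chain.R0[:, 1, 1])
    return pd.DataFrame(out)


def hpd_interval(samples, mass: float = 0.95) -> tuple:
    """Shortest contiguous interval over the sorted draws holding ``mass``.

    Exact for unimodal empirical posteriors; the leftmost window wins ties.
    Requires at least 100 draws (10 for mass 1.0, where the interval is
    simply the sample range).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    if n < 100 and mass < 1.0:
        raise ValueError(f"need >= 100 samples for an HPD interval, got {n}")
    k = int(np.ceil(mass * n))
    if k < 2:
        raise ValueError("interval needs at least 2 points")
    widths = x[k - 1:] - x[: n - k + 1]
    lo = int(np.argmin(widths))  # argmin returns the leftmost minimizer
    return float(x[lo]), float(x[lo + k - 1])


def significance_flag(lower: float, upper: float) -> bool:
    """True iff the interval excludes zero (boundary counts as inclusion)."""
    if lower > upper:
        raise ValueError("lower > upper")
    return (lower > 0.0) or (upper < 0.0)


def geweke_diagnostic(samples, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z: mean of the first 10% vs the last 50% of the chain.

    Segment-mean variances use Bartlett-windowed long-run variance estimates
    (lag window ~ sqrt of the segment length), so autocorrelation within each
    segment is accounted for.  A stationary chain gives |z| ~ N(0, 1)-ish;
    large |z| flags a drifting chain.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 1000:
        raise ValueError(f"need >= 1000 samples, got {n}")
    a = x[: int(first * n)]
    b = x[n - int(last * n):]

    def lrv(seg):
        m = seg.size
        seg = seg - seg.mean()
        maxlag = max(1, int(np.sqrt(m)))
        s = np.dot(seg, seg) / m
        for lag in range(1, maxlag + 1):
            gamma = np.dot(seg[:-lag], seg[lag:]) / m
            s += 2.0 * (1.0 - lag / (maxlag + 1.0)) * gamma
        return s

    va, vb = lrv(a), lrv(b)
    denom = va / a.size + vb / b.size
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("degenerate variance in Geweke segments")
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def effective_sample_size(samples) -> float:
    """Bulk effective sample size of one chain (via arviz)."""
    import arviz as az

    return float(az.ess(np.asarray(samples, dtype=float)[None, :]))


def summarize_univariate(chains: dict, mass: float = 0.95) -> pd.DataFrame:
    """Per-trait h2 / c2 / Vp table with posterior means and HPD bounds.

    ``chains`` maps trait name to its univariate :class:`MCMCChain`.
    """
    rows = []
    for trait, chain in chains.items():
        d = derive_ratios(chain)
        row = {"trait": trait}
        for quant, col in (("h2", "h2_1"), ("c2", "c2_1"), ("Vp", "Vp_1")):
            lo, hi = hpd_interval(d[col], mass)
            row[f"{quant}_mean"] = float(d[col].mean())
            row[f"{quant}_sd"] = float(d[col].std(ddof=1))
            row[f"{quant}_lo"] = lo
            row[f"{quant}_hi"] = hi
        try:
            row["geweke_z"] = geweke_diagnostic(d["h2_1"])
        except ValueError:
            row["geweke_z"] = np.nan
        row["ess_h2"] = effective_sample_size(d["h2_1"])
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_correlations(chains: dict, which: str = "rg",
                           mass: float = 0.95) -> pd.DataFrame:
    """Pairwise correlation table from bivariate chains.

    ``chains`` maps (trait_a, trait_b) tuples to bivariate chains; ``which``
    selects the genetic (``rg``), pen (``rc``) or residual (``re``)
    correlation.
    """
    rows = []
    for pair, chain in chains.items():
        trait_a, trait_b = pair
        d = derive_ratios(chain)
        vals = d[which].dropna()
        lo, hi = hpd_interval(vals, mass)
        rows.append({
            "trait_a": trait_a,
            "trait_b": trait_b,
            f"{which}_mean": float(vals.mean()),
            f"{which}_sd": float(vals.std(ddof=1)),
            f"{which}_lo": lo,
            f"{which}_hi": hi,
            "significant": significance_flag(lo, hi),
        })
    return pd.DataFrame(rows)


def spearman_matrix(trait_table: pd.DataFrame, columns=None,
                    min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlations with average-rank ties.

    Correlations with fewer than ``min_pairs`` complete pairs, or involving a
    constant column, are reported as missing.
    """
    cols = list(columns) if columns is not None else list(trait_table.columns)
    df = trait_table[cols].astype(float)
    rho = df.corr(method="spearman", min_periods=min_pairs)
    for col in cols:  # constant columns have zero rank variance: undefined
        vals = df[col].dropna()
        if vals.nunique() <= 1:
            rho.loc[col, :] = np.nan
            rho.loc[:, col] = np.nan
    return rho
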