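"""Correlation and variance-heterogeneity statistics.

Links expression discordance to phenotypic discordance (Spearman maps),
insulin to BMI (per-group OLS), and tests variance homogeneity (Bartlett,
Levene); includes the small-cohort quantile-split + mixture analysis that
separates insulin-concordant from insulin-discordant pairs after splitting
pairs on their mean expression of a buffer gene (NNAT-like).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DiscordanceMatrix
from .errors import ConfigurationError, InsufficientDataError
from . import mixture as mx

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spearman correlation maps
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _exact_rho_null(n: int) -> np.ndarray:
    """All n! Spearman rho values for untied ranks (exact null, n <= 9)."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n**2 - 1)
    vals = [
        1.0 - 6.0 * float(((base - np.asarray(perm, dtype=float)) ** 2).sum()) / denom
        for perm in permutations(range(1, n + 1))
    ]
    return np.sort(np.asarray(vals))


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a t-approximation p (exact enumeration for n<=9).

    Exact p-values use the permutation null of rho over untied ranks and
    are only applied when neither vector has ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and no_ties:
        null = _exact_rho_null(n)
        p = float((np.abs(null) >= abs(rho) - 1e-12).mean())
        return rho, min(p, 1.0)
    if abs(rho) >= 1.0:
        return rho, np.finfo(float).tiny
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


@dataclass
class CorrelationMap:
    rho: pd.DataFrame  # genes x traits
    neglog10p: pd.DataFrame
    cluster_mean_p: pd.DataFrame | None = None  # genes x clusters


def discordance_spearman(
    geneD: DiscordanceMatrix,
    traitD: DiscordanceMatrix,
    cluster_labels: pd.Series | None = None,
) -> CorrelationMap:
    """Gene x trait Spearman correlations of discordances over shared pairs.

    With cluster labels, additionally reports the per-gene mean of the
    correlation p-values over all traits within each cluster.  Constant
    columns yield missing cells with a warning.
    """
    shared = [p for p in geneD.pairs if p in set(traitD.pairs)]
    if len(shared) < 4:
        raise InsufficientDataError(f"only {len(shared)} shared pairs (need >= 4)")
    G = geneD.values.loc[shared]
    T = traitD.values.loc[shared]
    genes, traits = list(G.columns), list(T.columns)
    rho = np.full((len(genes), len(traits)), np.nan)
    pmat = np.full((len(genes), len(traits)), np.nan)
    groups = {"__all__": np.ones(len(shared), dtype=bool)}
    if cluster_labels is not None:
        lab = cluster_labels.reindex(shared)
        groups = {c: (lab == c).to_numpy() for c in sorted(lab.dropna().unique())}
    cluster_p = {c: np.full((len(genes), len(traits)), np.nan) for c in groups}

    gv = G.to_numpy(dtype=float)
    tv = T.to_numpy(dtype=float)
    for j, trait in enumerate(traits):
        y = tv[:, j]
        if np.std(y) == 0:
            log.warning("trait %s constant; correlations undefined", trait)
            continue
        for i in range(len(genes)):
            x = gv[:, i]
            if np.std(x) == 0:
                if j == 0:
                    log.warning("gene %s constant; correlations undefined", genes[i])
                continue
            r, p = spearman_rho_p(x, y)
            rho[i, j] = r
            pmat[i, j] = p
            for c, mask in groups.items():
                if cluster_labels is None:
                    continue
                if mask.sum() >= 4:
                    rc, pc = spearman_rho_p(x[mask], y[mask])
                    cluster_p[c][i, j] = pc
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pmat)
    rho_df = pd.DataFrame(rho, index=genes, columns=traits)
    nl_df = pd.DataFrame(neglog, index=genes, columns=traits)
    cm = None
    if cluster_labels is not None:
        cm = pd.DataFrame(
            {c: np.nanmean(cluster_p[c], axis=1) for c in groups}, index=genes
        )
    return CorrelationMap(rho_df, nl_df, cm)


# ---------------------------------------------------------------------------
# per-group OLS and variance homogeneity
# ---------------------------------------------------------------------------

def group_linear_fit(y: pd.Series, x: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group OLS of y on x: slope, intercept, R^2, slope-test p, n."""
    rows = []
    for g in sorted(pd.unique(groups.dropna())):
        mask = (groups == g).to_numpy()
        xi = x.to_numpy(dtype=float)[mask]
        yi = y.to_numpy(dtype=float)[mask]
        ok = np.isfinite(xi) & np.isfinite(yi)
        xi, yi = xi[ok], yi[ok]
        if len(xi) < 3:
            log.warning("group %s skipped: fewer than 3 points", g)
            continue
        if np.var(xi) == 0:
            log.warning("group %s skipped: zero x-variance", g)
            continue
        res = stats.linregress(xi, yi)
        rows.append(
            {
                "group": g,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r2": float(res.rvalue**2),
                "p": float(res.pvalue),
                "n": int(len(xi)),
            }
        )
    return pd.DataFrame(rows, columns=["group", "slope", "intercept", "r2", "p", "n"])


def adjust_on(y: pd.Series, x: pd.Series) -> pd.Series:
    """OLS residuals of y on x ('insulin adjusted on BMI')."""
    ok = y.notna() & x.notna()
    res = stats.linregress(x[ok].to_numpy(float), y[ok].to_numpy(float))
    out = y - (res.intercept + res.slope * x)
    return out.rename(f"{y.name}_adj" if y.name else "adjusted")


def variance_homogeneity(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    method: str = "bartlett",
) -> tuple[float, float]:
    """Bartlett or Levene (mean-centered) test of equal group variances."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    samples = [s[np.isfinite(s)] for s in samples]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise InsufficientDataError("need >= 2 groups with >= 2 values each")
    if method == "bartlett":
        if any(np.var(s, ddof=1) == 0 for s in samples):
            raise ConfigurationError("bartlett undefined for a zero-variance group")
        stat, p = stats.bartlett(*samples)
    elif method == "levene":
        stat, p = stats.levene(*samples, center="mean")
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# quantile-split + mixture separation of concordant/discordant pairs
# ---------------------------------------------------------------------------

@dataclass
class QuantileSplitResult:
    half: pd.Series  # pair -> 'low' / 'high'
    assignment: pd.Series  # pair -> 'concordant' / 'discordant'
    proportions: pd.DataFrame  # half x assignment proportions
    mixture: object  # fitted 1-D mixture (or None for the degenerate case)


def quantile_split_mixture(
    pair_gene_level: pd.Series,
    pair_discordance: pd.Series,
    seed: int = 0,
) -> QuantileSplitResult:
    """Median split on mean expression + mixture call on |discordance|.

    Pairs are split at the median of their mean expression (the median pair
    goes to the low half); a 1-D two-component Gaussian mixture (shared or
    free variances, chosen by BIC, against a single-component alternative)
    is fit to |discordance| and pairs are assigned concordant (lower-mean
    component) or discordant by posterior.  Proportions are tabulated per
    half.
    """
    pairs = [p for p in pair_gene_level.index if p in set(pair_discordance.index)]
    if len(pairs) < 6:
        raise InsufficientDataError(f"need >= 6 pairs, got {len(pairs)}")
    levels = pair_gene_level.loc[pairs]
    med = float(levels.median())
    half = pd.Series(
        np.where(levels.to_numpy(float) <= med, "low", "high"), index=pairs, name="half"
    )
    absd = pair_discordance.loc[pairs].abs().to_numpy(float)[:, None]

    fits = []
    if np.ptp(absd) > 0:
        for G in (1, 2):
            for cov_model in ("free",) if G == 1 else ("equal-spherical", "free"):
                try:
                    fits.append(
                        mx.fit_mixture_em(
                            absd, G=G, cov_model=cov_model, n_restarts=8, seed=seed
                        )
                    )
                except Exception:  # degenerate restarts on near-constant data
                    continue
    if not fits:
        assignment = pd.Series("concordant", index=pairs, name="assignment")
        props = _proportions(half, assignment)
        return QuantileSplitResult(half, assignment, props, None)
    best = min(fits, key=lambda m: m.bic)
    if best.G == 1:
        assignment = pd.Series("concordant", index=pairs, name="assignment")
    else:
        lower = int(np.argmin(best.means[:, 0]))
        labels = best.posteriors.argmax(axis=1)
        assignment = pd.Series(
            np.where(labels == lower, "concordant", "discordant"),
            index=pairs,
            name="assignment",
        )
    props = _proportions(half, assignment)
    return QuantileSplitResult(half, assignment, props, best)


def _proportions(half: pd.Series, assignment: pd.Series) -> pd.DataFrame:
    tab = pd.crosstab(half, assignment, normalize="index")
    for col in ("concordant", "discordant"):
        if col not in tab.columns:
            tab[col] = 0.0
    return tab[["concordant", "discordant"]]
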