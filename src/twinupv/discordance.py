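"""Co-twin discordance indices.

The discordance index of a trait in a pair is the difference of the
log-transformed values between co-twins, after orienting each pair by a
reference trait (BMI by default): d = log(heavy) - log(light).  Expression
matrices are already on the log2 scale, so expression discordance is the
plain heavy-minus-light difference with log base 2 recorded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DiscordanceMatrix, Orientation, TwinCohort
from .errors import ConfigurationError, InsufficientDataError

log = logging.getLogger(__name__)


def assign_reference(cohort: TwinCohort, reference_trait: str = "bmi") -> Orientation:
    """Orient every pair: light = co-twin with the lower reference value.

    Ties are broken by the lexicographically smaller individual ID becoming
    the light co-twin and are flagged.  Pairs with a missing or nonpositive
    reference value are dropped and listed in the orientation's rejects.
    """
    if reference_trait not in cohort.phenotypes.columns:
        raise ConfigurationError(f"reference trait {reference_trait!r} not in phenotypes")
    records, rejects = [], []
    for pair in cohort.pairs:
        a, b = sorted(cohort.members(pair))
        va = cohort.phenotypes.loc[a, reference_trait]
        vb = cohort.phenotypes.loc[b, reference_trait]
        if pd.isna(va) or pd.isna(vb):
            rejects.append((pair, "missing reference"))
            log.warning("pair %s dropped: missing reference %s", pair, reference_trait)
            continue
        if va <= 0 or vb <= 0:
            rejects.append((pair, "nonpositive reference"))
            log.warning("pair %s dropped: nonpositive reference %s", pair, reference_trait)
            continue
        tie = bool(va == vb)
        light, heavy = (a, b) if va <= vb else (b, a)
        records.append({"pair": pair, "light": light, "heavy": heavy, "tie": tie})
        if tie:
            log.warning("pair %s: reference tie, lexicographic tie-break applied", pair)
    table = pd.DataFrame(records, columns=["pair", "light", "heavy", "tie"])
    table = table.set_index("pair")
    return Orientation(table, reference_trait, rejects)


def trait_discordance(
    cohort: TwinCohort,
    orientation: Orientation,
    traits=None,
    log_base: str = "e",
    max_missing_frac: float = 0.2,
) -> DiscordanceMatrix:
    """Pair x trait matrix of log(heavy) - log(light).

    Nonpositive trait values yield missing cells (reported); a pair's row is
    dropped only when more than ``max_missing_frac`` of its cells are
    missing.
    """
    trait_list = list(traits) if traits is not None else list(cohort.trait_names)
    missing_cols = [t for t in trait_list if t not in cohort.phenotypes.columns]
    if missing_cols:
        raise ConfigurationError(f"traits not in phenotypes: {missing_cols}")
    base = np.e if log_base == "e" else 2.0

    pairs = orientation.pairs
    heavy = cohort.phenotypes.loc[[orientation.heavy(p) for p in pairs], trait_list]
    light = cohort.phenotypes.loc[[orientation.light(p) for p in pairs], trait_list]
    hv = heavy.to_numpy(dtype=float)
    lv = light.to_numpy(dtype=float)
    bad = ~(np.isfinite(hv) & np.isfinite(lv) & (hv > 0) & (lv > 0))
    if bad.any():
        for i, j in zip(*np.nonzero(bad)):
            log.warning(
                "pair %s trait %s: nonpositive/missing value, cell set missing",
                pairs[i], trait_list[j],
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (np.log(hv) - np.log(lv)) / np.log(base)
    d[bad] = np.nan
    values = pd.DataFrame(d, index=pd.Index(pairs, name="pair"), columns=trait_list)
    frac_missing = values.isna().mean(axis=1)
    keep = frac_missing <= max_missing_frac
    for pair in values.index[~keep]:
        log.warning("pair %s dropped: >%d%% cells missing", pair, int(100 * max_missing_frac))
    values = values.loc[keep]
    ori = Orientation(
        orientation.table.loc[values.index],
        orientation.reference_trait,
        list(orientation.rejects) + [(p, "excess missing cells") for p in frac_missing.index[~keep]],
    )
    return DiscordanceMatrix(values, ori, log_base)


def expression_discordance(
    cohort: TwinCohort, orientation: Orientation
) -> DiscordanceMatrix:
    """Pair x gene discordance: heavy minus light log2 expression."""
    if cohort.expression is None:
        raise ConfigurationError("cohort has no expression matrix")
    expr = cohort.expression
    present = set(expr.columns)
    pairs, rows = [], []
    rejects = list(orientation.rejects)
    for pair in orientation.pairs:
        hv, lv = orientation.heavy(pair), orientation.light(pair)
        if hv not in present or lv not in present:
            rejects.append((pair, "absent from expression matrix"))
            log.warning("pair %s dropped: co-twin absent from expression", pair)
            continue
        pairs.append(pair)
        rows.append(expr[hv].to_numpy(dtype=float) - expr[lv].to_numpy(dtype=float))
    if not pairs:
        raise InsufficientDataError("no pairs with expression for both co-twins")
    values = pd.DataFrame(
        np.asarray(rows), index=pd.Index(pairs, name="pair"), columns=expr.index
    )
    ori = Orientation(orientation.table.loc[pairs], orientation.reference_trait, rejects)
    return DiscordanceMatrix(values, ori, log_base="2")


def height_adjusted_traits(cohort: TwinCohort, mass_traits=None) -> TwinCohort:
    """Replace mass traits by mass / height^2 (FatMI/LeanMI analogues).

    Adjusted traits get the suffix ``_hadj``; BMI and height are left
    unchanged.  Individuals with nonpositive height are excluded (and their
    co-twins with them, to keep pairs intact).
    """
    if "height" not in cohort.phenotypes.columns:
        raise ConfigurationError("cohort lacks a height trait")
    if mass_traits is None:
        mass_traits = [
            t
            for t in cohort.trait_names
            if "mass" in t or t == "weight"
        ]
    heights = cohort.phenotypes["height"]
    bad_ind = heights.index[~(heights > 0)]
    pheno = cohort.phenotypes
    if len(bad_ind):
        bad_pairs = set(pheno.loc[bad_ind, "pair"])
        for ind in bad_ind:
            log.warning("individual %s excluded: nonpositive height", ind)
        pheno = pheno[~pheno["pair"].isin(bad_pairs)]
    pheno = pheno.copy()
    new_names = []
    for t in cohort.trait_names:
        if t in mass_traits:
            new = f"{t}_hadj"
            pheno[new] = pheno[t] / pheno["height"] ** 2
            pheno = pheno.drop(columns=[t])
            new_names.append(new)
        else:
            new_names.append(t)
    expr = cohort.expression
    if expr is not None:
        expr = expr[[c for c in expr.columns if c in set(pheno.index)]]
    return TwinCohort(pheno, expr, new_names, cohort.truth)


def zygosity_discordance_test(
    mz: DiscordanceMatrix, dz: DiscordanceMatrix, min_pairs: int = 3
) -> pd.DataFrame:
    """Per-trait one-sided rank-sum test of |d_MZ| < |d_DZ|.

    Returns a table with the mean absolute discordance of each group, the
    Mann-Whitney U statistic and the one-sided p-value.  Traits with fewer
    than ``min_pairs`` finite values in either group are skipped.
    """
    shared = [c for c in mz.columns if c in set(dz.columns)]
    if not shared:
        raise ConfigurationError("matrices share no trait columns")
    rows = []
    for trait in shared:
        a = mz.values[trait].dropna().abs().to_numpy()
        b = dz.values[trait].dropna().abs().to_numpy()
        if len(a) < min_pairs or len(b) < min_pairs:
            log.warning("trait %s skipped: fewer than %d pairs in a group", trait, min_pairs)
            continue
        res = stats.mannwhitneyu(a, b, alternative="less")
        rows.append(
            {
                "trait": trait,
                "mean_abs_mz": float(a.mean()),
                "mean_abs_dz": float(b.mean()),
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows, columns=["trait", "mean_abs_mz", "mean_abs_dz", "statistic", "p"])
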