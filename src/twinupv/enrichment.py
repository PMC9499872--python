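"""Preranked gene-set enrichment with a running-sum statistic.

Genes are sorted by a ranking statistic (here typically the Type-B
heavy-vs-light moderated t); walking down the list, set members add
|stat|^w normalized over members and non-members subtract 1/(N - n_set).
The enrichment score (ES) is the signed maximal deviation of this running
sum, the leading edge is the set members at or before the extremum, and
significance comes from a gene-permutation null (random same-size subsets),
switched to exhaustive subset enumeration when the number of distinct
subsets is small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .signature import _bh_adjust

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with unique members.

    Parsed sets are always non-empty; an empty tuple is permitted only as
    the sentinel result of a derivation that found nothing.
    """

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.genes)


def running_sum_es(
    stats_sorted: np.ndarray, member_mask: np.ndarray, weight_exponent: float = 1.0
) -> tuple[float, int]:
    """ES and extremum position for a sorted stat vector and member mask.

    Hits add |stat|^w / sum_hits |stat|^w; misses subtract 1/(N - n_set).
    Returns (ES, index of the running-sum extremum).  Ties between the
    positive and negative extreme go to the positive side.
    """
    n = len(stats_sorted)
    n_set = int(member_mask.sum())
    if n_set == 0 or n_set == n:
        raise ConfigurationError("degenerate set: 0 or all genes are members")
    w = np.abs(stats_sorted) ** weight_exponent
    hit_w = np.where(member_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member stats are 0 at w>0: fall back to equal steps
        hit_w = member_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~member_mask) / (n - n_set)
    run = np.cumsum(steps)
    imax, imin = int(np.argmax(run)), int(np.argmin(run))
    # ties (to float tolerance) between the extremes go to the positive side
    if run[imax] >= -run[imin] - 1e-12:
        return float(run[imax]), imax
    return float(run[imin]), imin


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    padj: float
    leading_edge: list[str]
    n_perm: int
    size: int


def preranked_enrichment(
    ranked_stats: pd.Series,
    sets: list[GeneSet],
    weight_exponent: float = 1.0,
    n_perm: int = 4000,
    seed: int = 0,
    exhaustive_limit: int = 500,
) -> list[EnrichmentResult]:
    """Preranked enrichment over a list of gene sets.

    The null ES distribution per set size comes from random same-size gene
    subsets (deterministic given seed); when C(N, n_set) <=
    ``exhaustive_limit`` all subsets are enumerated instead, so the p-value
    is exact.  p = (1 + #{same-sign |null| >= |ES|}) / (1 + #same-sign
    nulls); NES = ES / mean |null ES of matching sign|.  BH adjustment is
    applied across sets.  Sets with no member present are skipped with a
    warning; a set covering every ranked gene is an error.
    """
    stats_ = ranked_stats.astype(float)
    if not np.isfinite(stats_.to_numpy()).all():
        raise ConfigurationError("ranked stats must be finite")
    # descending by stat; ties broken by stable gene-name order
    order = stats_.sort_index().sort_values(ascending=False, kind="mergesort")
    genes = list(order.index)
    stat_arr = order.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)

    evaluated = []
    for gs in sets:
        present = [g for g in gs.genes if g in gene_pos]
        if not present:
            log.warning("set %s skipped: no members present", gs.name)
            continue
        if len(present) == n:
            raise ConfigurationError(f"degenerate set {gs.name!r}: covers all genes")
        evaluated.append((gs, present))

    null_cache: dict[int, np.ndarray] = {}

    def null_es(n_set: int) -> np.ndarray:
        if n_set not in null_cache:
            if comb(n, n_set) <= exhaustive_limit:
                vals = []
                for subset in combinations(range(n), n_set):
                    mask = np.zeros(n, dtype=bool)
                    mask[list(subset)] = True
                    vals.append(running_sum_es(stat_arr, mask, weight_exponent)[0])
                null_cache[n_set] = np.asarray(vals)
            else:
                vals = np.empty(n_perm)
                for b in range(n_perm):
                    idx = rng.choice(n, size=n_set, replace=False)
                    mask = np.zeros(n, dtype=bool)
                    mask[idx] = True
                    vals[b] = running_sum_es(stat_arr, mask, weight_exponent)[0]
                null_cache[n_set] = vals
        return null_cache[n_set]

    results = []
    for gs, present in evaluated:
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        es, ipeak = running_sum_es(stat_arr, mask, weight_exponent)
        if es >= 0:
            le = [g for g in genes[: ipeak + 1] if g in set(present)]
        else:
            le = [g for g in genes[ipeak:] if g in set(present)]
        null = null_es(len(present))
        same = null[null >= 0] if es >= 0 else null[null < 0]
        count = int((np.abs(same) >= abs(es)).sum())
        p = (1.0 + count) / (1.0 + len(same))
        denom = float(np.abs(same).mean()) if len(same) else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        results.append(
            EnrichmentResult(
                name=gs.name,
                es=es,
                nes=nes,
                p=p,
                padj=np.nan,
                leading_edge=le,
                n_perm=len(null),
                size=len(present),
            )
        )
    if results:
        padj = _bh_adjust(np.array([r.p for r in results]))
        for r, q in zip(results, padj):
            r.padj = float(q)
    return results


def derive_hdac_signature(
    results: list[EnrichmentResult],
    direction: str = "positive",
    padj_cutoff: float = 0.01,
) -> GeneSet:
    """Union of leading edges over significantly enriched sets.

    Sets qualify when padj < cutoff and the ES sign matches ``direction``
    ("positive" = enriched toward the heavy end of the ranking).  When no
    set qualifies an empty set is returned with a warning.
    """
    sign = 1.0 if direction == "positive" else -1.0
    members: set[str] = set()
    n_sets = 0
    for r in results:
        if r.padj < padj_cutoff and sign * r.es > 0:
            members |= set(r.leading_edge)
            n_sets += 1
    if not members:
        log.warning("no qualifying sets at padj < %g; empty HDAC signature", padj_cutoff)
    return GeneSet(
        "HDAC_signature",
        f"leading-edge union of {n_sets} sets",
        tuple(sorted(members)),
    )


def signature_score(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-individual mean of z-scored expression over the set's genes."""
    present = [g for g in gene_set.genes if g in expr.index]
    if not present:
        raise InsufficientDataError(f"no genes of {gene_set.name!r} present in expression")
    sub = expr.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    return pd.Series(z.mean(axis=0), index=expr.columns, name=f"{gene_set.name}_score")
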