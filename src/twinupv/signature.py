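"""Type-B gene-signature derivation and population stratification.

The signature machinery has four parts:

* a paired moderated differential-expression test (per pair cluster) that
  shrinks gene-wise variances toward a pooled prior by empirical Bayes,
* a specificity filter + k-means step that extracts the genes differential
  in the Type-B cluster but in no other cluster,
* k-means stratification of whole cohorts on the signature with
  saturation-point selection of k and bootstrap Jaccard stability, plus the
  per-individual median-rank (UPV-B rank) score,
* a PC-contribution procedure attributing expression variance to the
  signature via an inflection point on the sorted per-PC association curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.cluster import KMeans

from .cohort import Orientation
from .errors import ConfigurationError, InsufficientDataError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated paired t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to gene-wise variances.

    Works on the log-variance scale: for true variance v, E[log s^2] =
    log v + digamma(df/2) - log(df/2) and Var[log s^2] = trigamma(df/2).
    The excess variance of log s^2 across genes identifies the prior
    degrees of freedom d0; the mean identifies the prior variance s0^2.
    Returns (d0, s0sq); d0 = inf when the observed spread is no larger
    than the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        # a single gene carries no information about a shared prior
        return 0.0, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def paired_moderated_de(
    expr: pd.DataFrame,
    orientation: Orientation,
    pair_clusters: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_pairs: int = 3,
    prior_df: float | None = None,
) -> dict[object, pd.DataFrame]:
    """Per-cluster moderated paired differential expression (heavy - light).

    For each cluster the per-pair heavy-minus-light log differences are
    regressed on an intercept plus centered pair-level covariates; gene-wise
    residual variances are shrunk toward the pooled prior and the moderated
    t is referred to a t distribution with residual + prior df.  BH
    adjustment is applied within each cluster.

    ``prior_df`` overrides the estimated prior degrees of freedom (0 gives
    the ordinary paired t).  Clusters with fewer than ``min_pairs`` pairs
    are skipped with a warning.
    """
    results: dict[object, pd.DataFrame] = {}
    for cluster in sorted(pd.unique(pair_clusters)):
        pairs = [
            p
            for p in pair_clusters.index[pair_clusters == cluster]
            if p in set(orientation.pairs)
        ]
        if len(pairs) < min_pairs:
            log.warning("cluster %s skipped: %d pairs < %d", cluster, len(pairs), min_pairs)
            continue
        heavy = [orientation.heavy(p) for p in pairs]
        light = [orientation.light(p) for p in pairs]
        missing = [i for i in heavy + light if i not in expr.columns]
        if missing:
            raise ConfigurationError(f"individuals absent from expression: {missing[:5]}")
        Y = expr[heavy].to_numpy(dtype=float) - expr[light].to_numpy(dtype=float)
        n = len(pairs)
        X = np.ones((n, 1))
        if covariates is not None:
            cov = covariates.loc[pairs].to_numpy(dtype=float)
            cov = cov - cov.mean(axis=0, keepdims=True)
            keep = cov.std(axis=0) > 0
            if keep.any():
                X = np.hstack([X, cov[:, keep]])
        p_par = X.shape[1]
        df_resid = n - p_par
        if df_resid < 1:
            log.warning("cluster %s skipped: no residual df", cluster)
            continue
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = Y @ X @ XtX_inv  # genes x p
        resid = Y - beta @ X.T
        s2 = (resid**2).sum(axis=1) / df_resid
        if prior_df is None:
            d0, s0sq = fit_variance_prior(s2, df_resid)
        else:
            d0 = float(prior_df)
            _, s0sq = fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_total = 1e6
        elif d0 == 0:
            s2_post = s2
            df_total = df_resid
        else:
            s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
        effect = beta[:, 0]
        se = np.sqrt(np.maximum(s2_post, 1e-300) * XtX_inv[0, 0])
        t = np.where(se > 0, effect / se, 0.0)
        t = np.where((effect == 0) & (se == 0), 0.0, t)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        padj = _bh_adjust(p)
        results[cluster] = pd.DataFrame(
            {
                "gene": expr.index,
                "cluster": cluster,
                "effect": effect,
                "t": t,
                "p": p,
                "padj": padj,
                "n_pairs": n,
            }
        ).set_index("gene")
        results[cluster].attrs["prior_df"] = d0
        results[cluster].attrs["prior_var"] = s0sq
    return results


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    cummin = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(cummin, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Type-B signature
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """Directional gene list with derivation provenance."""

    genes: pd.DataFrame  # index gene, column 'direction'
    alpha: float
    source_cluster: object
    provenance: dict = field(default_factory=dict)

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes.index)

    def direction_of(self, gene: str) -> str:
        return str(self.genes.loc[gene, "direction"])

    def __len__(self) -> int:
        return len(self.genes)


def derive_typeB_signature(
    de_tables: dict,
    typeb_cluster,
    alpha: float = 0.001,
    gene_kmeans_k: int = 2,
    seed: int = 0,
) -> Signature:
    """Genes differential in the Type-B cluster and in no other cluster.

    Candidates (p < alpha in Type-B, p >= alpha everywhere else) are
    k-means-clustered on their absolute per-cluster effect profiles; the
    gene cluster whose centroid maximizes |TypeB effect| / (1 + mean
    |other-cluster effect|) is the signature.  Directions come from the
    sign of the Type-B effect.  An empty candidate set yields an empty
    signature with a warning, not an error.
    """
    if typeb_cluster not in de_tables:
        raise ConfigurationError(f"no DE table for Type-B cluster {typeb_cluster!r}")
    others = [c for c in de_tables if c != typeb_cluster]
    tb = de_tables[typeb_cluster]
    mask = tb["p"] < alpha
    for c in others:
        mask &= de_tables[c]["p"].reindex(tb.index) >= alpha
    candidates = list(tb.index[mask.fillna(False)])
    provenance = {
        "alpha": alpha,
        "n_candidates": len(candidates),
        "gene_kmeans_k": gene_kmeans_k,
        "clusters": [str(c) for c in de_tables],
    }
    if not candidates:
        log.warning("empty Type-B candidate set at alpha=%g", alpha)
        empty = pd.DataFrame(columns=["direction"])
        empty.index.name = "gene"
        return Signature(empty, alpha, typeb_cluster, provenance)

    profiles = np.column_stack(
        [de_tables[c].loc[candidates, "effect"].to_numpy(dtype=float) for c in de_tables]
    )
    tb_col = list(de_tables).index(typeb_cluster)
    k = min(gene_kmeans_k, len(candidates))
    if k >= 2:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(np.abs(profiles))
        centroids = km.cluster_centers_
        other_cols = [i for i in range(profiles.shape[1]) if i != tb_col]
        scores = centroids[:, tb_col] / (
            1.0 + (centroids[:, other_cols].mean(axis=1) if other_cols else 0.0)
        )
        chosen = int(np.argmax(scores))
        selected = [g for g, lab in zip(candidates, km.labels_) if lab == chosen]
    else:
        selected = candidates
    directions = [
        "up_in_heavy" if de_tables[typeb_cluster].loc[g, "effect"] > 0 else "down_in_heavy"
        for g in selected
    ]
    genes = pd.DataFrame({"direction": directions}, index=pd.Index(selected, name="gene"))
    provenance["n_selected"] = len(selected)
    return Signature(genes, alpha, typeb_cluster, provenance)


# ---------------------------------------------------------------------------
# population stratification
# ---------------------------------------------------------------------------

@dataclass
class StratificationResult:
    clusters: pd.Series  # individual -> cluster id (1..k)
    chosen_k: int
    dispersion: pd.Series  # k -> within-cluster sum of squares
    stability: pd.Series | None  # cluster id -> bootstrap Jaccard
    order: list  # individuals ordered by cluster then BMI


def stratify_individuals(
    expr: pd.DataFrame,
    signature: Signature,
    k_max: int = 10,
    n_boot: int = 100,
    seed: int = 0,
    saturation_drop: float = 0.10,
    phenotypes: pd.DataFrame | None = None,
) -> StratificationResult:
    """k-means stratification of individuals on z-scored signature genes.

    The number of clusters is the saturation point of the dispersion
    curve: the smallest k whose relative WSS drop to k+1 falls below
    ``saturation_drop``.  Per-cluster stability is the mean best-match
    Jaccard over ``n_boot`` bootstrap reclusterings (skipped at
    ``n_boot=0``).  Individuals are ordered by BMI within cluster when
    phenotypes are supplied.
    """
    if len(signature) == 0:
        raise ConfigurationError("signature is empty")
    missing = [g for g in signature.gene_names if g not in expr.index]
    if missing:
        raise ConfigurationError(f"signature genes absent from expression: {missing}")
    X = expr.loc[signature.gene_names].to_numpy(dtype=float).T  # individuals x genes
    n = X.shape[0]
    if n < 3 * min(k_max, 3):
        raise InsufficientDataError(f"too few individuals ({n}) for stratification")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd

    k_hi = min(k_max, n - 1)
    wss = {}
    fits = {}
    for k in range(1, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(X)
        wss[k] = float(km.inertia_)
        fits[k] = km
    chosen_k = k_hi
    for k in range(1, k_hi):
        drop = (wss[k] - wss[k + 1]) / wss[k] if wss[k] > 0 else 0.0
        if drop < saturation_drop:
            chosen_k = k
            break
    km = fits[chosen_k]
    raw = km.labels_
    # stable cluster ids 1..k by decreasing size
    sizes = pd.Series(raw).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    labels = pd.Series(
        [remap[v] for v in raw], index=expr.columns, name="cluster", dtype=int
    )

    stability = None
    if n_boot > 0 and chosen_k >= 1:
        rng = np.random.default_rng(seed)
        orig_sets = {c: set(labels.index[labels == c]) for c in sorted(remap.values())}
        acc = {c: [] for c in orig_sets}
        for _ in range(n_boot):
            samp = rng.choice(n, size=n, replace=True)
            uniq = np.unique(samp)
            kmb = KMeans(
                n_clusters=chosen_k, n_init=5,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X[samp])
            boot_labels = kmb.predict(X[uniq])
            boot_sets = {
                b: set(np.asarray(expr.columns)[uniq[boot_labels == b]])
                for b in range(chosen_k)
            }
            for c, members in orig_sets.items():
                inter_members = members & set(np.asarray(expr.columns)[uniq])
                if not inter_members:
                    continue
                best = max(
                    (len(inter_members & bs) / len(inter_members | bs) if (inter_members | bs) else 0.0)
                    for bs in boot_sets.values()
                )
                acc[c].append(best)
        stability = pd.Series(
            {c: (float(np.mean(v)) if v else np.nan) for c, v in acc.items()},
            name="jaccard_stability",
        )

    order = list(expr.columns)
    if phenotypes is not None and "bmi" in phenotypes.columns:
        bmi = phenotypes["bmi"].reindex(expr.columns)
        order = list(
            pd.DataFrame({"cluster": labels, "bmi": bmi})
            .sort_values(["cluster", "bmi"])
            .index
        )
    return StratificationResult(
        clusters=labels,
        chosen_k=chosen_k,
        dispersion=pd.Series(wss, name="wss"),
        stability=stability,
        order=order,
    )


def upvb_rank(expr: pd.DataFrame, signature: Signature) -> pd.Series:
    """Median direction-aligned cohort rank over the signature genes.

    Individuals are ranked 1..n per gene (average ranks on ties); ranks of
    down-regulated genes are reflected (n + 1 - rank) so that a high score
    always means a heavy-like Type-B transcriptional profile.
    """
    if len(signature) == 0:
        raise ConfigurationError("signature is empty")
    if expr.shape[1] < 2:
        raise InsufficientDataError("need at least 2 individuals to rank")
    present = [g for g in signature.gene_names if g in expr.index]
    absent = [g for g in signature.gene_names if g not in expr.index]
    for g in absent:
        log.warning("signature gene %s missing from expression; excluded", g)
    if not present:
        raise ConfigurationError("all signature genes missing from expression")
    sub = expr.loc[present]
    ranks = sub.rank(axis=1, method="average")
    n = expr.shape[1]
    down = [g for g in present if signature.direction_of(g) == "down_in_heavy"]
    ranks.loc[down] = n + 1 - ranks.loc[down]
    return ranks.median(axis=0).rename("upvb_rank")


# ---------------------------------------------------------------------------
# PC-based variance attribution
# ---------------------------------------------------------------------------

@dataclass
class PCContribution:
    selected_pcs: list[int]  # 0-based PC indices, association-sorted order
    cumulative_variance_fraction: float
    association: pd.Series  # PC index -> mean signature contribution
    explained_variance_ratio: np.ndarray
    contributions: np.ndarray | None = None  # genes x PCs, columns sum to 1
    uninformative: bool = False


def pc_signature_contribution(expr: pd.DataFrame, gene_set) -> PCContribution:
    """Share of expression variance carried by signature-associated PCs.

    PCA is run on the centered expression (genes as variables); per PC the
    gene contributions are the squared loadings (summing to 1 per PC), and
    the per-PC association is their mean over the gene set.  PCs sorted by
    descending association are cut at the inflection point (maximal
    discrete second difference of the sorted curve); the cumulative
    explained-variance fraction of the selected PCs is returned.  A flat
    association curve is reported as uninformative.
    """
    genes = list(gene_set)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ConfigurationError(f"gene_set members absent from expression: {missing[:5]}")
    n_ind = expr.shape[1]
    if n_ind < 3:
        raise InsufficientDataError("need at least 3 individuals for PCA")
    X = expr.to_numpy(dtype=float).T  # individuals x genes
    X = X - X.mean(axis=0, keepdims=True)
    # economical SVD: loadings V are genes x PCs with orthonormal columns
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    keep = S > S[0] * 1e-12 if S[0] > 0 else S > 0
    S, Vt = S[keep], Vt[keep]
    V = Vt.T
    evr = S**2 / np.sum(S**2)
    contrib = V**2  # per PC contributions sum to 1 (orthonormal columns)
    rows = [expr.index.get_loc(g) for g in genes]
    association = contrib[rows].mean(axis=0)
    assoc = pd.Series(association, index=np.arange(len(S)), name="association")
    order = np.argsort(-association, kind="mergesort")
    curve = association[order]
    spread = curve.max() - curve.min()
    if spread <= 1e-9 * max(curve.mean(), 1e-300) or len(curve) < 3:
        log.warning("uniform PC association; selection uninformative")
        return PCContribution([], 0.0, assoc, evr, contrib, uninformative=True)
    d2 = curve[:-2] - 2.0 * curve[1:-1] + curve[2:]
    inflection = int(np.argmax(d2)) + 1  # index of the first post-elbow point
    selected = [int(i) for i in order[:inflection]]
    cumvar = float(evr[selected].sum())
    return PCContribution(selected, cumvar, assoc, evr, contrib)
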