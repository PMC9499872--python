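"""Gaussian finite mixture modeling of body-composition data.

An EM implementation supporting a *supervised reference component*: the
wild-type group is first fit as a single Gaussian (closed form), then
mutant genotypes are fit with that component's parameters held fixed and
only the mixing weights and the remaining components free.  Bimodality is
called by BIC against the fixed-reference single-component model, and
animals are classified into morphs (light/heavy/obese) by maximum
posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigurationError, ConvergenceError, InsufficientDataError

log = logging.getLogger(__name__)

COV_MODELS = ("equal-spherical", "free")


@dataclass
class MixtureModel:
    """A fitted Gaussian mixture: parameters, likelihood, BIC, posteriors."""

    weights: np.ndarray  # (G,)
    means: np.ndarray  # (G, d)
    covariances: np.ndarray  # (G, d, d)
    cov_model: str
    log_likelihood: float
    bic: float
    n_params: int
    posteriors: np.ndarray  # (n, G), rows sum to 1
    loglik_trace: list[float] = field(default_factory=list)
    fixed_components: tuple[int, ...] = ()

    @property
    def G(self) -> int:
        return len(self.weights)

    @property
    def dimension(self) -> int:
        return self.means.shape[1]

    def labels(self) -> np.ndarray:
        return self.posteriors.argmax(axis=1)


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _count_params(G: int, d: int, cov_model: str, fixed: tuple[int, ...]) -> int:
    free_comps = G - len(fixed)
    p = (G - 1) + free_comps * d  # weights + free means
    if cov_model == "free":
        p += free_comps * d * (d + 1) // 2
    elif free_comps > 0:
        p += 1  # one shared spherical variance across free components
    return p


def _loglik(X, weights, means, covs) -> tuple[float, np.ndarray]:
    logp = np.column_stack(
        [np.log(weights[g]) + _log_gauss(X, means[g], covs[g]) for g in range(len(weights))]
    )
    tot = logsumexp(logp, axis=1)
    post = np.exp(logp - tot[:, None])
    return float(tot.sum()), post


def _kmeanspp_init(X: np.ndarray, G: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style center seeding."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, G):
        d2 = np.min(
            [((X - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers.append(X[rng.choice(n, p=probs)])
    return np.asarray(centers)


def fit_mixture_em(
    data,
    G: int,
    cov_model: str = "free",
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    fixed_components: dict | None = None,
) -> MixtureModel:
    """EM fit of a G-component Gaussian mixture.

    ``fixed_components`` maps component index -> (mean, cov); those
    parameters are never updated (their mixing weights remain free).  The
    best log-likelihood over ``n_restarts`` k-means++-style initializations
    is kept; the log-likelihood is monotone non-decreasing across
    iterations.  Restarts where a free component degenerates (variance
    collapsing toward zero) are discarded; if every restart degenerates a
    :class:`ConvergenceError` is raised.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if cov_model not in COV_MODELS:
        raise ConfigurationError(f"cov_model must be one of {COV_MODELS}")
    if n < G * (d + 1):
        raise InsufficientDataError(f"n={n} too small for G={G}, d={d}")
    fixed = {int(k): (np.asarray(m, float).reshape(d), np.asarray(c, float).reshape(d, d))
             for k, (m, c) in (fixed_components or {}).items()}
    free_idx = [g for g in range(G) if g not in fixed]

    if G == 1 and not fixed:
        mean = X.mean(axis=0, keepdims=True)
        cov = np.atleast_2d(np.cov(X.T, bias=True)).reshape(1, d, d)
        cov[0] = _regularize(cov[0])
        if cov_model == "equal-spherical":
            cov[0] = np.eye(d) * np.trace(cov[0]) / d
        ll, post = _loglik(X, np.ones(1), mean, cov)
        n_par = _count_params(1, d, cov_model, ())
        return MixtureModel(
            np.ones(1), mean, cov, cov_model, ll,
            -2.0 * ll + n_par * np.log(n), n_par, post, [ll],
        )

    var_floor = 1e-8 * max(float(np.var(X)), 1e-12)
    root = np.random.SeedSequence(seed)
    best: MixtureModel | None = None
    for restart_seed in root.spawn(n_restarts):
        rng = np.random.default_rng(restart_seed)
        means = _kmeanspp_init(X, G, rng)
        base_cov = _regularize(np.atleast_2d(np.cov(X.T, bias=True)).reshape(d, d))
        covs = np.repeat(base_cov[None], G, axis=0)
        weights = np.full(G, 1.0 / G)
        for g, (m, c) in fixed.items():
            means[g], covs[g] = m, c
        trace: list[float] = []
        degenerate = False
        prev = -np.inf
        for _ in range(max_iter):
            try:
                ll, post = _loglik(X, weights, means, covs)
            except np.linalg.LinAlgError:
                degenerate = True
                break
            trace.append(ll)
            if ll - prev < tol * max(1.0, abs(ll)) and len(trace) > 1:
                break
            prev = ll
            nk = post.sum(axis=0)
            if np.any(nk < 1e-8):
                degenerate = True
                break
            weights = nk / n
            for g in free_idx:
                means[g] = (post[:, g] @ X) / nk[g]
            if cov_model == "free":
                for g in free_idx:
                    diff = X - means[g]
                    cov = (post[:, g][:, None] * diff).T @ diff / nk[g]
                    if np.any(np.diag(cov) < var_floor):
                        degenerate = True
                        break
                    covs[g] = _regularize(cov)
            else:
                num = 0.0
                den = 0.0
                for g in free_idx:
                    diff = X - means[g]
                    num += float((post[:, g][:, None] * diff**2).sum())
                    den += float(nk[g])
                if den > 0:
                    sigma2 = num / (den * d)
                    if sigma2 < var_floor:
                        degenerate = True
                    for g in free_idx:
                        covs[g] = np.eye(d) * sigma2
            if degenerate:
                break
        if degenerate or not trace:
            continue
        ll, post = _loglik(X, weights, means, covs)
        n_par = _count_params(G, d, cov_model, tuple(fixed))
        model = MixtureModel(
            weights.copy(), means.copy(), covs.copy(), cov_model, ll,
            -2.0 * ll + n_par * np.log(n), n_par, post, trace,
            tuple(sorted(fixed)),
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if best is None:
        raise ConvergenceError(
            f"all {n_restarts} EM restarts degenerated (G={G}, cov_model={cov_model})"
        )
    return best


def _regularize(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    tr = float(np.trace(cov))
    if tr <= 0:
        tr = 1.0
    if np.linalg.eigvalsh(cov).min() > 1e-10 * tr:
        return cov
    log.warning("singular covariance; ridge of 1e-6 * trace added")
    return cov + np.eye(d) * 1e-6 * tr


def fit_reference_model(wt_data) -> MixtureModel:
    """Single-Gaussian fit of the wild-type group (closed-form moments).

    Singular covariances are handled by a small ridge (flagged via a
    warning).  Default usage is 2-D over (fat mass, lean mass).
    """
    X = np.asarray(wt_data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 3:
        raise InsufficientDataError("need >= 3 reference animals")
    d = X.shape[1]
    mean = X.mean(axis=0, keepdims=True)
    cov = np.atleast_2d(np.cov(X.T, bias=True)).reshape(1, d, d)
    cov[0] = _regularize_always(cov[0])
    ll, post = _loglik(X, np.ones(1), mean, cov)
    n_par = _count_params(1, d, "free", ())
    return MixtureModel(
        np.ones(1), mean, cov, "free", ll,
        -2.0 * ll + n_par * np.log(X.shape[0]), n_par, post, [ll],
    )


def _regularize_always(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    tr = float(np.trace(cov))
    if tr <= 0:
        tr = 1.0
    if np.linalg.eigvalsh(cov).min() > 1e-10 * tr:
        return cov
    log.warning("degenerate reference covariance; ridge applied")
    return cov + np.eye(d) * 1e-6 * tr


@dataclass
class MorphClassification:
    labels: pd.Series | np.ndarray  # light/heavy(/obese) per animal
    posteriors: np.ndarray
    model: MixtureModel | None
    reference_bic: float
    delta_bic: float  # reference-only BIC minus mixture BIC; > 0 = separation
    separated: bool


MORPHS = ("light", "heavy", "obese")


def classify_morphs(
    reference: MixtureModel,
    mutant_data,
    G: int = 2,
    cov_model: str = "free",
    n_restarts: int = 10,
    seed: int = 0,
) -> MorphClassification:
    """Classify mutant animals against the fixed wild-type reference.

    A G-component mixture is fit with component 0 pinned at the reference
    parameters (only the weights and the other components free); evidence
    for separation is the BIC improvement over the reference-only (G=1,
    all parameters fixed) model.  Free components are ordered by total
    mass so labels map to light/heavy(/obese).  An EM collapse onto the
    reference is reported as no separation, not an error.
    """
    X = np.asarray(mutant_data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 6:
        raise InsufficientDataError("need >= 6 mutant animals")
    ref_mean = reference.means[0]
    ref_cov = reference.covariances[0]
    ll_ref, _ = _loglik(X, np.ones(1), ref_mean[None], ref_cov[None])
    bic_ref = -2.0 * ll_ref  # zero free parameters

    try:
        model = fit_mixture_em(
            X, G=G, cov_model=cov_model, n_restarts=n_restarts, seed=seed,
            fixed_components={0: (ref_mean, ref_cov)},
        )
    except ConvergenceError:
        log.warning("free components collapsed; no separation")
        labels = np.array(["light"] * X.shape[0])
        return MorphClassification(labels, np.ones((X.shape[0], 1)), None, bic_ref, -np.inf, False)

    delta = bic_ref - model.bic
    separated = delta > 0
    if not separated:
        labels = np.array(["light"] * X.shape[0])
        post = np.ones((X.shape[0], 1))
        return MorphClassification(labels, post, model, bic_ref, float(delta), False)
    # order non-reference components by total mass (row sum of the mean)
    free = [g for g in range(model.G) if g != 0]
    order = [0] + sorted(free, key=lambda g: float(model.means[g].sum()))
    name_of = {g: MORPHS[i] for i, g in enumerate(order)}
    hard = model.labels()
    labels = np.array([name_of[int(g)] for g in hard])
    return MorphClassification(labels, model.posteriors, model, bic_ref, float(delta), True)
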