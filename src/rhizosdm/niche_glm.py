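"""Multivariate GLM niche test, coefficient biplot, and distribution grouping.

The niche test follows the mvabund/manyglm approach for multivariate
abundance data: an independent negative-binomial (log link) GLM per
genus, a multivariate statistic formed by summing per-genus
likelihood-ratio statistics for the environmental predictors, and a
permutation null obtained by resampling predictor rows against the count
matrix.  Genus niche positions are visualized by a PCA biplot of the
standardized coefficient matrix.  Latitudinal/longitudinal distribution
grouping uses Kruskal–Wallis with tie correction plus pairwise Dunn
z-tests summarized as a compact letter display.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings as _warnings
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .envpair import CuratedFrame, impute_for_model

logger = logging.getLogger(__name__)

_MIN_ALPHA = 1e-8
_MAX_ALPHA = 100.0


# ---------------------------------------------------------------------------
# Negative-binomial GLM (NB2, log link)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class NBFit:
    """A fitted NB2 log-link GLM: coefficients, likelihood, dispersion."""

    coef: np.ndarray
    llf: float
    deviance: float
    alpha: float
    converged: bool
    degenerate: bool = False


def _mom_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB2 dispersion: solves sum (y-mu)^2 = sum mu + a mu^2."""
    num = float(((y - mu) ** 2 - mu).sum())
    den = float((mu**2).sum())
    if den <= 0:
        return _MIN_ALPHA
    return float(np.clip(num / den, _MIN_ALPHA, _MAX_ALPHA))


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; the Poisson limit is used for tiny dispersion."""
    mu = np.clip(mu, 1e-12, None)
    if alpha < 1e-6:
        return float((y * np.log(mu) - mu - gammaln(y + 1)).sum())
    inv = 1.0 / alpha
    ll = (
        gammaln(y + inv)
        - gammaln(inv)
        - gammaln(y + 1)
        + y * np.log(alpha * mu / (1.0 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    )
    return float(ll.sum())


def nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float,
    beta0: Optional[np.ndarray] = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool]:
    """Fixed-dispersion NB2 IRLS (log link); returns (beta, llf, converged).

    This is the fast inner solver used inside the permutation loop; the
    public :func:`fit_nb_glm` goes through statsmodels and updates the
    dispersion.  A unit test pins the two against each other.
    """
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 1e-8))
    else:
        beta = beta0.copy()
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)          # IRLS weight for NB2, log link
        z = eta + (y - mu) / mu              # working response
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        beta = beta_new
        ll = nb_loglik(y, np.exp(np.clip(X @ beta, -30.0, 30.0)), alpha)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30.0, 30.0)
    return beta, nb_loglik(y, np.exp(eta), alpha), converged


def fit_nb_glm(
    counts: Sequence[float] | np.ndarray,
    X: np.ndarray,
    max_outer: int = 5,
) -> NBFit:
    """Negative-binomial log-link GLM with method-of-moments dispersion.

    The mean model is fit by IRLS (statsmodels GLM) at a fixed dispersion
    ``alpha``, which is then re-estimated from Pearson-type moments and
    the fit repeated until the dispersion stabilizes.  ``X`` is the full
    design matrix (include an intercept column).

    All-zero counts admit no finite intercept under the log link; the fit
    is returned flagged ``degenerate`` with a floored intercept instead
    of raising.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or len(y) != len(X):
        raise ValueError("counts and design matrix must align row-wise")
    if (y < 0).any():
        raise ValueError("negative count present")
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    p = X.shape[1]
    if y.sum() == 0:
        beta = np.zeros(p)
        beta[0] = -30.0  # exp(-30) ~ 0: guarded stand-in for -inf intercept
        mu = np.exp(np.clip(X @ beta, -30, 30))
        return NBFit(coef=beta, llf=nb_loglik(y, mu, _MIN_ALPHA), deviance=0.0,
                     alpha=_MIN_ALPHA, converged=True, degenerate=True)

    with _warnings.catch_warnings():
        # sparse overdispersed counts routinely trip statsmodels' perfect-
        # separation heuristic and 0/0 deviance terms; both are benign here
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        _warnings.filterwarnings("ignore", message=".*[Pp]erfect separation.*")
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        alpha = _mom_alpha(y, np.asarray(pois.fittedvalues))
        res = pois
        for _ in range(max_outer):
            res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            new_alpha = _mom_alpha(y, np.asarray(res.fittedvalues))
            if abs(new_alpha - alpha) < 1e-6 * (alpha + 1e-6):
                alpha = new_alpha
                break
            alpha = new_alpha
    mu = np.asarray(res.fittedvalues)
    return NBFit(
        coef=np.asarray(res.params),
        llf=nb_loglik(y, mu, alpha),
        deviance=float(res.deviance),
        alpha=alpha,
        converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# Multivariate (manyglm-style) permutation test
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MvGLMResult:
    coefficients: pd.DataFrame     # genus x (intercept + predictors)
    deviances: dict[str, float]
    statistic: float               # sum of per-genus LR statistics
    p_value: float
    n_resamples: int
    seed: int
    alphas: dict[str, float] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)


def manyglm_test(
    frame: CuratedFrame,
    predictors: Sequence[str] | None = None,
    n_resamples: int = 999,
    seed: int = 0,
) -> MvGLMResult:
    """Multivariate NB-GLM niche test with a row-permutation null.

    The observed statistic is the sum over genera of the likelihood-ratio
    statistic comparing the full model (intercept + standardized
    predictors) to the intercept-only null, each at the genus' observed
    dispersion.  Predictor rows are permuted jointly against the counts
    to build the null distribution; ``p = (1 + #{perm >= obs}) / (1 + B)``.
    """
    if len(frame.genera) < 2:
        raise ValueError("need at least two genera for the multivariate test")
    warnings: list[str] = []
    if n_resamples < 99:
        warnings.append(f"n_resamples={n_resamples} is low; p-values are coarse")
        logger.warning(warnings[-1])

    preds = list(predictors) if predictors is not None else list(frame.predictors)
    Ximp, _ = impute_for_model(frame)
    Z = Ximp[preds].to_numpy()
    sd = Z.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [p for p, k in zip(preds, keep) if not k]
        warnings.append(f"dropped constant predictors: {dropped}")
        preds = [p for p, k in zip(preds, keep) if k]
        Z = Z[:, keep]
        sd = sd[keep]
    Z = (Z - Z.mean(axis=0)) / sd
    n = len(Z)
    X_full = np.column_stack([np.ones(n), Z])

    counts = frame.counts()
    coef_rows, deviances, alphas = {}, {}, {}
    llf_full, llf_null, stats_obs = {}, {}, {}
    for g in frame.genera:
        y = counts[g].to_numpy(dtype=float)
        fit = fit_nb_glm(y, X_full)
        coef_rows[g] = fit.coef
        deviances[g] = fit.deviance
        alphas[g] = fit.alpha
        if fit.degenerate:
            warnings.append(f"genus {g}: all-zero counts, excluded from statistic")
            stats_obs[g] = 0.0
            continue
        # intercept-only null at the same dispersion (closed-form mean)
        mu0 = np.full(n, y.mean())
        llf_null[g] = nb_loglik(y, mu0, fit.alpha)
        llf_full[g] = fit.llf
        stats_obs[g] = max(0.0, 2.0 * (fit.llf - llf_null[g]))

    statistic = float(sum(stats_obs.values()))

    rng = np.random.default_rng(seed)
    exceed = 0
    active = [g for g in frame.genera if g in llf_null]
    ys = {g: counts[g].to_numpy(dtype=float) for g in active}
    starts = {g: coef_rows[g].copy() for g in active}  # warm starts
    for _ in range(n_resamples):
        perm = rng.permutation(n)
        Xp = np.column_stack([np.ones(n), Z[perm]])
        stat_p = 0.0
        for g in active:
            _, llf, _ = nb_irls(ys[g], Xp, alphas[g], beta0=starts[g])
            stat_p += max(0.0, 2.0 * (llf - llf_null[g]))
        if stat_p >= statistic - 1e-12:
            exceed += 1
    p_value = (1.0 + exceed) / (1.0 + n_resamples)

    coef_df = pd.DataFrame.from_dict(coef_rows, orient="index",
                                     columns=["intercept"] + preds)
    coef_df.index.name = "genus"
    return MvGLMResult(
        coefficients=coef_df,
        deviances=deviances,
        statistic=statistic,
        p_value=p_value,
        n_resamples=n_resamples,
        seed=seed,
        alphas=alphas,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Coefficient biplot
# ---------------------------------------------------------------------------


def niche_biplot(
    coefficients: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Project the standardized genus x predictor coefficients to 2 axes.

    Returns (scores, explained_variance_ratio, loadings).  Axis signs are
    fixed deterministically: the largest-magnitude loading on each axis
    is made positive.  Requires at least three genera.
    """
    C = coefficients.drop(columns=["intercept"], errors="ignore")
    if len(C) < 3:
        raise ValueError("biplot undefined for fewer than 3 genera")
    M = C.to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=0)
    keep = sd > 0
    M = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    cols = C.columns[keep]
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    k = min(2, len(S))
    scores = U[:, :k] * S[:k]
    load = Vt[:k]
    for ax in range(k):
        j = np.argmax(np.abs(load[ax]))
        if load[ax, j] < 0:
            load[ax] = -load[ax]
            scores[:, ax] = -scores[:, ax]
    if k < 2:  # degenerate rank-1 case: pad a zero axis
        scores = np.column_stack([scores, np.zeros(len(scores))])
        load = np.vstack([load, np.zeros(load.shape[1])])
    var = S**2
    explained = var / var.sum() if var.sum() > 0 else var
    scores_df = pd.DataFrame(scores, index=C.index, columns=["PC1", "PC2"])
    load_df = pd.DataFrame(load.T, index=cols, columns=["PC1", "PC2"])
    return scores_df, explained[:2], load_df


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn compact letter display
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GroupLetters:
    letters: dict[str, str]
    alpha: float
    statistic: float          # Kruskal-Wallis chi-squared (tie-corrected)
    p_value: float
    pairwise_p: pd.DataFrame


def _dunn_pairwise(groups: Mapping[str, np.ndarray],
                   adjust: str = "none") -> pd.DataFrame:
    """Two-sided Dunn z-test p-values on pooled ranks with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = np.array([len(groups[g]) for g in labels])
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    # mean rank per group
    mean_rank = {}
    start = 0
    for g, m in zip(labels, sizes):
        mean_rank[g] = ranks[start:start + m].mean()
        start += m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    base_var = N * (N + 1) / 12.0 - tie_term
    P = pd.DataFrame(np.ones((len(labels), len(labels))),
                     index=labels, columns=labels)
    raw = []
    pairs = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            se = np.sqrt(base_var * (1.0 / len(groups[gi]) + 1.0 / len(groups[gj])))
            z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            raw.append(p)
            pairs.append((gi, gj))
    if adjust == "holm":
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 0.0
        for rank_pos, idx in enumerate(order):
            running = max(running, (m - rank_pos) * raw[idx])
            adj[idx] = min(1.0, running)
        raw = list(adj)
    elif adjust != "none":
        raise ValueError(f"unknown adjustment: {adjust}")
    for (gi, gj), p in zip(pairs, raw):
        P.loc[gi, gj] = P.loc[gj, gi] = p
    return P


def kruskal_dunn_letters(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    adjust: str = "none",
) -> GroupLetters:
    """Kruskal–Wallis test plus Dunn post-hoc letters.

    Letters come from the maximal cliques of the non-significance graph,
    so two groups share a letter exactly when their pairwise Dunn test is
    non-significant at ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) == 0:
            raise ValueError(f"group {g} is empty")
    stat, p = stats.kruskal(*arrays.values())
    pairwise = _dunn_pairwise(arrays, adjust=adjust)

    labels = list(arrays)
    G = nx.Graph()
    G.add_nodes_from(labels)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            if pairwise.loc[gi, gj] >= alpha:
                G.add_edge(gi, gj)
    cliques = [tuple(sorted(c, key=labels.index)) for c in nx.find_cliques(G)]
    # deterministic letter order: cliques sorted by earliest member
    cliques.sort(key=lambda c: tuple(labels.index(g) for g in c))
    assigned: dict[str, list[str]] = {g: [] for g in labels}
    for li, clique in enumerate(cliques):
        letter = _letter(li)
        for g in clique:
            assigned[g].append(letter)
    letters = {g: "".join(sorted(v)) for g, v in assigned.items()}
    return GroupLetters(letters=letters, alpha=alpha, statistic=float(stat),
                        p_value=float(p), pairwise_p=pairwise)


def _letter(i: int) -> str:
    out = ""
    while True:
        out = chr(ord("a") + i % 26) + out
        i = i // 26 - 1
        if i < 0:
            return out
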