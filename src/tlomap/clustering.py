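"""Spatial spot clustering and cluster-level differential expression.

The embedding pipeline follows the classic recipe: PCA on the
normalized, variable-gene-restricted matrix; the number of informative
components chosen by a column-permutation test (Buja-Eyuboglu style,
BH-controlled at 5% FDR); a 3-component tSNE of the retained scores;
and ward.D2 hierarchical clustering of the tSNE coordinates with the
tree cut at a preset k. Cluster markers come from a per-gene negative
binomial GLM likelihood-ratio test with a log-depth offset, gated at
p < 0.001 and log-ratio > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from anndata import AnnData
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError

PC_SELECTION_FDR = 0.05
MIN_PCS = 2


@dataclass
class EmbeddingResult:
    pca_scores: np.ndarray  # spots x max_pcs
    explained_variance: np.ndarray
    perm_pvalues: np.ndarray
    perm_pvalues_bh: np.ndarray
    n_pcs_selected: int
    tsne: np.ndarray | None = None


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-spot label in 1..k
    k: int
    linkage: str = "ward.D2 on tSNE"
    scope: str = "whole_volume"


def pca_with_permutation(
    X: np.ndarray, max_pcs: int = 15, n_perm: int = 199, seed: int = 0
) -> EmbeddingResult:
    """PCA with a permutation test for the number of informative PCs.

    Each permuted dataset shuffles every gene column independently
    across spots, destroying inter-gene structure while preserving
    marginals. The rank-r p-value is the fraction of permutations whose
    rank-r eigenvalue reaches the observed one; BH adjustment is applied
    across ranks and components with adjusted p < 0.05 are retained
    (never fewer than 2, so a downstream embedding always exists).

    ``n_perm`` must be large enough that ``1/(n_perm+1)`` survives the
    BH correction over ``max_pcs`` ranks; the default 199 gives a
    granularity of 0.005.
    """
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    if n < max_pcs + 1 or g < max_pcs + 1:
        raise ParameterError(f"need more than max_pcs={max_pcs} spots and genes")
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives poor p-value resolution")
    rng = np.random.default_rng(seed)
    pca = PCA(n_components=max_pcs, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(X)
    observed = pca.explained_variance_.copy()

    exceed = np.zeros(max_pcs)
    for _ in range(n_perm):
        Xp = rng.permuted(X, axis=0)
        null_ev = (
            PCA(n_components=max_pcs, svd_solver="randomized", random_state=seed)
            .fit(Xp)
            .explained_variance_
        )
        exceed += null_ev >= observed
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    reject, bh, _, _ = multipletests(pvals, alpha=PC_SELECTION_FDR, method="fdr_bh")
    n_sel = max(MIN_PCS, int(reject.sum()))
    return EmbeddingResult(scores, observed, pvals, bh, n_sel)


def embed_tsne(
    emb: EmbeddingResult,
    n_components: int = 3,
    perplexity: float = 30.0,
    seed: int = 0,
) -> EmbeddingResult:
    """3-component tSNE of the selected PCA scores (deterministic per seed)."""
    scores = emb.pca_scores[:, : emb.n_pcs_selected]
    n = scores.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ParameterError(f"perplexity {perplexity} too large for {n} spots")
    # PCA init needs at least n_components input dimensions
    init = "pca" if scores.shape[1] >= n_components else "random"
    tsne = TSNE(
        n_components=n_components,
        perplexity=perplexity,
        random_state=seed,
        init=init,
        learning_rate="auto",
    )
    emb.tsne = tsne.fit_transform(scores)
    return emb


def cluster_ward(
    emb: EmbeddingResult,
    k: int,
    density: np.ndarray | None = None,
    scope: str = "whole_volume",
) -> ClusterAssignment:
    """Cut a ward.D2 tree of the tSNE coordinates at k clusters.

    Labels are renumbered so cluster 1 has the highest mean ``density``
    (when provided) — the infiltrate/TLO cluster by convention — or the
    most spots otherwise.
    """
    if emb.tsne is None:
        raise ValidationError("run embed_tsne first")
    pts = emb.tsne
    n_distinct = len(np.unique(pts, axis=0))
    if not 2 <= k <= pts.shape[0] or k > n_distinct:
        raise ParameterError(f"k={k} invalid for {n_distinct} distinct points")
    raw = fcluster(linkage(pts, method="ward"), t=k, criterion="maxclust")
    ids = np.unique(raw)
    if density is not None:
        order = sorted(ids, key=lambda c: -np.mean(np.asarray(density)[raw == c]))
    else:
        order = sorted(ids, key=lambda c: -(raw == c).sum())
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([relabel[c] for c in raw])
    return ClusterAssignment(labels, k, scope=scope)


# ---------------------------------------------------------------------------
# differential expression


def _mom_dispersion(y: np.ndarray, mu: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion alpha with var = mu + alpha mu^2."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return max(num / den if den > 0 else 0.0, floor)


def de_between_clusters(
    adata: AnnData,
    assignment: ClusterAssignment,
    p_threshold: float = 0.001,
    logratio_threshold: float = 0.5,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Cluster-vs-rest NB GLM likelihood-ratio tests for every gene.

    Per gene, an NB GLM with log-depth offset and a cluster indicator is
    compared against the intercept-only model (chi-square, 1 df); the
    dispersion is a per-gene method-of-moments estimate shared by both
    fits. The log-ratio is the difference of mean log1p size-factor-
    normalized expression in the cluster versus the rest. A gene is
    flagged DE iff p < ``p_threshold`` and log-ratio > ``logratio_threshold``.
    """
    labels = np.asarray(assignment.labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ParameterError("need at least 2 clusters")
    sizes = {c: int((labels == c).sum()) for c in clusters}
    small = [c for c, s in sizes.items() if s < min_cluster_size]
    if small:
        raise ParameterError(f"clusters below {min_cluster_size} spots: {small}")

    X = adata.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    X = X.astype(float)
    totals = X.sum(axis=1)
    offset = np.log(totals)
    sf = totals / np.median(totals)
    lognorm = np.log1p(X / sf[:, None])

    rows = []
    ones = np.ones((len(labels), 1))
    for j, gene in enumerate(adata.var_names):
        y = X[:, j]
        if y.sum() == 0:
            for c in clusters:
                rows.append((gene, int(c), 0.0, 0.0, 1.0))
            continue
        mu0 = totals * (y.sum() / totals.sum())
        alpha = _mom_dispersion(y, mu0)
        family = sm.families.NegativeBinomial(alpha=alpha)
        try:
            null = sm.GLM(y, ones, family=family, offset=offset).fit()
            ll0 = null.llf
        except Exception:  # noqa: BLE001 - degenerate gene
            for c in clusters:
                rows.append((gene, int(c), 0.0, 0.0, 1.0))
            continue
        for c in clusters:
            ind = (labels == c).astype(float)
            lr = lognorm[ind == 1, j].mean() - lognorm[ind == 0, j].mean()
            design = np.column_stack([np.ones_like(ind), ind])
            try:
                full = sm.GLM(y, design, family=family, offset=offset).fit()
                lrt = max(2.0 * (full.llf - ll0), 0.0)
                p = float(stats.chi2.sf(lrt, df=1))
            except Exception:  # noqa: BLE001
                lrt, p = 0.0, 1.0
            rows.append((gene, int(c), float(lr), float(lrt), p))

    frame = pd.DataFrame(
        rows, columns=["gene", "cluster", "log_ratio", "lrt_statistic", "p_value"]
    )
    frame["bh_adjusted_p"] = np.nan
    for c in clusters:
        mask = frame["cluster"] == c
        frame.loc[mask, "bh_adjusted_p"] = multipletests(
            frame.loc[mask, "p_value"], method="fdr_bh"
        )[1]
    frame["is_de"] = (frame["p_value"] < p_threshold) & (
        frame["log_ratio"] > logratio_threshold
    )
    return frame


def group_compare(values_a: pd.DataFrame, values_b: pd.DataFrame) -> pd.DataFrame:
    """Welch t test per feature between two spot groups, BH adjusted.

    ``values_a`` / ``values_b`` are observations x features with shared
    columns. Features with zero variance on both sides and equal means
    get p = 1. Significance is adjusted p <= 0.05.
    """
    features = list(values_a.columns)
    if list(values_b.columns) != features:
        raise ValidationError("feature columns differ between groups")
    if len(values_a) < 2 or len(values_b) < 2:
        raise ParameterError("each group needs at least 2 observations")
    ts, ps = [], []
    for f in features:
        a = values_a[f].to_numpy(dtype=float)
        b = values_b[f].to_numpy(dtype=float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                ts.append(0.0)
                ps.append(1.0)
                continue
            ts.append(np.inf if a.mean() > b.mean() else -np.inf)
            ps.append(0.0)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        ts.append(float(t))
        ps.append(float(p))
    bh = multipletests(ps, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature": features,
            "t": ts,
            "p": ps,
            "bh_p": bh,
            "significant": bh <= 0.05,
        }
    )
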