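"""Receptor-ligand interaction scoring and gene-set over-representation.

Interaction scoring follows the familiar permutation scheme: for a
receptor-ligand pair and a spot subset, the statistic is the mean of the
two partners' average normalized expression in the subset; the null
distribution permutes the subset labels across all spots. A pair is
reported when its log mean-expression ratio against the whole volume
exceeds 0.1 with permutation p < 0.01. Enrichment is a one-sided
hypergeometric over-representation test against user gene sets, BH
controlled at 5% FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError, ParameterError, ValidationError

LOG_RATIO_MIN = 0.1
INTERACTION_P_MAX = 0.01
MIN_SUBSET_SPOTS = 5


def score_interactions(
    adata: AnnData,
    labels: np.ndarray | pd.Series,
    pairs: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    layer: str = "normalized",
    subsets: list | None = None,
) -> pd.DataFrame:
    """Permutation test of receptor-ligand co-expression per spot subset.

    ``pairs`` has columns ``gene_a``, ``gene_b`` (optional ``name``).
    The p-value uses the add-one convention ``(1 + #{null >= obs}) /
    (n_perm + 1)`` so it is never zero. ``log_mean_ratio`` is the
    natural log of the subset statistic over the all-spot statistic.
    """
    labels = np.asarray(labels)
    if subsets is None:
        subsets = sorted(pd.unique(labels).tolist())
    for subset in subsets:
        if (labels == subset).sum() < MIN_SUBSET_SPOTS:
            raise ValidationError(
                f"subset {subset!r} has fewer than {MIN_SUBSET_SPOTS} spots"
            )
    Y = adata.layers[layer] if layer in adata.layers else adata.X
    Y = Y.toarray() if sp.issparse(Y) else np.asarray(Y, dtype=float)

    genes_needed = []
    usable = []
    for row in pairs.itertuples(index=False):
        if row.gene_a in adata.var_names and row.gene_b in adata.var_names:
            usable.append(row)
            genes_needed += [row.gene_a, row.gene_b]
        else:
            warnings.warn(f"pair ({row.gene_a}, {row.gene_b}) skipped: partner missing")
    if not usable:
        raise EmptyResultError("no scoreable pairs")
    gene_list = sorted(set(genes_needed))
    gidx = {g: i for i, g in enumerate(gene_list)}
    E = Y[:, [adata.var_names.get_loc(g) for g in gene_list]]  # spots x needed genes

    rng = np.random.default_rng(seed)
    n = len(labels)
    subset_masks = {s: labels == s for s in subsets}
    # null: per permutation, the subset-mean of each needed gene under
    # shuffled labels (one shared shuffle per permutation, as in label
    # permutation of the whole volume)
    null = {s: np.empty((n_perm, E.shape[1])) for s in subsets}
    for p in range(n_perm):
        perm = rng.permutation(n)
        Ep = E[perm]
        for s in subsets:
            null[s][p] = Ep[subset_masks[s]].mean(axis=0)
    global_mean = E.mean(axis=0)

    rows = []
    for row in usable:
        ia, ib = gidx[row.gene_a], gidx[row.gene_b]
        name = getattr(row, "name", f"{row.gene_a}_{row.gene_b}")
        for s in subsets:
            mask = subset_masks[s]
            obs = 0.5 * (E[mask, ia].mean() + E[mask, ib].mean())
            null_stat = 0.5 * (null[s][:, ia] + null[s][:, ib])
            p_val = (1.0 + np.sum(null_stat >= obs)) / (n_perm + 1.0)
            global_stat = 0.5 * (global_mean[ia] + global_mean[ib])
            with np.errstate(divide="ignore", invalid="ignore"):
                lmr = float(np.log(obs / global_stat)) if obs > 0 and global_stat > 0 else -np.inf
            rows.append(
                (
                    name,
                    row.gene_a,
                    row.gene_b,
                    s,
                    float(obs),
                    lmr,
                    float(p_val),
                    bool(lmr > LOG_RATIO_MIN and p_val < INTERACTION_P_MAX),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "gene_a",
            "gene_b",
            "subset",
            "mean_expr",
            "log_mean_ratio",
            "p_value",
            "significant",
        ],
    )


def enrich(
    query: list[str] | set[str],
    gene_sets: dict[str, list[str]],
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query against gene sets.

    Per set: upper-tail P[X >= k] with N = |universe|, K = |set within
    universe|, n = |query|; BH across sets; reported at adjusted
    p < 0.05. Degenerate sets spanning the whole universe are flagged.
    """
    universe = set(universe)
    if not universe:
        raise EmptyResultError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValidationError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe
        K = len(in_universe)
        k = len(query & in_universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p, K == N or n == N))
    frame = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "universe_size",
                       "p_value", "degenerate"]
    )
    frame["bh_p"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    frame["reported"] = frame["bh_p"] < 0.05
    return frame
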