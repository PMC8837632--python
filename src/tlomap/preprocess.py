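"""Spot filtering, normalization, and most-variable-gene selection."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import EmptyResultError, ParameterError, ValidationError

MIN_GENES_DEFAULT = 200


def _raw(adata: AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def filter_spots(adata: AnnData, min_genes: int = MIN_GENES_DEFAULT) -> AnnData:
    """Drop spots detecting fewer than ``min_genes`` genes (count > 0).

    A spot with exactly ``min_genes`` detected genes is kept ("minimal
    size" is an inclusive lower bound). The gene set is unchanged.
    """
    X = adata.X
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    keep = detected >= min_genes
    if not keep.any():
        raise EmptyResultError(
            f"all {adata.n_obs} spots have fewer than {min_genes} detected genes"
        )
    return adata[keep].copy()


def normalize(adata: AnnData, mode: str = "regression_residual") -> AnnData:
    """Add a ``"normalized"`` layer removing sequencing-depth differences.

    size_factor_log
        ``log1p(count / (total_i / median total))`` — the familiar
        median-scaled size-factor log transform.
    regression_residual
        Per-gene Pearson residuals of a depth-regression: the expected
        count is ``mu_ij = total_i * gene_share_j`` (a Poisson GLM with
        log total counts as offset, fit analytically), and the residual
        ``(x - mu) / sqrt(mu)`` is clipped at ``±sqrt(n_spots)``.
    """
    X = _raw(adata)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("zero-total spot encountered; run filter_spots first")
    adata = adata.copy()
    if mode == "size_factor_log":
        sf = totals / np.median(totals)
        adata.layers["normalized"] = np.log1p(X / sf[:, None])
    elif mode == "regression_residual":
        gene_share = X.sum(axis=0) / totals.sum()
        mu = np.outer(totals, gene_share)
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = (X - mu) / np.sqrt(mu)
        resid[~np.isfinite(resid)] = 0.0
        clip = np.sqrt(adata.n_obs)
        adata.layers["normalized"] = np.clip(resid, -clip, clip)
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    adata.uns["layer_tag"] = mode
    return adata


def size_factor_log(X: np.ndarray) -> np.ndarray:
    """Median-scaled size-factor log1p transform of a dense count matrix."""
    totals = X.sum(axis=1)
    sf = totals / np.median(totals)
    return np.log1p(X / sf[:, None])


def select_variable_genes(adata: AnnData, n_top: int) -> pd.DataFrame:
    """Rank genes by squared coefficient of variation minus its median.

    Counts are first divided by the per-spot size factor (the spot's
    total count); the CV² of each gene across spots is computed on that
    linear scale, and the selection statistic is CV² minus the median
    CV² over all genes with nonzero mean. Ties break toward higher mean,
    then gene symbol.
    """
    if n_top <= 0:
        raise ParameterError("n_top must be positive")
    X = _raw(adata).astype(float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("zero-total spot encountered; run filter_spots first")
    scaled = X / totals[:, None]
    mean = scaled.mean(axis=0)
    eligible = mean > 0
    var = scaled.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = var / mean**2
    cv2[~eligible] = np.nan
    statistic = cv2 - np.nanmedian(cv2)

    frame = pd.DataFrame(
        {
            "gene": adata.var_names,
            "mean": mean,
            "cv2": cv2,
            "statistic": statistic,
        }
    )
    frame = frame[eligible].copy()
    if n_top > len(frame):
        warnings.warn(
            f"n_top={n_top} exceeds {len(frame)} eligible genes; returning all"
        )
        n_top = len(frame)
    frame = frame.sort_values(
        ["statistic", "mean", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame["selected"] = frame["rank"] <= n_top
    return frame


def variable_gene_names(frame: pd.DataFrame) -> list[str]:
    return frame.loc[frame["selected"], "gene"].tolist()
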