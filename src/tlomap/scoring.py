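"""Marker-signature cell-type scoring of spatial spots.

For each cell type the normalized expression of its validated markers is
summed per spot (the raw score), scaled by the per-type maximum over
spots, and renormalized within each spot across cell types to give an
approximate cell-type proportion. Marker validation keeps a gene only if
it co-varies positively with the other markers of its type across spots
(pairwise Pearson correlation, applied when at least four markers are
present in the matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

from .errors import EmptyResultError, ParameterError, ValidationError
from .io import SignatureSet

COEXPRESSION_MIN_MARKERS = 4  # "more than 3" present markers


def _layer(adata: AnnData, layer: str | None) -> np.ndarray:
    """Expression matrix used for scoring.

    With ``layer=None`` the linear size-factor scale is computed from
    raw counts (count / spot total): signature sums must live on a
    non-negative depth-corrected scale to stay proportional to cell-type
    abundance, so neither Pearson residuals (signed) nor log counts
    (compressive) are suitable defaults here.
    """
    if layer is None:
        X = adata.X
        X = X.toarray() if sp.issparse(X) else np.asarray(X)
        X = X.astype(float)
        totals = X.sum(axis=1)
        if (totals == 0).any():
            raise ValidationError("zero-total spot; run filter_spots first")
        return X / (totals / np.median(totals))[:, None]
    if layer not in adata.layers:
        raise ValidationError(f"layer {layer!r} missing; run normalize first")
    X = adata.layers[layer]
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def valid_coexpressed_genes(
    adata: AnnData,
    markers: list[str],
    layer: str | None = None,
    mode: str = "mean",
) -> list[str]:
    """Filter a marker list to genes that co-vary positively across spots.

    Pairwise Pearson correlations are computed over spots on the
    normalized layer. With ``mode="mean"`` (default) gene *j* is kept
    iff its mean correlation with the other markers is positive; with
    ``mode="all"`` every pairwise correlation must be positive.
    Zero-variance markers are dropped with a warning (their correlation
    is undefined).
    """
    if mode not in ("mean", "all"):
        raise ParameterError(f"unknown co-expression mode {mode!r}")
    present = [g for g in markers if g in adata.var_names]
    if len(present) < COEXPRESSION_MIN_MARKERS:
        return []
    Y = _layer(adata, layer)[:, [adata.var_names.get_loc(g) for g in present]]
    sd = Y.std(axis=0)
    if (sd == 0).any():
        dropped = [g for g, s in zip(present, sd) if s == 0]
        warnings.warn(f"zero-variance markers dropped: {dropped}")
        present = [g for g, s in zip(present, sd) if s > 0]
        if len(present) < 2:
            return present
        Y = Y[:, sd > 0]
    corr = np.corrcoef(Y, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    if mode == "mean":
        keep = np.nanmean(corr, axis=1) > 0
    else:
        keep = np.nanmin(corr, axis=1) > 0
    return [g for g, k in zip(present, keep) if k]


@dataclass
class CellTypeScores:
    """Per-spot per-type scores and proportions.

    ``raw_score`` is the marker sum per spot; ``max_scaled`` divides by
    the per-type maximum over spots (in [0, 1]); ``proportions``
    renormalizes the max-scaled scores within each spot across all
    scoreable types. Types that could not be scored hold NaN columns and
    are excluded from the proportion denominator.
    """

    raw_score: pd.DataFrame
    max_scaled: pd.DataFrame
    proportions: pd.DataFrame
    valid_genes: dict[str, list[str]] = field(default_factory=dict)
    n_markers_present: dict[str, int] = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(self.raw_score.columns)

    def to_long(self) -> pd.DataFrame:
        parts = []
        for name, frame in (
            ("raw_score", self.raw_score),
            ("max_scaled", self.max_scaled),
            ("proportion", self.proportions),
        ):
            long = frame.reset_index(names="barcode").melt(
                id_vars="barcode", var_name="cell_type", value_name=name
            )
            parts.append(long.set_index(["barcode", "cell_type"]))
        return pd.concat(parts, axis=1).reset_index()


def score_cell_types(
    adata: AnnData,
    signatures: SignatureSet,
    layer: str | None = None,
    coexpression_mode: str = "mean",
    strict_presence: bool = False,
    proportion_mode: str = "per_spot",
) -> CellTypeScores:
    """Score each cell type per spot from its validated marker sum.

    The co-expression validity filter applies when a type has at least
    four markers present in the matrix. Types with fewer present
    markers are scored on those markers directly, or reported as
    not-scoreable (all-NaN) when ``strict_presence`` is set. Types whose
    validated marker set is empty score 0 and are excluded from the
    proportion denominator.

    ``proportion_mode="per_spot"`` (default) renormalizes the max-scaled
    scores across types within each spot; ``"per_type_over_regions"`` is
    a comparison mode dividing instead by each type's sum over spots.
    """
    if proportion_mode not in ("per_spot", "per_type_over_regions"):
        raise ParameterError(f"unknown proportion mode {proportion_mode!r}")
    Y = _layer(adata, layer)
    index = adata.obs_names
    raw = {}
    valid_genes: dict[str, list[str]] = {}
    n_present: dict[str, int] = {}
    for cell_type in signatures.cell_types:
        markers = signatures.genes(cell_type)
        present = [g for g in markers if g in adata.var_names]
        n_present[cell_type] = len(present)
        if len(present) >= COEXPRESSION_MIN_MARKERS:
            M = valid_coexpressed_genes(adata, present, layer, coexpression_mode)
        elif strict_presence or not present:
            valid_genes[cell_type] = []
            raw[cell_type] = np.full(len(index), np.nan)
            continue
        else:
            M = present
        valid_genes[cell_type] = M
        if not M:
            raw[cell_type] = np.zeros(len(index))
        else:
            cols = [adata.var_names.get_loc(g) for g in M]
            raw[cell_type] = Y[:, cols].sum(axis=1)

    raw_frame = pd.DataFrame(raw, index=index)
    scoreable = [t for t in raw_frame.columns if not raw_frame[t].isna().all()]
    if not scoreable:
        raise EmptyResultError("no scoreable cell types")

    max_scaled = raw_frame.copy()
    for t in scoreable:
        peak = raw_frame[t].max()
        max_scaled[t] = raw_frame[t] / peak if peak > 0 else 0.0

    proportions = max_scaled.copy()
    usable = [t for t in scoreable if not (max_scaled[t] == 0).all()]
    if proportion_mode == "per_spot":
        denom = max_scaled[usable].sum(axis=1)
        for t in scoreable:
            with np.errstate(invalid="ignore", divide="ignore"):
                proportions[t] = np.where(denom > 0, max_scaled[t] / denom, np.nan)
    else:
        for t in scoreable:
            total = max_scaled[t].sum()
            proportions[t] = max_scaled[t] / total if total > 0 else np.nan
    return CellTypeScores(raw_frame, max_scaled, proportions, valid_genes, n_present)


def colocalize(scores_a, scores_b) -> tuple[float, float]:
    """Pearson co-localization of two per-spot score maps.

    Returns ``(r, two-sided p)``; non-finite pairs are dropped first,
    and a zero-variance input yields ``(nan, nan)`` with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValidationError("need at least 3 paired finite values")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in a score map; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
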