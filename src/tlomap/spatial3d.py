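"""Cell-density TLO detection, serial-section registration, interpolation.

Nucleus tables (segmentation output) are aggregated into per-spot
windows matching the 200x200 px H&E crop around each barcoded area; the
within-section percentile of the window cell count is the cell density
score, and spots above the 70th percentile are flagged as candidate
tertiary lymphoid organ (TLO) regions. Consecutive sections are aligned
by point-set registration (rigid or scaled-rotation similarity
transforms, least-squares/Procrustes via multi-start ICP), and per-spot
scalars are interpolated over each section area on the Delaunay
triangulation for volume rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from .errors import EmptyResultError, ParameterError, SchemaError, ValidationError

DENSITY_THRESHOLD = 70.0
WINDOW_PX = 200


def aggregate_cells_to_spots(
    cells: pd.DataFrame, spots: pd.DataFrame, window_px: int = WINDOW_PX
) -> pd.DataFrame:
    """Count nuclei inside the axis-aligned window centered on each spot.

    Returns a frame aligned to ``spots`` with ``cell_count``,
    ``mean_area`` (NaN when empty), and ``keep`` — spots without any
    detected nucleus are flagged for removal downstream.
    """
    unknown = set(cells["section_id"]) - set(spots["section_id"])
    if unknown:
        raise SchemaError(f"cell sections absent from spot table: {sorted(unknown)}")
    half = window_px / 2.0
    counts = np.zeros(len(spots), dtype=int)
    mean_area = np.full(len(spots), np.nan)
    for sec, idx in spots.groupby("section_id").indices.items():
        sec_cells = cells[cells["section_id"] == sec]
        if sec_cells.empty:
            continue
        tree = cKDTree(sec_cells[["x", "y"]].to_numpy())
        centers = spots.iloc[idx][["x", "y"]].to_numpy()
        hits = tree.query_ball_point(centers, r=half, p=np.inf)
        areas = sec_cells["area"].to_numpy()
        for row, cell_idx in zip(idx, hits):
            counts[row] = len(cell_idx)
            if cell_idx:
                mean_area[row] = areas[cell_idx].mean()
    out = spots[["barcode", "section_id"]].copy()
    out["cell_count"] = counts
    out["mean_area"] = mean_area
    out["keep"] = counts > 0
    return out


def density_score(
    counts: pd.DataFrame, threshold: float = DENSITY_THRESHOLD
) -> pd.DataFrame:
    """Percentile cell-density score per spot within its section.

    ``counts`` needs ``cell_count`` and ``section_id`` columns. The
    score is ``100 * (rank - 1) / (n - 1)`` with average ranks for ties
    (a single-spot section scores 50 by convention), and ``is_tlo`` is
    strictly ``score > threshold``.
    """
    out = counts.copy()
    out["density_score"] = np.nan
    for sec, idx in out.groupby("section_id").indices.items():
        vals = out.iloc[idx]["cell_count"].to_numpy(dtype=float)
        if len(vals) == 1:
            score = np.array([50.0])
        else:
            ranks = stats.rankdata(vals, method="average")
            score = 100.0 * (ranks - 1.0) / (len(vals) - 1.0)
        out.iloc[idx, out.columns.get_loc("density_score")] = score
    out["is_tlo"] = out["density_score"] > threshold
    return out


def annotation_overlap(
    density: pd.DataFrame, annotations: pd.Series | np.ndarray, label: str = "infiltrate"
) -> float:
    """Fraction of label-annotated spots falling in TLO-flagged regions."""
    ann = np.asarray(annotations)
    if len(ann) != len(density):
        raise ValidationError("annotation length does not match density table")
    mask = ann == label
    if not mask.any():
        raise EmptyResultError(f"no spots annotated {label!r}")
    return float(density.loc[mask, "is_tlo"].mean())


# ---------------------------------------------------------------------------
# registration


@dataclass
class SectionTransform:
    theta: float  # radians
    scale: float
    tx: float
    ty: float
    rmsd: float = 0.0

    def apply(self, pts: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        R = np.array([[c, -s], [s, c]])
        return self.scale * pts @ R.T + np.array([self.tx, self.ty])

    def to_dict(self) -> dict:
        return {
            "theta_rad": self.theta,
            "scale": self.scale,
            "tx": self.tx,
            "ty": self.ty,
            "rmsd": self.rmsd,
        }


@dataclass
class Volume:
    """Registered multi-section stack."""

    spots: pd.DataFrame  # original columns + x_reg, y_reg
    transforms: dict[str, SectionTransform]
    reference: str
    grids: dict[str, dict] = field(default_factory=dict)

    def section_z(self) -> pd.Series:
        return self.spots.groupby("section_id")["z"].first().sort_values()


def _fit_similarity(P: np.ndarray, Q: np.ndarray, with_scale: bool) -> SectionTransform:
    """Least-squares similarity (or rigid) transform mapping P onto Q."""
    muP, muQ = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - muP, Q - muQ
    if np.linalg.matrix_rank(Pc, tol=1e-9) < 2:
        raise ValidationError("degenerate (collinear) landmarks")
    S = Qc.T @ Pc / len(P)
    U, D, Vt = np.linalg.svd(S)
    d = np.ones(2)
    if np.linalg.det(U @ Vt) < 0:
        d[-1] = -1.0
    R = U @ np.diag(d) @ Vt
    var_p = (Pc**2).sum() / len(P)
    s = float((D * d).sum() / var_p) if with_scale else 1.0
    t = muQ - s * (R @ muP)
    theta = float(np.arctan2(R[1, 0], R[0, 0]))
    out = SectionTransform(theta, s, float(t[0]), float(t[1]))
    out.rmsd = float(np.sqrt(((out.apply(P) - Q) ** 2).sum(axis=1).mean()))
    return out


def _icp(
    P: np.ndarray, Q: np.ndarray, with_scale: bool, n_starts: int = 12, max_iter: int = 60
) -> SectionTransform:
    """Multi-start iterative closest point with a closed-form inner fit."""
    tree = cKDTree(Q)
    muP, muQ = P.mean(axis=0), Q.mean(axis=0)
    best: SectionTransform | None = None
    for k in range(n_starts):
        theta0 = 2.0 * np.pi * k / n_starts
        current = SectionTransform(
            theta0,
            1.0,
            *(muQ - _rot(theta0) @ muP),
        )
        prev_rmsd = np.inf
        for _ in range(max_iter):
            moved = current.apply(P)
            _, nn = tree.query(moved)
            fit = _fit_similarity(P, Q[nn], with_scale)
            if abs(prev_rmsd - fit.rmsd) < 1e-12:
                current = fit
                break
            prev_rmsd = fit.rmsd
            current = fit
        if best is None or current.rmsd < best.rmsd:
            best = current
    assert best is not None
    return best


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def register_sections(
    spots: pd.DataFrame, mode: str = "rigid", reference: str | None = None
) -> Volume:
    """Register every section's spot cloud onto the reference section.

    ``mode="scaled_rotation"`` fits a similarity transform (rotation,
    isotropic scale, translation); ``mode="rigid"`` fixes the scale to
    1. The reference section (default: first in section order) keeps the
    identity transform.
    """
    if mode not in ("rigid", "scaled_rotation"):
        raise ParameterError(f"unknown registration mode {mode!r}")
    order = (
        spots.sort_values("z" if "z" in spots.columns else "section_id")["section_id"]
        .drop_duplicates()
        .tolist()
    )
    if len(order) < 2:
        raise ParameterError("need at least 2 sections to register")
    reference = reference or order[0]
    if reference not in order:
        raise ParameterError(f"reference section {reference!r} not present")
    with_scale = mode == "scaled_rotation"
    Q = spots.loc[spots["section_id"] == reference, ["x", "y"]].to_numpy(dtype=float)
    out = spots.copy()
    out["x_reg"] = np.nan
    out["y_reg"] = np.nan
    transforms: dict[str, SectionTransform] = {}
    for sec in order:
        mask = out["section_id"] == sec
        P = out.loc[mask, ["x", "y"]].to_numpy(dtype=float)
        if len(P) < 3:
            raise ParameterError(f"section {sec!r} has fewer than 3 spots")
        if sec == reference:
            tf = SectionTransform(0.0, 1.0, 0.0, 0.0, 0.0)
        else:
            tf = _icp(P, Q, with_scale)
        moved = tf.apply(P)
        out.loc[mask, "x_reg"] = moved[:, 0]
        out.loc[mask, "y_reg"] = moved[:, 1]
        transforms[sec] = tf
    return Volume(out, transforms, reference)


# ---------------------------------------------------------------------------
# interpolation


def interpolate_grid(
    values: np.ndarray, points: np.ndarray, grid_step: float
) -> dict:
    """Piecewise-linear interpolation of a per-spot scalar onto a grid.

    Uses the Delaunay triangulation of the spot positions; grid nodes
    outside the convex hull are masked. Linear fields are reproduced
    exactly inside the hull.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 4:
        raise ParameterError("need at least 4 spots to interpolate")
    if np.linalg.matrix_rank(points - points.mean(axis=0), tol=1e-9) < 2:
        raise ValidationError("all spots collinear; cannot triangulate")
    interp = LinearNDInterpolator(points, values)
    xg = np.arange(points[:, 0].min(), points[:, 0].max() + grid_step / 2, grid_step)
    yg = np.arange(points[:, 1].min(), points[:, 1].max() + grid_step / 2, grid_step)
    XX, YY = np.meshgrid(xg, yg)
    ZZ = interp(XX, YY)
    return {
        "x": xg,
        "y": yg,
        "grid": np.ma.masked_invalid(ZZ),
    }


def interpolate_volume(
    volume: Volume, values: pd.Series, grid_step: float, name: str = "value"
) -> Volume:
    """Interpolate a per-spot scalar per section and stack by z.

    ``values`` must be indexed like ``volume.spots`` (positionally).
    Slices are stored under ``volume.grids[name]`` keyed by section id;
    no smoothing is applied across sections.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) != len(volume.spots):
        raise ValidationError("values length does not match spots")
    slices = {}
    for sec, idx in volume.spots.groupby("section_id").indices.items():
        pts = volume.spots.iloc[idx][["x_reg", "y_reg"]].to_numpy()
        slices[str(sec)] = interpolate_grid(vals[idx], pts, grid_step)
    volume.grids[name] = slices
    return volume
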