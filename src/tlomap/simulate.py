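"""Synthetic multi-section synovium-like ST volumes with known ground truth.

The generator emulates the structure of an inflamed rheumatoid-arthritis
synovial biopsy profiled by spatial transcriptomics over consecutive
cryosections: a dense lymphocyte-rich aggregate (the TLO core) with
radially arranged surrounding zones at increasing distance, a sublining/
lining background, per-spot cell-type mixtures drawn from a marker-block
signature matrix, negative-binomial count noise with lognormal spot
depth, and a nucleus table whose density peaks inside the core (many
small cells) and falls off outside (fewer, larger cells). Two "patient
groups" differ in core composition: seropositive cores are lymphocyte
(T/B) dominated, seronegative cores fibroblast/dendritic-cell dominated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import ParameterError
from .io import SignatureSet

SPOT_PITCH_PX = 200.0  # center-to-center spot distance; one 200x200 window per spot

ZONES = ("TLO_core", "ring1", "ring2", "lining")

# zone-mean expected nucleus counts per spot window and mean nucleus areas
# (px^2): dense small cells in the aggregate, sparse large cells outside
ZONE_DENSITY = {"TLO_core": 60.0, "ring1": 30.0, "ring2": 20.0, "lining": 12.0}
ZONE_CELL_AREA = {"TLO_core": 30.0, "ring1": 80.0, "ring2": 80.0, "lining": 80.0}

CELL_TYPE_NAMES = [
    "T_cell", "B_cell", "Macrophage", "Fibroblast", "Dendritic_cell",
    "NK_cell", "Plasma_cell", "Monocyte", "Endothelial", "Mast_cell",
    "Pericyte", "Neutrophil", "ILC", "pDC", "Synoviocyte", "Mural_cell",
]


@dataclass
class SimParams:
    """Generator settings; defaults emulate one whole-biopsy volume."""

    n_sections: int = 3
    spots_per_section: int = 700
    n_genes: int = 2000
    n_cell_types: int = 16
    markers_per_type: int = 25
    tlo_centers: list[tuple[float, float, float]] | None = None  # (x, y, radius px)
    ring_width: float | None = None  # px; defaults to the core radius
    nb_dispersion: float = 10.0  # NB size parameter; larger -> Poisson
    depth_mean: float = 5000.0  # expected UMIs per spot
    depth_sigma: float = 0.3  # lognormal sd of spot depth (log scale)
    marker_logfc: float = 2.0  # log2 fold change of marker blocks
    background_expr: float = 1.0
    zone_concentration: float = 30.0  # Dirichlet concentration of spot mixtures
    group: str = "seropositive"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sections", "spots_per_section", "n_genes", "n_cell_types",
                     "markers_per_type"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_cell_types < 2:
            raise ParameterError("need at least 2 cell types")
        if self.nb_dispersion <= 0 or self.depth_mean <= 0:
            raise ParameterError("nb_dispersion and depth_mean must be positive")
        if self.group not in ("seropositive", "seronegative"):
            raise ParameterError("group must be seropositive or seronegative")
        side = int(np.ceil(np.sqrt(self.spots_per_section)))
        self.array_extent = side * SPOT_PITCH_PX
        if self.tlo_centers is None:
            half = self.array_extent / 2.0
            self.tlo_centers = [(half, half, 0.15 * self.array_extent)]
        for _, _, r in self.tlo_centers:
            if r > self.array_extent:
                raise ParameterError("TLO radius exceeds the array extent")
        if self.ring_width is None:
            self.ring_width = self.tlo_centers[0][2] if self.tlo_centers else 0.0

    @property
    def cell_type_names(self) -> list[str]:
        names = CELL_TYPE_NAMES[: self.n_cell_types]
        names += [f"type_{i}" for i in range(len(names), self.n_cell_types)]
        return names


def make_reference(params: SimParams) -> tuple[SignatureSet, pd.DataFrame]:
    """Build a marker-block signature matrix and its SignatureSet.

    Each cell type expresses every gene at ``background_expr`` and its
    own disjoint block of ``markers_per_type`` genes at
    ``background_expr * 2**marker_logfc``. The SignatureSet lists the
    block genes with ``avg_logfc = marker_logfc`` (so the standard
    logFC > 1 filter empties it when marker_logfc <= 1).
    """
    L, G, M = params.n_cell_types, params.n_genes, params.markers_per_type
    if G < L * M + 1:
        raise ParameterError(
            f"n_genes={G} too small to host {L} disjoint blocks of {M} markers"
        )
    genes = [f"gene_{i:05d}" for i in range(G)]
    B = np.full((L, G), params.background_expr, dtype=float)
    rows = []
    for l in range(L):
        block = slice(l * M, (l + 1) * M)
        B[l, block] *= 2.0 ** params.marker_logfc
        for g in genes[block]:
            rows.append((params.cell_type_names[l], g, params.marker_logfc, 1e-6))
    matrix = pd.DataFrame(B, index=params.cell_type_names, columns=genes)
    signatures = SignatureSet.from_frame(
        pd.DataFrame(rows, columns=["cell_type", "gene", "avg_logfc", "fdr"])
    )
    return signatures, matrix


def _zone_of(x: np.ndarray, y: np.ndarray, params: SimParams) -> np.ndarray:
    """Zone label per spot from distance to the nearest TLO center."""
    if not params.tlo_centers:
        return np.full(x.shape, "lining", dtype=object)
    d = np.full(x.shape, np.inf)
    r_near = np.zeros(x.shape)
    for cx, cy, r in params.tlo_centers:
        di = np.hypot(x - cx, y - cy)
        closer = di - r < d - r_near  # distance beyond that center's core edge
        d = np.where(closer, di, d)
        r_near = np.where(closer, r, r_near)
    w = params.ring_width
    zone = np.full(x.shape, "lining", dtype=object)
    zone[d < r_near + 2 * w] = "ring2"
    zone[d < r_near + w] = "ring1"
    zone[d < r_near] = "TLO_core"
    return zone


def _zone_base_proportions(params: SimParams) -> dict[str, np.ndarray]:
    """Zone-level mean cell-type proportions.

    Dominant roles follow synovial histology: the core is T/B-cell rich
    (seropositive) or fibroblast/DC rich (seronegative); ring1 is
    macrophage-heavy, ring2 fibroblast-heavy, and the lining a distinct
    synoviocyte-like mixture.
    """
    L = params.n_cell_types
    t_cell, b_cell, mac, fib, dc = 0, 1 % L, 2 % L, 3 % L, 4 % L
    lining_dom = (4 if L > 4 else L - 1) % L

    def base(dominants: list[int], weight: float = 0.6) -> np.ndarray:
        p = np.full(L, (1.0 - weight) / L)
        for idx in dominants:
            p[idx] += weight / len(dominants)
        return p / p.sum()

    if params.group == "seropositive":
        core = base([t_cell, b_cell], 0.7)
    else:
        core = base([fib, dc], 0.7)
    return {
        "TLO_core": core,
        "ring1": base([mac]),
        "ring2": base([fib]),
        "lining": base([lining_dom]) if lining_dom not in (fib,) else base([fib, mac], 0.5),
    }


def simulate_volume(
    params: SimParams, signature_matrix: pd.DataFrame
) -> tuple[AnnData, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-section volume from the signature matrix.

    Returns ``(counts, spot_table, ground_truth, cell_table)``. Spot
    expression is ``depth * (pi . B)`` (row-normalized), with NB noise;
    nuclei are placed uniformly within each spot's 200x200 px window.
    """
    rng = np.random.default_rng(params.seed)
    L = params.n_cell_types
    B = signature_matrix.to_numpy()
    genes = list(signature_matrix.columns)
    type_names = list(signature_matrix.index)
    if B.shape[0] != L:
        raise ParameterError("signature matrix rows must match n_cell_types")

    side = int(np.ceil(np.sqrt(params.spots_per_section)))
    base_idx = np.arange(side * side)[: params.spots_per_section]
    gx, gy = np.unravel_index(base_idx, (side, side))
    zone_base = _zone_base_proportions(params)

    spot_rows, gt_rows, cell_rows = [], [], []
    count_blocks = []
    for s in range(params.n_sections):
        sec = f"sec{s:02d}"
        jitter = rng.uniform(-0.05, 0.05, size=(2, len(base_idx))) * SPOT_PITCH_PX
        x = (gx + 0.5) * SPOT_PITCH_PX + jitter[0]
        y = (gy + 0.5) * SPOT_PITCH_PX + jitter[1]
        zones = _zone_of(x, y, params)

        alpha = np.stack([zone_base[z] for z in zones]) * params.zone_concentration
        props = np.empty((len(x), L))
        for i in range(len(x)):
            props[i] = rng.dirichlet(alpha[i])

        profile = props @ B
        profile /= profile.sum(axis=1, keepdims=True)
        depth = rng.lognormal(
            np.log(params.depth_mean) - params.depth_sigma**2 / 2,
            params.depth_sigma,
            size=len(x),
        )
        mean = profile * depth[:, None]
        size = params.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + np.maximum(mean, 1e-12)))
        counts[mean <= 0] = 0
        count_blocks.append(sp.csr_matrix(counts))

        true_density = np.array([ZONE_DENSITY[z] for z in zones])
        n_cells = rng.poisson(true_density)
        for i in range(len(x)):
            barcode = f"{sec}_spot{i:04d}"
            annotation = "infiltrate" if zones[i] == "TLO_core" else "other"
            spot_rows.append((barcode, x[i], y[i], sec, s, annotation))
            gt = {
                "barcode": barcode,
                "section_id": sec,
                "true_cluster": zones[i],
                "true_density": true_density[i],
                "group": params.group,
            }
            gt.update({f"prop_{t}": props[i, l] for l, t in enumerate(type_names)})
            gt_rows.append(gt)
            if n_cells[i]:
                half = SPOT_PITCH_PX / 2.0 - 5.0
                cx = x[i] + rng.uniform(-half, half, n_cells[i])
                cy = y[i] + rng.uniform(-half, half, n_cells[i])
                mean_area = ZONE_CELL_AREA[zones[i]]
                area = np.maximum(rng.normal(mean_area, 0.2 * mean_area, n_cells[i]), 5.0)
                for j in range(n_cells[i]):
                    cell_rows.append((cx[j], cy[j], area[j], sec))

    spot_table = pd.DataFrame(
        spot_rows, columns=["barcode", "x", "y", "section_id", "section_order", "annotation"]
    )
    ground_truth = pd.DataFrame(gt_rows)
    cell_table = pd.DataFrame(cell_rows, columns=["x", "y", "area", "section_id"])

    X = sp.vstack(count_blocks).tocsr()
    adata = AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(spot_table["barcode"], name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    for col in ("x", "y", "section_id", "annotation"):
        adata.obs[col] = spot_table[col].to_numpy()
    adata.obs["true_cluster"] = ground_truth["true_cluster"].to_numpy()
    adata.uns["layer_tag"] = "raw"
    return adata, spot_table, ground_truth, cell_table


def expected_mean(
    params: SimParams, signature_matrix: pd.DataFrame, proportions: np.ndarray
) -> np.ndarray:
    """Analytic expected counts for given mixture rows: depth * (pi . B)."""
    profile = proportions @ signature_matrix.to_numpy()
    profile /= profile.sum(axis=1, keepdims=True)
    return profile * params.depth_mean
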