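"""Readers and writers for on-disk artifacts.

Counts come in as MatrixMarket triplets (with ``barcodes.tsv`` /
``genes.tsv`` sidecars) or as a dense TSV with spots as rows. Spot
geometry, cell-type signature references, receptor-ligand pair lists and
GMT gene sets are plain tab-separated text. All results round-trip
through TSV/JSON; interpolated volume grids go to an NPZ container with
a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .errors import FormatError, SchemaError, ValidationError

MARKER_LOGFC_MIN = 1.0
MARKER_FDR_MAX = 0.05
MARKERS_PER_TYPE_MAX = 200


# ---------------------------------------------------------------------------
# signature reference


@dataclass
class SignatureSet:
    """Per-cell-type marker lists with effect sizes.

    ``markers`` maps cell type -> DataFrame with columns
    ``gene``, ``avg_logfc``, ``fdr``, already filtered (avg_logfc > 1,
    FDR < 0.05) and truncated to the 200 largest fold changes.
    """

    markers: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)

    @property
    def n_types(self) -> int:
        return len(self.markers)

    def genes(self, cell_type: str) -> list[str]:
        return self.markers[cell_type]["gene"].tolist()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SignatureSet":
        """Build from a long table, applying the marker filters.

        Markers must exceed avg_logfc 1 (strict) at FDR below 5%; per
        type the 200 largest fold changes are kept, ties broken by gene
        symbol for determinism.
        """
        required = {"cell_type", "gene", "avg_logfc", "fdr"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"signature table missing columns: {sorted(missing)}")
        out: dict[str, pd.DataFrame] = {}
        for cell_type, grp in frame.groupby("cell_type", sort=True):
            kept = grp[(grp["avg_logfc"] > MARKER_LOGFC_MIN) & (grp["fdr"] < MARKER_FDR_MAX)]
            kept = kept.sort_values(
                ["avg_logfc", "gene"], ascending=[False, True], kind="mergesort"
            ).head(MARKERS_PER_TYPE_MAX)
            if kept.empty:
                warnings.warn(
                    f"cell type {cell_type!r} has no markers passing filters; "
                    "retained with an empty marker list"
                )
            out[str(cell_type)] = kept[["gene", "avg_logfc", "fdr"]].reset_index(drop=True)
        return cls(out)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for cell_type, frame in self.markers.items():
            part = frame.copy()
            part.insert(0, "cell_type", cell_type)
            parts.append(part)
        if not parts:
            return pd.DataFrame(columns=["cell_type", "gene", "avg_logfc", "fdr"])
        return pd.concat(parts, ignore_index=True)


def read_signatures(path: str | Path) -> SignatureSet:
    """Read a cell-type marker reference TSV and apply the marker filters."""
    frame = pd.read_csv(path, sep="\t")
    return SignatureSet.from_frame(frame)


# ---------------------------------------------------------------------------
# counts


def _validate_counts(values, barcodes, genes) -> None:
    dup = pd.Index(barcodes)[pd.Index(barcodes).duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate barcodes: {dup}")
    mins = values.min() if not sp.issparse(values) else values.data.min(initial=0)
    if mins < 0:
        raise ValidationError("counts must be non-negative")


def read_counts(path: str | Path, format: str | None = None) -> AnnData:
    """Read a spots x genes count matrix into an AnnData.

    ``format`` is ``"mtx"`` or ``"tsv"``; inferred from the suffix when
    omitted. MTX files need ``barcodes.tsv`` and ``genes.tsv`` sidecars
    in the same directory (one name per line, barcodes = matrix rows).
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001 - re-typed for callers
            raise FormatError(f"malformed MatrixMarket file {path}: {exc}") from exc
        barcodes = (path.parent / "barcodes.tsv").read_text().split()
        genes = (path.parent / "genes.tsv").read_text().split()
        mat = sp.csr_matrix(mat)
        if mat.shape != (len(barcodes), len(genes)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(barcodes)} barcodes, {len(genes)} genes)"
            )
        _validate_counts(mat, barcodes, genes)
        adata = AnnData(
            X=mat,
            obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )
    elif format == "tsv":
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"malformed TSV {path}: {exc}") from exc
        if frame.empty and frame.columns.empty:
            raise FormatError(f"{path} has no header or no data")
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or np.isnan(values).any():
            raise FormatError(f"{path} contains non-numeric counts")
        if (values != np.round(values)).any():
            raise ValidationError("counts must be integers")
        _validate_counts(values, frame.index, frame.columns)
        adata = AnnData(
            X=sp.csr_matrix(values.astype(np.int64)),
            obs=pd.DataFrame(index=pd.Index(frame.index.astype(str), name="barcode")),
            var=pd.DataFrame(index=pd.Index(frame.columns.astype(str), name="gene")),
        )
    else:
        raise FormatError(f"unknown counts format {format!r}")
    adata.uns["layer_tag"] = "raw"
    return adata


def write_counts_mtx(adata: AnnData, outdir: str | Path) -> None:
    """Write raw counts as matrix.mtx + barcodes.tsv + genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(adata.X))
    (outdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    (outdir / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")


# ---------------------------------------------------------------------------
# spot geometry


def read_spot_table(path: str | Path, section_spacing_um: float = 7.0) -> pd.DataFrame:
    """Read the spot table and assign z from section order and spacing.

    Consecutive cryosections are cut at a fixed thickness, so the axial
    coordinate of section ``i`` (in section order) is
    ``i * section_spacing_um``. Section order comes from an explicit
    ``section_order`` column when present, else from sorted section ids.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"barcode": str, "section_id": str})
    return attach_z(frame, section_spacing_um)


def attach_z(frame: pd.DataFrame, section_spacing_um: float) -> pd.DataFrame:
    required = {"barcode", "x", "y", "section_id"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"spot table missing columns: {sorted(missing)}")
    if frame[["x", "y"]].isna().any().any() or not np.isfinite(frame[["x", "y"]]).all().all():
        raise ValidationError("spot coordinates must be finite")
    dup = frame.duplicated(subset=["barcode", "section_id"])
    if dup.any():
        dups = frame.loc[dup, ["barcode", "section_id"]].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (barcode, section_id): {dups}")
    if "section_order" in frame.columns:
        order = (
            frame[["section_id", "section_order"]]
            .drop_duplicates()
            .sort_values("section_order")["section_id"]
            .tolist()
        )
    else:
        order = sorted(frame["section_id"].unique())
    index = {sec: i for i, sec in enumerate(order)}
    frame = frame.copy()
    frame["z"] = frame["section_id"].map(index).astype(float) * float(section_spacing_um)
    return frame


def attach_spot_table(adata: AnnData, spots: pd.DataFrame) -> AnnData:
    """Join spot geometry (and annotation) onto the count matrix by barcode."""
    spots = spots.set_index("barcode")
    missing = adata.obs_names.difference(spots.index)
    if len(missing):
        raise ValidationError(f"{len(missing)} barcodes missing from spot table")
    aligned = spots.reindex(adata.obs_names)
    for col in aligned.columns:
        adata.obs[col] = aligned[col].values
    return adata


# ---------------------------------------------------------------------------
# receptor-ligand pairs / gene sets


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a receptor-ligand pair list TSV (gene_a, gene_b[, name])."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"gene_a", "gene_b"} - set(frame.columns)
    if missing:
        raise SchemaError(f"pair table missing columns: {sorted(missing)}")
    if "name" not in frame.columns:
        frame["name"] = frame["gene_a"] + "_" + frame["gene_b"]
    return frame


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# generic result writer


def write_results(obj, path: str | Path) -> Path:
    """Serialize a pipeline product to disk.

    DataFrames and objects exposing ``to_frame()``/``to_long()`` become
    TSV; dicts/lists become JSON; mappings of numpy arrays become an NPZ
    container plus a JSON metadata sidecar (grids).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    elif hasattr(obj, "to_long"):
        obj.to_long().to_csv(path, sep="\t", index=False)
    elif hasattr(obj, "to_frame"):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, dict) and obj and all(isinstance(v, np.ndarray) for v in obj.values()):
        np.savez(path.with_suffix(".npz"), **obj)
        meta = {k: {"shape": list(v.shape), "dtype": str(v.dtype)} for k, v in obj.items()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    elif isinstance(obj, (dict, list)):
        path.write_text(json.dumps(obj, indent=1, default=_json_default))
    else:
        raise ValidationError(f"do not know how to serialize {type(obj).__name__}")
    return path


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back any TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
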