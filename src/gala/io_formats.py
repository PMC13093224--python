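"""On-disk representations of slices, images, landmarks and alignment results.

All coordinates are continuous world coordinates (e.g. micrometres) with the
y axis increasing downward, matching image row order. Every other module
shares this convention.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger("gala")

__all__ = [
    "PointDataset",
    "HistologyImage",
    "LandmarkSet",
    "read_point_dataset",
    "read_histology",
    "write_alignment",
    "read_alignment",
]


@dataclass
class HistologyImage:
    """A histology image co-registered to world coordinates.

    ``pixels`` holds intensities in [0, 1]; ``scale`` is world units per
    pixel and ``offset`` the world coordinates of the centre of pixel
    (row 0, col 0).
    """

    pixels: np.ndarray
    scale: float
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if not self.scale > 0:
            raise ValueError("nonpositive scale")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("histology intensities must be finite")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def pixel_world_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinate vectors of pixel-column/row centres."""
        h, w = self.pixels.shape[:2]
        xs = self.offset[0] + self.scale * np.arange(w)
        ys = self.offset[1] + self.scale * np.arange(h)
        return xs, ys


@dataclass
class PointDataset:
    """One slice: spatial anchors (spots or cells) with expression.

    coords : (n, 2) world coordinates, columns (x, y).
    expr : (n, G) nonnegative expression matrix.
    gene_names : length-G unique identifiers.
    labels : optional length-n categorical region annotations.
    histology : optional linked :class:`HistologyImage`.
    resolution_hint : "spot" or "cell".
    """

    coords: np.ndarray
    expr: np.ndarray
    gene_names: list
    labels: Optional[np.ndarray] = None
    histology: Optional[HistologyImage] = None
    resolution_hint: str = "spot"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.expr = np.asarray(self.expr, dtype=float)
        self.gene_names = list(self.gene_names)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be n×2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        n = self.coords.shape[0]
        if self.expr.shape[0] != n:
            raise ValueError(
                f"point count mismatch: {n} coordinates vs "
                f"{self.expr.shape[0]} expression rows"
            )
        if self.expr.shape[1] != len(self.gene_names):
            raise ValueError(
                f"gene count mismatch: {self.expr.shape[1]} expression columns "
                f"vs {len(self.gene_names)} gene names"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("duplicate gene names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError("labels length must equal point count")
        if self.resolution_hint not in ("spot", "cell"):
            raise ValueError("resolution_hint must be 'spot' or 'cell'")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"unknown gene name: {name!r}") from None


@dataclass
class LandmarkSet:
    """Paired landmark coordinates, used for evaluation only."""

    target_pts: np.ndarray
    source_pts: np.ndarray
    names: Optional[list] = None

    def __post_init__(self) -> None:
        self.target_pts = np.asarray(self.target_pts, dtype=float).reshape(-1, 2)
        self.source_pts = np.asarray(self.source_pts, dtype=float).reshape(-1, 2)
        if self.target_pts.shape[0] != self.source_pts.shape[0]:
            raise ValueError(
                f"landmark count mismatch: {self.target_pts.shape[0]} target "
                f"vs {self.source_pts.shape[0]} source"
            )

    @property
    def n(self) -> int:
        return self.target_pts.shape[0]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_expr(expr_path, genes_path=None):
    expr_path = Path(expr_path)
    if expr_path.suffix == ".mtx":
        mat = mmread(os.fspath(expr_path))
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        if genes_path is None:
            raise ValueError("Matrix Market expression requires a genes list")
        genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        if mat.size and not np.any(mat):
            logger.warning("expression matrix has no nonzero entries")
        return mat, genes
    df = pd.read_csv(expr_path, sep=None, engine="python")
    genes = list(df.columns)
    if genes_path is not None:
        listed = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        if listed:
            genes = listed
    return df.to_numpy(dtype=float), genes


def read_point_dataset(
    coords_path,
    expr_path,
    genes_path=None,
    labels_path=None,
    resolution_hint: str = "spot",
) -> PointDataset:
    """Read one slice from a coordinates table plus an expression matrix.

    ``coords_path`` must be a headered CSV/TSV with columns ``x`` and ``y``.
    ``expr_path`` is either a dense points×genes CSV (gene names taken from
    its header unless ``genes_path`` is given) or a Matrix Market file with a
    mandatory plain-text genes list. Point and gene order are never changed.
    """
    cdf = pd.read_csv(coords_path, sep=None, engine="python")
    for col in ("x", "y"):
        if col not in cdf.columns:
            raise ValueError(f"coordinates file must have a '{col}' column")
    coords = cdf[["x", "y"]].to_numpy(dtype=float)
    expr, genes = _read_expr(expr_path, genes_path)
    labels = None
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep=None, engine="python")
        labels = ldf.iloc[:, -1].to_numpy()
    return PointDataset(coords, expr, genes, labels=labels,
                        resolution_hint=resolution_hint)


def read_histology(image_path, scale: float, offset=(0.0, 0.0)) -> HistologyImage:
    """Read a PNG/TIFF image and attach its world-coordinate registration.

    Accepts 8- or 16-bit, 1- or 3-channel images; intensities are scaled to
    [0, 1] floats. ``scale``/``offset`` place pixel centres in world space.
    """
    if not scale > 0:
        raise ValueError("nonpositive scale")
    raw = iio.imread(image_path)
    if raw.dtype == np.uint8:
        pix = raw.astype(float) / 255.0
    elif raw.dtype == np.uint16:
        pix = raw.astype(float) / 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        pix = raw.astype(float)
    else:
        raise ValueError(f"unsupported image bit depth: {raw.dtype}")
    if pix.ndim == 3:
        if pix.shape[2] == 4:  # drop alpha
            pix = pix[:, :, :3]
        if pix.shape[2] != 3:
            raise ValueError(f"unsupported channel count: {pix.shape[2]}")
    elif pix.ndim != 2:
        raise ValueError("image must be 2D greyscale or H×W×3 RGB")
    return HistologyImage(pix, scale=float(scale), offset=np.asarray(offset, float))


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark CSV with columns target_x,target_y,source_x,source_y."""
    df = pd.read_csv(path, sep=None, engine="python")
    req = ["target_x", "target_y", "source_x", "source_y"]
    for col in req:
        if col not in df.columns:
            raise ValueError(f"landmark file must have a '{col}' column")
    names = list(df["name"]) if "name" in df.columns else None
    return LandmarkSet(df[["target_x", "target_y"]].to_numpy(float),
                       df[["source_x", "source_y"]].to_numpy(float), names)


# ---------------------------------------------------------------------------
# alignment result serialization
# ---------------------------------------------------------------------------


def write_alignment(result, out_dir) -> dict:
    """Write an AlignmentResult to ``out_dir``.

    Emits ``aligned_coords.csv`` (x_aligned, y_aligned; original row order),
    ``transform.json`` (affine parameters, grid geometry, hyper-parameters,
    objective trace) and ``fields.npz`` (velocity field, match posterior,
    forward/inverse maps). Returns the mapping of artefact name to path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"unwritable output directory {out_dir}: {exc}") from exc

    coords_path = out_dir / "aligned_coords.csv"
    pd.DataFrame(result.aligned_source_coords,
                 columns=["x_aligned", "y_aligned"]).to_csv(
        coords_path, index=False, float_format="%.17g")

    aff = result.affine
    grid = result.match_grid
    meta = {
        "affine": {
            "theta": aff.theta, "log_sx": aff.log_sx, "log_sy": aff.log_sy,
            "tx": aff.tx, "ty": aff.ty, "reflect": bool(aff.reflect),
        },
        "grid": {
            "origin": list(map(float, grid.origin)),
            "dx": grid.dx, "H": grid.H, "W": grid.W,
        },
        "diffeo_grid": {
            "origin": list(map(float, result.diffeo.grid.origin)),
            "dx": result.diffeo.grid.dx,
            "H": result.diffeo.grid.H, "W": result.diffeo.grid.W,
        },
        "config": result.config,
        "objective_trace": result.objective_trace,
        "diagnostics": result.diagnostics,
    }
    meta_path = out_dir / "transform.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))

    fields_path = out_dir / "fields.npz"
    np.savez_compressed(
        fields_path,
        velocity=result.velocity.v if result.velocity is not None else np.zeros(0),
        P_M=result.match.P_M,
        phi=result.diffeo.phi,
        phi_inv=result.diffeo.phi_inv,
    )
    return {"coords": coords_path, "meta": meta_path, "fields": fields_path}


def read_alignment(out_dir) -> dict:
    """Reload the artefacts written by :func:`write_alignment`."""
    out_dir = Path(out_dir)
    coords = pd.read_csv(out_dir / "aligned_coords.csv",
                         float_precision="round_trip").to_numpy(float)
    meta = json.loads((out_dir / "transform.json").read_text())
    with np.load(out_dir / "fields.npz") as z:
        fields = {k: z[k].copy() for k in z.files}
    return {"aligned_coords": coords, "meta": meta, "fields": fields}
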