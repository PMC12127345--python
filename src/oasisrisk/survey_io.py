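"""Readers/writers for the tabular and raster formats the pipeline touches.

Tabular data are plain CSV (comma-separated, UTF-8, header required).
Rasters are single-band ESRI ASCII grids (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
rows of cell values, row 0 = north.  Cover is stored internally as a
fraction in [0, 1]; a survey file whose cover column contains any value
above 1 is taken to be in percent and divided by 100 (with a warning).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = ["site", "plot", "quadrat", "species", "count", "cover"]

#: Closed vocabularies for the categorical functional traits.
CATEGORICAL_VOCAB: Mapping[str, tuple[str, ...]] = {
    "life_form": ("annual", "biennial", "perennial"),
    "mating_system": ("selfing", "outcrossing", "mixed"),
    "pollination_mode": ("wind", "insect", "self"),
    "fruit_type": ("capsule", "utricle", "achene", "legume", "caryopsis", "berry"),
    "dispersal_mode": ("gravity", "wind", "animal", "water", "human"),
}

CONTINUOUS_TRAITS = ("sla", "height", "hundred_grain_weight", "flowering_duration")

TRAIT_COLUMNS = (
    ["species", "family", "genus"]
    + list(CONTINUOUS_TRAITS)
    + list(CATEGORICAL_VOCAB)
)


@dataclass
class SurveyTable:
    """Quadrat-level occurrence records.

    ``records`` has columns site, plot, quadrat, species, count, cover with
    cover as a fraction of quadrat area.  ``design`` is
    (n_sites, plots_per_site, quadrats_per_plot) when the survey follows a
    complete nested design.
    """

    records: pd.DataFrame
    design: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SURVEY_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"survey table missing columns: {missing}")
        r = self.records
        bad = r.index[r["count"] < 0]
        if len(bad):
            raise ValidationError(f"negative count at rows {list(bad[:5])}")
        bad = r.index[(r["cover"] < 0) | (r["cover"] > 1)]
        if len(bad):
            raise ValidationError(f"cover outside [0, 1] at rows {list(bad[:5])}")
        dup = r.duplicated(subset=["site", "plot", "quadrat", "species"])
        if dup.any():
            raise ValidationError(
                f"duplicate (site, plot, quadrat, species) at rows {list(r.index[dup][:5])}"
            )

    @property
    def n_units(self) -> int:
        """Number of sampling units (quadrats) in the design."""
        if self.design is not None:
            n_sites, plots, quads = self.design
            return n_sites * plots * quads
        return self.records.groupby(["site", "plot", "quadrat"]).ngroups

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    def total_count(self) -> int:
        return int(self.records["count"].sum())


@dataclass
class TraitTable:
    """Per-species functional traits: continuous plus categorical codes."""

    data: pd.DataFrame  # indexed by species id
    vocab: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CATEGORICAL_VOCAB)
    )

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate species ids: {list(dups[:5])}")
        for col in CONTINUOUS_TRAITS:
            if col in self.data.columns:
                vals = self.data[col].to_numpy(dtype=float)
                if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
                    bad = self.data.index[~(np.isfinite(vals) & (vals > 0))]
                    raise ValidationError(
                        f"non-positive {col} for species {list(bad[:5])}"
                    )
        for col, levels in self.vocab.items():
            if col in self.data.columns:
                seen = set(self.data[col].dropna().unique())
                extra = seen - set(levels)
                if extra:
                    raise ValidationError(
                        f"unknown {col} level(s) {sorted(extra)}; "
                        f"allowed: {sorted(levels)}"
                    )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class GridTransform:
    """Georeference of a north-up regular grid (ESRI ASCII convention)."""

    xllcorner: float
    yllcorner: float
    cellsize: float

    def cell_center(self, row: int, col: int, nrows: int) -> tuple[float, float]:
        """(x, y) of the center of cell (row, col); row 0 is the north row."""
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (nrows - row - 0.5) * self.cellsize
        return x, y

    def index_of(self, x: float, y: float, nrows: int) -> tuple[int, int]:
        col = int(math.floor((x - self.xllcorner) / self.cellsize))
        row = nrows - 1 - int(math.floor((y - self.yllcorner) / self.cellsize))
        return row, col


@dataclass
class EnvStack:
    """Aligned environmental raster layers with a shared nodata mask."""

    layers: dict[str, np.ndarray]
    transform: GridTransform
    nodata_mask: np.ndarray  # True where nodata

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise AlignmentError(f"layers have differing shapes: {shapes}")
        if self.layers and next(iter(shapes)) != self.nodata_mask.shape:
            raise AlignmentError("nodata mask shape differs from layer shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nodata_mask.shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def extract(self, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        """Sample every layer at point coordinates (cell-center convention).

        Points falling outside the grid or on masked cells yield NaN rows.
        """
        nrows, ncols = self.shape
        col = np.floor((np.asarray(x) - self.transform.xllcorner) / self.transform.cellsize).astype(int)
        row = nrows - 1 - np.floor(
            (np.asarray(y) - self.transform.yllcorner) / self.transform.cellsize
        ).astype(int)
        inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        out = {}
        r_safe = np.clip(row, 0, nrows - 1)
        c_safe = np.clip(col, 0, ncols - 1)
        valid = inside & ~self.nodata_mask[r_safe, c_safe]
        for name, layer in self.layers.items():
            vals = layer[r_safe, c_safe].astype(float)
            vals[~valid] = np.nan
            out[name] = vals
        return pd.DataFrame(out)


def read_survey(path: str | Path) -> SurveyTable:
    """Read a quadrat-level survey CSV.

    Cover given in percent (any value > 1) is divided by 100 with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[SURVEY_COLUMNS].copy()
    try:
        df["count"] = df["count"].astype(int)
        df["cover"] = df["cover"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric count/cover: {exc}") from exc
    bad = df.index[df["cover"] > 100]
    if len(bad):
        raise ValidationError(f"{path}: cover > 100 at rows {list(bad[:5])}")
    bad = df.index[df["count"] < 0]
    if len(bad):
        raise ValidationError(f"{path}: negative count at rows {list(bad[:5])}")
    if (df["cover"] > 1).any():
        logger.warning("%s: cover appears to be percent; dividing by 100", path)
        df["cover"] = df["cover"] / 100.0
    return SurveyTable(records=df.reset_index(drop=True))


def write_survey(survey: SurveyTable, path: str | Path) -> None:
    survey.records.to_csv(path, index=False)


def read_traits(path: str | Path) -> TraitTable:
    """Read a per-species trait CSV (one row per species)."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise FormatError(f"{path}: missing 'species' column")
    df = df.set_index("species")
    return TraitTable(data=df)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.data.to_csv(path, index=True, index_label="species")


# ---------------------------------------------------------------------------
# ESRI ASCII grid rasters


def read_raster(path: str | Path) -> tuple[np.ndarray, GridTransform, np.ndarray]:
    """Read one ESRI ASCII grid; returns (values, transform, nodata mask)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing header field {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    body = " ".join(lines[n_header:])
    try:
        values = np.array(body.split(), dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell value: {exc}") from exc
    if values.size != nrows * ncols:
        raise FormatError(
            f"{path}: expected {nrows * ncols} cells, found {values.size}"
        )
    grid = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    mask = np.isclose(grid, nodata) | ~np.isfinite(grid)
    transform = GridTransform(header["xllcorner"], header["yllcorner"], header["cellsize"])
    return grid, transform, mask


def read_raster_stack(paths: Sequence[str | Path]) -> EnvStack:
    """Read aligned single-band rasters into one stack.

    Mismatched shapes or transforms are an error (no resampling is done);
    the stack's nodata mask is the union of per-layer masks.
    """
    layers: dict[str, np.ndarray] = {}
    transform: GridTransform | None = None
    mask: np.ndarray | None = None
    for p in paths:
        grid, tr, m = read_raster(p)
        name = Path(p).stem
        if name in layers:
            raise ValidationError(f"duplicate layer name {name!r}")
        if transform is None:
            transform, mask = tr, m
        else:
            if grid.shape != next(iter(layers.values())).shape:
                raise AlignmentError(
                    f"{p}: shape {grid.shape} differs from first layer"
                )
            if tr != transform:
                raise AlignmentError(f"{p}: transform {tr} differs from {transform}")
            mask = mask | m
        layers[name] = grid
    if transform is None:
        raise ValidationError("no raster paths given")
    return EnvStack(layers=layers, transform=transform, nodata_mask=mask)


def write_raster(
    grid: np.ndarray,
    transform: GridTransform,
    path: str | Path,
    nodata_mask: np.ndarray | None = None,
    nodata_value: float = -9999.0,
) -> None:
    """Write a grid as an ESRI ASCII raster (full float precision)."""
    grid = np.asarray(grid, dtype=float)
    out = grid.copy()
    if nodata_mask is not None:
        out[nodata_mask] = nodata_value
    out[~np.isfinite(out)] = nodata_value
    nrows, ncols = out.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {transform.xllcorner!r}\n")
        fh.write(f"yllcorner {transform.yllcorner!r}\n")
        fh.write(f"cellsize {transform.cellsize!r}\n")
        fh.write(f"NODATA_value {nodata_value!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_presences(path: str | Path) -> pd.DataFrame:
    """Read presence points CSV with columns x, y, species."""
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "species") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df[["x", "y", "species"]].copy()
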