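"""Readers and writers for the formats the pipeline touches.

Volumes are MRC2014/CCP4 mode-2 maps (voxel size in the header, written and
read through gemmi).  Backbone models, bead tables, and measurement results
are CSV with strict headers; transforms and run manifests are JSON.  All
physical quantities are serialised in Å unless a column name states
otherwise.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .layerline import FilamentModel, LatticeMeasurement
from .registration import BeadSet, SimilarityTransform
from .volume import TomogramVolume

__all__ = [
    "read_volume", "write_volume",
    "read_backbones", "write_backbones",
    "read_beads", "write_beads",
    "write_results", "read_results",
    "write_transform", "read_transform",
    "write_points_csv",
]

_BACKBONE_COLS = ["filament_id", "point_index", "x", "y", "z"]
_RESULT_COLS = ["filament_id", "n_segments", "equator_loc",
                "layerline_locs", "delta_px", "spacing_A", "snr",
                "classification"]


# ---------------------------------------------------------------------------
# volumes (MRC2014 mode 2 via gemmi)

def read_volume(path) -> TomogramVolume:
    """Read an MRC2014/CCP4 mode-2 (or convertible integer mode) volume."""
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
        m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    except Exception as exc:  # corrupt header / unsupported mode
        raise ValueError(f"cannot read MRC volume {path}: {exc}") from exc
    arr = np.array(m.grid, copy=True)
    sp = m.grid.spacing
    if not np.allclose(sp, sp[0], rtol=1e-4):
        raise ValueError(f"anisotropic voxel sizes {sp} in {path}; the "
                         "pipeline assumes isotropic voxels")
    return TomogramVolume(arr, float(sp[0]))


def write_volume(volume: TomogramVolume, path) -> None:
    """Write a volume as an MRC2014 mode-2 map with voxel size in the header.

    Densities are stored as float32; a float32 volume round-trips bitwise.
    """
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(
        volume.densities, dtype=np.float32))
    n = volume.shape
    vx = volume.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(n[0] * vx, n[1] * vx, n[2] * vx,
                                      90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def write_spectrum(values: np.ndarray, pixel_size: float, path) -> None:
    """Write a 2D image (e.g. a summed power spectrum) as a 1-slice MRC."""
    vol = TomogramVolume(np.asarray(values, dtype=np.float32)[:, :, None],
                         pixel_size)
    write_volume(vol, path)


# ---------------------------------------------------------------------------
# backbones

def read_backbones(path, voxel_size: float) -> list[FilamentModel]:
    """Read traced backbones (CSV: filament_id, point_index, x, y, z voxels).

    Filaments are returned in file order of first appearance, points sorted
    by point_index.  Duplicate (filament_id, point_index) pairs are an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"backbone file not found: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != _BACKBONE_COLS:
        raise ValueError(f"backbone CSV {path}: expected header "
                         f"{_BACKBONE_COLS}, got {list(df.columns)}")
    bad = df[df[["x", "y", "z"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"backbone CSV {path}: malformed row(s) at line(s) "
                         f"{[i + 2 for i in bad.index.tolist()]}")
    dup = df.duplicated(subset=["filament_id", "point_index"])
    if dup.any():
        raise ValueError(f"backbone CSV {path}: duplicate (filament_id, "
                         f"point_index) at line(s) "
                         f"{[i + 2 for i in df.index[dup].tolist()]}")
    models = []
    for fid in df["filament_id"].drop_duplicates():
        sub = df[df["filament_id"] == fid].sort_values("point_index")
        models.append(FilamentModel(points=sub[["x", "y", "z"]].to_numpy(),
                                    voxel_size=voxel_size,
                                    filament_id=str(fid)))
    return models


def write_backbones(models: Sequence[FilamentModel], path) -> None:
    rows = []
    for m in models:
        for i, (x, y, z) in enumerate(m.points):
            rows.append((m.filament_id, i, x, y, z))
    pd.DataFrame(rows, columns=_BACKBONE_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# beads

def read_beads(path) -> BeadSet:
    """Read a bead table (CSV: id, x, y[, z], space, units)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bead file not found: {path}")
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:3] != ["id", "x", "y"] or cols[-2:] != ["space", "units"]:
        raise ValueError(f"bead CSV {path}: expected header id,x,y[,z],"
                         f"space,units, got {cols}")
    axes = ["x", "y", "z"] if "z" in cols else ["x", "y"]
    space = str(df["space"].iloc[0]) if len(df) else ""
    units = str(df["units"].iloc[0]) if len(df) else ""
    return BeadSet(ids=df["id"].tolist(),
                   coords=df[axes].to_numpy(dtype=float),
                   space=space, units=units)


def write_beads(beads: BeadSet, path) -> None:
    axes = ["x", "y", "z"][:beads.dims]
    df = pd.DataFrame(beads.coords, columns=axes)
    df.insert(0, "id", beads.ids)
    df["space"] = beads.space
    df["units"] = beads.units
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# measurement results

def write_results(measurements: Sequence[LatticeMeasurement], path) -> None:
    """Per-filament results CSV (multi-peak rows join locations with ';')."""
    rows = []
    for m in measurements:
        rows.append((m.filament_id, m.n_segments, m.equator_loc,
                     ";".join(repr(float(v)) for v in m.layerline_locs),
                     m.delta_px, m.spacing, m.snr, m.classification))
    pd.DataFrame(rows, columns=_RESULT_COLS).to_csv(
        path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"results file not found: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != _RESULT_COLS:
        raise ValueError(f"results CSV {path}: unexpected header "
                         f"{list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# transforms / generic tables

def write_transform(transform: SimilarityTransform, path) -> None:
    Path(path).write_text(json.dumps(transform.to_dict(), indent=2))


def read_transform(path) -> SimilarityTransform:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"transform file not found: {path}")
    return SimilarityTransform.from_dict(json.loads(path.read_text()))


def write_points_csv(df: pd.DataFrame, path, sidecar_params: dict | None = None
                     ) -> None:
    """Write a point table (e.g. lattice ground truth) with a JSON sidecar
    holding the generating parameters and seed."""
    df.to_csv(path, index=False)
    if sidecar_params is not None:
        side = Path(str(path) + ".json")
        side.write_text(json.dumps(sidecar_params, indent=2, default=str))
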