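"""ROI tables, time-series and phenotype I/O, spherical ROI extraction.

The packaged atlas covers 25 ROIs from four large-scale networks (salience,
default-mode, central-executive and theory-of-mind), each with an MNI
center; time series can be extracted from a 4D NIfTI volume by averaging
all voxels within a 10-mm sphere around each center.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROITable",
    "ROITimeSeries",
    "load_roi_table",
    "packaged_roi_table",
    "extract_sphere_timeseries",
    "read_timeseries",
    "write_timeseries",
    "read_phenotypes",
    "write_phenotypes",
]

NETWORKS = ("SN", "DMN", "CEN", "ToM")


@dataclass
class ROITable:
    """Atlas: ROI name, network membership, and MNI center (mm)."""

    table: pd.DataFrame  # columns: name, network, x, y, z

    def __post_init__(self) -> None:
        required = {"name", "network", "x", "y", "z"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ROI table missing columns: {sorted(missing)}")
        if self.table["name"].duplicated().any():
            dups = self.table.loc[self.table["name"].duplicated(), "name"].tolist()
            raise ValueError(f"duplicate ROI names: {dups}")
        for c in ("x", "y", "z"):
            vals = pd.to_numeric(self.table[c], errors="coerce")
            if vals.isna().any():
                raise ValueError(f"non-numeric coordinate in column {c!r}")
            self.table[c] = vals
        if len(self.table) == 0:
            raise ValueError("ROI table is empty")

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    @property
    def coordinates(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ROITimeSeries:
    """Per-subject ROI signal matrix (T timepoints x N ROIs)."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 2.0
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("time series must be a (T >= 2) x N matrix")
        if np.isnan(self.data).any():
            raise ValueError(f"NaN values in time series of {self.subject_id}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def load_roi_table(path: str | Path) -> ROITable:
    """Load and validate a delimited ROI table (name, network, x, y, z)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if len(df) == 0:
        raise ValueError(f"ROI table {path} has no rows")
    return ROITable(table=df)


def packaged_roi_table() -> ROITable:
    """The packaged 25-ROI SN/DMN/CEN/ToM atlas."""
    with importlib.resources.as_file(
        importlib.resources.files("metaconn") / "data" / "roi_atlas.csv"
    ) as p:
        return load_roi_table(p)


def extract_sphere_timeseries(
    volume4d, roi_table: ROITable, radius_mm: float = 10.0, tr_seconds: float | None = None,
    subject_id: str = "subject", aggregate: str = "mean",
) -> ROITimeSeries:
    """ROI signal from a spherical binary mask around each MNI center.

    Distances are measured in world (mm) coordinates through the volume's
    affine, so the result is independent of voxel size; voxels exactly at
    ``radius_mm`` are included.  ``aggregate`` is ``"mean"`` (default) or
    ``"eigenvariate"`` (first principal component over the sphere, scaled
    to the mean voxel SD and sign-aligned with the mean signal).  A sphere
    that contains no voxel raises an error naming the ROI.
    """
    import nibabel as nib

    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if isinstance(volume4d, (str, Path)):
        volume4d = nib.load(str(volume4d))
    data = np.asarray(volume4d.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D volume")
    affine = volume4d.affine
    nx, ny, nz, nt = data.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)], axis=0)
    world = (affine @ vox)[:3].T  # n_voxels x 3
    flat = data.reshape(-1, nt)
    out = np.empty((nt, len(roi_table)))
    if aggregate not in ("mean", "eigenvariate"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    for r, (name, center) in enumerate(zip(roi_table.names, roi_table.coordinates)):
        inside = np.linalg.norm(world - center, axis=1) <= radius_mm
        if not inside.any():
            raise ValueError(f"sphere of radius {radius_mm} mm around ROI {name!r} contains no voxels")
        voxels = flat[inside]
        mean_course = voxels.mean(axis=0)
        if aggregate == "mean" or voxels.shape[0] == 1:
            out[:, r] = mean_course
        else:
            centered = voxels - voxels.mean(axis=1, keepdims=True)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            pc = vt[0]
            if np.dot(pc, mean_course - mean_course.mean()) < 0:
                pc = -pc
            out[:, r] = pc * centered.std(axis=1).mean() * np.sqrt(nt) + mean_course.mean()
    if tr_seconds is None:
        zooms = volume4d.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return ROITimeSeries(subject_id=subject_id, data=out, tr_seconds=tr_seconds,
                         roi_names=roi_table.names)


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    """Write a time series as CSV, one column per ROI, header = ROI names."""
    names = ts.roi_names or [f"roi{r}" for r in range(ts.n_rois)]
    pd.DataFrame(ts.data, columns=names).to_csv(path, index=False, float_format="%.12g")


def read_timeseries(
    path: str | Path,
    roi_table: ROITable | None = None,
    tr_seconds: float = 2.0,
    subject_id: str | None = None,
) -> ROITimeSeries:
    """Read a delimited time series; columns are canonicalized to atlas order.

    When ``roi_table`` is given, the file must carry exactly the atlas ROI
    names (any order); columns are re-ordered to the table order.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.isna().any().any():
        raise ValueError(f"NaN cells in {path}")
    names = list(df.columns)
    if roi_table is not None:
        if set(names) != set(roi_table.names) or len(names) != len(roi_table):
            raise ValueError(
                f"{path}: columns {len(names)} do not match the {len(roi_table)}-ROI table"
            )
        df = df[roi_table.names]
        names = roi_table.names
    sid = subject_id if subject_id is not None else Path(path).stem
    return ROITimeSeries(subject_id=sid, data=df.to_numpy(dtype=float),
                         tr_seconds=tr_seconds, roi_names=names)


PHENO_REQUIRED = ("subject_id", "group", "site_id", "age", "sex")


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table; requires subject_id/group/site_id/age/sex."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(PHENO_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in phenotype table")
    return df
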