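"""Core containers and file I/O for 4D volume time series cohorts.

A cohort on disk is a flat directory::

    cohort/
        phenotype.tsv          subject_id  site  label
        mask.nii.gz            shared boolean brain mask (optional)
        sub-0000_bold.nii.gz   4D volume, TR recorded in the header zooms
        sub-0000_motion.txt    T x 6 motion parameters (mm, mm, mm, rad, rad, rad)
        ...

Volumes are NIfTI-1; motion traces are whitespace-delimited text with one
row per time point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume4D",
    "SubjectRecord",
    "save_volume",
    "load_volume",
    "save_motion_trace",
    "load_motion_trace",
    "write_phenotype",
    "read_phenotype",
    "read_cohort",
]


@dataclass
class Volume4D:
    """A 4D voxel grid (X, Y, Z, T) with acquisition metadata.

    Parameters
    ----------
    data:
        Real-valued array of shape ``(X, Y, Z, T)``; must be finite.
    tr:
        Repetition time in seconds (> 0); the temporal sampling interval.
    voxel_size:
        Voxel edge lengths in mm.
    mask:
        Optional boolean brain mask with the spatial shape of ``data``.
    """

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match spatial "
                    f"shape {self.data.shape[:3]}"
                )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def t(self) -> int:
        """Number of time points."""
        return self.data.shape[3]

    def effective_mask(self) -> np.ndarray:
        """The stored mask, or an all-True mask when none is set."""
        if self.mask is not None:
            return self.mask
        return np.ones(self.spatial_shape, dtype=bool)

    def with_data(self, data: np.ndarray) -> "Volume4D":
        """A copy of this volume carrying new data, same metadata."""
        return replace(self, data=data)

    def voxel_matrix(self, dtype=np.float32) -> np.ndarray:
        """In-mask voxel time series as a ``(T, V)`` matrix."""
        m = self.effective_mask()
        return np.ascontiguousarray(self.data[m].T.astype(dtype))


@dataclass
class SubjectRecord:
    """Phenotype entry for one scan: identity, site, label and QC state."""

    subject_id: str
    site: str
    label: int
    volume_path: Optional[Path] = None
    motion_path: Optional[Path] = None
    mean_fd: Optional[float] = None
    qc_pass: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def save_volume(vol: Volume4D, path: Path | str) -> Path:
    """Write a :class:`Volume4D` as NIfTI, recording TR in the header."""
    path = Path(path)
    affine = np.diag([*vol.voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms((*vol.voxel_size, float(vol.tr)))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def load_volume(path: Path | str, mask: Optional[np.ndarray] = None) -> Volume4D:
    """Read a 4D NIfTI; TR is taken from the 4th header zoom."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    if tr <= 0:
        raise ValueError(f"{path}: header does not record a positive TR")
    voxel_size = tuple(float(z) for z in zooms[:3])
    return Volume4D(data=data, tr=tr, voxel_size=voxel_size, mask=mask)


def save_mask(mask: np.ndarray, voxel_size: Sequence[float], path: Path | str) -> Path:
    path = Path(path)
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    nib.save(img, str(path))
    return path


def load_mask(path: Path | str) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_motion_trace(trace: np.ndarray, path: Path | str) -> Path:
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"motion trace must be (T, 6), got {trace.shape}")
    path = Path(path)
    np.savetxt(path, trace, fmt="%.10g")
    return path


def load_motion_trace(path: Path | str) -> np.ndarray:
    trace = np.loadtxt(path, ndmin=2)
    if trace.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {trace.shape[1]}")
    if not np.all(np.isfinite(trace)):
        raise ValueError(f"{path}: non-finite motion parameters")
    return trace


def write_phenotype(records: Sequence[SubjectRecord], path: Path | str) -> Path:
    rows = [
        {"subject_id": r.subject_id, "site": r.site, "label": r.label}
        for r in records
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_phenotype(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "site": str})
    required = {"subject_id", "site", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dupes}")
    return df


def read_cohort(cohort_dir: Path | str) -> list[SubjectRecord]:
    """Read ``phenotype.tsv`` and resolve per-subject file paths."""
    cohort_dir = Path(cohort_dir)
    df = read_phenotype(cohort_dir / "phenotype.tsv")
    records = []
    for row in df.itertuples(index=False):
        vol_path = cohort_dir / f"{row.subject_id}_bold.nii.gz"
        mot_path = cohort_dir / f"{row.subject_id}_motion.txt"
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                site=row.site,
                label=int(row.label),
                volume_path=vol_path if vol_path.exists() else None,
                motion_path=mot_path if mot_path.exists() else None,
            )
        )
    return records
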