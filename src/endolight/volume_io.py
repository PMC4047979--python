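"""Reading, writing and assembling spatially normalized gray-matter volumes.

All downstream analysis works on a stack of 3D volumes that share one voxel
grid (shape + affine). Inputs are NIfTI-1 files, one per participant, plus a
tab-separated manifest assigning each participant to one of the three study
groups (control, case, sibling). An optional integer-labeled atlas volume
with a label→name table supports anatomical reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed group names, in canonical order.
GROUPS: Tuple[str, ...] = ("control", "case", "sibling")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class Grid:
    """Shared voxel grid: array shape plus voxel-to-world affine."""

    shape: Tuple[int, int, int]
    affine: np.ndarray

    def matches(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class Volume:
    """One participant's gray-matter concentration map.

    ``data`` is a 3D float array (unitless tissue concentration, expected in
    [0, 1]); ``affine`` maps voxel indices to world (MNI) coordinates. The
    algorithm itself operates purely on voxel indices; the affine is carried
    through for output files.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.affine)


@dataclass
class Mask:
    """Boolean analysis mask on the shared grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class GroupedDataset:
    """Ordered stack of participant volumes with group labels.

    Order follows the manifest. All volumes share ``grid`` exactly (shape
    equal; affines equal within 1e-6); participant ids are unique.
    """

    volumes: List[Volume]
    labels: List[str]
    ids: List[str]
    grid: Grid
    _stack: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.volumes)
        if not (len(self.labels) == len(self.ids) == n):
            raise ValueError("volumes, labels and ids must have equal length")
        bad = sorted(set(self.labels) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group name(s) {bad}; allowed: {GROUPS}")
        if len(set(self.ids)) != n:
            raise ValueError("participant ids must be unique")
        for pid, vol in zip(self.ids, self.volumes):
            if not vol.grid.matches(self.grid):
                raise ValueError(f"volume for participant {pid!r} is not on the shared grid")

    def __len__(self) -> int:
        return len(self.volumes)

    def data_stack(self) -> np.ndarray:
        """All volumes stacked to shape (n_participants, nx, ny, nz)."""
        if self._stack is None:
            self._stack = np.stack([v.data for v in self.volumes])
        return self._stack

    def group_indices(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; allowed: {GROUPS}")
        return np.array([i for i, g in enumerate(self.labels) if g == group], dtype=int)

    def group_counts(self) -> Dict[str, int]:
        return {g: int(sum(lbl == g for lbl in self.labels)) for g in GROUPS}


@dataclass
class Atlas:
    """Integer-labeled parcellation volume (0 = background) with region names."""

    labels: np.ndarray
    names: Dict[int, str]
    sizes: Dict[int, int] = field(default=None)  # type: ignore[assignment]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be an integer array")
        if self.affine is None:
            self.affine = np.eye(4)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = sorted(present - set(self.names))
        if missing:
            raise ValueError(f"labels present in volume but missing from table: {missing}")
        if self.sizes is None:
            vals, counts = np.unique(self.labels, return_counts=True)
            self.sizes = {int(v): int(c) for v, c in zip(vals, counts) if v != 0}


def read_volume(path: PathLike) -> Volume:
    """Read one NIfTI-1 (optionally gzipped) volume.

    Data is cast to float64; NaN voxels are replaced by 0 and their count is
    logged (normalized maps commonly carry NaN at the brain border, and a
    single NaN would poison every cross-validation fold touching it).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise IOError(f"cannot read volume file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        logger.info("%s: replaced %d NaN voxel(s) with 0", path.name, n_nan)
        data = np.nan_to_num(data, nan=0.0)
    return Volume(data=data, affine=np.asarray(img.affine))


def write_volume(volume: Volume, path: PathLike) -> None:
    """Write a Volume to NIfTI-1 (float32 on disk, bit-exact for our range)."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    nib.save(img, str(path))


def load_dataset(manifest: Union[PathLike, pd.DataFrame]) -> GroupedDataset:
    """Assemble a GroupedDataset from a manifest.

    The manifest is a TSV file (or DataFrame) with columns ``id``, ``group``
    and ``path``; relative paths resolve against the manifest's directory.
    Manifest order is preserved. All volumes must share the grid of the
    first; the error names the first offending participant.
    """
    base = Path(".")
    if not isinstance(manifest, pd.DataFrame):
        mpath = Path(manifest)
        base = mpath.parent
        manifest = pd.read_csv(mpath, sep="\t", dtype=str)
    required = {"id", "group", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    bad = sorted(set(manifest["group"]) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown group name(s) {bad}; allowed: {GROUPS}")

    volumes, labels, ids = [], [], []
    grid = None
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        vol = read_volume(p)
        if grid is None:
            grid = vol.grid
        elif not vol.grid.matches(grid):
            raise ValueError(
                f"volume for participant {row.id!r} has grid {vol.shape} that does "
                f"not match the shared grid {grid.shape}"
            )
        volumes.append(vol)
        labels.append(str(row.group))
        ids.append(str(row.id))
    if grid is None:
        raise ValueError("manifest is empty")
    return GroupedDataset(volumes=volumes, labels=labels, ids=ids, grid=grid)


def build_mask(
    dataset: GroupedDataset, threshold: float = 0.1, min_fraction: float = 0.5
) -> Mask:
    """Gray-matter analysis mask.

    A voxel is in-mask iff its value exceeds ``threshold`` in at least
    ``min_fraction`` of participants. Defaults (0.1, 0.5) follow common
    gray-matter-map practice; both are exposed because the appropriate mask
    depends on the upstream segmentation.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    stack = dataset.data_stack()
    n = stack.shape[0]
    counts = (stack > threshold).sum(axis=0)
    mask = counts >= min_fraction * n
    if not mask.any():
        raise ValueError(
            f"mask is empty at threshold={threshold}, min_fraction={min_fraction}; "
            "lower the threshold"
        )
    return Mask(data=mask)


def read_atlas(label_path: PathLike, table_path: PathLike) -> Atlas:
    """Read an integer-labeled atlas volume plus its label→name TSV table."""
    img = nib.load(str(Path(label_path)))
    labels = np.asarray(img.get_fdata()).round().astype(np.int64)
    table = pd.read_csv(Path(table_path), sep="\t")
    if not {"label", "name"}.issubset(table.columns):
        raise ValueError("atlas table must have columns 'label' and 'name'")
    names = {int(l): str(n) for l, n in zip(table["label"], table["name"])}
    return Atlas(labels=labels, names=names, affine=np.asarray(img.affine))


def write_atlas(atlas: Atlas, label_path: PathLike, table_path: PathLike) -> None:
    """Write atlas labels (NIfTI, int16) and the label→name table (TSV)."""
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, str(label_path))
    rows = sorted(atlas.names.items())
    pd.DataFrame(rows, columns=["label", "name"]).to_csv(
        table_path, sep="\t", index=False
    )


def write_manifest(dataset_rows: Sequence[Tuple[str, str, str]], path: PathLike) -> None:
    """Write a manifest TSV with header id/group/path."""
    pd.DataFrame(dataset_rows, columns=["id", "group", "path"]).to_csv(
        path, sep="\t", index=False
    )
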