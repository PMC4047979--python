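"""Exhaustively overlapping cubic searchlight with cross-validated SVM accuracy.

One cubic region is centered on every in-mask voxel (cubes are clipped at
grid boundaries and restricted to in-mask voxels, so coverage extends to the
whole parenchyma). For each region, the gray-matter values of its member
voxels form one feature vector per participant, and a linear soft-margin SVM
(C = 1) is scored by stratified k-fold cross-validation; the pooled accuracy
is the region's statistic. Finally each voxel is assigned the highest
accuracy over all (selected) regions that contain it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._svm import LinearSVM
from .volume_io import GroupedDataset, Mask

logger = logging.getLogger(__name__)

Coord = Tuple[int, int, int]


@dataclass
class SearchlightParams:
    """Geometry and cross-validation settings.

    side : odd cube edge length in voxels (5 → 125-voxel regions).
    min_in_mask : regions with fewer in-mask members are dropped (logged).
    folds : stratified CV fold count.
    seed : global seed; each region's fold shuffle seed is derived from
        (seed, center) so parallel scheduling cannot change results.
    standardize : optionally z-score features (fit on training folds only);
        off by default.
    """

    side: int = 5
    min_in_mask: int = 1
    folds: int = 10
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.side < 1 or self.side % 2 == 0:
            raise ValueError(f"side must be odd and >= 1, got {self.side}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.min_in_mask < 1:
            raise ValueError("min_in_mask must be >= 1")


@dataclass
class ClassifierSpec:
    """Linear maximal-margin classifier g(x) = w·x + w0."""

    kernel: str = "linear"
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class RegionSpec:
    """One searchlight region: center voxel plus its in-mask members.

    Members are in fixed lexicographic (i, j, k) order; the center is a
    member whenever it is in-mask.
    """

    center: Coord
    members: np.ndarray  # (m, 3) int


@dataclass
class RegionAccuracy:
    center: Coord
    accuracy: float
    n_samples: int


def cube_members(center: Coord, side: int, mask: Mask) -> np.ndarray:
    """In-mask voxels of the side-cube around center, clipped to the grid."""
    h = side // 2
    shape = mask.shape
    lo = [max(center[d] - h, 0) for d in range(3)]
    hi = [min(center[d] + h, shape[d] - 1) + 1 for d in range(3)]
    sub = mask.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    local = np.argwhere(sub)  # argwhere is lexicographic in (i, j, k)
    return local + np.array(lo)


def enumerate_regions(mask: Mask, params: SearchlightParams) -> List[RegionSpec]:
    """One region per in-mask voxel (that voxel is the center).

    Cubes are clipped at grid boundaries and restricted to in-mask voxels;
    regions with fewer than ``min_in_mask`` members are dropped and the
    dropped count logged.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    regions: List[RegionSpec] = []
    dropped = 0
    for c in np.argwhere(mask.data):
        center = (int(c[0]), int(c[1]), int(c[2]))
        members = cube_members(center, params.side, mask)
        if len(members) < params.min_in_mask:
            dropped += 1
            continue
        regions.append(RegionSpec(center=center, members=members))
    if dropped:
        logger.info("dropped %d region(s) with < %d in-mask voxels", dropped, params.min_in_mask)
    return regions


def extract_features(
    dataset: GroupedDataset, region: RegionSpec, group_a: str, group_b: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Participants × member-voxels feature matrix and ±1 labels.

    Rows follow manifest order restricted to the two groups; columns follow
    the region's member order. ``group_a`` → −1, ``group_b`` → +1 (in the
    standard comparisons controls are group A, so "positive" means case).
    """
    idx_a = dataset.group_indices(group_a)
    idx_b = dataset.group_indices(group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        missing = group_a if idx_a.size == 0 else group_b
        raise ValueError(f"group {missing!r} has no participants in the dataset")
    rows = np.sort(np.concatenate([idx_a, idx_b]))
    stack = dataset.data_stack()
    m = region.members
    X = stack[rows][:, m[:, 0], m[:, 1], m[:, 2]]
    y = np.where(np.isin(rows, idx_b), 1, -1)
    return np.ascontiguousarray(X), y


def region_fold_seed(global_seed: int, center: Coord) -> int:
    """Deterministic per-region fold-shuffle seed from (global seed, center)."""
    ss = np.random.SeedSequence((int(global_seed), *[int(c) for c in center]))
    return int(ss.generate_state(1)[0] % (2**31))


def fold_partition(
    labels: np.ndarray, folds: int, seed: int
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified, seeded-shuffle k-fold partition over the label vector."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need two classes for cross-validation")
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def _pooled_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds_idx: Sequence[Tuple[np.ndarray, np.ndarray]],
    spec: ClassifierSpec,
    standardize: bool = False,
) -> float:
    """Pooled correct-prediction fraction over the given fold partition.

    Degenerate inputs (all participants identical in the region) fall back
    to majority-class prediction per fold, logged once per call. Folds whose
    training rows contain a single class (possible under permuted labels)
    predict that class.
    """
    n = len(y)
    if np.ptp(X, axis=0).max() == 0.0:
        logger.info("constant features in region; scoring majority-class prediction")
        correct = 0
        for tr, te in folds_idx:
            maj = -1 if (y[tr] == -1).sum() >= (y[tr] == 1).sum() else 1
            correct += int((y[te] == maj).sum())
        return correct / n

    correct = 0
    for tr, te in folds_idx:
        ytr = y[tr]
        if np.all(ytr == ytr[0]):
            correct += int((y[te] == ytr[0]).sum())
            continue
        Xtr, Xte = X[tr], X[te]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        clf = LinearSVM(C=spec.C).fit(Xtr, ytr)
        correct += int((clf.predict(Xte) == y[te]).sum())
    return correct / n


def cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    params: SearchlightParams,
    spec: ClassifierSpec,
    fold_seed: Optional[int] = None,
) -> float:
    """Stratified k-fold pooled accuracy of the linear SVM on one region."""
    y = np.asarray(labels)
    seed = params.seed if fold_seed is None else fold_seed
    folds_idx = fold_partition(y, params.folds, seed)
    return _pooled_accuracy(
        np.asarray(features, dtype=np.float64), y, folds_idx, spec, params.standardize
    )


def reference_svc(spec: ClassifierSpec) -> SVC:
    """The high-level estimator equivalent of the internal fast SVM path."""
    return SVC(kernel="linear", C=spec.C)


def run_searchlight(
    dataset: GroupedDataset,
    mask: Mask,
    group_a: str,
    group_b: str,
    params: SearchlightParams,
    spec: ClassifierSpec,
    regions: Optional[Sequence[RegionSpec]] = None,
) -> List[RegionAccuracy]:
    """Cross-validated accuracy for every searchlight region.

    Results are independent of processing order: each region's fold seed is
    derived from (params.seed, center). Pass ``regions`` to score a
    pre-enumerated (or subsampled) region list.
    """
    if regions is None:
        regions = enumerate_regions(mask, params)
    out: List[RegionAccuracy] = []
    for region in regions:
        X, y = extract_features(dataset, region, group_a, group_b)
        acc = cv_accuracy(X, y, params, spec, fold_seed=region_fold_seed(params.seed, region.center))
        out.append(RegionAccuracy(center=region.center, accuracy=acc, n_samples=len(y)))
    return out


def project_to_voxels(
    region_stats: Sequence[RegionAccuracy],
    selected: Optional[Iterable[Coord]],
    mask: Mask,
    params: SearchlightParams,
) -> np.ndarray:
    """Max-projection: each voxel gets the highest accuracy over selected
    regions whose members contain it; uncovered or out-of-mask voxels are 0.
    """
    stats: Dict[Coord, float] = {tuple(s.center): s.accuracy for s in region_stats}
    if selected is None:
        chosen = list(stats)
    else:
        chosen = [tuple(c) for c in selected]
        missing = [c for c in chosen if c not in stats]
        if missing:
            raise ValueError(f"selected centers without region statistics: {missing[:5]}")
    vmap = np.zeros(mask.shape, dtype=np.float64)
    for center in chosen:
        members = cube_members(center, params.side, mask)
        mi, mj, mk = members[:, 0], members[:, 1], members[:, 2]
        np.maximum.at(vmap, (mi, mj, mk), stats[center])
    vmap[~mask.data] = 0.0
    return vmap
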