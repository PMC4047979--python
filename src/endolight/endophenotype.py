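"""Candidate-endophenotype maps, atlas reports, and the classifier transfer test.

Two pairwise searchlight comparisons (controls vs cases, controls vs
siblings) each yield a voxel map of significant accuracies. Voxels
significant in both comparisons — their voxelwise intersection — are the
candidate endophenotype: locations where cases and unaffected siblings both
differ from controls. An anatomical atlas converts the three maps into a
per-region accounting of voxel counts and percentages.

The transfer test probes whether the two comparisons pick up the *same*
pattern: for each region significant in the controls-vs-case comparison, a
classifier trained on controls and cases is applied to the siblings. If the
fraction of siblings labeled "case" is within 10 percentage points of the
cases' own cross-validated positive rate, the region's pattern is shared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._svm import LinearSVM
from .inference import FdrResult, RegionPValue
from .searchlight import (
    ClassifierSpec,
    RegionAccuracy,
    RegionSpec,
    SearchlightParams,
    extract_features,
    fold_partition,
    project_to_voxels,
    region_fold_seed,
)
from .volume_io import Atlas, GroupedDataset, Mask

logger = logging.getLogger(__name__)

#: Default accuracy histogram bin edges (significant accuracies, proportions).
DEFAULT_BIN_EDGES: Tuple[float, ...] = (0.65, 0.70, 0.75, 0.80, 0.85)


@dataclass
class SignificanceMap:
    """Voxel map of one pairwise comparison after FDR filtering.

    ``voxel_accuracy`` is the max-projection over significant regions only;
    ``voxel_significant`` marks voxels covered by at least one significant
    region.
    """

    comparison: Tuple[str, str]
    voxel_accuracy: np.ndarray
    voxel_significant: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_significant = np.asarray(self.voxel_significant, dtype=bool)
        if self.voxel_accuracy.shape != self.voxel_significant.shape:
            raise ValueError("accuracy and significance maps must share a shape")


@dataclass
class RegionReportRow:
    """Atlas-region accounting of significant voxels for both comparisons."""

    region_name: str
    n_sig_a: int
    pct_a: float
    n_sig_b: int
    pct_b: float
    n_common: int
    pct_common: float


@dataclass
class TransferResult:
    """Per-region outcome of the case→sibling classifier transfer."""

    center: Tuple[int, int, int]
    positive_rate_case: float
    sibling_as_case_rate: float
    in_band: bool


def build_significance_map(
    comparison: Tuple[str, str],
    region_stats: Sequence[RegionAccuracy],
    pvalues: Sequence[RegionPValue],
    fdr: FdrResult,
    mask: Mask,
    params: SearchlightParams,
) -> SignificanceMap:
    """Project the accuracies of FDR-significant regions to voxels."""
    if len(pvalues) != len(fdr.significant):
        raise ValueError("FDR result is not aligned with the p-value list")
    selected = [pv.center for pv, sig in zip(pvalues, fdr.significant) if sig]
    vmap = project_to_voxels(region_stats, selected, mask, params)
    return SignificanceMap(
        comparison=tuple(comparison), voxel_accuracy=vmap, voxel_significant=vmap > 0
    )


def overlap_maps(map_a: SignificanceMap, map_b: SignificanceMap) -> np.ndarray:
    """Voxelwise AND of two significance maps (the candidate endophenotype)."""
    if map_a.voxel_significant.shape != map_b.voxel_significant.shape:
        raise ValueError("significance maps are on different grids")
    return map_a.voxel_significant & map_b.voxel_significant


def atlas_report(
    map_a: SignificanceMap,
    map_b: SignificanceMap,
    common: np.ndarray,
    atlas: Atlas,
) -> List[RegionReportRow]:
    """Per-atlas-region significant-voxel counts and percentages.

    Percentages use the atlas region size as denominator. Rows with no
    significant voxels in either comparison are omitted; rows are sorted by
    the common-voxel count, descending (ties by name for stable output).
    """
    if atlas.labels.shape != map_a.voxel_significant.shape:
        raise ValueError("atlas is on a different grid than the maps")
    rows: List[RegionReportRow] = []
    for label, size in sorted(atlas.sizes.items()):
        in_region = atlas.labels == label
        n_a = int((map_a.voxel_significant & in_region).sum())
        n_b = int((map_b.voxel_significant & in_region).sum())
        n_c = int((common & in_region).sum())
        if n_a == 0 and n_b == 0 and n_c == 0:
            continue
        rows.append(
            RegionReportRow(
                region_name=atlas.names[label],
                n_sig_a=n_a,
                pct_a=100.0 * n_a / size,
                n_sig_b=n_b,
                pct_b=100.0 * n_b / size,
                n_common=n_c,
                pct_common=100.0 * n_c / size,
            )
        )
    rows.sort(key=lambda r: (-r.n_common, r.region_name))
    return rows


def report_to_frame(rows: Sequence[RegionReportRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.region_name,
                "n_A": r.n_sig_a,
                "pct_A": r.pct_a,
                "n_B": r.n_sig_b,
                "pct_B": r.pct_b,
                "n_common": r.n_common,
                "pct_common": r.pct_common,
            }
            for r in rows
        ]
    )


def transfer_experiment(
    dataset: GroupedDataset,
    significant_regions_a: Sequence[RegionSpec],
    slparams: SearchlightParams,
    spec: ClassifierSpec,
    band: float = 0.10,
) -> Tuple[List[TransferResult], float]:
    """Case→sibling classifier transfer over the significant regions.

    Per region: (1) the cases' positive rate under the same stratified CV
    as the accuracy mapping (fraction of cases correctly labeled "case");
    (2) one classifier trained on *all* controls and cases, applied to the
    siblings — the fraction labeled "case" is the sibling positive rate.
    A region is in-band when the two rates differ by at most ``band``
    (10 percentage points by default). Returns the per-region results and
    the fraction of regions in band.
    """
    if dataset.group_indices("sibling").size == 0:
        raise ValueError("transfer experiment requires sibling participants")
    sib_rows = dataset.group_indices("sibling")
    stack = dataset.data_stack()

    results: List[TransferResult] = []
    for region in significant_regions_a:
        X, y = extract_features(dataset, region, "control", "case")
        case_mask = y == 1
        n_case = int(case_mask.sum())
        folds_idx = fold_partition(
            y, slparams.folds, region_fold_seed(slparams.seed, region.center)
        )
        case_correct = 0
        for tr, te in folds_idx:
            clf = LinearSVM(C=spec.C).fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            case_correct += int(((pred == 1) & (y[te] == 1)).sum())
        positive_rate_case = case_correct / n_case

        final = LinearSVM(C=spec.C).fit(X, y)
        m = region.members
        X_sib = stack[sib_rows][:, m[:, 0], m[:, 1], m[:, 2]]
        sib_rate = float((final.predict(X_sib) == 1).mean())
        diff = abs(positive_rate_case - sib_rate)
        results.append(
            TransferResult(
                center=tuple(region.center),
                positive_rate_case=positive_rate_case,
                sibling_as_case_rate=sib_rate,
                in_band=bool(diff <= band + 1e-12),
            )
        )
    frac = float(np.mean([r.in_band for r in results])) if results else 0.0
    return results, frac


def accuracy_histogram(
    region_stats_a: Sequence[RegionAccuracy],
    region_stats_b: Sequence[RegionAccuracy],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> Tuple[np.ndarray, np.ndarray]:
    """Counts of significant regions per accuracy bin, per comparison.

    Inputs should already be restricted to significant regions. Bins follow
    numpy half-open convention with the last bin closed.
    """
    edges = np.asarray(bin_edges, dtype=float)
    acc_a = np.array([s.accuracy for s in region_stats_a])
    acc_b = np.array([s.accuracy for s in region_stats_b])
    counts_a, _ = np.histogram(acc_a, bins=edges)
    counts_b, _ = np.histogram(acc_b, bins=edges)
    return counts_a, counts_b
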