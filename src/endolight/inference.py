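"""Permutation significance of region accuracies and BH FDR control.

The null distribution of each region's cross-validated accuracy is built by
re-running the identical CV procedure under random relabelings of the
participants; the p-value is the fraction of permutations whose accuracy
strictly exceeds the observed one. Because label exchangeability is a
property of the label vector and not of any particular region, one shared
set of seeded permutations may be reused across all regions (the default).
The permuted runs reuse the observed run's fold partition and permute the
data-to-label assignment, so every null run keeps the stratified fold
balance of the observed run and the null reflects reassignment only.

Multiplicity over the (many thousands of) regions is handled with the
Benjamini–Hochberg step-up procedure at a target FDR level α.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .searchlight import (
    ClassifierSpec,
    Coord,
    RegionAccuracy,
    RegionSpec,
    SearchlightParams,
    _pooled_accuracy,
    enumerate_regions,
    extract_features,
    fold_partition,
    region_fold_seed,
)
from .volume_io import GroupedDataset, Mask

logger = logging.getLogger(__name__)


@dataclass
class PermutationParams:
    """Permutation-test settings.

    estimator : "strict" counts only permutations strictly above the
        observed accuracy and divides by B (can return p = 0); "plus_one"
        uses (c + 1)/(B + 1), which never returns an exact zero.
    shared_permutations : reuse one seeded set of B permuted label vectors
        for every region (valid under exchangeability, and B times cheaper
        to draw); if off, each region draws its own B permutations from a
        seed derived from (seed, center).
    """

    n_permutations: int = 1000
    seed: int = 0
    shared_permutations: bool = True
    estimator: str = "strict"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.estimator not in ("strict", "plus_one"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class RegionPValue:
    center: Coord
    p: float
    observed_accuracy: float


@dataclass
class FdrResult:
    """Benjamini–Hochberg step-up outcome over one family of tests."""

    alpha: float
    significant: np.ndarray  # bool, aligned with the input p-value order
    k_star: int
    threshold_p: float


def _estimate_p(count_greater: int, n_perm: int, estimator: str) -> float:
    if estimator == "strict":
        return count_greater / n_perm
    return (count_greater + 1) / (n_perm + 1)


def _permutation_indices(
    n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(B, n) array of uniform random permutations of row indices."""
    out = np.empty((n_perm, n), dtype=np.intp)
    for b in range(n_perm):
        out[b] = rng.permutation(n)
    return out


def permutation_pvalue(
    features: np.ndarray,
    labels: np.ndarray,
    observed_accuracy: float,
    slparams: SearchlightParams,
    spec: ClassifierSpec,
    permparams: PermutationParams,
    fold_seed: Optional[int] = None,
    permuted: Optional[np.ndarray] = None,
) -> RegionPValue:
    """Permutation p-value for one region.

    ``permuted`` supplies pre-drawn row permutations (shared mode);
    otherwise B permutations are drawn from ``permparams.seed``.

    Each permutation randomly reassigns the participant data vectors to the
    fixed label vector before re-running the identical CV procedure — the
    same exchangeability null as relabeling, but every fold keeps the
    observed run's stratified class balance, which keeps the permutation
    accuracies calibrated against the (stratified) observed accuracy.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    seed = slparams.seed if fold_seed is None else fold_seed
    folds_idx = fold_partition(y, slparams.folds, seed)
    if permuted is None:
        rng = np.random.default_rng(permparams.seed)
        permuted = _permutation_indices(len(y), permparams.n_permutations, rng)
    count = 0
    for perm in permuted:
        acc = _pooled_accuracy(X[perm], y, folds_idx, spec, slparams.standardize)
        if acc > observed_accuracy:
            count += 1
    p = _estimate_p(count, len(permuted), permparams.estimator)
    return RegionPValue(center=(0, 0, 0), p=p, observed_accuracy=observed_accuracy)


def run_permutation_map(
    dataset: GroupedDataset,
    mask: Mask,
    group_a: str,
    group_b: str,
    region_stats: Sequence[RegionAccuracy],
    slparams: SearchlightParams,
    spec: ClassifierSpec,
    permparams: PermutationParams,
    regions: Optional[Sequence[RegionSpec]] = None,
) -> List[RegionPValue]:
    """Permutation p-value for every region in ``region_stats``.

    ``region_stats`` must come from ``run_searchlight`` on the same
    configuration (the observed accuracies and per-region fold seeds are
    reused). Reproducible from ``permparams.seed``.
    """
    if regions is None:
        regions = enumerate_regions(mask, slparams)
    by_center = {tuple(r.center): r for r in regions}
    shared: Optional[np.ndarray] = None
    out: List[RegionPValue] = []
    for stat in region_stats:
        center = tuple(stat.center)
        region = by_center.get(center)
        if region is None:
            raise ValueError(f"no enumerated region for center {center}")
        X, y = extract_features(dataset, region, group_a, group_b)
        if permparams.shared_permutations:
            if shared is None:
                rng = np.random.default_rng(permparams.seed)
                shared = _permutation_indices(len(y), permparams.n_permutations, rng)
            permuted = shared
        else:
            ss = np.random.SeedSequence((int(permparams.seed), *center))
            rng = np.random.default_rng(int(ss.generate_state(1)[0] % (2**31)))
            permuted = _permutation_indices(len(y), permparams.n_permutations, rng)
        res = permutation_pvalue(
            X,
            y,
            stat.accuracy,
            slparams,
            spec,
            permparams,
            fold_seed=region_fold_seed(slparams.seed, center),
            permuted=permuted,
        )
        out.append(RegionPValue(center=center, p=res.p, observed_accuracy=stat.accuracy))
    return out


def benjamini_hochberg(pvalues: Sequence[float], alpha: float = 0.05) -> FdrResult:
    """Benjamini–Hochberg step-up rule at FDR level ``alpha``.

    Sort p ascending, find k* = max{k : p(k) ≤ k·α/m}; declare significant
    every test with p ≤ p(k*). Ties are handled by the ≤ comparison. With an
    empty input or no qualifying rank, nothing is significant.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if p.size == 0:
        return FdrResult(alpha=alpha, significant=np.zeros(0, dtype=bool), k_star=0, threshold_p=float("nan"))
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ks = np.flatnonzero(p_sorted <= (np.arange(1, m + 1) * alpha / m))
    if ks.size == 0:
        return FdrResult(alpha=alpha, significant=np.zeros(m, dtype=bool), k_star=0, threshold_p=float("nan"))
    k_star = int(ks[-1]) + 1
    threshold = float(p_sorted[k_star - 1])
    return FdrResult(
        alpha=alpha,
        significant=p <= threshold,
        k_star=k_star,
        threshold_p=threshold,
    )
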