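"""Pairwise non-isomorphism distances between partial datasets.

The default metric converts the Pearson correlation cc of common unmerged
intensities into d = sqrt(1 - cc^2); the alternative metric is the maximal
absolute difference of the unit-cell lengths.  Pairs whose unit cells differ
by more than 1% in any parameter are assigned distance 1 (the "null
correlation" sentinel) before any intensity comparison, which flags outlier
crystals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reflection_io import PartialDataset
from .symmetry import (
    CrystalCell,
    cells_compatible,
    encode_keys,
    reduce_many,
)

__all__ = [
    "DistanceMatrix",
    "UndefinedCorrelation",
    "merged_key_arrays",
    "common_pairs",
    "correlation",
    "cc_to_distance",
    "distance_to_cc",
    "cell_distance",
    "build_matrix",
]

DEFAULT_N_MIN = 3


class UndefinedCorrelation(ValueError):
    """cc cannot be computed: too few common reflections or zero variance."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with common-reflection counts.

    ``n_common`` is populated only for the cc metric; for the cell metric it
    stays zero.
    """

    labels: list[str]
    d: np.ndarray
    n_common: np.ndarray
    metric: str = "cc"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)


def merged_key_arrays(
    ds: PartialDataset, anomalous: bool = False, d_min: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a dataset to one intensity per unique ASU key.

    Repeated observations of one reflection within a wedge are combined by
    the inverse-variance weighted mean, so the correlation between wedges is
    independent of per-wedge multiplicity.  Returns sorted encoded keys and
    the matching merged intensities.  ``d_min`` optionally discards
    higher-resolution observations before merging.
    """
    hkl = ds.hkl_array()
    intensity = ds.intensity_array()
    sigma = ds.sigma_array()
    if d_min is not None:
        from .symmetry import d_spacings

        keep = d_spacings(hkl, ds.cell) >= d_min - 1e-9
        hkl, intensity, sigma = hkl[keep], intensity[keep], sigma[keep]
        if len(hkl) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0)
    asu, parity = reduce_many(hkl, ds.spacegroup, anomalous=anomalous)
    codes = encode_keys(asu, parity if anomalous else None)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    w = 1.0 / sigma[order] ** 2
    wi = w * intensity[order]
    uniq, start = np.unique(codes, return_index=True)
    wsum = np.add.reduceat(w, start)
    wisum = np.add.reduceat(wi, start)
    return uniq, wisum / wsum


def common_pairs(
    ds_a: PartialDataset,
    ds_b: PartialDataset,
    anomalous: bool = False,
    d_min: float | None = None,
) -> list[tuple[float, float]]:
    """Paired per-reflection intensities over the shared unique keys.

    Each dataset is first collapsed per ASU key; the returned pairs cover
    the intersection of the two key sets in sorted-key order.
    """
    ka, ia = merged_key_arrays(ds_a, anomalous=anomalous, d_min=d_min)
    kb, ib = merged_key_arrays(ds_b, anomalous=anomalous, d_min=d_min)
    _, idx_a, idx_b = np.intersect1d(ka, kb, assume_unique=True, return_indices=True)
    return list(zip(ia[idx_a].tolist(), ib[idx_b].tolist()))


def correlation(pairs: Sequence[tuple[float, float]], n_min: int = DEFAULT_N_MIN) -> float:
    """Pearson correlation of paired common intensities.

    Raises :class:`UndefinedCorrelation` when fewer than ``n_min`` pairs are
    available or either vector has zero variance; callers map that to
    distance 1.
    """
    if len(pairs) < max(n_min, 2):
        raise UndefinedCorrelation(f"only {len(pairs)} common reflections")
    arr = np.asarray(pairs, dtype=float)
    sx = arr[:, 0].std()
    sy = arr[:, 1].std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelation("zero intensity variance")
    cc = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
    return max(-1.0, min(1.0, cc))


def cc_to_distance(cc: float | None) -> float:
    """Map a correlation coefficient to the non-isomorphism distance.

    d = sqrt(1 - cc^2) for cc > 0; anticorrelated or undefined pairs are
    maximally non-isomorphous (d = 1).
    """
    if cc is None or math.isnan(cc) or cc <= 0.0:
        return 1.0
    cc = min(cc, 1.0)
    return math.sqrt(1.0 - cc * cc)


def distance_to_cc(d: float) -> float:
    """Expected pairwise correlation at a linkage distance d (inverse map)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError("distance must lie in [0, 1]")
    return math.sqrt(1.0 - d * d)


def cell_distance(cell_a: CrystalCell, cell_b: CrystalCell) -> float:
    """Maximal absolute variation over the unit-cell lengths a, b, c (Angstrom)."""
    return max(abs(xa - xb) for xa, xb in zip(cell_a.lengths, cell_b.lengths))


def build_matrix(
    datasets: Sequence[PartialDataset],
    metric: str = "cc",
    anomalous: bool = False,
    n_min: int = DEFAULT_N_MIN,
    cell_tol: float = 0.01,
    d_min: float | None = None,
) -> DistanceMatrix:
    """Build the full pairwise distance matrix over a set of partial datasets.

    For the cc metric, any pair failing the unit-cell compatibility gate
    gets distance 1 without computing a correlation; mixed space groups are
    a hard error.  For the cell metric the maximal cell-length difference is
    always used.
    """
    n = len(datasets)
    if n < 2:
        raise ValueError("need at least two datasets to build a distance matrix")
    labels = [ds.id for ds in datasets]
    if len(set(labels)) != n:
        raise ValueError("dataset ids must be unique")
    d = np.zeros((n, n))
    n_common = np.zeros((n, n), dtype=np.int64)

    if metric == "cell":
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = cell_distance(datasets[i].cell, datasets[j].cell)
        return DistanceMatrix(labels=labels, d=d, n_common=n_common, metric="cell")

    if metric != "cc":
        raise ValueError(f"unknown metric {metric!r}")

    groups = {ds.spacegroup.number for ds in datasets}
    if len(groups) > 1:
        offenders = ", ".join(
            f"{ds.id}:{ds.spacegroup.number}" for ds in datasets
        )
        raise ValueError(f"cc metric requires one space group; got {offenders}")

    merged = [merged_key_arrays(ds, anomalous=anomalous, d_min=d_min) for ds in datasets]
    for i in range(n):
        ki, ii = merged[i]
        for j in range(i + 1, n):
            if not cells_compatible(datasets[i].cell, datasets[j].cell, tol=cell_tol):
                d[i, j] = d[j, i] = 1.0
                continue
            kj, ij = merged[j]
            _, xa, xb = np.intersect1d(ki, kj, assume_unique=True, return_indices=True)
            n_common[i, j] = n_common[j, i] = len(xa)
            try:
                cc = correlation(list(zip(ii[xa], ij[xb])), n_min=n_min)
            except UndefinedCorrelation:
                cc = None
            d[i, j] = d[j, i] = cc_to_distance(cc)
    return DistanceMatrix(labels=labels, d=d, n_common=n_common, metric="cc")
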