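"""Pooling, intensity merging and data-quality statistics.

Selected partial datasets are concatenated, reduced to the asymmetric unit
(with Friedel mates kept separate when anomalous signal is to be measured),
and merged by the inverse-variance weighted mean.  The statistics block
mirrors what multi-crystal merging programs report: completeness,
multiplicity, half-set correlation CC1/2, Rmerge/Rmeas/Rpim, <I/sigma> and
the mean anomalous signal sigAno, overall and in resolution shells of equal
volume in 1/d^3.

No inter-dataset scaling is applied by default; an optional per-dataset
multiplicative scale (median ratio against a running reference) can be
switched on for data that are not already on a common scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reflection_io import PartialDataset
from .symmetry import (
    AsuKey,
    CrystalCell,
    SpaceGroupInfo,
    d_spacings,
    decode_keys,
    encode_keys,
    reduce_many,
    unique_reflections,
)

__all__ = [
    "ObservationPool",
    "MergedReflection",
    "MergeStatistics",
    "pool",
    "merge_intensities",
    "r_factors",
    "cc_half",
    "sig_ano",
    "statistics",
]


@dataclass
class ObservationPool:
    """Concatenated observations of a cluster, tagged by ASU key and source.

    ``codes`` encodes the merged (h,k,l) representative without parity;
    ``parity`` carries the Bijvoet sign separately (0 when Friedel's law is
    assumed true or the reflection is centric).
    """

    codes: np.ndarray
    parity: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    source: np.ndarray
    d: np.ndarray
    cell: CrystalCell
    spacegroup: SpaceGroupInfo
    anomalous: bool

    def __len__(self) -> int:
        return len(self.codes)

    def group_codes(self) -> np.ndarray:
        """Merging keys: hkl code with the Bijvoet-minus bit set when anomalous.

        Matches the convention of :func:`isomerge.symmetry.encode_keys`, so
        these codes are directly comparable with the theoretical unique set.
        """
        if not self.anomalous:
            return self.codes
        return self.codes | (self.parity.astype(np.int64) == -1)


def pool(
    selection_members: Sequence[str],
    datasets: Sequence[PartialDataset],
    anomalous: bool = False,
    scale: bool = False,
) -> ObservationPool:
    """Concatenate the observations of the selected datasets.

    Every observation of every member appears exactly once, tagged by its
    source dataset index and ASU key.  With ``scale`` on, each dataset after
    the first is multiplied by the median intensity ratio of its common
    reflections against the running merged reference.
    """
    if len(set(selection_members)) != len(selection_members):
        raise ValueError("cluster members must be distinct")
    by_id = {ds.id: ds for ds in datasets}
    missing = [m for m in selection_members if m not in by_id]
    if missing:
        raise KeyError(f"member id(s) not found: {', '.join(missing)}")
    members = [by_id[m] for m in selection_members]
    sgs = {ds.spacegroup.number for ds in members}
    if len(sgs) > 1:
        raise ValueError(f"cannot pool datasets with mixed space groups: {sorted(sgs)}")

    codes_all, parity_all, i_all, s_all, src_all, d_all = [], [], [], [], [], []
    ref_sum: dict[int, float] = {}
    for idx, ds in enumerate(members):
        hkl = ds.hkl_array()
        asu, parity = reduce_many(hkl, ds.spacegroup, anomalous=anomalous)
        codes = encode_keys(asu)
        intensity = ds.intensity_array().copy()
        sigma = ds.sigma_array().copy()
        if scale:
            factor = _median_ratio_scale(codes, intensity, ref_sum)
            intensity *= factor
            sigma *= factor
            for c, i in zip(codes.tolist(), intensity.tolist()):
                ref_sum.setdefault(c, i)
        codes_all.append(codes)
        parity_all.append(parity)
        i_all.append(intensity)
        s_all.append(sigma)
        src_all.append(np.full(len(codes), idx, dtype=np.int32))
        d_all.append(d_spacings(hkl, ds.cell))
    return ObservationPool(
        codes=np.concatenate(codes_all),
        parity=np.concatenate(parity_all),
        intensity=np.concatenate(i_all),
        sigma=np.concatenate(s_all),
        source=np.concatenate(src_all),
        d=np.concatenate(d_all),
        cell=members[0].cell,
        spacegroup=members[0].spacegroup,
        anomalous=anomalous,
    )


def _median_ratio_scale(
    codes: np.ndarray, intensity: np.ndarray, ref: dict[int, float]
) -> float:
    if not ref:
        return 1.0
    ratios = []
    for c, i in zip(codes.tolist(), intensity.tolist()):
        r = ref.get(c)
        if r is not None and i > 0 and r > 0:
            ratios.append(r / i)
    if len(ratios) < 3:
        return 1.0
    return float(np.median(ratios))


@dataclass
class MergedReflection:
    """A unique reflection after merging.

    Friedel-separated fields are populated only when merging was anomalous;
    a missing mate leaves the corresponding fields ``None``.
    """

    key: AsuKey
    i_mean: float
    sigma: float
    multiplicity: int
    d: float
    i_plus: float | None = None
    sigma_plus: float | None = None
    n_plus: int = 0
    i_minus: float | None = None
    sigma_minus: float | None = None
    n_minus: int = 0


def _ivw(intensity: np.ndarray, sigma: np.ndarray) -> tuple[float, float]:
    w = 1.0 / sigma**2
    return float(np.sum(w * intensity) / np.sum(w)), float(math.sqrt(1.0 / np.sum(w)))


def merge_intensities(obs_pool: ObservationPool, anomalous: bool | None = None) -> list[MergedReflection]:
    """Merge the pool per unique reflection by inverse-variance weighting.

    i_mean = sum(I/sigma^2) / sum(1/sigma^2), sigma = sqrt(1/sum(1/sigma^2)).
    With anomalous on, the overall mean still pools both Friedel mates while
    the per-mate fields hold the separated merges.
    """
    if len(obs_pool) == 0:
        raise ValueError("empty observation pool")
    if anomalous is None:
        anomalous = obs_pool.anomalous
    order = np.argsort(obs_pool.codes, kind="stable")
    codes = obs_pool.codes[order]
    parity = obs_pool.parity[order]
    intensity = obs_pool.intensity[order]
    sigma = obs_pool.sigma[order]
    d = obs_pool.d[order]
    uniq, start = np.unique(codes, return_index=True)
    bounds = np.append(start, len(codes))
    hkl, _ = decode_keys(uniq)
    merged: list[MergedReflection] = []
    for n, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        i_mean, sig = _ivw(intensity[lo:hi], sigma[lo:hi])
        key = AsuKey(int(hkl[n, 0]), int(hkl[n, 1]), int(hkl[n, 2]),
                     "merged" if not anomalous else "plus")
        rec = MergedReflection(
            key=key,
            i_mean=i_mean,
            sigma=sig,
            multiplicity=hi - lo,
            d=float(d[lo:hi].mean()),
        )
        if anomalous:
            pp = parity[lo:hi] >= 0  # centrics (parity 0) counted with plus
            if pp.any():
                rec.i_plus, rec.sigma_plus = _ivw(intensity[lo:hi][pp], sigma[lo:hi][pp])
                rec.n_plus = int(pp.sum())
            mm = ~pp
            if mm.any():
                rec.i_minus, rec.sigma_minus = _ivw(intensity[lo:hi][mm], sigma[lo:hi][mm])
                rec.n_minus = int(mm.sum())
        merged.append(rec)
    return merged


def _group_slices(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    _, start = np.unique(sorted_codes, return_index=True)
    bounds = np.append(start, len(codes))
    return order, bounds[:-1], bounds[1:]


def r_factors(obs_pool: ObservationPool) -> tuple[float | None, float | None, float | None]:
    """(Rmerge, Rmeas, Rpim) over multiply-observed unique reflections.

    Rmerge = sum_h sum_i |I_i - <I>| / sum_h sum_i I_i with <I> the
    unweighted group mean; Rmeas corrects each group numerator by
    sqrt(n/(n-1)) and Rpim by sqrt(1/(n-1)).  Groups observed once are
    excluded from numerators and denominator; if no group has n >= 2 the
    R-factors are undefined (``None``).
    """
    codes = obs_pool.group_codes()
    order, lo_arr, hi_arr = _group_slices(codes)
    intensity = obs_pool.intensity[order]
    num_merge = num_meas = num_pim = denom = 0.0
    any_group = False
    for lo, hi in zip(lo_arr, hi_arr):
        n = hi - lo
        if n < 2:
            continue
        any_group = True
        vals = intensity[lo:hi]
        dev = np.abs(vals - vals.mean()).sum()
        num_merge += dev
        num_meas += dev * math.sqrt(n / (n - 1))
        num_pim += dev * math.sqrt(1.0 / (n - 1))
        denom += vals.sum()
    if not any_group or denom == 0:
        return None, None, None
    return num_merge / denom, num_meas / denom, num_pim / denom


def cc_half(obs_pool: ObservationPool, seed: int = 0) -> float | None:
    """Half-set correlation CC1/2 by random splitting.

    Observations of each multiply-observed unique reflection are shuffled
    and split into two halves; for odd groups the extra observation goes to
    alternating halves.  The Pearson correlation of the per-group half means
    across groups is returned; ``None`` when fewer than two usable groups
    exist.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    codes = obs_pool.group_codes()
    order, lo_arr, hi_arr = _group_slices(codes)
    intensity = obs_pool.intensity[order]
    half1, half2 = [], []
    toggle = 0
    for lo, hi in zip(lo_arr, hi_arr):
        n = hi - lo
        if n < 2:
            continue
        vals = intensity[lo:hi][rng.permutation(n)]
        split = n // 2
        if n % 2 == 1:
            split += toggle
            toggle = 1 - toggle
        half1.append(vals[:split].mean())
        half2.append(vals[split:].mean())
    if len(half1) < 2:
        return None
    a = np.asarray(half1)
    b = np.asarray(half2)
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def sig_ano(merged: Sequence[MergedReflection]) -> float | None:
    """Mean anomalous signal |I+ - I-| / sqrt(sigma+^2 + sigma-^2).

    Computed on intensities over keys with both Friedel mates measured;
    ``None`` when no key is eligible.  Under a null anomalous signal this
    statistic concentrates near the half-normal mean sqrt(2/pi) ~ 0.798.
    """
    vals = []
    for r in merged:
        if r.i_plus is not None and r.i_minus is not None:
            vals.append(
                abs(r.i_plus - r.i_minus) / math.sqrt(r.sigma_plus**2 + r.sigma_minus**2)
            )
    if not vals:
        return None
    return float(np.mean(vals))


@dataclass
class ShellStatistics:
    d_max: float
    d_min: float
    n_total: int
    n_unique: int
    completeness: float
    multiplicity: float
    cc_half: float | None
    r_merge: float | None
    r_meas: float | None
    r_pim: float | None
    i_over_sigma: float
    sig_ano: float | None


@dataclass
class MergeStatistics:
    """Overall and per-shell merging statistics."""

    overall: ShellStatistics
    shells: list[ShellStatistics]
    anomalous: bool
    seed: int

    def to_json(self) -> str:
        def row(s: ShellStatistics) -> dict:
            return {k: v for k, v in vars(s).items()}

        return json.dumps(
            {
                "anomalous": self.anomalous,
                "seed": self.seed,
                "overall": row(self.overall),
                "shells": [row(s) for s in self.shells],
            },
            indent=1,
        )

    def table(self) -> str:
        """Human-readable summary table."""
        o = self.overall
        lines = [
            f"Resolution range (A)        {o.d_max:.2f}-{o.d_min:.2f}",
            f"Total No. of reflections    {o.n_total}",
            f"No. of unique reflections   {o.n_unique}",
            f"Completeness (%)            {100 * o.completeness:.1f}",
            f"Multiplicity                {o.multiplicity:.1f}",
            f"Half-set correlation CC1/2  "
            + (f"{o.cc_half:.3f}" if o.cc_half is not None else "n/a"),
            f"<I/sigma(I)>                {o.i_over_sigma:.1f}",
            f"Rmerge                      "
            + (f"{o.r_merge:.3f}" if o.r_merge is not None else "n/a"),
            f"Rmeas                       "
            + (f"{o.r_meas:.3f}" if o.r_meas is not None else "n/a"),
            f"Rpim                        "
            + (f"{o.r_pim:.3f}" if o.r_pim is not None else "n/a"),
        ]
        if self.anomalous and o.sig_ano is not None:
            lines.append(f"sigAno                      {o.sig_ano:.3f}")
        return "\n".join(lines)


def _subset_pool(obs_pool: ObservationPool, mask: np.ndarray) -> ObservationPool:
    return ObservationPool(
        codes=obs_pool.codes[mask],
        parity=obs_pool.parity[mask],
        intensity=obs_pool.intensity[mask],
        sigma=obs_pool.sigma[mask],
        source=obs_pool.source[mask],
        d=obs_pool.d[mask],
        cell=obs_pool.cell,
        spacegroup=obs_pool.spacegroup,
        anomalous=obs_pool.anomalous,
    )


def _shell_stats(
    obs_pool: ObservationPool,
    merged: list[MergedReflection],
    theory_codes: np.ndarray,
    d_max: float,
    d_min: float,
    seed: int,
) -> ShellStatistics:
    anomalous = obs_pool.anomalous
    # with anomalous on, Bijvoet mates count separately, like the theory set
    observed = np.unique(obs_pool.group_codes())
    present = np.intersect1d(theory_codes, observed, assume_unique=True)
    n_unique = len(observed)
    n_total = len(obs_pool)
    rm, rme, rp = r_factors(obs_pool)
    cch = cc_half(obs_pool, seed=seed)
    ios = float(np.mean([r.i_mean / r.sigma for r in merged])) if merged else float("nan")
    sa = sig_ano(merged) if anomalous else None
    return ShellStatistics(
        d_max=d_max,
        d_min=d_min,
        n_total=n_total,
        n_unique=n_unique,
        completeness=len(present) / len(theory_codes) if len(theory_codes) else float("nan"),
        multiplicity=n_total / n_unique if n_unique else float("nan"),
        cc_half=cch,
        r_merge=rm,
        r_meas=rme,
        r_pim=rp,
        i_over_sigma=ios,
        sig_ano=sa,
    )


def statistics(
    obs_pool: ObservationPool,
    d_min: float | None = None,
    n_shells: int = 10,
    seed: int = 0,
) -> MergeStatistics:
    """Full statistics block for a merged pool, overall and per shell.

    Shells have equal volume in 1/d^3 between the observed d_max and
    ``d_min`` (default: highest resolution present in the pool).
    Completeness counts unique reflections present against the theoretical
    count for the pool's cell and space group.
    """
    if len(obs_pool) == 0:
        raise ValueError("empty observation pool")
    anomalous = obs_pool.anomalous
    if d_min is None:
        d_min = float(obs_pool.d.min())
    d_max = float(obs_pool.d.max())
    theory_codes, theory_d = unique_reflections(
        obs_pool.cell, obs_pool.spacegroup, d_min, anomalous=anomalous
    )
    # clip pool to resolution range
    keep = obs_pool.d >= d_min - 1e-9
    clipped = _subset_pool(obs_pool, keep)
    merged_all = merge_intensities(clipped)
    overall = _shell_stats(clipped, merged_all, theory_codes, d_max, d_min, seed)

    # equal-volume shells in 1/d^3
    s_lo = 1.0 / d_max**3
    s_hi = 1.0 / d_min**3
    edges_s = np.linspace(s_lo, s_hi, n_shells + 1)
    edges_d = edges_s ** (-1.0 / 3.0)
    shells = []
    s_pool = 1.0 / clipped.d**3
    s_theory = 1.0 / theory_d**3
    for i in range(n_shells):
        lo, hi = edges_s[i], edges_s[i + 1]
        if i == n_shells - 1:
            mask = (s_pool >= lo - 1e-12) & (s_pool <= hi + 1e-12)
            tmask = (s_theory >= lo - 1e-12) & (s_theory <= hi + 1e-12)
        else:
            mask = (s_pool >= lo - 1e-12) & (s_pool < hi)
            tmask = (s_theory >= lo - 1e-12) & (s_theory < hi)
        sub = _subset_pool(clipped, mask)
        merged_sub = merge_intensities(sub) if len(sub) else []
        shells.append(
            _shell_stats(
                sub,
                merged_sub,
                np.sort(theory_codes[tmask]),
                float(edges_d[i]),
                float(edges_d[i + 1]),
                seed,
            )
        )
    return MergeStatistics(overall=overall, shells=shells, anomalous=anomalous, seed=seed)
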