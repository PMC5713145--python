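"""Space-group-aware reflection bookkeeping.

Reciprocal-space symmetry for unmerged intensity data: reduction of Miller
indices to a canonical asymmetric-unit (ASU) representative, Friedel-pair
handling, d-spacing from the reciprocal metric tensor, enumeration of the
theoretically observable unique reflections (for completeness), and the
unit-cell compatibility gate used when screening dataset pairs.

A small set of space groups common in serial-crystallography test cases is
embedded as explicit operator tables; any other group can be constructed
from its International Tables number via :mod:`gemmi`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
import numpy as np

__all__ = [
    "CrystalCell",
    "SpaceGroupInfo",
    "AsuKey",
    "InvalidReflectionError",
    "reduce_to_asu",
    "reduce_many",
    "d_spacing",
    "d_spacings",
    "count_unique",
    "unique_reflections",
    "cells_compatible",
    "encode_keys",
    "decode_keys",
]


class InvalidReflectionError(ValueError):
    """Raised for Miller indices that carry no diffraction information."""


@dataclass(frozen=True)
class CrystalCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def parameters(self) -> tuple[float, ...]:
        return (*self.lengths, *self.angles)

    def reciprocal_metric(self) -> np.ndarray:
        """Inverse of the direct metric tensor G; 1/d^2 = h G* h^T."""
        al, be, ga = (math.radians(x) for x in self.angles)
        a, b, c = self.lengths
        g = np.array(
            [
                [a * a, a * b * math.cos(ga), a * c * math.cos(be)],
                [a * b * math.cos(ga), b * b, b * c * math.cos(al)],
                [a * c * math.cos(be), b * c * math.cos(al), c * c],
            ]
        )
        return np.linalg.inv(g)


# Explicit operator tables (ITA standard settings).  These keep the core
# reflection bookkeeping self-contained for the groups exercised in tests.
_EMBEDDED_TRIPLETS: dict[int, tuple[str, tuple[str, ...]]] = {
    1: ("P 1", ("x,y,z",)),
    19: (
        "P 21 21 21",
        (
            "x,y,z",
            "-x+1/2,-y,z+1/2",
            "x+1/2,-y+1/2,-z",
            "-x,y+1/2,-z+1/2",
        ),
    ),
    92: (
        "P 41 21 2",
        (
            "x,y,z",
            "-y+1/2,x+1/2,z+1/4",
            "-x,-y,z+1/2",
            "y+1/2,-x+1/2,z+3/4",
            "x+1/2,-y+1/2,-z+3/4",
            "-y,-x,-z+1/2",
            "-x+1/2,y+1/2,-z+1/4",
            "y,x,-z",
        ),
    ),
    94: (
        "P 42 21 2",
        (
            "x,y,z",
            "-y+1/2,x+1/2,z+1/2",
            "-x,-y,z",
            "y+1/2,-x+1/2,z+1/2",
            "x+1/2,-y+1/2,-z+1/2",
            "-y,-x,-z",
            "-x+1/2,y+1/2,-z+1/2",
            "y,x,-z",
        ),
    ),
    96: (
        "P 43 21 2",
        (
            "x,y,z",
            "-y+1/2,x+1/2,z+3/4",
            "-x,-y,z+1/2",
            "y+1/2,-x+1/2,z+1/4",
            "x+1/2,-y+1/2,-z+1/4",
            "-y,-x,-z+1/2",
            "-x+1/2,y+1/2,-z+3/4",
            "y,x,-z",
        ),
    ),
}


def _parse_triplet(triplet: str) -> tuple[np.ndarray, tuple[Fraction, ...]]:
    """Parse an 'x,y,z'-style operator into (rotation matrix, translation)."""
    rot = np.zeros((3, 3), dtype=np.int64)
    trans = []
    for i, term in enumerate(triplet.replace(" ", "").split(",")):
        shift = Fraction(0)
        j = 0
        sign = 1
        while j < len(term):
            ch = term[j]
            if ch == "+":
                sign, j = 1, j + 1
            elif ch == "-":
                sign, j = -1, j + 1
            elif ch in "xyz":
                rot[i, "xyz".index(ch)] = sign
                sign = 1
                j += 1
            else:
                k = j
                while k < len(term) and (term[k].isdigit() or term[k] == "/"):
                    k += 1
                shift += sign * Fraction(term[j:k])
                sign = 1
                j = k
        trans.append(shift % 1)
    return rot, tuple(trans)


@dataclass(frozen=True)
class SpaceGroupInfo:
    """A space group as an explicit list of (rotation, translation) operators.

    Rotations are 3x3 integer matrices acting on fractional coordinates;
    translations are exact fractions.  Reciprocal-space equivalence of a
    Miller index h is h' = h . R (row vector times matrix).
    """

    number: int
    symbol: str
    symops: tuple[tuple[np.ndarray, tuple[Fraction, ...]], ...] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.symops:
            raise ValueError("space group requires at least one operator")
        dets = [round(float(np.linalg.det(rot))) for rot, _ in self.symops]
        if any(abs(d) != 1 for d in dets):
            raise ValueError("rotation parts must have determinant +/-1")
        has_identity = any(
            np.array_equal(rot, np.eye(3, dtype=np.int64)) and all(t == 0 for t in tr)
            for rot, tr in self.symops
        )
        if not has_identity:
            raise ValueError("identity operation missing")

    @classmethod
    def from_number(cls, number: int) -> "SpaceGroupInfo":
        return _spacegroup_from_number(int(number))

    @property
    def rotations(self) -> np.ndarray:
        """All rotation parts stacked into an (n_ops, 3, 3) integer array."""
        return np.stack([rot for rot, _ in self.symops])

    @property
    def translations(self) -> np.ndarray:
        """Translation parts as floats, shape (n_ops, 3)."""
        return np.array([[float(t) for t in tr] for _, tr in self.symops])


@lru_cache(maxsize=64)
def _spacegroup_from_number(number: int) -> SpaceGroupInfo:
    if number in _EMBEDDED_TRIPLETS:
        symbol, triplets = _EMBEDDED_TRIPLETS[number]
    else:
        import gemmi

        sg = gemmi.find_spacegroup_by_number(number)
        if sg is None:
            raise ValueError(f"unknown space-group number {number}")
        symbol = sg.hm
        triplets = tuple(op.triplet() for op in sg.operations())
    symops = tuple(_parse_triplet(t) for t in triplets)
    return SpaceGroupInfo(number=number, symbol=symbol, symops=symops)


@dataclass(frozen=True)
class AsuKey:
    """Canonical ASU representative of a Miller index.

    ``friedel`` is ``"merged"`` when Friedel's law is assumed true, else
    ``"plus"``/``"minus"`` records which Bijvoet mate the observation is.
    """

    h: int
    k: int
    l: int
    friedel: str = "merged"

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


# --- vectorised core -------------------------------------------------------

def _orbit_max(hkl: np.ndarray, rotations: np.ndarray) -> np.ndarray:
    """Lexicographically greatest index over the rotational orbit of each row."""
    # equiv[i, j] = hkl[i] . R_j  -> shape (n, n_ops, 3)
    equiv = np.einsum("ni,oij->noj", hkl, rotations)
    # lexicographic max via a single comparable scalar per triple
    score = (
        (equiv[..., 0].astype(np.int64) + _OFF) * (1 << 40)
        + (equiv[..., 1].astype(np.int64) + _OFF) * (1 << 20)
        + (equiv[..., 2].astype(np.int64) + _OFF)
    )
    best = np.argmax(score, axis=1)
    return equiv[np.arange(len(hkl)), best]


def reduce_many(
    hkl: np.ndarray, sg: SpaceGroupInfo, anomalous: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce an (n, 3) array of Miller indices to ASU representatives.

    Returns ``(asu_hkl, parity)`` where parity is +1 / -1 for the Bijvoet
    mates and 0 for merged or centric reflections.
    """
    hkl = np.asarray(hkl, dtype=np.int64)
    if hkl.ndim != 2 or hkl.shape[1] != 3:
        raise ValueError("expected an (n, 3) index array")
    if np.any(np.all(hkl == 0, axis=1)):
        raise InvalidReflectionError("(0,0,0) is not a valid reflection")
    rot = sg.rotations
    plus = _orbit_max(hkl, rot)
    minus = _orbit_max(-hkl, rot)
    merged = _lexmax_pair(plus, minus)
    if not anomalous:
        return merged, np.zeros(len(hkl), dtype=np.int8)
    parity = np.zeros(len(hkl), dtype=np.int8)
    from_plus = np.all(merged == plus, axis=1)
    from_minus = np.all(merged == minus, axis=1)
    parity[from_plus & ~from_minus] = 1
    parity[from_minus & ~from_plus] = -1
    # centric reflections (both orbits meet) keep parity 0
    return merged, parity


def _lexmax_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    sa = (a[:, 0] + _OFF) * (1 << 40) + (a[:, 1] + _OFF) * (1 << 20) + (a[:, 2] + _OFF)
    sb = (b[:, 0] + _OFF) * (1 << 40) + (b[:, 1] + _OFF) * (1 << 20) + (b[:, 2] + _OFF)
    return np.where((sa >= sb)[:, None], a, b)


def reduce_to_asu(
    h: int, k: int, l: int, sg: SpaceGroupInfo, anomalous: bool = False
) -> AsuKey:
    """Map one Miller index to its canonical asymmetric-unit key.

    The canonical representative is the lexicographically greatest index in
    the symmetry orbit (including the Friedel-inverted orbit when
    ``anomalous`` is off or the reflection is centric).
    """
    asu, parity = reduce_many(np.array([[h, k, l]]), sg, anomalous=anomalous)
    if not anomalous:
        friedel = "merged"
    else:
        friedel = {1: "plus", -1: "minus", 0: "plus"}[int(parity[0])]
    return AsuKey(int(asu[0, 0]), int(asu[0, 1]), int(asu[0, 2]), friedel)


# --- integer key packing (20 bits per index + parity bit) ------------------

_OFF = 1 << 19


def encode_keys(asu_hkl: np.ndarray, parity: np.ndarray | None = None) -> np.ndarray:
    """Pack ASU indices (and optional Bijvoet parity) into sortable int64 codes."""
    h = asu_hkl[:, 0].astype(np.int64) + _OFF
    k = asu_hkl[:, 1].astype(np.int64) + _OFF
    l = asu_hkl[:, 2].astype(np.int64) + _OFF
    code = (h << 41) | (k << 21) | (l << 1)
    if parity is not None:
        code = code | (parity.astype(np.int64) == -1)
    return code


def decode_keys(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`encode_keys`; returns (hkl array, parity array)."""
    codes = np.asarray(codes, dtype=np.int64)
    minus = (codes & 1).astype(np.int8)
    l = ((codes >> 1) & 0xFFFFF) - _OFF
    k = ((codes >> 21) & 0xFFFFF) - _OFF
    h = (codes >> 41) - _OFF
    parity = np.where(minus == 1, -1, 1).astype(np.int8)
    return np.stack([h, k, l], axis=1), parity


# --- geometry ---------------------------------------------------------------

def d_spacings(hkl: np.ndarray, cell: CrystalCell) -> np.ndarray:
    """Resolution d (Angstrom) for each row of an (n, 3) index array."""
    hkl = np.asarray(hkl, dtype=float)
    gstar = cell.reciprocal_metric()
    inv_d2 = np.einsum("ni,ij,nj->n", hkl, gstar, hkl)
    if np.any(inv_d2 <= 0):
        raise InvalidReflectionError("(0,0,0) has no d-spacing")
    return 1.0 / np.sqrt(inv_d2)


def d_spacing(h: int, k: int, l: int, cell: CrystalCell) -> float:
    """Resolution of one reflection from the general metric-tensor form."""
    return float(d_spacings(np.array([[h, k, l]]), cell)[0])


# --- unique-reflection enumeration ------------------------------------------

def _systematic_absence_mask(hkl: np.ndarray, sg: SpaceGroupInfo) -> np.ndarray:
    """True where h.R == h for some operator whose h.t is non-integral."""
    absent = np.zeros(len(hkl), dtype=bool)
    for rot, trans in sg.symops:
        tr = np.array([float(t) for t in trans])
        if not tr.any():
            continue
        fixed = np.all(hkl @ rot == hkl, axis=1)
        if not fixed.any():
            continue
        phase = hkl[fixed] @ tr
        absent_here = np.abs(phase - np.round(phase)) > 1e-9
        idx = np.flatnonzero(fixed)
        absent[idx[absent_here]] = True
    return absent


@lru_cache(maxsize=16)
def _unique_cached(
    cell_params: tuple[float, ...], sg_number: int, d_min: float, anomalous: bool
) -> tuple[np.ndarray, np.ndarray]:
    cell = CrystalCell(*cell_params)
    sg = SpaceGroupInfo.from_number(sg_number)
    # conservative per-axis index bounds, then exact d filtering
    hmax = int(cell.a / d_min) + 2
    kmax = int(cell.b / d_min) + 2
    lmax = int(cell.c / d_min) + 2
    h = np.arange(-hmax, hmax + 1)
    k = np.arange(-kmax, kmax + 1)
    l = np.arange(-lmax, lmax + 1)
    grid = np.stack(np.meshgrid(h, k, l, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    d = d_spacings(grid, cell)
    grid = grid[d >= d_min - 1e-9]
    grid = grid[~_systematic_absence_mask(grid, sg)]
    asu, parity = reduce_many(grid, sg, anomalous=anomalous)
    codes = encode_keys(asu, parity if anomalous else None)
    codes, first = np.unique(codes, return_index=True)
    dvals = d_spacings(asu[first], cell)
    return codes, dvals


def unique_reflections(
    cell: CrystalCell, sg: SpaceGroupInfo, d_min: float, anomalous: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """All theoretically observable unique reflections to ``d_min``.

    Returns encoded ASU key codes (sorted) and their d-spacings, excluding
    systematic absences.  With ``anomalous`` on, acentric Bijvoet mates
    count as separate keys.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    codes, dvals = _unique_cached(cell.parameters(), sg.number, float(d_min), bool(anomalous))
    return codes.copy(), dvals.copy()


def count_unique(
    cell: CrystalCell, sg: SpaceGroupInfo, d_min: float, anomalous: bool = False
) -> int:
    """Number of theoretically observable unique reflections to ``d_min``."""
    codes, _ = unique_reflections(cell, sg, d_min, anomalous=anomalous)
    return int(len(codes))


# --- cell compatibility ------------------------------------------------------

def cells_compatible(cell_a: CrystalCell, cell_b: CrystalCell, tol: float = 0.01) -> bool:
    """Check all six cell parameters agree within a relative tolerance.

    The relative difference of every length and angle against the pair mean
    must not exceed ``tol`` (default 1%).  Pairs failing this gate are
    treated as maximally non-isomorphous before any intensity comparison.
    """
    for xa, xb in zip(cell_a.parameters(), cell_b.parameters()):
        mean = 0.5 * (xa + xb)
        if abs(xa - xb) / mean > tol:
            return False
    return True
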