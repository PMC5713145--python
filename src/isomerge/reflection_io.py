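"""Reading and writing unmerged reflection data.

Two plain-text dialects are read: the XDS-ASCII unmerged format
(``!FORMAT=XDS_ASCII`` header, ``ITEM_`` column declarations) and a minimal
whitespace table with a ``# cell`` / ``# spacegroup`` header, which is also
the format the synthetic-data generator writes.  Merged reflections,
distance matrices and linkage tables are written as documented text files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .symmetry import CrystalCell, SpaceGroupInfo

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import ClusterSelection, LinkageTree
    from .distance import DistanceMatrix
    from .merging import MergedReflection, MergeStatistics

logger = logging.getLogger(__name__)

__all__ = [
    "Observation",
    "PartialDataset",
    "Manifest",
    "FormatError",
    "read_xds_ascii",
    "read_reflection_file",
    "read_manifest",
    "write_dataset",
    "write_merged",
    "read_merged",
    "write_distance_matrix",
    "write_linkage_table",
    "write_outputs",
]


class FormatError(ValueError):
    """A reflection file or manifest violates its documented format."""


@dataclass(frozen=True)
class Observation:
    """One unmerged intensity measurement."""

    h: int
    k: int
    l: int
    intensity: float
    sigma: float


@dataclass
class PartialDataset:
    """One crystal's unmerged observations plus cell and space group.

    The unit of clustering: a small rotation wedge, typically a few percent
    complete on its own.  Observations are stored as parallel arrays
    (``hkl``, ``intensity``, ``sigma``) in file order; the ``observations``
    property offers them as :class:`Observation` records.
    """

    id: str
    cell: CrystalCell
    spacegroup: SpaceGroupInfo
    hkl: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    wavelength: float | None = None
    source: str | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.hkl) == 0:
            raise FormatError(f"dataset {self.id!r} has no usable observations")
        if not (len(self.hkl) == len(self.intensity) == len(self.sigma)):
            raise ValueError("hkl, intensity and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("all stored sigmas must be positive")

    @classmethod
    def from_observations(
        cls,
        id: str,
        cell: CrystalCell,
        spacegroup: SpaceGroupInfo,
        observations: Sequence[Observation],
        **kwargs,
    ) -> "PartialDataset":
        return cls(
            id=id,
            cell=cell,
            spacegroup=spacegroup,
            hkl=np.array([[o.h, o.k, o.l] for o in observations], dtype=np.int64),
            intensity=np.array([o.intensity for o in observations]),
            sigma=np.array([o.sigma for o in observations]),
            **kwargs,
        )

    @property
    def observations(self) -> list[Observation]:
        return [
            Observation(int(h), int(k), int(l), float(i), float(s))
            for (h, k, l), i, s in zip(self.hkl, self.intensity, self.sigma)
        ]

    def hkl_array(self) -> np.ndarray:
        return self.hkl

    def intensity_array(self) -> np.ndarray:
        return self.intensity

    def sigma_array(self) -> np.ndarray:
        return self.sigma

    def __len__(self) -> int:
        return len(self.hkl)


@dataclass
class Manifest:
    """Ordered list of (dataset id, file path) driving one clustering run."""

    entries: list[tuple[str, Path]]
    metric: str = "cc"
    options: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def load(self) -> list[PartialDataset]:
        return [read_reflection_file(path, dataset_id=ds_id) for ds_id, path in self.entries]


# --- readers -----------------------------------------------------------------

def _build_dataset(
    dataset_id: str,
    cell: CrystalCell,
    sg: SpaceGroupInfo,
    rows: list[tuple[int, int, int, float, float]],
    wavelength: float | None,
    source: str,
) -> PartialDataset:
    if not rows:
        raise FormatError(f"{source}: no usable observations (empty data block)")
    arr = np.array(rows, dtype=float)
    keep = arr[:, 4] > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d observation(s) with sigma <= 0", dataset_id, dropped)
    arr = arr[keep]
    if len(arr) == 0:
        raise FormatError(f"{source}: no usable observations (all sigma <= 0)")
    return PartialDataset(
        id=dataset_id,
        cell=cell,
        spacegroup=sg,
        hkl=arr[:, :3].astype(np.int64),
        intensity=arr[:, 3],
        sigma=arr[:, 4],
        wavelength=wavelength,
        source=source,
        n_dropped=dropped,
    )


def read_xds_ascii(path: str | Path, dataset_id: str | None = None) -> PartialDataset:
    """Read one unmerged XDS-ASCII reflection file.

    Header lines start with ``!``; the unit cell, space-group number and the
    H/K/L/IOBS/SIGMA column positions are taken from the header.  Extra
    columns are ignored.  Observations with sigma <= 0 (XDS misfit flag) are
    dropped and counted in ``n_dropped``.
    """
    path = Path(path)
    cell = None
    sg_number = None
    wavelength = None
    columns: dict[str, int] = {}
    rows: list[tuple[int, int, int, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!"):
                body = line[1:].strip()
                if body.startswith("UNIT_CELL_CONSTANTS="):
                    vals = [float(x) for x in body.split("=", 1)[1].split()]
                    if len(vals) != 6:
                        raise FormatError(f"{path}: malformed UNIT_CELL_CONSTANTS")
                    cell = CrystalCell(*vals)
                elif body.startswith("SPACE_GROUP_NUMBER="):
                    sg_number = int(float(body.split("=", 1)[1]))
                elif body.startswith("X-RAY_WAVELENGTH="):
                    wavelength = float(body.split("=", 1)[1].split()[0])
                elif body.startswith("ITEM_"):
                    name, pos = body[5:].split("=", 1)
                    columns[name.strip()] = int(pos) - 1
                elif body.startswith("END_OF_DATA"):
                    break
                continue
            if not line.strip():
                continue
            fields = line.split()
            try:
                ih, ik, il = columns["H"], columns["K"], columns["L"]
                ii, isig = columns["IOBS"], columns["SIGMA(IOBS)"]
            except KeyError as exc:
                raise FormatError(f"{path}: missing ITEM_{exc.args[0]} column declaration") from None
            rows.append(
                (
                    int(fields[ih]),
                    int(fields[ik]),
                    int(fields[il]),
                    float(fields[ii]),
                    float(fields[isig]),
                )
            )
    if cell is None:
        raise FormatError(f"{path}: missing UNIT_CELL_CONSTANTS header")
    if sg_number is None:
        raise FormatError(f"{path}: missing SPACE_GROUP_NUMBER header")
    ds_id = dataset_id or path.stem
    return _build_dataset(ds_id, cell, SpaceGroupInfo.from_number(sg_number), rows, wavelength, str(path))


def _read_table(path: Path, dataset_id: str | None) -> PartialDataset:
    cell = None
    sg_number = None
    wavelength = None
    rows: list[tuple[int, int, int, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if not parts:
                    continue
                if parts[0] == "cell":
                    if len(parts) != 7:
                        raise FormatError(f"{path}:{lineno}: '# cell' needs six values")
                    cell = CrystalCell(*(float(x) for x in parts[1:]))
                elif parts[0] == "spacegroup":
                    sg_number = int(parts[1])
                elif parts[0] == "wavelength":
                    wavelength = float(parts[1])
                continue
            fields = line.split()
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected 'h k l I sigma'")
            rows.append(
                (int(fields[0]), int(fields[1]), int(fields[2]), float(fields[3]), float(fields[4]))
            )
    if cell is None:
        raise FormatError(f"{path}: missing '# cell' header")
    if sg_number is None:
        raise FormatError(f"{path}: missing '# spacegroup' header")
    ds_id = dataset_id or path.stem
    return _build_dataset(ds_id, cell, SpaceGroupInfo.from_number(sg_number), rows, wavelength, str(path))


def read_reflection_file(path: str | Path, dataset_id: str | None = None) -> PartialDataset:
    """Read a reflection file, auto-detecting XDS-ASCII vs the plain table."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!"):
        return read_xds_ascii(path, dataset_id=dataset_id)
    return _read_table(path, dataset_id)


def read_manifest(path: str | Path, metric: str = "cc", **options) -> Manifest:
    """Read a manifest: one dataset per line, ``id path`` or just ``path``.

    Dataset ids default to the file stem.  Duplicate ids or paths are
    rejected with the offending line numbers.
    """
    path = Path(path)
    entries: list[tuple[str, Path]] = []
    seen_ids: dict[str, int] = {}
    seen_paths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 1:
                entry_path = Path(parts[0])
                ds_id = entry_path.stem
            else:
                ds_id, entry_path = parts[0], Path(parts[1])
            if ds_id in seen_ids:
                raise FormatError(
                    f"{path}: duplicate dataset id {ds_id!r} on lines {seen_ids[ds_id]} and {lineno}"
                )
            key = str(entry_path)
            if key in seen_paths:
                raise FormatError(
                    f"{path}: duplicate path {key!r} on lines {seen_paths[key]} and {lineno}"
                )
            if not entry_path.is_absolute():
                entry_path = path.parent / entry_path
            if not entry_path.exists():
                raise OSError(f"{path}:{lineno}: dataset file not found: {entry_path}")
            seen_ids[ds_id] = lineno
            seen_paths[key] = lineno
            entries.append((ds_id, entry_path))
    return Manifest(entries=entries, metric=metric, options=dict(options))


# --- writers -----------------------------------------------------------------

def write_dataset(ds: PartialDataset, path: str | Path) -> None:
    """Write a partial dataset in the plain whitespace-table dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        c = ds.cell
        fh.write(f"# cell {c.a:.4f} {c.b:.4f} {c.c:.4f} {c.alpha:.4f} {c.beta:.4f} {c.gamma:.4f}\n")
        fh.write(f"# spacegroup {ds.spacegroup.number}\n")
        if ds.wavelength is not None:
            fh.write(f"# wavelength {ds.wavelength:.6f}\n")
        fh.write("# columns h k l intensity sigma\n")
        for (h, k, l), i, s in zip(ds.hkl, ds.intensity, ds.sigma):
            fh.write(f"{h} {k} {l} {i:.6g} {s:.6g}\n")


def write_merged(
    merged: Sequence["MergedReflection"],
    cell: CrystalCell,
    sg: SpaceGroupInfo,
    anomalous: bool,
    path: str | Path,
) -> None:
    """Write merged unique reflections as a documented text table."""
    path = Path(path)
    with open(path, "w") as fh:
        c = cell
        fh.write(f"# cell {c.a:.4f} {c.b:.4f} {c.c:.4f} {c.alpha:.4f} {c.beta:.4f} {c.gamma:.4f}\n")
        fh.write(f"# spacegroup {sg.number}\n")
        fh.write(f"# anomalous {'on' if anomalous else 'off'}\n")
        if anomalous:
            fh.write(
                "# columns h k l imean sigma multiplicity"
                " iplus sigplus nplus iminus sigminus nminus\n"
            )
        else:
            fh.write("# columns h k l imean sigma multiplicity\n")
        for r in merged:
            base = f"{r.key.h} {r.key.k} {r.key.l} {r.i_mean:.6g} {r.sigma:.6g} {r.multiplicity}"
            if anomalous:
                def fmt(x):
                    return "nan" if x is None else f"{x:.6g}"

                base += (
                    f" {fmt(r.i_plus)} {fmt(r.sigma_plus)} {r.n_plus}"
                    f" {fmt(r.i_minus)} {fmt(r.sigma_minus)} {r.n_minus}"
                )
            fh.write(base + "\n")


def read_merged(path: str | Path):
    """Read back a merged reflection file written by :func:`write_merged`.

    Returns ``(records, cell, sg_number, anomalous)`` with records as a list
    of dicts keyed by the column names.
    """
    path = Path(path)
    cell = None
    sg_number = None
    anomalous = False
    colnames: list[str] = []
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[0] == "cell":
                    cell = CrystalCell(*(float(x) for x in parts[1:7]))
                elif parts[0] == "spacegroup":
                    sg_number = int(parts[1])
                elif parts[0] == "anomalous":
                    anomalous = parts[1] == "on"
                elif parts[0] == "columns":
                    colnames = parts[1:]
                continue
            fields = line.split()
            rec = {}
            for name, value in zip(colnames, fields):
                if name in ("h", "k", "l", "multiplicity", "nplus", "nminus"):
                    rec[name] = int(value)
                else:
                    rec[name] = float(value)
            records.append(rec)
    return records, cell, sg_number, anomalous


def write_distance_matrix(dm: "DistanceMatrix", path: str | Path) -> None:
    """Write a labelled square distance matrix as text."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# metric {dm.metric}\n")
        fh.write("labels " + " ".join(dm.labels) + "\n")
        for label, row in zip(dm.labels, dm.d):
            fh.write(label + " " + " ".join(f"{x:.6f}" for x in row) + "\n")


def write_linkage_table(tree: "LinkageTree", path: str | Path) -> None:
    """One merge per row: left_node right_node height new_size.

    Leaves are numbered 0..N-1 in manifest order; internal nodes N, N+1, ...
    in merge order.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# left_node right_node height new_size\n")
        for left, right, height, size in tree.merges:
            fh.write(f"{left} {right} {height:.6f} {size}\n")


def write_outputs(
    outdir: str | Path,
    dm: "DistanceMatrix",
    tree: "LinkageTree",
    selection: "ClusterSelection",
    merged_results: Sequence[tuple[list, "MergeStatistics"]],
    cell: CrystalCell,
    sg: SpaceGroupInfo,
    anomalous: bool,
) -> list[Path]:
    """Write the run-level matrix/linkage plus one directory per merged cluster.

    ``merged_results[i]`` pairs the merged reflections and statistics of
    ``selection.clusters[i]``; a cluster whose entry is ``None`` (e.g. a
    singleton skipped from merging) gets no directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_distance_matrix(dm, outdir / "distance_matrix.txt")
    write_linkage_table(tree, outdir / "linkage.txt")
    written: list[Path] = []
    if not any(res is not None for res in merged_results):
        warnings.warn("no clusters merged; nothing to write", stacklevel=2)
        return written
    for i, (members, result) in enumerate(zip(selection.clusters, merged_results)):
        if result is None:
            continue
        merged, stats = result
        cdir = outdir / f"cluster_{i:03d}"
        cdir.mkdir(exist_ok=True)
        write_merged(merged, cell, sg, anomalous, cdir / "merged.refl")
        with open(cdir / "members.txt", "w") as fh:
            fh.write("\n".join(members) + "\n")
        with open(cdir / "threshold.txt", "w") as fh:
            fh.write(f"{selection.threshold:.6f}\n")
        with open(cdir / "statistics.json", "w") as fh:
            fh.write(stats.to_json())
        written.append(cdir)
    return written
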